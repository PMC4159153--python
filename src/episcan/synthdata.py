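"""Synthetic cohorts and annotation tracks with the structure the scan assumes.

The generator produces LD-structured biallelic genotypes (a one-parameter
left-neighbour copying model), optional sibling pairs for relatedness,
quantitative phenotypes decomposed into additive/dominance marginal effects,
centred 3x3 epistatic effect matrices, covariate effects, a polygenic
background of stated heritability and i.i.d. environmental noise, plus
enhancer (BED) and chromatin-interaction (BEDPE) tracks.  Every stochastic
call threads one numpy Generator seeded explicitly; identical seeds give
bit-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, make_marker_map, validate_marker_map

__all__ = [
    "EffectSpec",
    "HaplotypePanel",
    "SyntheticCohort",
    "simulate_haplotypes",
    "simulate_genotypes",
    "simulate_phenotype",
    "simulate_covariates",
    "simulate_annotations",
    "simulate_cohort",
    "inject_missing",
    "uniform_marker_map",
    "additive_effect_for_variance",
    "center_epistasis",
    "interaction_variance",
    "xor_matrix",
]


# ---------------------------------------------------------------------------
# effect specification
# ---------------------------------------------------------------------------

@dataclass
class EffectSpec:
    """Planted genetic architecture of a synthetic trait.

    marginal maps snp_id -> (a, d): additive effect a per alternate allele and
    dominance deviation d for heterozygotes, in trait units.  epistatic maps an
    ordered (snp1, snp2) pair to a 3x3 genotype-combination effect matrix
    (row = genotype of snp1).  h2_poly is the polygenic heritability
    sigma_g^2/(sigma_g^2+sigma_e^2) of the non-fixed part of the trait;
    sigma_e is the environmental SD in trait units.
    """

    marginal: dict = field(default_factory=dict)
    epistatic: dict = field(default_factory=dict)
    h2_poly: float = 0.0
    covariate_effects: dict = field(default_factory=dict)
    sigma_e: float = 1.0

    def validate(self, markers: pd.DataFrame) -> None:
        ids = set(markers["snp_id"])
        for s in self.marginal:
            if s not in ids:
                raise ValueError(f"marginal effect references unknown SNP {s!r}")
        for s1, s2 in self.epistatic:
            if s1 not in ids or s2 not in ids:
                raise ValueError(f"epistatic pair ({s1!r}, {s2!r}) references unknown SNP")
        if not (0.0 <= self.h2_poly < 1.0):
            raise ValueError("h2_poly must be in [0, 1)")
        if self.sigma_e < 0:
            raise ValueError("sigma_e must be non-negative")


def additive_effect_for_variance(p: float, target_var: float) -> float:
    """Additive effect size a with explained variance a^2 * 2p(1-p) = target_var."""
    return float(np.sqrt(target_var / (2.0 * p * (1.0 - p))))


def _hwe_probs(p: float) -> np.ndarray:
    q = 1.0 - p
    return np.array([q * q, 2 * p * q, p * p])


def center_epistasis(mat: np.ndarray, p1: float, p2: float) -> np.ndarray:
    """Double-centre a 3x3 effect matrix under HWE genotype frequencies.

    After centring the matrix contributes no marginal (row/column mean)
    effect at either locus, so the planted interaction variance has the
    closed form given by :func:`interaction_variance`.
    """
    mat = np.asarray(mat, dtype=np.float64)
    w1, w2 = _hwe_probs(p1), _hwe_probs(p2)
    row = mat @ w2
    col = w1 @ mat
    grand = w1 @ mat @ w2
    return mat - row[:, None] - col[None, :] + grand


def interaction_variance(mat: np.ndarray, p1: float, p2: float) -> float:
    """Variance contributed by a centred 3x3 matrix at two independent HWE loci."""
    w1, w2 = _hwe_probs(p1), _hwe_probs(p2)
    mean = w1 @ mat @ w2
    return float(w1 @ (np.asarray(mat) ** 2) @ w2 - mean ** 2)


def xor_matrix(scale: float = 1.0) -> np.ndarray:
    """XOR-like pure-interaction pattern: corners and centre +1, edges -1."""
    m = np.array([[1.0, -1.0, 1.0], [-1.0, 1.0, -1.0], [1.0, -1.0, 1.0]])
    return scale * m


# ---------------------------------------------------------------------------
# haplotypes and genotypes
# ---------------------------------------------------------------------------

@dataclass
class HaplotypePanel:
    haplotypes: np.ndarray  # uint8 (n_hap, n_snps)
    markers: pd.DataFrame
    freqs: np.ndarray

    @property
    def n_hap(self) -> int:
        return self.haplotypes.shape[0]


def uniform_marker_map(n_snps: int, spacing_bp: int = 5000, chrom: str = "1",
                       start: int = 10_000) -> pd.DataFrame:
    """Evenly spaced marker map on one chromosome (convenience for fixtures)."""
    pos = start + spacing_bp * np.arange(n_snps, dtype=np.int64)
    return make_marker_map([f"rs{chrom}_{i}" for i in range(n_snps)], [chrom] * n_snps, pos)


def simulate_haplotypes(n_hap: int, markers: pd.DataFrame, ld_decay_bp: float = 50_000.0,
                        maf_range=(0.05, 0.5), seed: int = 0) -> HaplotypePanel:
    """Simulate a 0/1 haplotype panel with distance-decaying LD.

    LD comes from a left-neighbour copying kernel: each haplotype carries a
    latent uniform that is re-drawn at site j with probability
    1 - exp(-delta_bp / ld_decay_bp) and otherwise copied from site j-1; the
    allele is the indicator u < p_j.  Copying the uniform (not the allele)
    preserves each site's target frequency exactly while giving comonotone
    correlation between neighbours, so mean r^2 decays monotonically with
    distance and two co-located same-frequency sites are in complete LD.
    """
    if n_hap < 2:
        raise ValueError("n_hap must be >= 2")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    validate_marker_map(markers)
    rng = np.random.default_rng(seed)
    m = len(markers)
    freqs = rng.uniform(lo, hi, size=m)

    pos = markers["pos"].to_numpy()
    chrom = markers["chrom"].to_numpy()
    hap = np.empty((n_hap, m), dtype=np.uint8)
    u = rng.random(n_hap)
    hap[:, 0] = u < freqs[0]
    for j in range(1, m):
        if chrom[j] != chrom[j - 1]:
            switch_p = 1.0
        else:
            delta = pos[j] - pos[j - 1]
            if ld_decay_bp <= 0:
                switch_p = 1.0
            else:
                switch_p = 1.0 - np.exp(-delta / ld_decay_bp)
        fresh = rng.random(n_hap)
        switch = rng.random(n_hap) < switch_p
        u = np.where(switch, fresh, u)
        hap[:, j] = u < freqs[j]
    return HaplotypePanel(hap, markers.reset_index(drop=True), freqs)


def simulate_genotypes(panel: HaplotypePanel, n_samples: int, n_families: int = 0,
                       seed: int = 0):
    """Draw diploid genotypes from a haplotype panel.

    Returns (GenotypeMatrix, kinship_true).  Haplotypes are sampled with
    replacement, so any panel size supports any cohort size.  The first
    2*n_families samples form sibling pairs: each pair shares two parental
    haplotype pairs and each sib inherits one haplotype per parent at random,
    giving expected kinship 0.25.  kinship_true is on the kinship-coefficient
    scale (diagonal 0.5, unrelated 0) with the sib entries set to the
    realised identity-by-descent sharing.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if 2 * n_families > n_samples:
        raise ValueError("not enough samples for the requested families")
    rng = np.random.default_rng(seed)
    H = panel.haplotypes
    nh = panel.n_hap
    g = np.empty((n_samples, H.shape[1]), dtype=np.int8)
    kinship = np.zeros((n_samples, n_samples))
    np.fill_diagonal(kinship, 0.5)

    s = 0
    for _ in range(n_families):
        mom = rng.integers(0, nh, size=2)
        dad = rng.integers(0, nh, size=2)
        picks = rng.integers(0, 2, size=4)  # sib1 (mom, dad), sib2 (mom, dad)
        g[s] = H[mom[picks[0]]].astype(np.int8) + H[dad[picks[1]]]
        g[s + 1] = H[mom[picks[2]]].astype(np.int8) + H[dad[picks[3]]]
        realised = (int(picks[0] == picks[2]) + int(picks[1] == picks[3])) / 4.0
        kinship[s, s + 1] = kinship[s + 1, s] = realised
        s += 2
    n_rest = n_samples - s
    if n_rest:
        idx = rng.integers(0, nh, size=(n_rest, 2))
        g[s:] = H[idx[:, 0]].astype(np.int8) + H[idx[:, 1]]

    gm = GenotypeMatrix(g, panel.markers.copy())
    return gm, kinship


def inject_missing(g: GenotypeMatrix, rate: float, seed: int = 0) -> GenotypeMatrix:
    """Set a uniformly random fraction of calls to missing (post-phenotype)."""
    if not (0.0 <= rate < 1.0):
        raise ValueError("missing rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    geno = g.genotypes.copy()
    mask = rng.random(geno.shape) < rate
    geno[mask] = MISSING
    return GenotypeMatrix(geno, g.markers.copy(), g.samples.copy())


# ---------------------------------------------------------------------------
# phenotype and covariates
# ---------------------------------------------------------------------------

COVARIATE_COLUMNS = ["sex", "age", "bmi", "creatinine", "treatment", "centre"]


def simulate_covariates(n_samples: int, seed: int = 0) -> pd.DataFrame:
    """Cohort-style covariates: sex, age, BMI, creatinine, treatment flag, centre."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "sex": rng.integers(0, 2, n_samples),
            "age": rng.normal(54.0, 6.0, n_samples).round(1),
            "bmi": rng.normal(27.0, 4.5, n_samples).round(1),
            "creatinine": rng.normal(1.0, 0.2, n_samples).round(3),
            "treatment": rng.integers(0, 2, n_samples),
            "centre": rng.integers(0, 4, n_samples),
        }
    )


def simulate_phenotype(g: GenotypeMatrix, spec: EffectSpec, covariates: pd.DataFrame | None = None,
                       kinship: np.ndarray | None = None, seed: int = 0) -> pd.DataFrame:
    """Simulate a quantitative trait from a planted architecture.

    y = sum additive+dominance marginal terms + sum centred 3x3 epistatic
    lookups + covariate terms + polygenic draw N(0, sigma_g^2 * 2K) + noise
    N(0, sigma_e^2), with sigma_g^2 = h2_poly/(1-h2_poly) * sigma_e^2 so the
    polygenic heritability of the non-fixed part equals spec.h2_poly.

    Returns a phenotype table (sample_id, trait, covariates).  Missing
    genotypes (if any were already injected) contribute their SNP's mean
    coded value.
    """
    spec.validate(g.markers)
    rng = np.random.default_rng(seed)
    n = g.n_samples
    y = np.zeros(n)

    freqs = g.allele_freq()

    def snp_dosage(snp):
        idx = g.index_of(snp)
        d = g.genotypes[:, idx].astype(np.float64)
        miss = d == MISSING
        if miss.any():
            d[miss] = 2.0 * freqs[idx]
        return d, idx

    for snp, (a, d_eff) in spec.marginal.items():
        dos, _ = snp_dosage(snp)
        y += a * dos + d_eff * (dos == 1)

    for (s1, s2), mat in spec.epistatic.items():
        d1, i1 = snp_dosage(s1)
        d2, i2 = snp_dosage(s2)
        for snp, idx in ((s1, i1), (s2, i2)):
            if freqs[idx] in (0.0, 1.0) or np.isnan(freqs[idx]):
                warnings.warn(
                    f"epistatic pair references monomorphic SNP {snp!r}; "
                    "its effect is inestimable downstream",
                    stacklevel=2,
                )
        mat = np.asarray(mat, dtype=np.float64)
        y += mat[np.clip(np.rint(d1), 0, 2).astype(int), np.clip(np.rint(d2), 0, 2).astype(int)]

    if covariates is not None:
        for cov, beta in spec.covariate_effects.items():
            y += beta * covariates[cov].to_numpy(dtype=np.float64)

    if spec.h2_poly > 0:
        if kinship is None:
            raise ValueError("h2_poly > 0 requires a kinship matrix")
        sigma_g2 = spec.h2_poly / (1.0 - spec.h2_poly) * spec.sigma_e ** 2
        # relationship matrix A = 2K; draw u ~ N(0, sigma_g2 * A)
        w, v = np.linalg.eigh(2.0 * np.asarray(kinship))
        w = np.clip(w, 0.0, None)
        y += v @ (np.sqrt(sigma_g2 * w) * rng.standard_normal(n))

    y += rng.normal(0.0, spec.sigma_e, n)

    out = pd.DataFrame({"sample_id": g.samples, "trait": y})
    if covariates is not None:
        out = pd.concat([out, covariates.reset_index(drop=True)], axis=1)
    return out


# ---------------------------------------------------------------------------
# annotation tracks
# ---------------------------------------------------------------------------

def simulate_annotations(markers: pd.DataFrame, enhancer_density: float = 0.05,
                         chiapet_rate: float = 20.0, seed: int = 0,
                         interval_mean_bp: float = 2000.0):
    """Synthetic enhancer BED and chromatin-interaction BEDPE tracks.

    Enhancer intervals are laid down per chromosome as an alternating
    gap/interval renewal process with exponential lengths chosen so the
    covered fraction of the mapped span is approximately enhancer_density.
    chiapet_rate is the expected number of interactions per Mb of mapped
    span; anchors are 2-kb intervals at random positions within the span.
    Returns (bed DataFrame [chrom,start,end,name], bedpe DataFrame
    [chrom1,start1,end1,chrom2,start2,end2,name,score]); BED/BEDPE
    coordinates are 0-based half-open.
    """
    if len(markers) == 0:
        raise ValueError("empty marker map")
    if not (0.0 <= enhancer_density < 1.0):
        raise ValueError("enhancer_density must be in [0, 1)")
    rng = np.random.default_rng(seed)

    bed_rows, bedpe_rows = [], []
    k_bed = k_pet = 0
    for chrom, sub in markers.groupby("chrom", sort=False):
        lo = int(sub["pos"].min()) - 1
        hi = int(sub["pos"].max())
        span = max(hi - lo, 1)

        if enhancer_density > 0:
            mean_gap = interval_mean_bp * (1.0 - enhancer_density) / enhancer_density
            x = lo + rng.exponential(mean_gap)
            while x < hi:
                length = max(int(rng.exponential(interval_mean_bp)), 50)
                start = int(x)
                end = min(start + length, hi)
                bed_rows.append((chrom, start, end, f"enh{k_bed}"))
                k_bed += 1
                x = end + rng.exponential(mean_gap)

        n_int = rng.poisson(chiapet_rate * span / 1e6)
        anchor = 2000
        for _ in range(n_int):
            a1 = int(rng.integers(lo, max(hi - anchor, lo + 1)))
            a2 = int(rng.integers(lo, max(hi - anchor, lo + 1)))
            s1, s2 = sorted((a1, a2))
            bedpe_rows.append((chrom, s1, s1 + anchor, chrom, s2, s2 + anchor,
                               f"loop{k_pet}", 1))
            k_pet += 1

    bed = pd.DataFrame(bed_rows, columns=["chrom", "start", "end", "name"])
    bedpe = pd.DataFrame(
        bedpe_rows,
        columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2", "name", "score"],
    )
    bed = bed.sort_values(["chrom", "start"]).reset_index(drop=True)
    bedpe = bedpe.sort_values(["chrom1", "start1"]).reset_index(drop=True)
    return bed, bedpe


# ---------------------------------------------------------------------------
# one-call cohort bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    genotypes: GenotypeMatrix
    phenotype: pd.DataFrame
    kinship_true: np.ndarray
    effects: EffectSpec
    seed: int

    def __post_init__(self):
        n = self.genotypes.n_samples
        if len(self.phenotype) != n or self.kinship_true.shape != (n, n):
            raise ValueError("row counts disagree across cohort components")


def simulate_cohort(n_samples: int, n_snps: int, seed: int, effects: EffectSpec | None = None,
                    n_families: int = 0, spacing_bp: int = 5000, ld_decay_bp: float = 50_000.0,
                    maf_range=(0.05, 0.5), missing_rate: float = 0.0,
                    with_covariates: bool = True, markers: pd.DataFrame | None = None,
                    n_hap: int | None = None) -> SyntheticCohort:
    """Simulate a full cohort in one call; sub-seeds are derived from ``seed``."""
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(5)]
    if markers is None:
        markers = uniform_marker_map(n_snps, spacing_bp=spacing_bp)
    if effects is None:
        effects = EffectSpec()
    if n_hap is None:
        n_hap = max(2 * n_samples, 200)
    panel = simulate_haplotypes(n_hap, markers, ld_decay_bp=ld_decay_bp,
                                maf_range=maf_range, seed=seeds[0])
    g, kin = simulate_genotypes(panel, n_samples, n_families=n_families, seed=seeds[1])
    cov = simulate_covariates(n_samples, seed=seeds[2]) if with_covariates else None
    pheno = simulate_phenotype(g, effects, covariates=cov, kinship=kin, seed=seeds[3])
    if missing_rate > 0:
        g = inject_missing(g, missing_rate, seed=seeds[4])
    return SyntheticCohort(g, pheno, kin, effects, seed)
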