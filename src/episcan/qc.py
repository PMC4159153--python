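"""Genotype and sample quality control.

Implements the array-QC protocol used before the scans: per-SNP filters
(minor allele frequency >= 2%, call rate >= 95%, Hardy-Weinberg equilibrium
P >= 1e-10), per-sample filters (call rate >= 97%, Benjamini-Hochberg FDR
0.01 on unacceptably *high* heterozygosity, age >= 18, BMI <= 50,
creatinine within 3 SD of the cohort mean) and principal-component outlier
removal on the genomic kinship matrix.  One pass, in the order listed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import GenotypeMatrix

__all__ = ["QcReport", "hwe_chi2_p", "snp_filters", "sample_filters",
           "pca_outlier_removal", "run_qc"]


@dataclass
class QcReport:
    """Pass/fail masks plus per-entity failure reasons (True = keep)."""

    snp_mask: np.ndarray
    sample_mask: np.ndarray
    reasons: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [(ent, r) for ent, rs in self.reasons.items() for r in rs]
        return pd.DataFrame(rows, columns=["entity", "rule"])


def _add_reason(reasons: dict, entity, rule: str) -> None:
    reasons.setdefault(entity, []).append(rule)


def hwe_chi2_p(n0: int, n1: int, n2: int) -> float:
    """1-df chi-square P for deviation from Hardy-Weinberg proportions.

    Observed genotype counts (hom-ref, het, hom-alt) against expectations at
    the sample allele frequency; no continuity correction.
    """
    n = n0 + n1 + n2
    if n == 0:
        return np.nan
    p = (2 * n2 + n1) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0
    exp = np.array([q * q * n, 2 * p * q * n, p * p * n])
    obs = np.array([n0, n1, n2], dtype=float)
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    return float(stats.chi2.sf(chi2, 1))


def snp_filters(g: GenotypeMatrix, maf_min: float = 0.02, snp_callrate_min: float = 0.95,
                hwe_p_min: float = 1e-10):
    """Per-SNP pass/fail with reasons; MAF computed on called genotypes only.

    Returns (mask, stats DataFrame, reasons dict keyed by snp_id).
    """
    if g.n_snps == 0 or g.n_samples == 0:
        raise ValueError("empty genotype matrix")
    geno = g.genotypes
    called = g.called
    n_called = called.sum(axis=0)
    callrate = g.snp_call_rate()
    freq = g.allele_freq()
    maf = np.minimum(freq, 1.0 - freq)
    maf = np.where(np.isnan(maf), 0.0, maf)

    n0 = ((geno == 0) & called).sum(axis=0)
    n1 = (geno == 1).sum(axis=0)
    n2 = (geno == 2).sum(axis=0)
    hwe_p = np.array([hwe_chi2_p(a, b, c) for a, b, c in zip(n0, n1, n2)])

    reasons: dict = {}
    mask = np.ones(g.n_snps, dtype=bool)
    ids = g.markers["snp_id"].to_numpy()
    for j in range(g.n_snps):
        if maf[j] < maf_min:
            _add_reason(reasons, ids[j], "maf")
        if callrate[j] < snp_callrate_min:
            _add_reason(reasons, ids[j], "callrate")
        if n_called[j] > 0 and hwe_p[j] < hwe_p_min:
            _add_reason(reasons, ids[j], "hwe")
        mask[j] = ids[j] not in reasons

    table = pd.DataFrame({"snp_id": ids, "maf": maf, "call_rate": callrate,
                          "hwe_p": hwe_p, "pass": mask})
    return mask, table, reasons


def sample_filters(g: GenotypeMatrix, pheno: pd.DataFrame, ind_callrate_min: float = 0.97,
                   het_fdr: float = 0.01, age_min: float = 18.0, bmi_max: float = 50.0,
                   creat_sd: float = 3.0):
    """Per-sample pass/fail with reasons.

    The heterozygosity rule is one-sided: per-sample heterozygous-call
    proportions are z-scored against the cohort and upper-tail normal
    P-values are thresholded by Benjamini-Hochberg at ``het_fdr``.  Samples
    with a missing covariate needed by a rule are flagged "unevaluable" and
    excluded.  Returns (mask, stats DataFrame, reasons dict keyed by
    sample id).
    """
    n = g.n_samples
    reasons: dict = {}
    callrate = g.sample_call_rate()
    called = g.called
    with np.errstate(invalid="ignore"):
        het = (g.genotypes == 1).sum(axis=1) / np.maximum(called.sum(axis=1), 1)

    sd = het.std(ddof=1)
    if sd > 0 and n > 2:
        z = (het - het.mean()) / sd
        pvals = stats.norm.sf(z)
        het_fail = multipletests(pvals, alpha=het_fdr, method="fdr_bh")[0]
    else:
        het_fail = np.zeros(n, dtype=bool)

    pheno = pheno.reset_index(drop=True)
    ids = g.samples

    def col(name):
        return pheno[name].to_numpy(dtype=float) if name in pheno.columns else None

    age, bmi, creat = col("age"), col("bmi"), col("creatinine")
    if creat is not None:
        finite = np.isfinite(creat)
        c_mean = creat[finite].mean() if finite.any() else np.nan
        c_sd = creat[finite].std(ddof=1) if finite.sum() > 1 else np.nan

    for i in range(n):
        if callrate[i] < ind_callrate_min:
            _add_reason(reasons, ids[i], "callrate")
        if het_fail[i]:
            _add_reason(reasons, ids[i], "het")
        for name, arr in (("age", age), ("bmi", bmi), ("creatinine", creat)):
            if arr is not None and not np.isfinite(arr[i]):
                _add_reason(reasons, ids[i], f"unevaluable:{name}")
        if age is not None and np.isfinite(age[i]) and age[i] < age_min:
            _add_reason(reasons, ids[i], "age")
        if bmi is not None and np.isfinite(bmi[i]) and bmi[i] > bmi_max:
            _add_reason(reasons, ids[i], "bmi")
        if creat is not None and np.isfinite(creat[i]) and np.isfinite(c_sd) and c_sd > 0:
            if abs(creat[i] - c_mean) > creat_sd * c_sd:
                _add_reason(reasons, ids[i], "creatinine")

    mask = np.array([ids[i] not in reasons for i in range(n)])
    table = pd.DataFrame({"sample_id": ids, "call_rate": callrate, "het": het, "pass": mask})
    return mask, table, reasons


def _pc_scores(kinship: np.ndarray, n_pc: int) -> np.ndarray:
    w, v = np.linalg.eigh(kinship)
    order = np.argsort(w)[::-1][:n_pc]
    return v[:, order] * np.sqrt(np.clip(w[order], 0.0, None))


def pca_outlier_removal(kinship: np.ndarray, n_pc: int = 3, sd_mult: float = 6.0) -> np.ndarray:
    """Drop samples whose score on any leading kinship PC exceeds sd_mult SDs.

    One re-iteration after removal (outliers can mask each other); returns a
    keep-mask.  Rejects cohorts smaller than n_pc + 1.
    """
    kinship = np.asarray(kinship, dtype=float)
    n = kinship.shape[0]
    if n <= n_pc:
        raise ValueError(f"need more than {n_pc} samples for {n_pc} PCs")
    keep = np.ones(n, dtype=bool)
    for _ in range(2):
        sub = kinship[np.ix_(keep, keep)]
        scores = _pc_scores(sub, n_pc)
        sd = scores.std(axis=0, ddof=1)
        sd[sd == 0] = np.inf
        bad = (np.abs(scores - scores.mean(axis=0)) > sd_mult * sd).any(axis=1)
        if not bad.any():
            break
        idx = np.flatnonzero(keep)
        keep[idx[bad]] = False
    return keep


def run_qc(g: GenotypeMatrix, pheno: pd.DataFrame, kinship: np.ndarray | None = None,
           **thresholds) -> QcReport:
    """One-pass QC: SNP filters, sample filters, optional PC-outlier removal."""
    snp_kw = {k: thresholds[k] for k in ("maf_min", "snp_callrate_min", "hwe_p_min")
              if k in thresholds}
    samp_kw = {k: thresholds[k] for k in ("ind_callrate_min", "het_fdr", "age_min",
                                          "bmi_max", "creat_sd") if k in thresholds}
    snp_mask, _, snp_reasons = snp_filters(g, **snp_kw)
    sample_mask, _, samp_reasons = sample_filters(g, pheno, **samp_kw)
    reasons = {**snp_reasons, **samp_reasons}
    if kinship is not None:
        pc_keep = pca_outlier_removal(kinship, n_pc=thresholds.get("n_pc", 3),
                                      sd_mult=thresholds.get("sd_mult", 6.0))
        for i in np.flatnonzero(~pc_keep):
            _add_reason(reasons, g.samples[i], "pc_outlier")
        sample_mask = sample_mask & pc_keep
    counts: dict = {}
    for rs in reasons.values():
        for r in rs:
            counts[r] = counts.get(r, 0) + 1
    return QcReport(snp_mask, sample_mask, reasons, counts)
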