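"""Marginal association scan and the full pairwise epistasis scan.

The pairwise scan follows a screen-then-verify design.  Screening builds,
for every SNP pair, the 9-cell two-locus genotype contingency table over
pairwise-complete samples (counts come from bit-plane AND/popcount
identities; trait sums and sums of squares from a fused single pass) and
compares the saturated cell-means model against the best 5-parameter
additive+dominance two-locus main-effect fit with a pooled-within-cell F
statistic.  Every emitted pair is then verified with an exact least-squares
factor-coded partial F test (``pair_full_test``), whose P-value is the
reported interaction P (P_int); on complete data with no empty cells the
two are the same test.

Significance thresholds are Bonferroni corrections of the actual numbers of
tests: 0.05 / (m(m-1)/2) for the full scan and 0.05 / ((m-1) k) for pairs
involving at least one of k marginal SNPs, with fixed conventions 1e-5 for
local interactions (same chromosome, within 1 Mb) and 5e-8 for single-SNP
genome-wide significance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit, prange
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

from .containers import GenotypeMatrix, round_half_up

__all__ = ["Thresholds", "derive_thresholds", "BitGenotypes", "encode_bitwise",
           "marginal_scan", "pair_screen", "pair_full_test", "ld_r2",
           "classify_pairs", "scan_pairs", "T_LOCAL", "T_GWAS"]

T_LOCAL = 1.0e-05
T_GWAS = 5.0e-08
LOCAL_DIST_BP = 1_000_000  # inclusive boundary


# ---------------------------------------------------------------------------
# thresholds
# ---------------------------------------------------------------------------

def _round_2sf(x: float) -> float:
    return float(f"{x:.1e}")


@dataclass(frozen=True)
class Thresholds:
    """Bonferroni-derived significance thresholds for the pairwise scan.

    ``t_full``/``t_marginal`` are the two-significant-figure reported values
    (what a reader quotes); the raw, unrounded values used in comparisons
    are kept alongside.
    """

    t_full: float
    t_marginal: float | None
    t_full_raw: float
    t_marginal_raw: float | None
    m_snps: int
    n_marginal: int
    t_local: float = T_LOCAL
    t_gwas: float = T_GWAS


def derive_thresholds(m_snps: int, n_marginal: int) -> Thresholds:
    """Thresholds from the actual numbers of tests.

    t_full = 0.05 / (m(m-1)/2) over all pairs; t_marginal = 0.05 / ((m-1) k)
    over pairs involving at least one of the k marginal SNPs (undefined when
    k = 0).
    """
    if m_snps < 2:
        raise ValueError("need at least 2 SNPs")
    if n_marginal < 0:
        raise ValueError("n_marginal must be >= 0")
    t_full_raw = 0.05 / (m_snps * (m_snps - 1) / 2.0)
    if n_marginal > 0:
        t_marg_raw = 0.05 / ((m_snps - 1) * n_marginal)
        t_marg = _round_2sf(t_marg_raw)
    else:
        t_marg_raw = t_marg = None
    return Thresholds(_round_2sf(t_full_raw), t_marg, t_full_raw, t_marg_raw,
                      m_snps, n_marginal)


# ---------------------------------------------------------------------------
# bitwise genotype encoding
# ---------------------------------------------------------------------------

@dataclass
class BitGenotypes:
    """Per-SNP bit planes: one plane per genotype class plus a called mask.

    planes[j, k] packs the boolean vector (genotype == k) over samples into
    bytes; ``called[j]`` packs the non-missing mask.  The planes of one SNP
    are mutually disjoint and their union is the called mask, so popcounts
    reproduce genotype counts and plane ANDs across two SNPs reproduce the
    9-cell pairwise contingency table over pairwise-complete samples.
    """

    planes: np.ndarray   # uint8 (n_snps, 3, n_bytes)
    called: np.ndarray   # uint8 (n_snps, n_bytes)
    n_samples: int

    def counts(self, j: int) -> np.ndarray:
        """Genotype counts (n0, n1, n2) of SNP j via popcount."""
        return np.bitwise_count(self.planes[j]).sum(axis=1)

    def cross_counts(self, i: int, j: int) -> np.ndarray:
        """9-cell contingency of SNPs i and j via plane AND + popcount."""
        out = np.empty((3, 3), dtype=np.int64)
        for a in range(3):
            for b in range(3):
                out[a, b] = int(np.bitwise_count(self.planes[i, a] & self.planes[j, b]).sum())
        return out

    def decode(self) -> np.ndarray:
        """Lossless inverse of :func:`encode_bitwise` (int8, -1 missing)."""
        m, _, _ = self.planes.shape
        out = np.full((self.n_samples, m), -1, dtype=np.int8)
        for j in range(m):
            for k in range(3):
                bits = np.unpackbits(self.planes[j, k])[: self.n_samples].astype(bool)
                out[bits, j] = k
        return out


def encode_bitwise(g: GenotypeMatrix | np.ndarray) -> BitGenotypes:
    """Pack 0/1/2/missing genotypes into per-class bit planes."""
    geno = g.genotypes if isinstance(g, GenotypeMatrix) else np.asarray(g, dtype=np.int8)
    n, m = geno.shape
    planes = np.empty((m, 3, (n + 7) // 8), dtype=np.uint8)
    for k in range(3):
        planes[:, k, :] = np.packbits((geno == k).T, axis=1)
    called = np.packbits((geno >= 0).T, axis=1)
    return BitGenotypes(planes, called, n)


# ---------------------------------------------------------------------------
# marginal (single-SNP) scan
# ---------------------------------------------------------------------------

def marginal_scan(y, g: GenotypeMatrix, V: np.ndarray | None = None) -> pd.DataFrame:
    """1-df score test of each SNP against the residual trait.

    With V = None (the GRAMMAR default: the trait is already the polygenic
    environmental residual) the statistic is the ordinary least-squares
    score test [(g-gbar)' r]^2 / [(g-gbar)'(g-gbar) sigma2_hat] ~ chi2(1),
    computed over called samples.  A supplied covariance V generalises it to
    [(g-gbar)' V^-1 r]^2 / [(g-gbar)' V^-1 (g-gbar) sigma2_hat] with
    sigma2_hat = r' V^-1 r / n (missing genotypes mean-imputed on that path).
    Monomorphic SNPs get P = NaN.
    """
    y = np.asarray(y, dtype=float)
    geno = g.genotypes
    called = g.called

    if V is None:
        c = called.astype(np.float64)
        g0 = np.where(called, geno, 0).astype(np.float64)
        nj = c.sum(axis=0)
        s_g = g0.sum(axis=0)
        s_y = y @ c
        s_gy = y @ g0
        s_gg = (g0 * g0).sum(axis=0)
        s_yy = (y * y) @ c
        with np.errstate(invalid="ignore", divide="ignore"):
            num = s_gy - s_g * s_y / nj
            den_g = s_gg - s_g ** 2 / nj
            sigma2 = (s_yy - s_y ** 2 / nj) / nj
            chi2 = num ** 2 / (den_g * sigma2)
        chi2 = np.where(den_g > 1e-12, chi2, np.nan)
    else:
        n = y.size
        cf = cho_factor(V)
        freq = g.allele_freq()
        gd = np.where(called, geno, 2.0 * freq[None, :]).astype(np.float64)
        gd = gd - gd.mean(axis=0)
        vi_1 = cho_solve(cf, np.ones(n))
        y = y - float(y @ vi_1) / float(vi_1.sum())  # V-weighted centring
        vi_y = cho_solve(cf, y)
        vi_g = cho_solve(cf, gd)
        sigma2 = float(y @ vi_y) / n
        num = vi_y @ gd
        den_g = np.einsum("ij,ij->j", gd, vi_g)
        with np.errstate(invalid="ignore", divide="ignore"):
            chi2 = num ** 2 / (den_g * sigma2)
        chi2 = np.where(den_g > 1e-12, chi2, np.nan)

    p = stats.chi2.sf(chi2, 1)
    return pd.DataFrame({
        "snp_id": g.markers["snp_id"],
        "chrom": g.markers["chrom"],
        "pos": g.markers["pos"],
        "chi2": chi2,
        "p": p,
        "marginal": p < T_GWAS,
    })


# ---------------------------------------------------------------------------
# pairwise screening
# ---------------------------------------------------------------------------

@njit(parallel=True, cache=True)
def _pair_cell_stats(codes, y, pairs):  # pragma: no cover - numba
    P = pairs.shape[0]
    n = y.size
    N = np.zeros((P, 9))
    S = np.zeros((P, 9))
    Q = np.zeros((P, 9))
    for p in prange(P):
        c1 = codes[pairs[p, 0]]
        c2 = codes[pairs[p, 1]]
        for i in range(n):
            a = c1[i]
            b = c2[i]
            if a >= 0 and b >= 0:
                k = 3 * a + b
                N[p, k] += 1.0
                S[p, k] += y[i]
                Q[p, k] += y[i] * y[i]
    return N, S, Q


# fixed cell design for the two-locus main-effects model: intercept,
# additive and dominance at each locus, one row per cell (g1, g2)
_CELLS_G1 = np.repeat(np.arange(3.0), 3)
_CELLS_G2 = np.tile(np.arange(3.0), 3)
_MAIN_DESIGN = np.column_stack([
    np.ones(9), _CELLS_G1, (_CELLS_G1 == 1.0).astype(float),
    _CELLS_G2, (_CELLS_G2 == 1.0).astype(float),
])


def _screen_pvalues(N, S, Q):
    """Vectorised screening F test from per-pair 9-cell statistics.

    Returns (p, F, df_int, df_resid); pairs with df_int <= 0 or no residual
    degrees of freedom get NaN.
    """
    tot_n = N.sum(axis=1)
    tot_s = S.sum(axis=1)
    tot_q = Q.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        correction = tot_s ** 2 / tot_n
        ss_total = tot_q - correction
        ss_cells = np.where(N > 0, S ** 2 / np.where(N > 0, N, 1.0), 0.0).sum(axis=1) - correction
    ss_within = ss_total - ss_cells

    C = _MAIN_DESIGN
    A = np.einsum("ck,pc,cl->pkl", C, N, C)
    b = np.einsum("ck,pc->pk", C, S)
    beta = np.linalg.pinv(A, hermitian=True) @ b[..., None]
    ss_main = (beta[..., 0] * b).sum(axis=1) - correction

    eig = np.linalg.eigvalsh(A)
    tol = eig[:, -1:] * 1e-9
    rank_main = (eig > tol).sum(axis=1)
    n_cells = (N > 0).sum(axis=1)
    df_int = n_cells - rank_main
    df_res = tot_n - n_cells

    num = ss_cells - ss_main
    valid = (df_int > 0) & (df_res > 0)
    F = np.full(tot_n.shape, np.nan)
    p = np.full(tot_n.shape, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.maximum(ss_total, 1.0)
        degenerate = valid & (ss_within <= 1e-12 * scale)
        ok = valid & ~degenerate
        F[ok] = (num[ok] / df_int[ok]) / (ss_within[ok] / df_res[ok])
        p[ok] = stats.f.sf(F[ok], df_int[ok], df_res[ok])
        # no within-cell variance: interaction either absent (p=1) or exact (p=0)
        F[degenerate] = 0.0
        p[degenerate] = np.where(num[degenerate] <= 1e-12 * scale[degenerate], 1.0, 0.0)
    return p, F, df_int, df_res


def _pair_index(markers: pd.DataFrame, window: str, max_dist_bp: int) -> np.ndarray:
    chrom = markers["chrom"].to_numpy()
    pos = markers["pos"].to_numpy()
    m = len(markers)
    if window == "all":
        idx = np.array(list(itertools.combinations(range(m), 2)), dtype=np.int64)
        return idx.reshape(-1, 2)
    if window != "local":
        raise ValueError("window must be 'all' or 'local'")
    pairs = []
    for i in range(m):
        j = i + 1
        while j < m and chrom[j] == chrom[i] and pos[j] - pos[i] <= max_dist_bp:
            pairs.append((i, j))
            j += 1
    return np.array(pairs, dtype=np.int64).reshape(-1, 2)


def pair_screen(g: GenotypeMatrix, y, window: str = "all",
                max_dist_bp: int = LOCAL_DIST_BP, emit_p: float = T_LOCAL) -> pd.DataFrame:
    """Screen all pairs (or same-chromosome pairs within ``max_dist_bp``).

    Returns the pairs with p_screen <= emit_p, lexicographically ordered SNP
    ids within each pair, plus the number of pairs skipped for lack of
    interaction degrees of freedom.
    """
    y = np.asarray(y, dtype=float)
    y = y - y.mean()
    pairs = _pair_index(g.markers, window, max_dist_bp)
    if pairs.size == 0:
        return pd.DataFrame(columns=["i", "j", "snp1", "snp2", "p_screen",
                                     "F_screen", "df_int", "n"])
    codes = np.ascontiguousarray(g.genotypes.T)
    N, S, Q = _pair_cell_stats(codes, y, pairs)
    p, F, df_int, df_res = _screen_pvalues(N, S, Q)

    keep = np.isfinite(p) & (p <= emit_p)
    ids = g.markers["snp_id"].to_numpy()
    i_idx, j_idx = pairs[keep, 0], pairs[keep, 1]
    out = pd.DataFrame({
        "i": i_idx, "j": j_idx,
        "snp1": ids[i_idx], "snp2": ids[j_idx],
        "p_screen": p[keep], "F_screen": F[keep],
        "df_int": df_int[keep], "n": N.sum(axis=1)[keep].astype(np.int64),
    })
    swap = (out["snp1"] > out["snp2"]).to_numpy()
    if swap.any():
        for a, b in (("i", "j"), ("snp1", "snp2")):
            va, vb = out[a].to_numpy().copy(), out[b].to_numpy().copy()
            va[swap], vb[swap] = vb[swap], va[swap].copy()
            out[a], out[b] = va, vb
    out.attrs["n_pairs_tested"] = int(np.isfinite(p).sum())
    out.attrs["n_pairs_skipped"] = int((~np.isfinite(p)).sum())
    out.attrs["min_p_screen"] = float(np.nanmin(p)) if np.isfinite(p).any() else np.nan
    out.attrs["argmin_pair"] = tuple(pairs[np.nanargmin(p)]) if np.isfinite(p).any() else None
    return out.sort_values("p_screen", kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# exact pair test
# ---------------------------------------------------------------------------

def _dummies(v: np.ndarray) -> np.ndarray:
    return np.column_stack([(v == 1).astype(float), (v == 2).astype(float)])


def pair_full_test(g1, g2, y, background: np.ndarray | None = None) -> dict:
    """Exact factor-coded interaction test: full 9-cell vs main-effects model.

    Both SNPs are coded as 3-level factors; the full model adds their four
    interaction product columns.  The partial F test uses rank-aware degrees
    of freedom, so empty cells or collinear background columns reduce df
    rather than failing.  Returns a dict with p_full, F, df_int, df_resid,
    rss_main, rss_full, n.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(g1) & np.isfinite(g2) & np.isfinite(y) & (g1 >= 0) & (g2 >= 0)
    if background is not None:
        background = np.atleast_2d(np.asarray(background, dtype=float))
        if background.shape[0] != y.size:
            background = background.T
        mask &= np.isfinite(background).all(axis=1)
    n = int(mask.sum())
    if n < 4:
        raise ValueError("too few pairwise-complete samples")
    a, b, yy = g1[mask], g2[mask], y[mask] - y[mask].mean()
    d1, d2 = _dummies(a), _dummies(b)
    cols = [np.ones(n), d1, d2]
    if background is not None:
        cols.append(background[mask])
    X_main = np.column_stack(cols)
    inter = np.column_stack([d1[:, i] * d2[:, j] for i in range(2) for j in range(2)])
    X_full = np.column_stack([X_main, inter])

    def fit(X):
        beta, _, rank, _ = np.linalg.lstsq(X, yy, rcond=None)
        resid = yy - X @ beta
        return float(resid @ resid), int(rank)

    rss_main, rank_main = fit(X_main)
    rss_full, rank_full = fit(X_full)
    df_int = rank_full - rank_main
    df_res = n - rank_full
    out = {"n": n, "rss_main": rss_main, "rss_full": rss_full,
           "df_int": df_int, "df_resid": df_res,
           "rank_deficient": rank_full < X_full.shape[1]}
    if df_int <= 0 or df_res <= 0:
        out.update(F=np.nan, p_full=np.nan)
        return out
    scale = max(float(yy @ yy), 1.0)
    if rss_full <= 1e-12 * scale:
        drop = rss_main - rss_full
        out.update(F=0.0, p_full=1.0 if drop <= 1e-12 * scale else 0.0)
        return out
    F = ((rss_main - rss_full) / df_int) / (rss_full / df_res)
    out.update(F=float(F), p_full=float(stats.f.sf(F, df_int, df_res)))
    return out


def ld_r2(g1, g2) -> float:
    """Composite LD: squared Pearson correlation of 0/1/2 dosages.

    Computed over pairwise-complete samples; NaN if either SNP is
    monomorphic on that subset.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    mask = np.isfinite(g1) & np.isfinite(g2) & (g1 >= 0) & (g2 >= 0)
    a, b = g1[mask], g2[mask]
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        return np.nan
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_pairs(pairs: pd.DataFrame, thresholds: Thresholds, marginal_ids,
                   markers: pd.DataFrame) -> pd.DataFrame:
    """Attach distance, and genomewide / marginal_pair / local category flags.

    A pair is genomewide iff P_int < t_full; marginal_pair iff
    P_int < t_marginal and at least one SNP is a marginal SNP; local iff both
    SNPs are on the same chromosome at most 1 Mb apart (inclusive) and
    P_int < 1e-5.  dist_kb is |pos1 - pos2| / 1000 rounded half-up to one
    decimal, same-chromosome pairs only.
    """
    marginal_ids = set(marginal_ids)
    info = markers.set_index("snp_id")
    rows = []
    for _, row in pairs.iterrows():
        c1, p1 = info.loc[row["snp1"], ["chrom", "pos"]]
        c2, p2 = info.loc[row["snp2"], ["chrom", "pos"]]
        p_int = row["p_full"] if "p_full" in row and np.isfinite(row.get("p_full", np.nan)) \
            else row["p_screen"]
        same = c1 == c2
        dist_kb = round_half_up(abs(int(p1) - int(p2)) / 1000.0, 1) if same else np.nan
        cats = []
        if p_int < thresholds.t_full_raw:
            cats.append("genomewide")
        if (thresholds.t_marginal_raw is not None and p_int < thresholds.t_marginal_raw
                and (row["snp1"] in marginal_ids or row["snp2"] in marginal_ids)):
            cats.append("marginal_pair")
        if same and abs(int(p1) - int(p2)) <= LOCAL_DIST_BP and p_int < thresholds.t_local:
            cats.append("local")
        rows.append({"chr1": c1, "pos1": int(p1), "chr2": c2, "pos2": int(p2),
                     "dist_kb": dist_kb, "category": ",".join(cats)})
    extra_cols = ["chr1", "pos1", "chr2", "pos2", "dist_kb", "category"]
    extra = pd.DataFrame(rows, index=pairs.index, columns=extra_cols)
    return pd.concat([pairs, extra], axis=1)


# ---------------------------------------------------------------------------
# orchestrated pairwise scan
# ---------------------------------------------------------------------------

PAIR_COLUMNS = ["chr1", "snp1", "pos1", "chr2", "snp2", "pos2",
                "dist_kb", "r2", "p_screen", "p_full", "category"]


def scan_pairs(g: GenotypeMatrix, y, thresholds: Thresholds | None = None,
               window: str = "all", max_dist_bp: int = LOCAL_DIST_BP,
               emit_p: float | None = None, marginal_ids=()) -> pd.DataFrame:
    """Screen, verify, and classify SNP pairs; returns a Table-1-style frame.

    Every screened pair below ``emit_p`` (default: the local-interaction
    threshold 1e-5) is re-tested exactly with :func:`pair_full_test`; the
    reported P_int is the exact p_full, with p_screen retained for audit.
    """
    if thresholds is None:
        thresholds = derive_thresholds(g.n_snps, len(tuple(marginal_ids)))
    if emit_p is None:
        emit_p = thresholds.t_local
    screened = pair_screen(g, y, window=window, max_dist_bp=max_dist_bp, emit_p=emit_p)
    y = np.asarray(y, dtype=float)
    p_full = np.empty(len(screened))
    r2 = np.empty(len(screened))
    for k, row in screened.iterrows():
        d1 = g.genotypes[:, int(row["i"])].astype(float)
        d2 = g.genotypes[:, int(row["j"])].astype(float)
        d1[d1 < 0] = np.nan
        d2[d2 < 0] = np.nan
        p_full[k] = pair_full_test(d1, d2, y)["p_full"]
        r2[k] = ld_r2(d1, d2)
    screened = screened.assign(p_full=p_full, r2=r2)
    out = classify_pairs(screened, thresholds, marginal_ids, g.markers)
    out.attrs.update(screened.attrs)
    out = out.sort_values(["p_full", "snp1", "snp2"], kind="mergesort").reset_index(drop=True)
    return out[PAIR_COLUMNS + ["F_screen", "df_int", "n"]]
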