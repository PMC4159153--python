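"""Conditional tests, forward selection and variance-explained accounting.

Candidate terms are single SNPs (additive-only encoding when used as
background, per the convention that marginal SNPs condition additively) or
SNP pairs (full 9-cell factor coding).  Conditional significance of a term
given a background is a rank-aware partial F test on the residual trait;
forward selection greedily adds the term with the lowest conditional P
until none falls below alpha.  Variance explained refits the polygenic
model with the accepted terms as fixed effects and reports the variance of
their fitted contribution as a percentage of the trait variance,
accumulated along the selection path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix
from .grammar import PolygenicModel

__all__ = ["ModelTerm", "SelectionPath", "ReplicationRecord", "term_design",
           "conditional_test", "forward_select", "variance_explained",
           "replication_check"]

RANK_TOL = 1e-8


@dataclass(frozen=True)
class ModelTerm:
    """One model term: a marginal SNP or an epistatic SNP pair."""

    kind: str                 # "marginal" | "pair"
    snps: tuple
    encoding: str = "additive"  # additive | full (pairs are always full)

    def __post_init__(self):
        if self.kind not in ("marginal", "pair"):
            raise ValueError("kind must be 'marginal' or 'pair'")
        if self.kind == "pair" and self.encoding == "additive":
            raise ValueError("additive-only encoding is for marginal terms")
        object.__setattr__(self, "snps", tuple(self.snps))

    def label(self) -> str:
        return "x".join(self.snps)


def _dosage(g: GenotypeMatrix, snp: str) -> np.ndarray:
    return g.dosage(snp)


def term_design(term: ModelTerm, g: GenotypeMatrix) -> np.ndarray:
    """Design columns for a term (NaN rows where any genotype is missing).

    Marginal additive: the 0/1/2 dosage.  Marginal full: dosage + het
    indicator.  Pair: additive + dominance at both loci plus the four
    interaction product columns (the full 9-cell parameterisation; columns
    already spanned by the background drop out by rank in the tests).
    """
    if term.kind == "marginal":
        d = _dosage(g, term.snps[0])
        if term.encoding == "additive":
            return d[:, None]
        return np.column_stack([d, (d == 1).astype(float)])
    d1, d2 = _dosage(g, term.snps[0]), _dosage(g, term.snps[1])
    h1, h2 = (d1 == 1).astype(float), (d2 == 1).astype(float)
    nanrow = np.isnan(d1) | np.isnan(d2)
    cols = np.column_stack([
        d1, h1, d2, h2,
        d1 * d2, d1 * h2, h1 * d2, h1 * h2,
    ])
    cols[nanrow] = np.nan
    return cols


def _background_design(background, g: GenotypeMatrix, n: int) -> np.ndarray:
    cols = [np.ones((n, 1))]
    for t in background:
        cols.append(term_design(t, g))
    return np.column_stack(cols)


def _rank_rss(X: np.ndarray, y: np.ndarray):
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return int(rank), float(resid @ resid)


def conditional_test(term: ModelTerm, background, y, g: GenotypeMatrix) -> dict:
    """Partial F test of a term with background terms held as fixed effects.

    Returns {'p': float or NaN, 'reason': ..., 'df': ...}.  A term whose
    columns add no rank beyond the background (e.g. conditioning a SNP on
    itself) is flagged collinear with P absent.  With an empty background
    this is exactly the unconditional association/interaction test.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    Xb = _background_design(background, g, n)
    Xt = term_design(term, g)
    mask = np.isfinite(y) & np.isfinite(Xb).all(axis=1) & np.isfinite(Xt).all(axis=1)
    yy = y[mask] - y[mask].mean()
    Xb, Xt = Xb[mask], Xt[mask]
    rank_b, rss_b = _rank_rss(Xb, yy)
    rank_f, rss_f = _rank_rss(np.column_stack([Xb, Xt]), yy)
    df_term = rank_f - rank_b
    df_res = int(mask.sum()) - rank_f
    if df_term <= 0:
        return {"p": np.nan, "reason": "collinear", "df": 0, "n": int(mask.sum())}
    if df_res <= 0:
        return {"p": np.nan, "reason": "no residual df", "df": df_term, "n": int(mask.sum())}
    scale = max(float(yy @ yy), 1.0)
    if rss_f <= 1e-12 * scale:
        p = 1.0 if (rss_b - rss_f) <= 1e-12 * scale else 0.0
        return {"p": p, "reason": None, "df": df_term, "n": int(mask.sum())}
    F = ((rss_b - rss_f) / df_term) / (rss_f / df_res)
    return {"p": float(stats.f.sf(F, df_term, df_res)), "F": float(F),
            "reason": None, "df": df_term, "n": int(mask.sum())}


@dataclass
class SelectionPath:
    """Ordered accepted terms with entry P-values and cumulative variance %."""

    terms: list = field(default_factory=list)
    entry_p: list = field(default_factory=list)
    cumulative_variance: list = field(default_factory=list)

    @property
    def final_variance(self) -> float:
        return self.cumulative_variance[-1] if self.cumulative_variance else 0.0

    def to_frame(self, g: GenotypeMatrix | None = None) -> pd.DataFrame:
        rows = []
        for t, p, v in zip(self.terms, self.entry_p, self.cumulative_variance):
            row = {"kind": t.kind, "snp1": t.snps[0],
                   "snp2": t.snps[1] if len(t.snps) > 1 else "",
                   "p": p, "variance_explained_cum": v}
            if g is not None:
                info = g.markers.set_index("snp_id")
                row["pos1"] = int(info.loc[t.snps[0], "pos"])
                row["pos2"] = int(info.loc[t.snps[1], "pos"]) if len(t.snps) > 1 else np.nan
            rows.append(row)
        return pd.DataFrame(rows)


def _genomic_order(term: ModelTerm, g: GenotypeMatrix):
    info = g.markers.set_index("snp_id")
    return tuple((str(info.loc[s, "chrom"]), int(info.loc[s, "pos"])) for s in term.snps)


def forward_select(candidates, y, g: GenotypeMatrix, alpha: float = 0.05,
                   kinship: np.ndarray | None = None) -> SelectionPath:
    """Greedy forward selection over marginal SNPs and epistatic pairs.

    At each round every remaining candidate is conditionally tested against
    the current background; the lowest conditional P enters (ties broken by
    genomic order), until no candidate reaches ``alpha``.  Accepted marginal
    terms join the background additive-only; pairs join with full coding.
    Cumulative variance explained is computed at each step.
    """
    remaining = list(candidates)
    if not remaining:
        raise ValueError("candidate list is empty")
    path = SelectionPath()
    background: list = []
    while remaining:
        best = None
        for t in remaining:
            res = conditional_test(t, background, y, g)
            p = res["p"]
            if not np.isfinite(p):
                continue
            key = (p, _genomic_order(t, g))
            if best is None or key < best[0]:
                best = (key, t)
        if best is None or best[0][0] >= alpha:
            break
        _, chosen = best
        path.terms.append(chosen)
        path.entry_p.append(best[0][0])
        background.append(chosen)
        remaining = [t for t in remaining if t is not chosen]
    path.cumulative_variance = variance_explained(path.terms, y, g, kinship=kinship)
    return path


def variance_explained(terms, y, g: GenotypeMatrix, kinship: np.ndarray | None = None) -> list:
    """Cumulative trait variance (%) explained by the terms' fixed effects.

    For each prefix of the path the polygenic model is refit with the terms'
    design columns as fixed effects (identity covariance when no kinship is
    supplied, i.e. ordinary least squares on the residual trait) and the
    variance of the fitted genetic contribution is reported as a percentage
    of the trait variance.  Singular columns are dropped by rank.
    """
    y = np.asarray(y, dtype=float)
    out = []
    var_y = float(np.var(y))
    for k in range(1, len(terms) + 1):
        X = np.column_stack([term_design(t, g) for t in terms[:k]])
        mask = np.isfinite(y) & np.isfinite(X).all(axis=1)
        Xm, ym = X[mask], y[mask]
        # drop rank-deficient columns so the mixed-model design is full rank
        qr_r = np.linalg.qr(Xm - Xm.mean(axis=0), mode="r")
        diag = np.abs(np.diag(qr_r))
        keep_cols = np.ones(Xm.shape[1], dtype=bool)
        if (diag <= RANK_TOL * max(diag.max(), 1.0)).any():
            keep_cols = _independent_columns(Xm)
        Xm = Xm[:, keep_cols]
        if kinship is not None:
            Km = np.asarray(kinship)[np.ix_(mask, mask)]
            fit = PolygenicModel(ym, Xm, Km).fit()
            beta = fit.params
            Xd = np.column_stack([np.ones(Xm.shape[0]), Xm])
            contrib = Xd[:, 1:] @ beta[1:]
        else:
            Xd = np.column_stack([np.ones(Xm.shape[0]), Xm])
            beta, _, _, _ = np.linalg.lstsq(Xd, ym, rcond=None)
            contrib = Xd[:, 1:] @ beta[1:]
        out.append(float(np.var(contrib) / var_y * 100.0))
    return out


def _independent_columns(X: np.ndarray) -> np.ndarray:
    """Greedy left-to-right selection of linearly independent columns."""
    keep = np.zeros(X.shape[1], dtype=bool)
    basis = np.ones((X.shape[0], 1))
    rank = 1
    for j in range(X.shape[1]):
        trial = np.column_stack([basis, X[:, j]])
        r = np.linalg.matrix_rank(trial, tol=None)
        if r > rank:
            keep[j] = True
            basis, rank = trial, r
    return keep


@dataclass
class ReplicationRecord:
    """Cross-cohort replication status of one discovery pair."""

    snp1: str
    snp2: str
    both_typed: bool
    p_int_replication: float | None
    replicated: bool | None  # None == NA (not directly replicable)


def replication_check(discovery_pairs, g2: GenotypeMatrix, y2, alpha: float = 0.05):
    """SNP-identity replication: both SNPs typed in cohort 2 and P_int < alpha.

    ``discovery_pairs`` is an iterable of (snp1, snp2).  Pairs with either
    SNP absent from cohort 2's marker map get replicated = None (NA).
    """
    from .scan import pair_full_test

    typed = set(g2.markers["snp_id"])
    y2 = np.asarray(y2, dtype=float)
    records = []
    for snp1, snp2 in discovery_pairs:
        if snp1 not in typed or snp2 not in typed:
            records.append(ReplicationRecord(snp1, snp2, False, None, None))
            continue
        p = pair_full_test(g2.dosage(snp1), g2.dosage(snp2), y2)["p_full"]
        records.append(ReplicationRecord(snp1, snp2, True, float(p), bool(p < alpha)))
    return records
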