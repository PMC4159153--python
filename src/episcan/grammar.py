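"""Polygenic residualisation of the trait (the GRAMMAR strategy).

The analysis trait for all scans is the environmental residual of a
single-variance-component mixed model:

    y = X beta + u + e,   u ~ N(0, sigma_g^2 A),   e ~ N(0, sigma_e^2 I)

where A = 2K is the relationship matrix built from the genomic kinship K, X
holds an intercept, covariates and the first 10 kinship principal
components, and h2 = sigma_g^2 / (sigma_g^2 + sigma_e^2).  REML estimation
reduces to a 1-D search over h2 after one eigendecomposition of A.  The
environmental residual

    pgresidualY = y - X beta_hat - BLUP(u)

is returned by :meth:`PolygenicResults.pgresidual` and used as the trait in
every downstream association and interaction test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import MISSING, GenotypeMatrix

__all__ = ["genomic_kinship", "kinship_pcs", "rank_inverse_normal",
           "PolygenicModel", "PolygenicResults", "fit_polygenic"]


def genomic_kinship(g: GenotypeMatrix) -> np.ndarray:
    """Allele-frequency-weighted genomic kinship (kinship-coefficient scale).

    K_ij = mean over called SNPs of (g_i - 2p)(g_j - 2p) / (2p(1-p)) / 2.
    Diagonal is ~0.5 for non-inbred samples, full sibs ~0.25, unrelated ~0.
    Missing calls contribute zero to the numerator and are excluded from the
    per-pair SNP count.  Monomorphic SNPs are skipped.
    """
    if g.n_samples < 2:
        raise ValueError("need at least 2 samples")
    geno = g.genotypes.astype(np.float64)
    called = g.called
    if (~called).all(axis=1).any():
        raise ValueError("sample with all genotypes missing")
    p = g.allele_freq()
    poly = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    if poly.sum() < 2:
        raise ValueError("need at least 2 polymorphic SNPs")
    geno = geno[:, poly]
    called = called[:, poly]
    p = p[poly]

    denom = np.sqrt(2.0 * p * (1.0 - p))
    x = np.where(called, (geno - 2.0 * p) / denom, 0.0)
    num = x @ x.T
    cnt = called.astype(np.float64) @ called.astype(np.float64).T
    cnt[cnt == 0] = np.nan
    return num / cnt / 2.0


def kinship_pcs(kinship: np.ndarray, n_pc: int = 10) -> np.ndarray:
    """Leading principal-component scores of the kinship matrix."""
    w, v = np.linalg.eigh(np.asarray(kinship, dtype=float))
    order = np.argsort(w)[::-1][:n_pc]
    return v[:, order] * np.sqrt(np.clip(w[order], 0.0, None))


def rank_inverse_normal(y) -> np.ndarray:
    """Rank-based inverse-normal transform: Phi^{-1}((rank - 0.5)/n).

    Ties share the averaged rank.  Output has mean ~0 and SD ~1 and is
    invariant to any monotone transform of the input.
    """
    y = np.asarray(y, dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("constant vector cannot be rank-transformed")
    ranks = stats.rankdata(y, method="average")
    return stats.norm.ppf((ranks - 0.5) / y.size)


class PolygenicModel:
    """Single-component mixed model for a quantitative trait.

    Parameters
    ----------
    endog : (n,) array
        Trait values (typically already covariate-corrected and
        rank-inverse-normal transformed).
    exog : (n, p) array or None
        Fixed-effect design.  An intercept column is prepended if absent.
    kinship : (n, n) array or None
        Genomic kinship (coefficient scale); the model covariance uses
        A = 2 * kinship.  None means no genetic structure (OLS limit).
    """

    def __init__(self, endog, exog=None, kinship=None):
        self.endog = np.asarray(endog, dtype=float)
        n = self.endog.size
        if exog is None:
            exog = np.ones((n, 1))
        else:
            exog = np.atleast_2d(np.asarray(exog, dtype=float))
            if exog.shape[0] != n:
                exog = exog.T
            if not np.any(np.ptp(exog, axis=0) == 0):
                exog = np.column_stack([np.ones(n), exog])
        if np.linalg.matrix_rank(exog) < exog.shape[1]:
            raise ValueError("fixed-effect design is rank deficient")
        self.exog = exog
        if kinship is None:
            kinship = 0.5 * np.eye(n)
        kinship = np.asarray(kinship, dtype=float)
        if kinship.shape != (n, n):
            raise ValueError("kinship shape mismatch")
        if not np.allclose(kinship, kinship.T, atol=1e-8):
            raise ValueError("kinship must be symmetric")
        self.kinship = kinship

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, trait: str, covariates=(),
                       kinship=None, n_pcs: int = 10, transform: bool = True):
        """Build the model from a phenotype table.

        Covariate columns are taken from ``data``; if ``kinship`` is given,
        its first ``n_pcs`` principal components are appended to the design.
        ``transform`` applies :func:`rank_inverse_normal` to the trait after
        an OLS covariate pre-correction, mirroring the usual two-step
        protocol (correct, normalise, then fit the polygenic model).
        """
        y = data[trait].to_numpy(dtype=float)
        cols = [data[c].to_numpy(dtype=float) for c in covariates]
        X = np.column_stack([np.ones(len(data))] + cols) if cols else np.ones((len(data), 1))
        if transform:
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            y = rank_inverse_normal(y - X @ beta + (X @ beta).mean())
        if kinship is not None and n_pcs > 0:
            X = np.column_stack([X, kinship_pcs(kinship, n_pcs)])
        return cls(y, X, kinship)

    # -- REML machinery ----------------------------------------------------

    def _profile(self, h2: float, d: np.ndarray, yt: np.ndarray, xt: np.ndarray):
        """Profiled REML pieces at a given h2 on the eigenbasis of A."""
        n, p = xt.shape
        w = h2 * d + (1.0 - h2)
        if np.any(w <= 0):
            return None
        wi = 1.0 / w
        xtwx = (xt * wi[:, None]).T @ xt
        xtwy = (xt * wi[:, None]).T @ yt
        try:
            beta = np.linalg.solve(xtwx, xtwy)
        except np.linalg.LinAlgError:
            return None
        r = yt - xt @ beta
        rss = float(r @ (wi * r))
        sigma_p2 = rss / (n - p)
        sign, logdet_x = np.linalg.slogdet(xtwx)
        if sign <= 0 or sigma_p2 <= 0:
            return None
        ll = -0.5 * ((n - p) * (np.log(sigma_p2) + 1.0) + np.sum(np.log(w)) + logdet_x)
        return ll, beta, sigma_p2, r, wi

    def fit(self, h2_tol: float = 1e-8) -> "PolygenicResults":
        """REML fit via Brent search on h2 in [0, 1) after one eigendecomposition."""
        A = 2.0 * self.kinship
        d, U = np.linalg.eigh(A)
        yt = U.T @ self.endog
        xt = U.T @ self.exog

        def neg_ll(h2):
            out = self._profile(h2, d, yt, xt)
            return np.inf if out is None else -out[0]

        res = optimize.minimize_scalar(neg_ll, bounds=(0.0, 1.0 - 1e-6),
                                       method="bounded",
                                       options={"xatol": h2_tol})
        h2 = float(res.x)
        ll_hat = -float(res.fun)
        ll0 = -neg_ll(0.0)
        if not np.isfinite(ll_hat):
            raise ValueError("non-finite REML likelihood; check kinship conditioning")
        # flat-likelihood tie-break (e.g. kinship proportional to identity):
        # prefer the no-heritability boundary unless the optimum truly improves.
        if ll_hat - ll0 <= 1e-6:
            h2, ll_hat = 0.0, ll0
        out = self._profile(h2, d, yt, xt)
        ll, beta, sigma_p2, r, wi = out
        sigma_g2 = h2 * sigma_p2
        sigma_e2 = (1.0 - h2) * sigma_p2
        # BLUP of u on the eigenbasis: h2*d/(h2*d + 1-h2) * residual
        shrink = h2 * d * wi
        blup = U @ (shrink * r)
        fitted_fixed = self.exog @ beta
        pgresid = self.endog - fitted_fixed - blup
        xtwx = (xt * wi[:, None]).T @ xt
        bse = np.sqrt(np.diag(np.linalg.inv(xtwx)) * sigma_p2)
        return PolygenicResults(self, h2, sigma_g2, sigma_e2, beta, bse, ll, pgresid, blup)


@dataclass
class PolygenicResults:
    """REML estimates, environmental residuals and a summary table."""

    model: PolygenicModel
    h2: float
    sigma_g2: float
    sigma_e2: float
    params: np.ndarray
    bse: np.ndarray
    loglik: float
    pgresidual: np.ndarray
    blup: np.ndarray

    def summary(self) -> str:
        lines = [
            "Polygenic mixed model (REML)",
            "=" * 44,
            f"n samples            {self.model.endog.size}",
            f"heritability h2      {self.h2:.4f}",
            f"sigma_g^2            {self.sigma_g2:.4f}",
            f"sigma_e^2            {self.sigma_e2:.4f}",
            f"REML log-likelihood  {self.loglik:.4f}",
            "-" * 44,
            f"{'coef':>12} {'est':>10} {'se':>10}",
        ]
        for j, (b, s) in enumerate(zip(self.params, self.bse)):
            lines.append(f"{'x%d' % j:>12} {b:>10.4f} {s:>10.4f}")
        return "\n".join(lines)

    def to_report(self) -> dict:
        return {"n": int(self.model.endog.size), "h2": self.h2,
                "sigma_g2": self.sigma_g2, "sigma_e2": self.sigma_e2,
                "loglik": self.loglik}


def fit_polygenic(y, X, kinship) -> PolygenicResults:
    """Functional wrapper: REML fit of the polygenic model."""
    return PolygenicModel(y, X, kinship).fit()
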