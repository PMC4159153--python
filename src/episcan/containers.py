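"""Core in-memory containers shared across the pipeline.

Genotypes are held as an int8 samples x SNPs matrix coded as the count of
the alternate allele (0/1/2) with ``MISSING`` (-1) for no-calls.  The marker
map is a pandas DataFrame with 1-based physical positions, mirroring the
BIM/VCF convention; BED/BEDPE annotation coordinates are 0-based half-open
and converted in :mod:`episcan.enrich` only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

MARKER_COLUMNS = ["snp_id", "chrom", "pos", "allele_ref", "allele_alt"]


def make_marker_map(snp_ids, chroms, positions, allele_ref=None, allele_alt=None) -> pd.DataFrame:
    """Assemble and validate a marker map DataFrame."""
    n = len(snp_ids)
    if allele_ref is None:
        allele_ref = ["A"] * n
    if allele_alt is None:
        allele_alt = ["G"] * n
    m = pd.DataFrame(
        {
            "snp_id": list(snp_ids),
            "chrom": list(chroms),
            "pos": np.asarray(positions, dtype=np.int64),
            "allele_ref": list(allele_ref),
            "allele_alt": list(allele_alt),
        }
    )
    validate_marker_map(m)
    return m


def validate_marker_map(markers: pd.DataFrame) -> None:
    """Check uniqueness of snp ids and strictly increasing positions per chromosome."""
    missing = [c for c in MARKER_COLUMNS if c not in markers.columns]
    if missing:
        raise ValueError(f"marker map missing columns: {missing}")
    if markers["snp_id"].duplicated().any():
        dup = markers.loc[markers["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise ValueError(f"duplicate snp_id in marker map: {dup!r}")
    for chrom, sub in markers.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"positions not strictly increasing on chromosome {chrom}")


@dataclass
class GenotypeMatrix:
    """Samples x SNPs alternate-allele dosages with a marker map.

    Attributes
    ----------
    genotypes : int8 ndarray, shape (n_samples, n_snps)
        0/1/2 alternate-allele counts, -1 for missing calls.
    markers : DataFrame
        Columns snp_id, chrom, pos (1-based), allele_ref, allele_alt.
    samples : ndarray of str
        Sample identifiers, one per row.
    """

    genotypes: np.ndarray
    markers: pd.DataFrame
    samples: np.ndarray = field(default=None)

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (samples x SNPs)")
        validate_marker_map(self.markers)
        if self.genotypes.shape[1] != len(self.markers):
            raise ValueError("genotype column count does not match marker map")
        if self.samples is None:
            self.samples = np.array([f"S{i:06d}" for i in range(self.genotypes.shape[0])])
        else:
            self.samples = np.asarray(self.samples, dtype=object)
        if len(self.samples) != self.genotypes.shape[0]:
            raise ValueError("sample id count does not match genotype rows")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def called(self) -> np.ndarray:
        return self.genotypes != MISSING

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per SNP over called genotypes (NaN if none called)."""
        g = self.genotypes.astype(np.float64)
        called = self.called
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(called, g, 0.0).sum(axis=0) / (2.0 * called.sum(axis=0))

    def snp_call_rate(self) -> np.ndarray:
        return self.called.mean(axis=0)

    def sample_call_rate(self) -> np.ndarray:
        return self.called.mean(axis=1)

    def dosage(self, snp_id: str) -> np.ndarray:
        """Float dosage vector for one SNP, NaN at missing calls."""
        idx = self.index_of(snp_id)
        g = self.genotypes[:, idx].astype(np.float64)
        g[g == MISSING] = np.nan
        return g

    def index_of(self, snp_id: str) -> int:
        hits = np.flatnonzero((self.markers["snp_id"] == snp_id).to_numpy())
        if hits.size == 0:
            raise KeyError(f"unknown snp_id {snp_id!r}")
        return int(hits[0])

    def subset(self, sample_mask=None, snp_mask=None) -> "GenotypeMatrix":
        g = self.genotypes
        samples = self.samples
        markers = self.markers
        if sample_mask is not None:
            sample_mask = np.asarray(sample_mask)
            g = g[sample_mask]
            samples = samples[sample_mask]
        if snp_mask is not None:
            snp_mask = np.asarray(snp_mask)
            g = g[:, snp_mask]
            markers = markers.loc[snp_mask].reset_index(drop=True)
        return GenotypeMatrix(g.copy(), markers.copy(), samples.copy())


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero to a fixed number of decimals.

    Table-style columns (pair distance in kb, enrichment fold) use one
    decimal with conventional half-up rounding rather than banker's rounding.
    """
    factor = 10.0 ** decimals
    return float(np.floor(abs(x) * factor + 0.5) / factor * np.sign(x))
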