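"""File formats: PLINK bed/bim/fam, phenotype TSV, BED4 and BEDPE.

The PLINK .bed codec implements the standard SNP-major 2-bit dialect
(magic bytes 0x6C 0x1B, mode 0x01): per SNP, samples are packed four to a
byte, low bits first, with codes 00 = homozygous A1, 01 = missing,
10 = heterozygous, 11 = homozygous A2.  A1 is treated as the alternate
(counted) allele by default, so 00 decodes to dosage 2; pass
``a1_alt=False`` to flip the orientation.  SNP positions are 1-based
(BIM/VCF convention); BED/BEDPE tracks are 0-based half-open.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, make_marker_map

__all__ = ["read_plink", "write_plink", "read_phenotype", "write_phenotype",
           "read_bed_track", "write_bed_track", "read_bedpe", "write_bedpe"]

_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit code -> dosage with A1 = alternate allele
_CODE_TO_DOSAGE_A1ALT = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE_A1ALT = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


def write_plink(g: GenotypeMatrix, prefix: str, a1_alt: bool = True) -> None:
    """Write a PLINK bed/bim/fam fileset (SNP-major)."""
    n, m = g.n_samples, g.n_snps
    code_of = dict(_DOSAGE_TO_CODE_A1ALT)
    if not a1_alt:
        code_of = {2: 0b11, MISSING: 0b01, 1: 0b10, 0: 0b00}
    lut = np.empty(4, dtype=np.uint8)
    for dosage, code in code_of.items():
        lut[dosage if dosage != MISSING else 3] = code
    geno = g.genotypes.copy()
    geno[geno == MISSING] = 3
    codes = lut[geno]  # (n, m) 2-bit codes

    nbytes = (n + 3) // 4
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_MAGIC)
        buf = np.zeros((m, nbytes), dtype=np.uint8)
        for offset in range(4):
            idx = np.arange(offset, n, 4)
            block = np.zeros((m, nbytes), dtype=np.uint8)
            block[:, : idx.size] = codes[idx].T
            buf |= block << (2 * offset)
        fh.write(buf.tobytes())

    bim = g.markers
    with open(prefix + ".bim", "w") as fh:
        for _, r in bim.iterrows():
            a1 = r["allele_alt"] if a1_alt else r["allele_ref"]
            a2 = r["allele_ref"] if a1_alt else r["allele_alt"]
            fh.write(f"{r['chrom']}\t{r['snp_id']}\t0\t{r['pos']}\t{a1}\t{a2}\n")
    with open(prefix + ".fam", "w") as fh:
        for s in g.samples:
            fh.write(f"{s}\t{s}\t0\t0\t0\t-9\n")


def read_plink(prefix: str, a1_alt: bool = True) -> GenotypeMatrix:
    """Read a PLINK bed/bim/fam fileset into a GenotypeMatrix."""
    for ext in (".bed", ".bim", ".fam"):
        if not os.path.exists(prefix + ext):
            raise FileNotFoundError(prefix + ext)
    fam = pd.read_csv(prefix + ".fam", sep=r"\s+", header=None,
                      names=["fid", "iid", "father", "mother", "sex", "pheno"],
                      dtype={"iid": str, "fid": str})
    bim = pd.read_csv(prefix + ".bim", sep=r"\s+", header=None,
                      names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
                      dtype={"chrom": str, "snp_id": str})
    n, m = len(fam), len(bim)
    nbytes = (n + 3) // 4

    with open(prefix + ".bed", "rb") as fh:
        magic = fh.read(3)
        if magic[:2] != _MAGIC[:2]:
            raise ValueError(f"not a PLINK .bed file (magic {magic[:2].hex()})")
        if magic[2:3] != _MAGIC[2:3]:
            raise ValueError("only SNP-major (mode 0x01) .bed files are supported")
        data = np.frombuffer(fh.read(), dtype=np.uint8)
    expected = m * nbytes
    if data.size != expected:
        raise ValueError(
            f"truncated .bed: expected {expected} data bytes for {n} samples x "
            f"{m} SNPs, found {data.size}")
    data = data.reshape(m, nbytes)
    codes = np.empty((n, m), dtype=np.uint8)
    for offset in range(4):
        # sample i lives in byte i // 4 at bit offset 2 * (i % 4)
        idx = np.arange(offset, n, 4)
        sub = (data >> (2 * offset)) & 0b11  # (m, nbytes)
        codes[idx] = sub[:, : idx.size].T
    if a1_alt:
        table = _CODE_TO_DOSAGE_A1ALT
    else:
        table = np.array([0, MISSING, 1, 2], dtype=np.int8)
    geno = table[codes]

    if a1_alt:
        allele_alt, allele_ref = bim["a1"], bim["a2"]
    else:
        allele_alt, allele_ref = bim["a2"], bim["a1"]
    markers = make_marker_map(bim["snp_id"], bim["chrom"], bim["pos"],
                              allele_ref=list(allele_ref), allele_alt=list(allele_alt))
    return GenotypeMatrix(geno, markers, fam["iid"].to_numpy(dtype=object))


def write_phenotype(pheno: pd.DataFrame, path: str) -> None:
    pheno.to_csv(path, sep="\t", index=False)


def read_phenotype(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str})


def write_bed_track(track: pd.DataFrame, path: str) -> None:
    track.to_csv(path, sep="\t", header=False, index=False)


def read_bed_track(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :4]
    df.columns = ["chrom", "start", "end", "name"][: df.shape[1]]
    df["chrom"] = df["chrom"].astype(str)
    return df


def write_bedpe(bedpe: pd.DataFrame, path: str) -> None:
    bedpe.to_csv(path, sep="\t", header=False, index=False)


def read_bedpe(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = ["chrom1", "start1", "end1", "chrom2", "start2", "end2", "name", "score"]
    df = df.iloc[:, : len(names)]
    df.columns = names[: df.shape[1]]
    df["chrom1"] = df["chrom1"].astype(str)
    df["chrom2"] = df["chrom2"].astype(str)
    return df
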