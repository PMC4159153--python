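"""Pipeline driver: qc -> polygenic residuals -> scans -> model build -> enrichment.

The configuration is a plain YAML mapping; every stage writes a tab-separated
artifact into the output directory and appends to a plain-text log, so a rerun
with the same config and seed reproduces every file byte for byte.  Output
conventions: SNP positions 1-based, BED/BEDPE half-open, P-values in
scientific notation with 4 significant digits, dist_kb and fold with one
decimal.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import enrich, grammar, modelbuild, plinkio, qc, scan, synthdata
from .containers import GenotypeMatrix

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("episcan")


@dataclass
class PipelineConfig:
    """Inputs, thresholds and switches for one pipeline run."""

    out_dir: str = "episcan_out"
    seed: int = 1
    # input: either a PLINK prefix + phenotype TSV, or a synthetic cohort
    plink_prefix: str | None = None
    phenotype_path: str | None = None
    simulate: dict = field(default_factory=dict)   # kwargs for simulate_cohort
    covariates: list = field(default_factory=lambda: list(synthdata.COVARIATE_COLUMNS))
    # qc thresholds
    maf_min: float = 0.02
    snp_callrate_min: float = 0.95
    hwe_p_min: float = 1e-10
    ind_callrate_min: float = 0.97
    het_fdr: float = 0.01
    # scan
    scan_window: str = "local"       # 'local' or 'all'
    emit_p: float | None = None
    n_pcs: int = 10
    # selection / enrichment
    alpha: float = 0.05
    enhancer_bed: str | None = None
    chiapet_bedpe: str | None = None
    sex_stratified: bool = False

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def validate(self) -> None:
        for p in (self.plink_prefix and self.plink_prefix + ".bed",
                  self.phenotype_path, self.enhancer_bed, self.chiapet_bedpe):
            if p and not os.path.exists(p):
                raise FileNotFoundError(p)
        for t in (self.maf_min, self.snp_callrate_min, self.hwe_p_min,
                  self.ind_callrate_min, self.het_fdr, self.alpha):
            if t <= 0:
                raise ValueError("thresholds must be positive")


def _fmt(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            if col in ("dist_kb", "fold"):
                out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.1f}")
            else:
                out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.4g}")
    return out


def _write(df: pd.DataFrame, path: str, header_note: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {header_note}; positions 1-based, BED half-open\n")
        _fmt(df).to_csv(fh, sep="\t", index=False)


def _load_inputs(config: PipelineConfig):
    if config.plink_prefix:
        g = plinkio.read_plink(config.plink_prefix)
        pheno = plinkio.read_phenotype(config.phenotype_path)
        return g, pheno
    kwargs = dict(config.simulate)
    kwargs.setdefault("n_samples", 500)
    kwargs.setdefault("n_snps", 200)
    cohort = synthdata.simulate_cohort(seed=config.seed, **kwargs)
    return cohort.genotypes, cohort.phenotype


def _run_scan_stages(g: GenotypeMatrix, pgresid: np.ndarray, config: PipelineConfig,
                     out_dir: str, tag: str = ""):
    suffix = f".{tag}" if tag else ""
    gwas = scan.marginal_scan(pgresid, g)
    _write(gwas, os.path.join(out_dir, f"gwas{suffix}.tsv"), "single-SNP score-test scan")
    marginal_ids = gwas.loc[gwas["marginal"].fillna(False), "snp_id"].tolist()
    thresholds = scan.derive_thresholds(g.n_snps, len(marginal_ids))
    log.info("thresholds%s: t_full=%.6g (raw %.6g) t_marginal=%s t_local=%g t_gwas=%g",
             suffix, thresholds.t_full, thresholds.t_full_raw,
             thresholds.t_marginal, thresholds.t_local, thresholds.t_gwas)
    pairs = scan.scan_pairs(g, pgresid, thresholds=thresholds,
                            window=config.scan_window, emit_p=config.emit_p,
                            marginal_ids=marginal_ids)
    _write(pairs, os.path.join(out_dir, f"pairs{suffix}.tsv"),
           "pairwise interaction scan; P_int = p_full")
    return gwas, thresholds, pairs, marginal_ids


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order; returns a dict of in-memory artifacts."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    handler = logging.FileHandler(os.path.join(config.out_dir, "episcan.log"), mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    stage = "load"
    try:
        g, pheno = _load_inputs(config)
        artifacts: dict = {}

        stage = "qc"
        report = qc.run_qc(g, pheno, maf_min=config.maf_min,
                           snp_callrate_min=config.snp_callrate_min,
                           hwe_p_min=config.hwe_p_min,
                           ind_callrate_min=config.ind_callrate_min,
                           het_fdr=config.het_fdr)
        _write(report.to_frame(), os.path.join(config.out_dir, "qc_report.tsv"),
               "QC failures (entity, rule)")
        g = g.subset(report.sample_mask, report.snp_mask)
        pheno = pheno.loc[report.sample_mask].reset_index(drop=True)
        log.info("qc: kept %d samples, %d SNPs (%s)", g.n_samples, g.n_snps,
                 report.counts or "no failures")
        artifacts["qc"] = report

        stage = "grammar"
        kin = grammar.genomic_kinship(g)
        covs = [c for c in config.covariates if c in pheno.columns]
        model = grammar.PolygenicModel.from_dataframe(
            pheno, "trait", covariates=covs, kinship=kin,
            n_pcs=min(config.n_pcs, g.n_samples - len(covs) - 2))
        fit = model.fit()
        log.info("polygenic fit: h2=%.4f sigma_g2=%.4f sigma_e2=%.4f loglik=%.3f",
                 fit.h2, fit.sigma_g2, fit.sigma_e2, fit.loglik)
        resid = pd.DataFrame({"sample_id": g.samples, "pgresidualY": fit.pgresidual})
        _write(resid, os.path.join(config.out_dir, "pgresidual.tsv"),
               "polygenic environmental residuals")
        with open(os.path.join(config.out_dir, "polygenic_fit.txt"), "w") as fh:
            fh.write(fit.summary() + "\n")
        artifacts["fit"] = fit

        stage = "scan"
        gwas, thresholds, pairs, marginal_ids = _run_scan_stages(
            g, fit.pgresidual, config, config.out_dir)
        artifacts.update(gwas=gwas, thresholds=thresholds, pairs=pairs)
        if config.sex_stratified and "sex" in pheno.columns:
            for sex, label in ((0, "female"), (1, "male")):
                sel = (pheno["sex"] == sex).to_numpy()
                if sel.sum() < 20:
                    continue
                sub = g.subset(sample_mask=sel)
                _, _, spairs, _ = _run_scan_stages(sub, fit.pgresidual[sel],
                                                   config, config.out_dir, tag=label)
                artifacts[f"pairs_{label}"] = spairs

        stage = "modelbuild"
        candidates = [modelbuild.ModelTerm("marginal", (s,)) for s in marginal_ids]
        seen = set()
        for _, prow in pairs.iterrows():
            key = (prow["snp1"], prow["snp2"])
            if prow["category"] and key not in seen:
                seen.add(key)
                candidates.append(modelbuild.ModelTerm("pair", key, encoding="full"))
        if candidates:
            path = modelbuild.forward_select(candidates, fit.pgresidual, g,
                                             alpha=config.alpha)
            _write(path.to_frame(g), os.path.join(config.out_dir, "selection.tsv"),
                   "forward-selection path; cumulative variance explained in %")
            artifacts["selection"] = path
        else:
            log.info("modelbuild: no candidates; selection skipped")

        stage = "enrich"
        if config.enhancer_bed:
            track = plinkio.read_bed_track(config.enhancer_bed)
            pos = g.markers["pos"].to_numpy()
            chroms = g.markers["chrom"].to_numpy()
            bg = enrich.overlap_flags(pos, track, chroms)
            tag_ids = {s for _, prow in pairs.iterrows() if prow["category"]
                       for s in (prow["snp1"], prow["snp2"])}
            tagged = g.markers["snp_id"].isin(tag_ids).to_numpy()
            if tagged.any() and 0 < bg.mean() < 1:
                res = enrich.enrichment_test(int(tagged.sum()),
                                             int((bg & tagged).sum()),
                                             float(bg.mean()), cell_type="synthetic")
                enr = pd.DataFrame([dataclasses.asdict(res)])
                _write(enr, os.path.join(config.out_dir, "enrichment.tsv"),
                       "enhancer overlap enrichment vs genotyped background")
                artifacts["enrichment"] = res
        if config.chiapet_bedpe:
            loops = plinkio.read_bedpe(config.chiapet_bedpe)
            bins = enrich.bin_snps(g.markers["pos"].to_numpy(),
                                   g.markers["chrom"].to_numpy())
            bins = enrich.count_chiapet(bins, loops)
            _write(bins, os.path.join(config.out_dir, "chiapet_bins.tsv"),
                   "25-kb regions with ChIA-PET interaction counts (+-100 kb)")
            artifacts["chiapet"] = bins
        return artifacts
    except Exception:
        log.exception("pipeline halted at stage %r", stage)
        raise
    finally:
        handler.close()
        log.removeHandler(handler)
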