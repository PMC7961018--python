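"""Scan orchestration: genes x outcomes x timepoints, sensitivity runs.

Each timepoint is analyzed independently.  The scan emits a long-format
table (one row per gene/outcome/timepoint with full diagnostics) and a
wide table (genes as rows, outcome/timepoint combined p-values as
columns), with uncorrected significance flags at 0.05 and 0.1 plus
Benjamini-Hochberg adjusted columns.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import GxEConfig, GxETestResult, mixge_gene_test
from .genotype import (
    GenotypeMatrix,
    extract_gene_snps,
    read_gene_loci,
    read_genotypes,
    _bh_adjust,
)
from .phenotype import load_cohort
from .posthoc import SlopeResult, compute_ges, read_eqtl_annotation, simple_slopes

logger = logging.getLogger(__name__)

__all__ = ["ScanConfig", "run_scan", "run_maternal_sensitivity", "run_posthoc"]


@dataclass
class ScanConfig:
    """Paths and options for a full scan."""

    genotypes: str = ""
    phenotypes: str = ""
    gene_loci: str = ""
    eqtl_annotation: str | None = None
    maternal_genotypes: str | None = None
    outcomes: list[str] = field(default_factory=lambda: ["volume"])
    timepoints: list[str] | None = None
    flank_bp: int = 1000
    hwe_alpha: float = 0.05
    hwe_correction: str = "bonferroni"
    weights: str = "equal"
    ridge: str | float = "gcv"
    permutation_guard: bool = False
    out_dir: str | None = None
    seed: int = 0

    @classmethod
    def from_file(cls, path: str) -> "ScanConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def gxe_config(self, outcome: str) -> GxEConfig:
        return GxEConfig(
            outcome=outcome,
            hwe_alpha=self.hwe_alpha,
            hwe_correction=self.hwe_correction,
            weights=self.weights,
            ridge=self.ridge,
            permutation_guard=self.permutation_guard,
            seed=self.seed,
        )


def _load_inputs(config: ScanConfig):
    genotypes = read_genotypes(config.genotypes)
    cohort = load_cohort(config.phenotypes)
    loci = read_gene_loci(config.gene_loci, flank_bp=config.flank_bp)
    timepoints = config.timepoints
    if timepoints is None:
        timepoints = sorted(cohort["timepoint"].astype(str).unique())
    return genotypes, cohort, loci, timepoints


def _result_row(res: GxETestResult, outcome: str, timepoint: str) -> dict:
    return {
        "gene": res.gene_name,
        "outcome": outcome,
        "timepoint": timepoint,
        "n": res.n_subjects,
        "n_snps": res.n_snps_tested,
        "stat_fixed": res.stat_fixed,
        "p_fixed": res.p_fixed,
        "Q": res.Q,
        "p_vc": res.p_vc,
        "p_combined": res.p_combined,
        "method": ";".join(res.method_flags),
        "skipped": res.skipped,
        "skip_reason": res.skip_reason,
    }


def _finalize(rows: list[dict]) -> tuple[pd.DataFrame, pd.DataFrame]:
    long_df = pd.DataFrame(rows)
    tested = ~long_df["skipped"]
    p = long_df.loc[tested, "p_combined"].to_numpy()
    long_df["sig05"] = tested & (long_df["p_combined"] < 0.05)
    long_df["sig10"] = tested & (long_df["p_combined"] < 0.1)
    long_df["p_combined_bh"] = np.nan
    if tested.any():
        long_df.loc[tested, "p_combined_bh"] = _bh_adjust(p)
    wide_df = long_df.pivot_table(
        index="gene",
        columns=["outcome", "timepoint"],
        values="p_combined",
        sort=False,
    )
    wide_df.columns = [f"{o}@{t}" for o, t in wide_df.columns]
    return long_df, wide_df.reset_index()


def _write_outputs(config: ScanConfig, long_df, wide_df, stem: str) -> None:
    if config.out_dir is None:
        return
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    long_df.to_csv(out / f"{stem}_long.csv", index=False)
    wide_df.to_csv(out / f"{stem}_wide.csv", index=False)
    cfg = {k: v for k, v in asdict(config).items()}
    meta = {
        "version": __version__,
        "seed": config.seed,
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
    }
    (out / f"{stem}_metadata.json").write_text(json.dumps(meta, indent=2, default=str))


def run_scan(config: ScanConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the MixGE test for every gene x outcome x timepoint.

    Genes with zero surviving SNPs are recorded as skipped and the scan
    continues.  Returns (long table, wide table); both are written to
    ``config.out_dir`` when set, together with run metadata.
    """
    genotypes, cohort, loci, timepoints = _load_inputs(config)
    rows = []
    for locus in loci:
        gene_gm = extract_gene_snps(genotypes, locus)
        for outcome in config.outcomes:
            for tp in timepoints:
                sub = cohort[cohort["timepoint"].astype(str) == tp]
                res = mixge_gene_test(
                    sub, gene_gm, config.gxe_config(outcome), gene_name=locus.gene_name
                )
                rows.append(_result_row(res, outcome, tp))
    long_df, wide_df = _finalize(rows)
    _write_outputs(config, long_df, wide_df, "scan")
    return long_df, wide_df


def maternal_pc_covariates(
    maternal: GenotypeMatrix, subject_ids: list[str], n_child: int, var_retained: float = 0.90
) -> pd.DataFrame:
    """Top principal components of maternal dosages as extra covariates.

    Components are added up to ``var_retained`` cumulative variance,
    capped at n/10 columns so the design stays comfortably full rank.
    """
    gm = maternal.select_subjects(subject_ids)
    d, _ = gm.imputed_dosages(max_missing=1.0)
    d = d - d.mean(axis=0)
    u, sv, _ = np.linalg.svd(d, full_matrices=False)
    var = sv**2
    if var.sum() == 0:
        raise ValueError("maternal genotypes have no variance")
    k = int(np.searchsorted(np.cumsum(var) / var.sum(), var_retained) + 1)
    k = max(1, min(k, n_child // 10, (sv > 1e-10 * sv[0]).sum()))
    pcs = u[:, :k] * sv[:k]
    return pd.DataFrame(
        pcs, index=pd.Index(subject_ids), columns=[f"maternal_pc{i+1}" for i in range(k)]
    )


def run_maternal_sensitivity(config: ScanConfig) -> pd.DataFrame:
    """Scan with maternal genotype components appended to the covariates.

    Maternal dosages for each gene's SNP window are compressed to their
    top principal components (90% variance, capped at n/10 columns) and
    entered into X; base and maternal-adjusted p-values are reported
    side by side.
    """
    if not config.maternal_genotypes:
        raise ValueError("maternal_genotypes path is required")
    genotypes, cohort, loci, timepoints = _load_inputs(config)
    maternal = read_genotypes(config.maternal_genotypes)
    unmatched = sorted(set(genotypes.subject_ids) - set(maternal.subject_ids))
    if unmatched:
        raise ValueError(f"maternal file lacks matched subjects: {unmatched[:10]}")
    if maternal.n_snps == genotypes.n_snps and np.array_equal(
        np.nan_to_num(maternal.dosages), np.nan_to_num(genotypes.dosages)
    ):
        logger.warning("maternal and child dosage matrices are identical")
    rows = []
    for locus in loci:
        gene_gm = extract_gene_snps(genotypes, locus)
        gene_mat = extract_gene_snps(maternal, locus)
        for outcome in config.outcomes:
            for tp in timepoints:
                sub = cohort[cohort["timepoint"].astype(str) == tp]
                base = mixge_gene_test(
                    sub, gene_gm, config.gxe_config(outcome), gene_name=locus.gene_name
                )
                extra = None
                if gene_mat.n_snps and not base.skipped:
                    extra = maternal_pc_covariates(
                        gene_mat, gene_gm.subject_ids, base.n_subjects
                    )
                adj = mixge_gene_test(
                    sub,
                    gene_gm,
                    config.gxe_config(outcome),
                    gene_name=locus.gene_name,
                    extra_covariates=extra,
                )
                rows.append(
                    {
                        "gene": locus.gene_name,
                        "outcome": outcome,
                        "timepoint": tp,
                        "n_maternal_pcs": 0 if extra is None else extra.shape[1],
                        "p_combined_base": base.p_combined,
                        "p_combined_maternal": adj.p_combined,
                        "p_fixed_base": base.p_fixed,
                        "p_fixed_maternal": adj.p_fixed,
                        "p_vc_base": base.p_vc,
                        "p_vc_maternal": adj.p_vc,
                        "skipped": base.skipped or adj.skipped,
                    }
                )
    df = pd.DataFrame(rows)
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "maternal_sensitivity.csv", index=False)
    return df


def run_posthoc(
    config: ScanConfig, gene: str, outcome: str, timepoint: str
) -> tuple[SlopeResult, pd.DataFrame]:
    """GES simple-slope post-hoc for one gene/outcome/timepoint.

    Returns the slope result and a plot-data frame (per-subject
    exposure, covariate-adjusted outcome, GES and GES group) sufficient
    to redraw the low/high-GES moderation panels.
    """
    if not config.eqtl_annotation:
        raise ValueError("eqtl_annotation path is required for post-hoc analysis")
    genotypes, cohort, loci, _ = _load_inputs(config)
    locus = next((l for l in loci if l.gene_name == gene), None)
    if locus is None:
        raise ValueError(f"gene {gene!r} not in the locus table")
    annotation = read_eqtl_annotation(config.eqtl_annotation)
    gene_gm = extract_gene_snps(genotypes, locus)
    sub = cohort[cohort["timepoint"].astype(str) == timepoint].reset_index(drop=True)
    keep = sub["subject_id"].astype(str).isin(gene_gm.subject_ids)
    sub = sub[keep].reset_index(drop=True)
    gm = gene_gm.select_subjects(sub["subject_id"].astype(str).tolist())
    ges = compute_ges(gm, annotation)
    slopes = simple_slopes(sub, ges, outcome=outcome)
    # covariate-adjusted outcome for plotting: remove fitted covariate
    # contributions, keep exposure/GES structure
    from .posthoc import _covariate_matrix, _ols

    include_post = "E_postnatal" in sub.columns and timepoint != "birth"
    covs = _covariate_matrix(sub, include_post)
    y = sub[outcome].to_numpy(float)
    e = sub["E_prenatal"].to_numpy(float)
    ok = np.isfinite(y) & np.isfinite(e) & np.isfinite(covs).all(axis=1)
    X = np.column_stack([np.ones(ok.sum()), covs[ok]])
    beta, _, _ = _ols(X, y[ok])
    adjusted = y[ok] - covs[ok] @ beta[1:]
    plot_df = pd.DataFrame(
        {
            "subject_id": sub.loc[ok, "subject_id"].to_numpy(),
            "E_prenatal": e[ok],
            "adjusted_outcome": adjusted,
            "ges": ges[ok],
            "ges_group": np.where(ges[ok] >= slopes.ges_mean, "high", "low"),
        }
    )
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            [
                {
                    "gene": gene,
                    "outcome": outcome,
                    "timepoint": timepoint,
                    "n": slopes.n,
                    "ges_mean": slopes.ges_mean,
                    "ges_sd": slopes.ges_sd,
                    "slope_low": slopes.slope_low.slope,
                    "se_low": slopes.slope_low.se,
                    "p_low": slopes.slope_low.p,
                    "slope_high": slopes.slope_high.slope,
                    "se_high": slopes.slope_high.se,
                    "p_high": slopes.slope_high.p,
                    "interaction": slopes.interaction.slope,
                    "se_interaction": slopes.interaction.se,
                    "p_interaction": slopes.interaction.p,
                    "n_low": int((plot_df["ges_group"] == "low").sum()),
                    "n_high": int((plot_df["ges_group"] == "high").sum()),
                }
            ]
        ).to_csv(out / "posthoc_slopes.csv", index=False)
        plot_df.to_csv(out / "posthoc_plotdata.csv", index=False)
    return slopes, plot_df
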