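"""Gene-expression scores from eQTL annotations and simple-slope analysis.

The gene-expression score (GES) counts, per subject, the alleles across
a gene's eQTL-annotated SNPs that are associated with higher expression
of the gene; a higher GES therefore indicates genotype associated with
higher expression.  The moderation post-hoc fits

    Y ~ covariates + E + GES + E x GES

and reports the simple slope of the outcome on the exposure at
GES = mean - 1 SD (low-expression group) and mean + 1 SD (high).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import _dummy_code
from .genotype import GenotypeMatrix

__all__ = [
    "EqtlAnnotation",
    "read_eqtl_annotation",
    "compute_ges",
    "SlopeEstimate",
    "SlopeResult",
    "simple_slopes",
]


@dataclass(frozen=True)
class EqtlAnnotation:
    """One SNP's expression-increasing allele from an eQTL resource."""

    snp_id: str
    increasing_allele: str
    source_note: str = ""


def read_eqtl_annotation(path: str) -> list[EqtlAnnotation]:
    """Read a CSV with columns snp_id, increasing_allele[, source_note]."""
    df = pd.read_csv(path)
    for col in ("snp_id", "increasing_allele"):
        if col not in df.columns:
            raise ValueError(f"annotation file missing column {col!r}")
    notes = df["source_note"] if "source_note" in df.columns else [""] * len(df)
    anns = [
        EqtlAnnotation(str(s), str(a), str(n))
        for s, a, n in zip(df["snp_id"], df["increasing_allele"], notes)
    ]
    if len({a.snp_id for a in anns}) != len(anns):
        raise ValueError("duplicated snp_id in annotation file")
    return anns


def compute_ges(genotypes: GenotypeMatrix, annotation: list[EqtlAnnotation]) -> np.ndarray:
    """Per-subject gene-expression score.

    GES = sum over annotated SNPs of the dosage of the
    expression-increasing allele: the alt dosage d when that allele is
    the alt allele, 2 - d when it is the ref allele.  SNPs without an
    annotation contribute nothing; missing dosages are mean-imputed.
    """
    by_id = {a.snp_id: a for a in annotation}
    dos, _ = genotypes.imputed_dosages(max_missing=1.0)
    ges = np.zeros(genotypes.n_subjects)
    for j, snp in enumerate(genotypes.snps):
        ann = by_id.get(snp.snp_id)
        if ann is None:
            continue
        if ann.increasing_allele == snp.alt_allele:
            ges += dos[:, j]
        elif ann.increasing_allele == snp.ref_allele:
            ges += 2.0 - dos[:, j]
        else:
            raise ValueError(
                f"annotation allele {ann.increasing_allele!r} for SNP {snp.snp_id} "
                f"matches neither ref ({snp.ref_allele}) nor alt ({snp.alt_allele})"
            )
    return ges


@dataclass
class SlopeEstimate:
    slope: float
    se: float
    p: float


@dataclass
class SlopeResult:
    """Simple slopes of outcome on exposure at GES mean -/+ 1 SD."""

    ges_mean: float
    ges_sd: float
    slope_low: SlopeEstimate
    slope_high: SlopeEstimate
    interaction: SlopeEstimate
    n: int


def _covariate_matrix(df: pd.DataFrame, include_postnatal: bool) -> np.ndarray:
    sex_map = {"male": 1.0, "female": 0.0, "1": 1.0, "0": 0.0, "m": 1.0, "f": 0.0}
    parts = [
        pd.DataFrame(
            {
                "sex": df["sex"].astype(str).str.lower().map(sex_map),
                "age_at_scan": df["age_at_scan"].astype(float),
            },
            index=df.index,
        ),
        _dummy_code(df["education"], "edu"),
        _dummy_code(df["ethnicity"], "eth"),
    ]
    if include_postnatal:
        parts.append(df[["E_postnatal"]].astype(float))
    return pd.concat(parts, axis=1).to_numpy(dtype=float)


def simple_slopes(
    cohort: pd.DataFrame,
    ges: np.ndarray,
    outcome: str = "volume",
    include_postnatal: bool | None = None,
    at: tuple[float, float] | None = None,
    subgroup_mode: bool = False,
) -> SlopeResult:
    """Moderation analysis of the exposure effect by the GES.

    Fits Y ~ covariates + E + GES + E x GES by least squares and
    evaluates the exposure slope b_E + b_int * g0 at g0 = GES mean -/+ 1
    SD (or the values in ``at``), with standard errors from the
    coefficient covariance and two-sided t p-values.

    ``subgroup_mode`` instead splits subjects at the GES mean and fits
    the covariate-adjusted exposure slope separately in each subgroup
    (sensitivity variant); the interaction estimate still comes from the
    pooled model.
    """
    if include_postnatal is None:
        tp = cohort["timepoint"].astype(str).unique() if "timepoint" in cohort else ["birth"]
        include_postnatal = "E_postnatal" in cohort.columns and not (
            len(tp) == 1 and tp[0] == "birth"
        )
    ges = np.asarray(ges, dtype=float)
    if len(ges) != len(cohort):
        raise ValueError("GES vector length must match the cohort table")
    covs = _covariate_matrix(cohort, include_postnatal)
    y = cohort[outcome].to_numpy(dtype=float)
    e = cohort["E_prenatal"].to_numpy(dtype=float)
    keep = np.isfinite(y) & np.isfinite(e) & np.isfinite(covs).all(axis=1)
    y, e, g, covs = y[keep], e[keep], ges[keep], covs[keep]
    n = len(y)
    if n < 10:
        raise ValueError("fewer than 10 complete rows")
    if np.std(g) == 0:
        raise ValueError("no genetic variation at annotated SNPs")
    g_mean, g_sd = float(g.mean()), float(g.std(ddof=1))
    lo, hi = at if at is not None else (g_mean - g_sd, g_mean + g_sd)

    X = np.column_stack([np.ones(n), covs, e, g, e * g])
    i_e, i_int = X.shape[1] - 3, X.shape[1] - 1
    beta, cov_b, dof = _ols(X, y)
    interaction = _estimate(beta[i_int], cov_b[i_int, i_int], dof)

    def slope_at(g0: float) -> SlopeEstimate:
        b = beta[i_e] + beta[i_int] * g0
        var = (
            cov_b[i_e, i_e] + g0**2 * cov_b[i_int, i_int] + 2 * g0 * cov_b[i_e, i_int]
        )
        return _estimate(b, var, dof)

    if subgroup_mode:
        low_mask = g < g_mean
        slopes = []
        for mask in (low_mask, ~low_mask):
            Xs = np.column_stack([np.ones(mask.sum()), covs[mask], e[mask]])
            bs, cs, ds = _ols(Xs, y[mask])
            slopes.append(_estimate(bs[-1], cs[-1, -1], ds))
        slope_low, slope_high = slopes
    else:
        slope_low, slope_high = slope_at(lo), slope_at(hi)
    return SlopeResult(g_mean, g_sd, slope_low, slope_high, interaction, n)


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - p
    if dof < 1:
        raise ValueError("not enough residual degrees of freedom")
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.pinv(X.T @ X)
    return beta, cov, dof


def _estimate(b: float, var: float, dof: int) -> SlopeEstimate:
    se = float(np.sqrt(max(var, 0.0)))
    if se == 0:
        return SlopeEstimate(float(b), 0.0, 1.0)
    t = b / se
    return SlopeEstimate(float(b), se, float(2 * stats.t.sf(abs(t), dof)))
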