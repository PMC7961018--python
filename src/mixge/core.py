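"""Gene-set gene-environment interaction (GxE) score tests.

The model for a gene with m SNPs is

    Y = Z beta + diag(E) G pi + diag(E) G delta,   Z = [X, E, G],

where X holds the covariates (intercept, sex, age at scan, SES/education
and ethnicity dummies, optionally the postnatal exposure and maternal
genotype components), E is the continuous exposure, and G the n x m
dosage matrix.  ``pi`` is a single fixed (accumulative/burden) GxE
coefficient on the weighted SNP sum; ``delta`` are per-SNP random GxE
effects with variance tau capturing heterogeneous interaction.

Both hypotheses are tested by score tests against a shared null model in
which X and E enter unpenalized and the G main effects are
ridge-penalized (lambda by generalized cross-validation), since m often
exceeds n.  The burden statistic is referred to chi-square(1); the
variance-component statistic to its weighted chi-square mixture via
characteristic-function inversion.  The gene-level p-value is the Fisher
combination of the two, with the variance-component stage orthogonalized
to the burden regressor so the two p-values are asymptotically
independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotype import GenotypeMatrix, filter_hwe
from .quadform import davies_mixture_pvalue, liu_mixture_pvalue, signed_quadform_sf0

logger = logging.getLogger(__name__)

__all__ = [
    "DesignMatrices",
    "MixGEFit",
    "GxETestResult",
    "GxEConfig",
    "build_design",
    "fit_null_model",
    "burden_gxe_score_test",
    "variance_component_gxe_test",
    "combine_fixed_and_vc",
    "mixge_gene_test",
    "snp_weights",
]

_EIG_TRUNC = 1e-10


@dataclass
class DesignMatrices:
    """Aligned outcome, covariate, exposure and genotype blocks.

    ``X`` includes the intercept.  ``E`` is the exposure as given;
    ``E_centered`` (used to form interaction regressors) is mean-centered
    so that every reported p-value is invariant to location shifts of
    the exposure.  ``G`` is the dosage block after per-SNP mean
    imputation of missing entries.
    """

    y: np.ndarray
    X: np.ndarray
    E: np.ndarray
    G: np.ndarray
    subject_ids: list[str]
    x_names: list[str]
    snp_ids: list[str]
    n_dropped: int = 0

    def __post_init__(self) -> None:
        n = len(self.y)
        if not (self.X.shape[0] == n == len(self.E) == self.G.shape[0]):
            raise ValueError("inconsistent block heights")
        sd = self.X.std(axis=0)
        const = (sd == 0) & (np.arange(self.X.shape[1]) != 0)
        if const.any():
            bad = [self.x_names[j] for j in np.where(const)[0]]
            raise ValueError(f"constant non-intercept covariate columns: {bad}")

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def m(self) -> int:
        return self.G.shape[1]

    @property
    def E_centered(self) -> np.ndarray:
        return self.E - self.E.mean()

    @property
    def Z(self) -> np.ndarray:
        return np.column_stack([self.X, self.E, self.G])


def _dummy_code(series: pd.Series, prefix: str) -> pd.DataFrame:
    """k-1 dummies against the most frequent category."""
    s = series.astype(str)
    ref = s.value_counts().idxmax()
    levels = [l for l in s.value_counts().index if l != ref]
    out = pd.DataFrame({f"{prefix}_{l}": (s == l).astype(float) for l in levels})
    out.index = series.index
    return out


def build_design(
    cohort: pd.DataFrame,
    genotypes: GenotypeMatrix,
    outcome: str,
    extra_covariates: pd.DataFrame | None = None,
    include_postnatal: bool | None = None,
) -> DesignMatrices:
    """Assemble aligned design blocks from a cohort table and genotypes.

    Covariates are intercept, sex (female = 0), age at scan, education
    and ethnicity dummies (reference = most frequent category), plus the
    postnatal exposure when ``include_postnatal`` is true (default: true
    whenever the cohort's timepoint is not "birth" and the column is
    present).  Rows with any missing outcome, exposure or covariate are
    dropped listwise with a logged count, as are subjects absent from
    the genotype matrix.  ``extra_covariates`` (e.g. maternal genotype
    components) is a subject_id-indexed frame appended to X.
    """
    if outcome not in cohort.columns:
        raise ValueError(f"outcome column {outcome!r} not in cohort table")
    df = cohort.copy()
    if include_postnatal is None:
        tp = df["timepoint"].astype(str).unique() if "timepoint" in df else ["birth"]
        include_postnatal = "E_postnatal" in df.columns and not (
            len(tp) == 1 and tp[0] == "birth"
        )
    sex_map = {"male": 1.0, "female": 0.0, "1": 1.0, "0": 0.0, "m": 1.0, "f": 0.0}
    sex = df["sex"].astype(str).str.lower().map(sex_map)
    if sex.isna().any() and not df["sex"].isna().any():
        raise ValueError("unrecognized sex coding; expected male/female or 0/1")
    parts = [
        pd.DataFrame({"sex": sex, "age_at_scan": df["age_at_scan"]}, index=df.index),
        _dummy_code(df["education"], "edu"),
        _dummy_code(df["ethnicity"], "eth"),
    ]
    if include_postnatal:
        if "E_postnatal" not in df.columns:
            raise ValueError("postnatal exposure requested but E_postnatal missing")
        parts.append(df[["E_postnatal"]].astype(float))
    xdf = pd.concat(parts, axis=1)
    keep = (
        df[outcome].notna()
        & df["E_prenatal"].notna()
        & xdf.notna().all(axis=1)
        & df["subject_id"].astype(str).isin(genotypes.subject_ids)
    )
    if extra_covariates is not None:
        keep &= df["subject_id"].astype(str).isin(extra_covariates.index.astype(str))
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("build_design: dropped %d incomplete/unmatched rows", n_dropped)
    df, xdf = df[keep], xdf[keep]
    subject_ids = df["subject_id"].astype(str).tolist()
    X = np.column_stack([np.ones(len(df)), xdf.to_numpy(dtype=float)])
    x_names = ["intercept"] + list(xdf.columns)
    if extra_covariates is not None:
        extra = extra_covariates.loc[subject_ids].to_numpy(dtype=float)
        X = np.column_stack([X, extra])
        x_names += [str(c) for c in extra_covariates.columns]
    if len(df) < X.shape[1] + 5:
        raise ValueError(
            f"insufficient sample: {len(df)} usable rows for {X.shape[1]} covariates"
        )
    gm = genotypes.select_subjects(subject_ids)
    G, snp_keep = gm.imputed_dosages()
    G = G[:, snp_keep]
    snp_ids = [s for s, k in zip(gm.snp_ids, snp_keep) if k]
    return DesignMatrices(
        y=df[outcome].to_numpy(dtype=float),
        X=X,
        E=df["E_prenatal"].to_numpy(dtype=float),
        G=G,
        subject_ids=subject_ids,
        x_names=x_names,
        snp_ids=snp_ids,
        n_dropped=n_dropped,
    )


@dataclass
class MixGEFit:
    """Fitted null model Y ~ X + E + (ridge) G.

    Stores the pieces needed to apply the symmetric residual operator
    M = I - P_U - S_lambda, where P_U projects onto the unpenalized
    block U = [X, E] and S_lambda is the ridge smoother on the
    U-residualized G block.
    """

    beta_unpenalized: np.ndarray
    gamma_ridge: np.ndarray
    lam: float
    residuals: np.ndarray
    sigma2_hat: float
    edf: float
    _Q_u: np.ndarray = field(repr=False, default=None)
    _A: np.ndarray = field(repr=False, default=None)  # left singular vectors of G~
    _shrink: np.ndarray = field(repr=False, default=None)  # d^2/(d^2+lam)

    def apply_M(self, v: np.ndarray) -> np.ndarray:
        """Residual operator applied to a vector or column-stacked matrix."""
        out = v - self._Q_u @ (self._Q_u.T @ v)
        if self._A is not None and self._A.size:
            if out.ndim == 1:
                out = out - self._A @ (self._shrink * (self._A.T @ out))
            else:
                out = out - self._A @ (self._shrink[:, None] * (self._A.T @ out))
        return out

    def M_matrix(self) -> np.ndarray:
        """The symmetric residual operator M = I - P_U - S_lambda as a dense matrix."""
        n = self._Q_u.shape[0]
        return self.apply_M(np.eye(n))


def fit_null_model(d: DesignMatrices, ridge: str | float = "gcv") -> MixGEFit:
    """Fit the null model with unpenalized [X, E] and ridge-penalized G.

    ``ridge`` is "gcv" (generalized cross-validation over a log-spaced
    grid) or a fixed non-negative penalty.  With m = 0 SNPs, or with
    lambda = 0 on a full-rank G, the fit is exactly ordinary least
    squares.  Residuals are orthogonal to [X, E] by construction.
    """
    U = np.column_stack([d.X, d.E])
    if np.linalg.matrix_rank(U) < U.shape[1]:
        # name the offending columns for the error message
        names = d.x_names + ["E"]
        r = np.linalg.qr(U, mode="r")
        bad = [names[j] for j in np.where(np.abs(np.diag(r)) < 1e-8)[0]]
        raise ValueError(f"collinear unpenalized columns: {bad or names}")
    Q_u, R_u = np.linalg.qr(U)
    y_res = d.y - Q_u @ (Q_u.T @ d.y)
    n, m = d.n, d.m
    if m == 0:
        beta = np.linalg.solve(R_u, Q_u.T @ d.y)
        edf = U.shape[1]
        sigma2 = float(y_res @ y_res) / (n - edf)
        return MixGEFit(beta, np.zeros(0), 0.0, y_res, sigma2, edf, Q_u, None, None)
    G_res = d.G - Q_u @ (Q_u.T @ d.G)
    A, sv, Bt = np.linalg.svd(G_res, full_matrices=False)
    nz = sv > 1e-10 * (sv[0] if sv.size else 1.0)
    A, sv, Bt = A[:, nz], sv[nz], Bt[nz]
    z = A.T @ y_res
    d2 = sv**2
    if ridge == "gcv":
        grid = np.geomspace(1e-4, 1e4, 45) * (d2.mean() if d2.size else 1.0)
        h = d2[None, :] / (d2[None, :] + grid[:, None])  # shrinkage per lambda
        rss = float(y_res @ y_res) - np.sum((z**2)[None, :] * h * (2 - h), axis=1)
        df_model = U.shape[1] + h.sum(axis=1)
        gcv = n * rss / (n - df_model) ** 2
        lam = float(grid[int(np.argmin(gcv))])
    else:
        lam = float(ridge)
        if lam < 0:
            raise ValueError("ridge penalty must be >= 0")
    shrink = d2 / (d2 + lam) if lam > 0 else np.ones_like(d2)
    resid = y_res - A @ (shrink * z)
    gamma = Bt.T @ ((sv / (d2 + lam) if lam > 0 else 1.0 / sv) * z)
    beta = np.linalg.solve(R_u, Q_u.T @ (d.y - d.G @ gamma))
    edf = U.shape[1] + float(shrink.sum())
    dof = max(n - edf, 1.0)
    sigma2 = float(resid @ resid) / dof
    if sigma2 <= 0:
        raise ValueError("non-positive residual variance")
    return MixGEFit(beta, gamma, lam, resid, sigma2, edf, Q_u, A, shrink)


def snp_weights(d: DesignMatrices, scheme: str = "equal") -> np.ndarray:
    """Per-SNP weights: "equal" (all one) or "beta" (Beta(1,25) pdf of MAF)."""
    if scheme == "equal":
        return np.ones(d.m)
    if scheme == "beta":
        af = d.G.mean(axis=0) / 2.0
        maf = np.minimum(af, 1 - af)
        return stats.beta.pdf(maf, 1, 25)
    raise ValueError(f"unknown weight scheme {scheme!r}")


def burden_gxe_score_test(
    fit: MixGEFit, d: DesignMatrices, weights: np.ndarray | None = None
) -> tuple[float, float, bool]:
    """Score test of the accumulative (burden) GxE coefficient pi.

    Forms the single regressor s = diag(E_centered) G w and tests its
    addition to the null via (s'r)^2 / (sigma2 * ||Ms||^2), referred to
    chi-square(1); ||Ms||^2 reduces to the projection form s'P0s when
    the null contains no ridge-penalized block.  Returns (statistic, p, degenerate_flag); a regressor
    numerically inside the null span yields p = 1 with the flag set.
    """
    if np.std(d.E) == 0:
        raise ValueError("exposure has no variance")
    w = np.ones(d.m) if weights is None else np.asarray(weights, float)
    s = d.E_centered * (d.G @ w)
    ms = fit.apply_M(s)
    # Var(s'MY) = sigma^2 * s'M^2 s; equals s'Ms only for idempotent M
    denom = float(ms @ ms)
    if denom <= 1e-12 * max(float(s @ s), 1e-300):
        return 0.0, 1.0, True
    stat = float(s @ fit.residuals) ** 2 / (fit.sigma2_hat * denom)
    return stat, float(stats.chi2.sf(stat, 1)), False


def variance_component_gxe_test(
    fit: MixGEFit,
    d: DesignMatrices,
    weights: np.ndarray | None = None,
    orthogonalize_to: np.ndarray | None = None,
) -> tuple[float, np.ndarray, float, str]:
    """Score test of the heterogeneous GxE variance component tau.

    With C = diag(E_centered) G W^(1/2), the statistic is
    Q = r'C C'r / (2 sigma2).  Its large-sample null distribution is
    the weighted chi-square mixture with weights the nonzero
    eigenvalues of (1/2) (MC)'(MC), M the null residual operator
    (C'P0C/2 when M is a projection); those eigenvalues are returned
    for diagnostics.  The p-value itself uses the exact
    finite-sample form that accounts for the plug-in variance
    estimate: the event Q >= q is the indefinite quadratic form
    Y' (M C C'M - (2q/nu) M^2) Y >= 0 with nu the residual degrees of
    freedom, evaluated by signed-eigenvalue inversion (falling back to
    the large-sample mixture when the inversion fails).  When
    ``orthogonalize_to`` is given (the burden regressor), M is further
    deflated by it so the resulting p-value is asymptotically
    independent of the burden test.  Returns (Q, eigenvalues, p,
    method).
    """
    if d.m < 1:
        raise ValueError("need at least one SNP")
    w = np.ones(d.m) if weights is None else np.asarray(weights, float)
    C = d.E_centered[:, None] * d.G * np.sqrt(w)[None, :]
    if not C.any():
        return 0.0, np.zeros(0), 1.0, "davies"
    u = None
    if orthogonalize_to is not None:
        mu = fit.apply_M(orthogonalize_to)
        nrm = float(mu @ mu)
        if nrm > 1e-12 * max(float(orthogonalize_to @ orthogonalize_to), 1e-300):
            u = mu / np.sqrt(nrm)
    r = fit.residuals
    B = fit.apply_M(C)
    if u is not None:
        r = r - u * float(u @ fit.residuals)
        B = B - np.outer(u, u @ B)
    score = C.T @ r
    q_stat = float(score @ score) / (2.0 * fit.sigma2_hat)
    lam = np.linalg.eigvalsh(B.T @ B) / 2.0
    lam = lam[lam > _EIG_TRUNC * max(lam.max(), 1e-300)]
    if lam.size == 0 or q_stat <= 0:
        return q_stat, lam, 1.0, "davies"
    # exact ratio form: Q >= q  <=>  Y'(M2 K M2 - (2q/nu) M^2) Y >= 0
    n = d.n
    nu = max(n - fit.edf, 1.0)
    m_mat = fit.M_matrix()
    composite = B @ B.T - (2.0 * q_stat / nu) * (m_mat @ m_mat)
    ev = np.linalg.eigvalsh(composite)
    ev = ev[np.abs(ev) > _EIG_TRUNC * max(np.abs(ev).max(), 1e-300)]
    if ev.size:
        ps = signed_quadform_sf0(ev)
        if np.isfinite(ps):
            return q_stat, lam, float(ps), ps.method
    pd_ = davies_mixture_pvalue(q_stat, lam)
    return q_stat, lam, float(pd_), pd_.method


def combine_fixed_and_vc(p_fixed: float, p_vc: float) -> float:
    """Fisher combination of the burden and variance-component p-values.

    X = -2 (ln p_fixed + ln p_vc) referred to chi-square(4); valid when
    the two stages are independent, which the orthogonalized
    variance-component stage supports.
    """
    if not (0 < p_fixed <= 1 and 0 < p_vc <= 1):
        raise ValueError("p-values must lie in (0, 1]")
    x = -2.0 * (np.log(p_fixed) + np.log(p_vc))
    return float(stats.chi2.sf(x, 4))


@dataclass
class GxEConfig:
    """Options for a single-gene MixGE test."""

    outcome: str = "volume"
    hwe_alpha: float = 0.05
    hwe_correction: str = "bonferroni"
    apply_hwe_filter: bool = True
    weights: str = "equal"
    ridge: str | float = "gcv"
    include_postnatal: bool | None = None
    permutation_guard: bool = False
    n_permutations: int = 100_000
    seed: int = 0


@dataclass
class GxETestResult:
    """Per-gene GxE test result: one row of the scan output."""

    gene_name: str
    n_subjects: int = 0
    n_snps_tested: int = 0
    stat_fixed: float = float("nan")
    p_fixed: float = float("nan")
    Q: float = float("nan")
    p_vc: float = float("nan")
    p_combined: float = float("nan")
    eigenvalues: np.ndarray = field(default_factory=lambda: np.zeros(0))
    method_flags: list[str] = field(default_factory=list)
    skipped: bool = False
    skip_reason: str = ""


def _permutation_pvalue(
    fit: MixGEFit,
    d: DesignMatrices,
    C: np.ndarray,
    u: np.ndarray | None,
    q_obs: float,
    n_perm: int,
    seed: int,
) -> float:
    """Residual-permutation p for the variance-component statistic.

    Residuals are permuted, added back to the fitted values, and the
    whole statistic (including the variance estimate) is recomputed, so
    the permutation reference matches the ratio-form null.
    """
    rng = np.random.default_rng(seed)
    M = fit.M_matrix()
    r = fit.residuals
    yh_m = (d.y - r) @ M
    nu = max(d.n - fit.edf, 1.0)
    hits = 0
    done = 0
    while done < n_perm:
        k = min(4000, n_perm - done)
        idx = rng.permuted(np.tile(np.arange(d.n), (k, 1)), axis=1)
        rf = yh_m[None, :] + r[idx] @ M
        sigma2 = (rf**2).sum(axis=1) / nu
        if u is not None:
            rf = rf - np.outer(rf @ u, u)
        scores = rf @ C  # k x m
        q = (scores**2).sum(axis=1) / (2.0 * sigma2)
        hits += int((q >= q_obs).sum())
        done += k
    return (1 + hits) / (1 + n_perm)


def mixge_gene_test(
    cohort: pd.DataFrame,
    gene_genotypes: GenotypeMatrix,
    config: GxEConfig | None = None,
    gene_name: str = "gene",
    extra_covariates: pd.DataFrame | None = None,
) -> GxETestResult:
    """Run the full MixGE test for one gene's SNP set.

    Applies the Hardy-Weinberg filter, builds the design, fits the
    ridge null model, runs the burden and (orthogonalized)
    variance-component score tests, and Fisher-combines them.  A gene
    with zero SNPs surviving the filter returns a skipped record rather
    than raising.
    """
    config = config or GxEConfig()
    gm = gene_genotypes
    if config.apply_hwe_filter and gm.n_snps:
        gm, _ = filter_hwe(gm, alpha=config.hwe_alpha, correction=config.hwe_correction)
    if gm.n_snps == 0:
        return GxETestResult(
            gene_name=gene_name, skipped=True, skip_reason="no SNPs after filtering"
        )
    d = build_design(
        cohort,
        gm,
        outcome=config.outcome,
        extra_covariates=extra_covariates,
        include_postnatal=config.include_postnatal,
    )
    if d.m == 0:
        return GxETestResult(
            gene_name=gene_name, skipped=True, skip_reason="no SNPs after missingness filter"
        )
    fit = fit_null_model(d, ridge=config.ridge)
    w = snp_weights(d, config.weights)
    stat_f, p_fixed, degen = burden_gxe_score_test(fit, d, w)
    s = d.E_centered * (d.G @ w)
    q_stat, lam, p_vc, method = variance_component_gxe_test(
        fit, d, w, orthogonalize_to=None if degen else s
    )
    flags = [method] + (["degenerate_burden"] if degen else [])
    if config.permutation_guard and lam.size:
        p_liu = liu_mixture_pvalue(q_stat, lam)
        lo, hi = sorted([max(p_vc, 1e-300), max(p_liu, 1e-300)])
        if hi / lo > 2.0:
            C = d.E_centered[:, None] * d.G * np.sqrt(w)[None, :]
            u = None
            if not degen:
                ms = fit.apply_M(s)
                nrm = float(ms @ ms)
                if nrm > 0:
                    u = ms / np.sqrt(nrm)
            p_vc = _permutation_pvalue(
                fit, d, C, u, q_stat, config.n_permutations, config.seed
            )
            flags.append("permutation")
    p_comb = combine_fixed_and_vc(max(p_fixed, 1e-300), max(p_vc, 1e-300))
    return GxETestResult(
        gene_name=gene_name,
        n_subjects=d.n,
        n_snps_tested=d.m,
        stat_fixed=stat_f,
        p_fixed=p_fixed,
        Q=q_stat,
        p_vc=p_vc,
        p_combined=p_comb,
        eigenvalues=lam,
        method_flags=flags,
    )
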