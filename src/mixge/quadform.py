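"""Tail probabilities of positively weighted sums of chi-square(1) variables.

The variance-component score statistic is asymptotically distributed as
Q ~ sum_i lambda_i * chi2_1 under the null.  P(Q >= q) is computed by
numerical inversion of the characteristic function (Davies/Imhof,
implemented as an error-bounded Gil-Pelaez midpoint sum), with exact
closed forms when all eigenvalues coincide (a scaled chi-square) and a
Liu-style moment-matching fallback (non-central chi-square matched on
skewness/kurtosis) when the inversion is infeasible or leaves (0, 1].
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["davies_mixture_pvalue", "liu_mixture_pvalue", "MixturePValue"]

_CHUNK = 200_000
_KMAX = 2_500_000


class MixturePValue(float):
    """A p-value carrying the method used to compute it."""

    method: str

    def __new__(cls, value: float, method: str) -> "MixturePValue":
        obj = super().__new__(cls, value)
        obj.method = method
        return obj


def liu_mixture_pvalue(q: float, eigenvalues) -> float:
    """Moment-matching tail probability for sum_i lambda_i chi2_1.

    Matches the first moments of Q to a scaled (non-central) chi-square
    following Liu, Tang & Zhang's construction.
    """
    lam = np.asarray(eigenvalues, dtype=float).ravel()
    lam = lam[lam > 0]
    if lam.size == 0:
        raise ValueError("no positive eigenvalues")
    c1, c2, c3, c4 = (float(np.sum(lam**k)) for k in (1, 2, 3, 4))
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        ncp = s1 * a**3 - a**2
        dof = a**2 - 2 * ncp
    else:
        dof = 1.0 / s2
        ncp = 0.0
    t = (q - c1) / np.sqrt(2 * c2) * np.sqrt(2 * (dof + 2 * ncp)) + dof + ncp
    if ncp > 0:
        p = stats.ncx2.sf(t, dof, ncp)
    else:
        p = stats.chi2.sf(t, dof)
    return float(min(max(p, 0.0), 1.0))


def _gil_pelaez_sum(q: float, lam: np.ndarray, eps: float) -> float | None:
    """Midpoint-rule Gil-Pelaez inversion; None when infeasible at eps.

    Supports signed eigenvalues (the quadratic form need not be
    positive).  The grid step bounds the aliasing error (period
    2*pi/step placed far in the tail); the truncation point U satisfies
    integral_U^inf du / (u * prod(|lam_i| u)^(1/2)) <= pi * eps.
    """
    m = lam.size
    mu = float(lam.sum())
    sigma = float(np.sqrt(2.0 * np.sum(lam**2)))
    log_u = (
        np.log(2.0 / m) - 0.5 * float(np.sum(np.log(np.abs(lam)))) - np.log(np.pi * eps)
    ) / (m / 2.0)
    if log_u > 50:  # truncation point astronomically far
        return None
    u_max = float(np.exp(log_u))
    step = 2.0 * np.pi / (abs(q) + abs(mu) + 30.0 * sigma)
    n_points = int(np.ceil(u_max / step))
    if n_points > _KMAX:
        return None
    total = 0.0
    for start in range(0, n_points, _CHUNK):
        u = (np.arange(start, min(start + _CHUNK, n_points)) + 0.5) * step
        lu = np.outer(u, lam)
        theta = 0.5 * np.arctan(lu).sum(axis=1) - 0.5 * q * u
        log_rho = 0.25 * np.log1p(lu**2).sum(axis=1)
        total += float(np.sum(np.sin(theta) / (u * np.exp(log_rho))))
    return 0.5 + (step / np.pi) * total


def davies_mixture_pvalue(q: float, eigenvalues) -> MixturePValue:
    """P(sum_i lambda_i chi2_1 >= q), eigenvalues all central 1-df.

    Eigenvalues below 1e-10 x the largest are truncated.  The returned
    float carries ``method`` in {"davies", "liu_fallback"}; the exact
    scaled chi-square closed form used when all eigenvalues coincide is
    reported as "davies".
    """
    lam = np.asarray(eigenvalues, dtype=float).ravel()
    lam = lam[lam > 0]
    if lam.size == 0:
        raise ValueError("no positive eigenvalues")
    lam = lam[lam > 1e-10 * lam.max()]
    if q <= 0:
        return MixturePValue(1.0, "davies")
    if np.allclose(lam, lam[0], rtol=1e-12, atol=0.0):
        # Q/lam ~ chi2 with len(lam) df, exactly
        return MixturePValue(float(stats.chi2.sf(q / lam[0], lam.size)), "davies")
    for eps in (1e-7, 1e-6, 1e-5):
        p = _gil_pelaez_sum(q, lam, eps)
        if p is not None:
            break
    if p is None or not np.isfinite(p) or p <= 0.0 or p > 1.0:
        return MixturePValue(liu_mixture_pvalue(q, lam), "liu_fallback")
    return MixturePValue(min(p, 1.0), "davies")


def signed_quadform_sf0(eigenvalues) -> MixturePValue:
    """P(sum_i lambda_i chi2_1 >= 0) for eigenvalues of mixed sign.

    This is the tail probability of an indefinite Gaussian quadratic
    form at zero, as arises when a variance-component statistic is
    compared against its own plug-in variance estimate (the event
    Q >= q rewritten as a single quadratic form >= 0).  Returns None's
    fallback (the definite-form Davies value is supplied by the caller)
    encoded as method "liu_fallback" only if the inversion fails.
    """
    lam = np.asarray(eigenvalues, dtype=float).ravel()
    lam = lam[np.abs(lam) > 1e-12 * max(np.abs(lam).max(), 1e-300)]
    if lam.size == 0:
        raise ValueError("no nonzero eigenvalues")
    if (lam > 0).all():
        return MixturePValue(1.0, "davies")
    if (lam < 0).all():
        return MixturePValue(0.0, "davies")
    for eps in (1e-8, 1e-7, 1e-6):
        p = _gil_pelaez_sum(0.0, lam, eps)
        if p is not None:
            break
    if p is None or not np.isfinite(p) or not (0.0 <= p <= 1.0):
        return MixturePValue(float("nan"), "liu_fallback")
    return MixturePValue(p, "davies")
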