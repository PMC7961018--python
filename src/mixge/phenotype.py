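"""Per-subject phenotype tables, questionnaire scoring and demographics.

The exposure of interest is a depressive-symptom questionnaire total
(EPDS: 10 items scored 0-3, total 0-30) measured prenatally; the same
scale at a postnatal timepoint enters later analyses as a covariate.
Outcomes are quantitative regional brain measures (volume in mm^3 or
thickness in mm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScaleResponse",
    "EPDS_ITEMS",
    "EPDS_ITEM_MAX",
    "prorate_total",
    "max_scale_total",
    "group_anova",
    "load_cohort",
    "COHORT_REQUIRED_COLUMNS",
]

EPDS_ITEMS = 10
EPDS_ITEM_MAX = 3

#: Columns a cohort table must provide; outcome columns are free-form
#: (any quantitative column can serve as the outcome).
COHORT_REQUIRED_COLUMNS = (
    "subject_id",
    "E_prenatal",
    "sex",
    "age_at_scan",
    "ethnicity",
    "education",
    "timepoint",
)


@dataclass
class ScaleResponse:
    """One subject's item-level responses on a fixed-length scale.

    ``item_scores`` holds integers in [0, item_max] with None for
    unanswered items.
    """

    item_scores: list[int | None]
    n_items: int = EPDS_ITEMS
    item_max: int = EPDS_ITEM_MAX

    def __post_init__(self) -> None:
        if len(self.item_scores) != self.n_items:
            raise ValueError("item_scores length must equal n_items")
        for s in self.item_scores:
            if s is not None and not (0 <= s <= self.item_max):
                raise ValueError(f"item score {s} outside [0, {self.item_max}]")


def max_scale_total(n_items: int, item_max: int) -> int:
    """Maximum attainable total of a scale: n_items x item_max.

    For the 10-item EPDS scored 0-3 this is 30.
    """
    if n_items < 1 or item_max < 0:
        raise ValueError("need n_items >= 1 and item_max >= 0")
    return n_items * item_max


def prorate_total(resp: ScaleResponse, min_answered: int = 8) -> float | None:
    """Questionnaire total with proration for near-complete responses.

    Fully answered scales return the plain sum.  When at least
    ``min_answered`` but fewer than all items are answered, the observed
    sum is scaled by n_items / n_answered and kept fractional.  Fewer
    answered items yield None (missing).
    """
    if min_answered > resp.n_items:
        raise ValueError("min_answered exceeds n_items")
    answered = [s for s in resp.item_scores if s is not None]
    k = len(answered)
    if k == resp.n_items:
        return float(sum(answered))
    if k >= min_answered:
        return sum(answered) * resp.n_items / k
    return None


def group_anova(values, groups) -> tuple[float, int, int, float]:
    """One-way fixed-effects ANOVA across labelled groups.

    Returns (F, df1, df2, p) with df1 = k - 1 and df2 = N - k.  When all
    groups share a common constant value, F is defined as 0 with p = 1.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[groups == g] for g in labels]
    for s in samples:
        if len(s) < 2:
            raise ValueError("each group needs at least 2 values")
    k = len(samples)
    n = len(values)
    df1, df2 = k - 1, n - k
    if np.allclose(values, values[0]):
        return 0.0, df1, df2, 1.0
    f, p = stats.f_oneway(*samples)
    if not math.isfinite(f):
        f, p = 0.0, 1.0
    return float(f), df1, df2, float(p)


def load_cohort(path: str) -> pd.DataFrame:
    """Read a cohort CSV and validate the column contract.

    Required columns: subject_id, E_prenatal, sex, age_at_scan,
    ethnicity, education, timepoint; E_postnatal and any number of
    outcome columns may be present.  Missing values are empty cells or
    NA.  Duplicate subject ids within a timepoint are rejected.
    """
    df = pd.read_csv(path)
    missing = [c for c in COHORT_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    dup = df.duplicated(subset=["subject_id", "timepoint"])
    if dup.any():
        raise ValueError("duplicated subject_id within a timepoint")
    return df
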