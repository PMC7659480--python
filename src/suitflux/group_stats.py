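"""Group summaries and control-vs-treated comparisons.

Values are summarized as mean with sample standard deviation and compared
with a two-sided unpaired t-test (Student by default, Welch on request).
Significance stars follow the usual thresholds: * p<0.05, ** p<0.01,
*** p<0.001.  Each contrast is reported with its own p-value; no
multiple-testing correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .metrics import percent_change

__all__ = ["GroupComparison", "summarize", "compare", "stars"]

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def stars(p_value: float) -> str:
    """Significance stars for a p-value (ns / * / ** / ***)."""
    for threshold, label in STAR_THRESHOLDS:
        if p_value < threshold:
            return label
    return "ns"


@dataclass(frozen=True)
class GroupComparison:
    """One control-vs-treated contrast row."""

    metric: str
    state: str
    mean_control: float
    sd_control: float | None
    n_control: int
    mean_treated: float
    sd_treated: float | None
    n_treated: int
    percent_change: float
    t_statistic: float
    p_value: float
    significance: str


def summarize(values) -> tuple[float, float | None, int]:
    """Mean, sample standard deviation (n-1 denominator) and n.

    The sd is ``None`` for a single observation (undefined, not zero).
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty list")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else None
    return mean, sd, int(arr.size)


def compare(
    control,
    treated,
    variant: str = "student",
    metric: str = "",
    state: str = "",
) -> GroupComparison:
    """Two-sided unpaired t-test of treated against control.

    ``variant`` selects the classic equal-variance Student test (default)
    or Welch's unequal-variance test.  The percent change is computed on
    the group means.
    """
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    a = np.asarray(list(control), dtype=float)
    b = np.asarray(list(treated), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group for a t-test")
    res = sps.ttest_ind(b, a, equal_var=(variant == "student"))
    t_stat = float(res.statistic)
    p_val = float(res.pvalue)
    if math.isnan(p_val):  # zero variance in both groups, identical means
        t_stat, p_val = 0.0, 1.0
    mc, sc, nc = summarize(a)
    mt, st, nt = summarize(b)
    return GroupComparison(
        metric=metric,
        state=state,
        mean_control=mc,
        sd_control=sc,
        n_control=nc,
        mean_treated=mt,
        sd_treated=st,
        n_treated=nt,
        percent_change=percent_change(mc, mt) if mc != 0 else float("nan"),
        t_statistic=t_stat,
        p_value=p_val,
        significance=stars(p_val),
    )
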