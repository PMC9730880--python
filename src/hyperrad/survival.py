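"""Landmark survival analysis and cohort comparison statistics.

Overall survival is summarized with the Kaplan-Meier estimator, compared
between patient groups with the log-rank test, and quantified with hazard
ratios from univariable proportional-hazards fits (Efron tie handling, Wald
95% CI).  The survival clock is re-origined at a landmark (3 months after
treatment start by default) to avoid guarantee-time bias: patients who die
or are censored before the landmark are excluded and the remaining times are
reduced by it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

__all__ = [
    "landmark_filter",
    "km_estimate",
    "logrank_test",
    "hazard_ratio",
    "fisher_exact",
    "mann_whitney",
    "KMResult",
    "HazardRatioResult",
]


@dataclass
class KMResult:
    times: np.ndarray          # event/censoring times in ascending order
    survival: np.ndarray       # S(t) at those times
    median: float              # first t with S(t) <= 0.5; inf if not reached

    @property
    def median_reached(self) -> bool:
        return math.isfinite(self.median)


@dataclass
class HazardRatioResult:
    hr: float
    ci_low: float
    ci_high: float
    p: float


def landmark_filter(records: pd.DataFrame, landmark_months: float = 3.0
                    ) -> pd.DataFrame:
    """Restrict to patients still at risk at the landmark; shift the clock.

    Patients with an event or censoring at or before the landmark are
    excluded; surviving patients' times are reduced by the landmark.
    """
    if landmark_months == 0:
        return records.copy()
    out = records[records["time"] > landmark_months].copy()
    if len(out) == 0:
        raise ValueError("no patients remain after the landmark")
    out["time"] = out["time"] - landmark_months
    return out


def km_estimate(records: pd.DataFrame) -> KMResult:
    """Product-limit survival estimate with the first-crossing median."""
    if len(records) == 0:
        raise ValueError("need at least one record")
    kmf = KaplanMeierFitter()
    kmf.fit(records["time"], records["event"])
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    below = surv <= 0.5
    median = float(times[below][0]) if below.any() else math.inf
    return KMResult(times, surv, median)


def logrank_test(group_a: pd.DataFrame, group_b: pd.DataFrame
                 ) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p)."""
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be nonempty")
    res = _ll_logrank(group_a["time"], group_b["time"],
                      group_a["event"], group_b["event"])
    return float(res.test_statistic), float(res.p_value)


def hazard_ratio(group: pd.DataFrame, reference: pd.DataFrame
                 ) -> HazardRatioResult:
    """Hazard ratio of ``group`` vs ``reference`` with Wald 95% CI."""
    df = pd.concat([
        reference[["time", "event"]].assign(exposed=0),
        group[["time", "event"]].assign(exposed=1),
    ], ignore_index=True)
    if df["event"].sum() == 0:
        raise ValueError("no events in the pooled data")
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    row = cph.summary.loc["exposed"]
    return HazardRatioResult(
        hr=float(np.exp(row["coef"])),
        ci_low=float(np.exp(row["coef lower 95%"])),
        ci_high=float(np.exp(row["coef upper 95%"])),
        p=float(row["p"]),
    )


def fisher_exact(table: list[list[int]] | np.ndarray) -> float:
    """Two-sided Fisher exact p for a 2x2 table; degenerate margins give 1."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t.sum(0) == 0).any() or (t.sum(1) == 0).any():
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def mann_whitney(values_a, values_b) -> float:
    """Two-sided tie-corrected Mann-Whitney U p-value."""
    a, b = np.asarray(values_a, float), np.asarray(values_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    if np.ptp(np.r_[a, b]) == 0:
        return 1.0  # all observations tied: no evidence either way
    return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method="asymptotic",
                                    use_continuity=False).pvalue)
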