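"""Concordance between organoid drug-response calls and patient outcomes.

Each patient contributes a PDO class (oxaliplatin-sensitive OS vs resistant
OR — the "test") and a clinical outcome under oxaliplatin-based therapy
(responder vs non-responder — the "truth").  The module computes confusion
metrics from the collapsed 2x2 table, Fisher's exact test of association,
and a one-sided Cochran-Armitage test for a monotone trend of clinical
events across the ordered four-category PDO response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Cohort2x2",
    "TrendTable",
    "confusion_metrics",
    "fisher_exact",
    "cochran_armitage",
    "DegenerateVarianceError",
    "round_for_display",
]


class DegenerateVarianceError(ValueError):
    """Trend-statistic variance is zero; no test possible."""


@dataclass(frozen=True)
class Cohort2x2:
    """Collapsed cohort: PDO class (OS/OR) vs clinical response.

    a: OS-PDO responders, b: OS-PDO non-responders,
    c: OR-PDO responders, d: OR-PDO non-responders.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        counts = (self.a, self.b, self.c, self.d)
        if any(int(v) != v or v < 0 for v in counts):
            raise ValueError("cell counts must be nonnegative integers")
        if sum(counts) == 0:
            raise ValueError("table must contain at least one patient")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])

    @classmethod
    def from_patients(cls, df: pd.DataFrame) -> "Cohort2x2":
        """Collapse a patient table with columns pdo_class (OS/OR) and
        outcome (responder/non-responder)."""
        sens = df["pdo_class"].eq("OS")
        resp = df["outcome"].eq("responder")
        return cls(
            int((sens & resp).sum()),
            int((sens & ~resp).sum()),
            int((~sens & resp).sum()),
            int((~sens & ~resp).sum()),
        )


@dataclass(frozen=True)
class TrendTable:
    """Events/n across ordered categories, with numeric trend scores."""

    categories: tuple[str, ...]
    events: tuple[int, ...]
    n: tuple[int, ...]
    scores: tuple[float, ...]

    def __post_init__(self):
        k = len(self.categories)
        if k < 2:
            raise ValueError("need at least 2 ordered categories")
        if not (len(self.events) == len(self.n) == len(self.scores) == k):
            raise ValueError("events, n and scores must match categories")
        if any(e < 0 or e > m for e, m in zip(self.events, self.n)):
            raise ValueError("0 <= events <= n required per category")
        diffs = np.diff(self.scores)
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError("scores must be strictly monotone")


def confusion_metrics(t: Cohort2x2) -> dict:
    """Sensitivity, specificity, PPV, NPV and accuracy, in percent.

    A metric whose denominator is empty is reported as None (undefined),
    never as 0.  Values are full precision; use :func:`round_for_display`
    for one-decimal reporting.
    """
    def ratio(num, den):
        return 100.0 * num / den if den > 0 else None

    return {
        "sensitivity_pct": ratio(t.a, t.a + t.c),
        "specificity_pct": ratio(t.d, t.b + t.d),
        "ppv_pct": ratio(t.a, t.a + t.b),
        "npv_pct": ratio(t.d, t.c + t.d),
        "accuracy_pct": ratio(t.a + t.d, t.total),
        "n_correct": t.a + t.d,
        "n_total": t.total,
    }


def round_for_display(metrics: dict, decimals: int = 1) -> dict:
    return {
        k: (round(v, decimals) if isinstance(v, float) else v) for k, v in metrics.items()
    }


def fisher_exact(t: Cohort2x2) -> float:
    """Two-sided Fisher exact p: the total hypergeometric probability of all
    tables with the observed margins at most as probable as the observed one."""
    return float(stats.fisher_exact(t.as_array(), alternative="two-sided")[1])


def cochran_armitage(t: TrendTable, alternative: str = "decreasing") -> float:
    """One-sided Cochran-Armitage trend test (asymptotic, no continuity
    correction, population-variance N denominator).

    The statistic is T = sum_i events_i * x_i with expectation
    p_bar * sum_i n_i x_i and variance
    p_bar (1 - p_bar) [sum n_i x_i^2 - (sum n_i x_i)^2 / N], p_bar the
    pooled event rate.  ``alternative="decreasing"`` tests for event
    proportions falling as the score increases (lower normal tail);
    "increasing" takes the upper tail; "two-sided" doubles the smaller.
    The p-value is invariant to affine rescaling of the scores.
    """
    events = np.asarray(t.events, dtype=float)
    n = np.asarray(t.n, dtype=float)
    x = np.asarray(t.scores, dtype=float)
    total_events, total_n = events.sum(), n.sum()
    if total_events == 0 or total_events == total_n:
        return 1.0  # all or none: no trend evidence
    p_bar = total_events / total_n
    stat = float(events @ x)
    expected = p_bar * float(n @ x)
    variance = p_bar * (1.0 - p_bar) * (float(n @ x**2) - float(n @ x) ** 2 / total_n)
    if variance <= 0:
        raise DegenerateVarianceError("zero trend variance; scores carry no spread")
    z = (stat - expected) / np.sqrt(variance)
    if alternative == "decreasing":
        return float(stats.norm.cdf(z))
    if alternative == "increasing":
        return float(stats.norm.sf(z))
    if alternative == "two-sided":
        return float(2.0 * stats.norm.sf(abs(z)))
    raise ValueError("alternative must be 'decreasing', 'increasing' or 'two-sided'")
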