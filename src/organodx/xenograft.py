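"""Tumor-growth-inhibition (TGI) scoring for paired xenograft arms.

Organoid-derived xenografts are randomized into a vehicle-control and a
drug-treated arm and measured repeatedly.  The growth-normalized statistic

    %TGI = { [1 - (T_t/T_0) / (C_t/C_0)] / [1 - C_0/C_t] } x 100

uses per-arm *median* volumes: T_t, T_0 for the treated arm at day t and
baseline, C_t, C_0 for controls.  Complete stasis of the treated arm gives
exactly 100%, identical growth in both arms gives 0%, and regression exceeds
100%.  A median %TGI of at least 50% at the treatment endpoint defines
significant anti-tumor activity (an in vivo responder).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TumorCourse",
    "TgiResult",
    "RESPONDER_TGI_CUTOFF",
    "compute_tgi",
    "summarize_arms",
    "DegenerateControlError",
    "MissingTimepointError",
]

RESPONDER_TGI_CUTOFF = 50.0

ARMS = ("control", "treated")


class DegenerateControlError(ValueError):
    """Control arm did not change volume between day 0 and the endpoint."""


class MissingTimepointError(KeyError):
    """Requested day absent from one of the arms."""


@dataclass(frozen=True)
class TumorCourse:
    """Long-format paired xenograft volume series.

    ``data`` columns: mouse_id, arm ("control"/"treated"), day, volume_mm3.
    Every mouse must carry a day-0 record and both arms must be non-empty.
    """

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data
        required = {"mouse_id", "arm", "day", "volume_mm3"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if not set(df["arm"]).issubset(ARMS):
            raise ValueError(f"arm must be one of {ARMS}")
        if df.empty or set(df["arm"]) != set(ARMS):
            raise ValueError("both control and treated arms must be non-empty")
        if (df["volume_mm3"] <= 0).any():
            raise ValueError("volumes must be positive")
        without_day0 = set(df["mouse_id"]) - set(df.loc[df["day"] == 0, "mouse_id"])
        if without_day0:
            raise ValueError(f"mice missing a day-0 record: {sorted(without_day0)}")

    def days(self, arm: str) -> np.ndarray:
        return np.sort(self.data.loc[self.data["arm"] == arm, "day"].unique())

    def shared_days(self) -> np.ndarray:
        return np.intersect1d(self.days("control"), self.days("treated"))

    def median_volume(self, arm: str, day) -> float:
        sel = self.data[(self.data["arm"] == arm) & (self.data["day"] == day)]
        if sel.empty:
            raise MissingTimepointError(f"no {arm} measurements on day {day}")
        return float(sel["volume_mm3"].median())

    @classmethod
    def read_csv(cls, path) -> "TumorCourse":
        return cls(pd.read_csv(path))

    def write_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


@dataclass(frozen=True)
class TgiResult:
    tgi_pct: float
    responder: bool
    endpoint_day: float


def summarize_arms(course: TumorCourse) -> pd.DataFrame:
    """Per-arm, per-day median volume and mouse count."""
    return (
        course.data.groupby(["arm", "day"], sort=True)["volume_mm3"]
        .agg(median_volume_mm3="median", n_mice="count")
        .reset_index()
    )


def compute_tgi(course: TumorCourse, day=None, cutoff: float = RESPONDER_TGI_CUTOFF) -> TgiResult:
    """Evaluate %TGI at ``day`` (default: last day shared by both arms).

    Raises :class:`DegenerateControlError` when the control medians did not
    change (the formula's denominator vanishes) and
    :class:`MissingTimepointError` when the day is absent from either arm.
    """
    if day is None:
        shared = course.shared_days()
        later = shared[shared > 0]
        if later.size == 0:
            raise MissingTimepointError("no post-baseline day shared by both arms")
        day = later[-1]
    t0 = course.median_volume("treated", 0)
    tt = course.median_volume("treated", day)
    c0 = course.median_volume("control", 0)
    ct = course.median_volume("control", day)
    if np.isclose(ct, c0):
        raise DegenerateControlError("control arm shows no net growth; %TGI undefined")
    tgi = 100.0 * (1.0 - (tt / t0) / (ct / c0)) / (1.0 - c0 / ct)
    return TgiResult(tgi_pct=float(tgi), responder=bool(tgi >= cutoff), endpoint_day=float(day))
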