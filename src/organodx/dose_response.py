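"""Four-parameter logistic (4PL) dose-response analysis for organoid drug screens.

A viability plate measures ATP-based viability (percent of untreated control)
of one patient-derived organoid (PDO) line across a dose grid of a drug, in
replicate.  The module fits

    V(d) = bottom + (top - bottom) / (1 + (d / ic50)^hill)

to the replicate means, derives potency (IC50), efficacy (Emax = percent
inhibition at the highest tested dose) and a normalized area under the
dose-response curve (AUC), classifies each line into four response categories
on the log10 IC50 scale, and quantifies potency/efficacy shifts under
combination therapy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit

__all__ = [
    "DosePlate",
    "DoseResponseFit",
    "ResponseCall",
    "CombinationShift",
    "DEFAULT_BOUNDARIES",
    "CATEGORIES",
    "fourpl",
    "fit_4pl",
    "classify_response",
    "invert_icx",
    "combination_shift",
    "fit_plate_table",
    "read_plates",
    "write_plates",
    "UnattainableEffectError",
    "InsufficientDataError",
]

#: log10(IC50 [uM]) category boundaries: strong / moderate / minor / non-responder.
#: Intervals are half-open [low, high); values below the first boundary are
#: still "strong", values above the last are still "non".
DEFAULT_BOUNDARIES: tuple[float, float, float, float, float] = (0.14, 0.57, 0.98, 1.24, 2.00)

#: Response categories ordered from most to least sensitive.
CATEGORIES: tuple[str, ...] = ("strong", "moderate", "minor", "non")

#: Categories collapsing to the sensitive (OS) vs resistant (OR) groups.
OS_CATEGORIES = frozenset({"strong", "moderate"})


class InsufficientDataError(ValueError):
    """Fewer distinct doses than the 4PL fit requires."""


class UnattainableEffectError(ValueError):
    """Requested inhibition level exceeds the curve's maximal inhibition."""


def fourpl(d, top, bottom, hill, ic50):
    """Decreasing four-parameter logistic: viability as a function of dose."""
    d = np.asarray(d, dtype=float)
    return bottom + (top - bottom) / (1.0 + (d / ic50) ** hill)


@dataclass(frozen=True)
class DosePlate:
    """One drug x one PDO viability plate: dose grid x replicates, in percent."""

    pdo_id: str
    drug: str
    doses: np.ndarray  # uM, strictly increasing
    viability: np.ndarray  # percent, shape (n_doses, n_replicates)

    def __post_init__(self):
        doses = np.asarray(self.doses, dtype=float)
        viab = np.atleast_2d(np.asarray(self.viability, dtype=float))
        if doses.ndim != 1 or doses.size == 0:
            raise ValueError("doses must be a non-empty 1-D array")
        if np.any(doses <= 0):
            raise ValueError("doses must be positive")
        if np.any(np.diff(doses) <= 0):
            raise ValueError("doses must be strictly increasing")
        if viab.shape[0] != doses.size:
            raise ValueError("viability must have one row per dose")
        if np.nanmin(viab) < 0:
            raise ValueError("viability must be non-negative")
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "viability", viab)

    @property
    def n_replicates(self) -> int:
        return self.viability.shape[1]

    def replicate_means(self) -> np.ndarray:
        return np.nanmean(self.viability, axis=1)

    def to_tidy(self) -> pd.DataFrame:
        """Long-format table: pdo_id, drug, dose_uM, replicate, viability_pct."""
        rows = [
            (self.pdo_id, self.drug, d, r + 1, self.viability[i, r])
            for i, d in enumerate(self.doses)
            for r in range(self.n_replicates)
        ]
        return pd.DataFrame(rows, columns=["pdo_id", "drug", "dose_uM", "replicate", "viability_pct"])

    @classmethod
    def from_tidy(cls, df: pd.DataFrame) -> "DosePlate":
        pdo_ids = df["pdo_id"].unique()
        drugs = df["drug"].unique() if "drug" in df else np.array(["drug"])
        if len(pdo_ids) != 1 or len(drugs) != 1:
            raise ValueError("from_tidy expects a single pdo_id/drug; use read_plates for tables")
        wide = df.pivot_table(index="dose_uM", columns="replicate", values="viability_pct")
        return cls(str(pdo_ids[0]), str(drugs[0]), wide.index.to_numpy(), wide.to_numpy())


@dataclass(frozen=True)
class DoseResponseFit:
    """Fitted 4PL parameters with derived potency/efficacy summaries.

    ``censored`` marks curves that never reach 50% inhibition within the
    tested range; their IC50 is capped at the maximal tested dose.
    """

    top: float
    bottom: float
    hill: float
    ic50: float  # uM
    emax: float  # percent inhibition at max tested dose, floored at 0
    auc: float  # normalized area in [0, 1]
    converged: bool
    censored: bool
    max_dose: float = field(default=np.nan)

    @property
    def log10_ic50(self) -> float:
        return float(np.log10(self.ic50))


@dataclass(frozen=True)
class ResponseCall:
    """Four-category response call and its OS/OR group collapse."""

    category: str
    group: str  # "OS" (sensitive) or "OR" (resistant)
    log10_ic50: float


@dataclass(frozen=True)
class CombinationShift:
    """Potency/efficacy shift of a combination relative to monotherapy."""

    relative_ic50: float  # combo IC50 / mono IC50
    delta_emax: float  # combo Emax - mono Emax, percentage points
    orders_of_magnitude: float  # -log10(relative_ic50)
    mono_censored: bool


def fit_4pl(plate: DosePlate) -> DoseResponseFit:
    """Least-squares 4PL fit to replicate-mean viabilities.

    Curves whose inhibition at the top dose stays below 50%, or for which the
    optimizer fails, are returned with ``converged=False`` and the IC50
    censored at the maximal tested dose.  Parameters are box-bounded
    (0 <= bottom, top <= 120; 0.1 <= hill <= 10; IC50 within a decade of the
    dose range) to stabilize 8-point fits.
    """
    doses = plate.doses
    if doses.size < 4:
        raise InsufficientDataError("4PL fitting requires at least 4 distinct doses")
    y = plate.replicate_means()
    if np.all(np.isnan(y)):
        raise ValueError("all viability values are NaN")

    dmax = float(doses[-1])
    inhibition_at_max = 100.0 - float(y[-1])
    emax = max(0.0, inhibition_at_max)

    # robust start: top/bottom from the data, unit slope, IC50 near mid-response
    p0_top = float(np.max(y))
    p0_bottom = float(np.min(y))
    half = 0.5 * (p0_top + p0_bottom)
    p0_ic50 = float(doses[np.argmin(np.abs(y - half))])
    lower = (1e-6, 0.0, 0.1, doses[0] / 10.0)
    upper = (120.0, 120.0, 10.0, dmax * 10.0)
    p0 = (p0_top, max(p0_bottom, 0.0), 1.0, np.clip(p0_ic50, lower[3], upper[3]))

    params, ok = None, False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OptimizeWarning)
            params, _ = curve_fit(fourpl, doses, y, p0=p0, bounds=(lower, upper), maxfev=20000)
        ok = np.all(np.isfinite(params)) and params[1] < params[0]
    except RuntimeError:
        ok = False

    if params is not None and np.all(np.isfinite(params)):
        top, bottom, hill, ic50 = (float(v) for v in params)
    else:
        top, bottom, hill, ic50 = p0_top, p0_bottom, 1.0, dmax

    censored = (inhibition_at_max < 50.0) or not ok
    if censored:
        ic50 = dmax
    converged = ok and not censored

    # AUC: viability normalized by fitted top, trapezoid over log10 dose
    # rescaled to [0, 1]; comparable across dose grids.
    x = np.log10(doses)
    x = (x - x[0]) / (x[-1] - x[0])
    auc = float(np.clip(np.trapezoid(np.clip(y / top, 0.0, 1.0), x), 0.0, 1.0))

    return DoseResponseFit(top, bottom, hill, ic50, emax, auc, converged, censored, dmax)


def classify_response(log10_ic50: float, boundaries=DEFAULT_BOUNDARIES) -> ResponseCall:
    """Map a log10 IC50 (uM) to a response category and the OS/OR group.

    Categories use half-open intervals [low, high) on ``boundaries``; values
    below the first boundary map to "strong" and values at or above the last
    map to "non".  Strong/moderate responders form the oxaliplatin-sensitive
    (OS) group, minor/non-responders the resistant (OR) group.
    """
    x = float(log10_ic50)
    if np.isnan(x):
        raise ValueError("log10_ic50 must be finite, got NaN")
    b = tuple(float(v) for v in boundaries)
    if len(b) != 5 or any(b[i] >= b[i + 1] for i in range(4)):
        raise ValueError("boundaries must be 5 increasing values")
    if x < b[1]:
        category = "strong"
    elif x < b[2]:
        category = "moderate"
    elif x < b[3]:
        category = "minor"
    else:
        category = "non"
    group = "OS" if category in OS_CATEGORIES else "OR"
    return ResponseCall(category, group, x)


def invert_icx(fit: DoseResponseFit, x: float) -> float:
    """Dose (uM) producing ``x`` percent inhibition relative to the fitted top.

    Algebraic inversion of the 4PL; raises :class:`UnattainableEffectError`
    when the curve's plateau (bottom) leaves less than ``x`` percent of
    achievable inhibition.  Used to pick minimum effective doses (IC10-IC40)
    for combination partners.
    """
    if not 0.0 < x < 100.0:
        raise ValueError("x must be strictly between 0 and 100")
    if not fit.converged:
        raise ValueError("invert_icx requires a converged fit")
    max_inhibition = 100.0 * (fit.top - fit.bottom) / fit.top
    if x >= max_inhibition:
        raise UnattainableEffectError(
            f"{x}% inhibition unattainable: curve plateaus at {max_inhibition:.1f}%"
        )
    q = x * fit.top / (100.0 * (fit.top - fit.bottom))
    u = q / (1.0 - q)
    return float(fit.ic50 * u ** (1.0 / fit.hill))


def combination_shift(mono: DoseResponseFit, combo: DoseResponseFit) -> CombinationShift:
    """Relative IC50 and Emax gain of a combination over monotherapy.

    A sensitizing partner shows relative_ic50 well below 1 (potency gain in
    orders of magnitude) and a positive delta_emax.  A censored monotherapy
    IC50 is propagated as a warning flag since the true ratio is then a bound.
    """
    if mono.censored:
        warnings.warn("monotherapy IC50 is censored; relative IC50 is a lower bound", stacklevel=2)
    rel = combo.ic50 / mono.ic50
    return CombinationShift(
        relative_ic50=float(rel),
        delta_emax=float(combo.emax - mono.emax),
        orders_of_magnitude=float(-np.log10(rel)),
        mono_censored=mono.censored,
    )


def fit_plate_table(plates: list[DosePlate], boundaries=DEFAULT_BOUNDARIES) -> pd.DataFrame:
    """Fit every plate and tabulate parameters, summaries and response calls."""
    rows = []
    for plate in plates:
        fit = fit_4pl(plate)
        call = classify_response(fit.log10_ic50, boundaries)
        rows.append(
            {
                "pdo_id": plate.pdo_id,
                "drug": plate.drug,
                "top": fit.top,
                "bottom": fit.bottom,
                "hill": fit.hill,
                "ic50_uM": fit.ic50,
                "log10_ic50": fit.log10_ic50,
                "emax_pct": fit.emax,
                "auc": fit.auc,
                "category": call.category,
                "group": call.group,
                "censored": fit.censored,
            }
        )
    return pd.DataFrame(rows)


def read_plates(path) -> list[DosePlate]:
    """Read tidy plate CSV (pdo_id, drug, dose_uM, replicate, viability_pct)."""
    df = pd.read_csv(path)
    if "drug" not in df:
        df = df.assign(drug="drug")
    return [
        DosePlate.from_tidy(sub)
        for _, sub in df.groupby(["pdo_id", "drug"], sort=True)
    ]


def write_plates(plates: list[DosePlate], path) -> None:
    pd.concat([p.to_tidy() for p in plates], ignore_index=True).to_csv(path, index=False)
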