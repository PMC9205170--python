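"""Synthetic study-condition generators for the whole analysis pipeline.

Each generator emulates one raw-data stream of a PDO oxaliplatin study so
every downstream stage is testable without any download:

* viability plates on the standard 8-dose oxaliplatin grid
  (0.03-100 uM, four replicates) from known 4PL ground truth, with additive
  Gaussian percent-scale noise clipped at zero;
* an 8-vs-8 OR/OS negative-binomial count matrix (variance mu + alpha*mu^2)
  with planted differential features and per-sample library-size factors;
* exponential xenograft growth (5 mice/arm, measurements at 3-day intervals)
  with multiplicative noise and a treatment effect on the growth rate;
* a 17-patient outcome cohort drawn from class-conditional response
  probabilities.

Every generator takes an explicit scenario + seed and uses one private RNG
stream per call, so identical inputs give bitwise-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .concordance import Cohort2x2
from .dose_response import DosePlate, fourpl
from .signatures import CountMatrix
from .xenograft import TumorCourse

__all__ = [
    "ScreenScenario",
    "CountScenario",
    "XenoScenario",
    "CohortScenario",
    "PAPER_DOSE_GRID",
    "gen_dose_plate",
    "gen_counts",
    "gen_xeno_course",
    "gen_cohort",
]

#: The study's oxaliplatin dose grid, in uM.
PAPER_DOSE_GRID: tuple[float, ...] = (0.03, 0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0)


def _rng(seed: int, *stream) -> np.random.Generator:
    # one independent stream per generator call; SeedSequence keys keep
    # different (seed, stream) pairs statistically independent
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, stream)]))


@dataclass(frozen=True)
class ScreenScenario:
    """Viability-screen conditions: dose grid, replication, 4PL truths, noise."""

    fourpl_truth: tuple  # per-PDO (top %, bottom %, hill, ic50 uM)
    dose_grid: tuple = PAPER_DOSE_GRID
    n_replicates: int = 4
    noise_sd: float = 5.0  # percent-viability SD
    seed: int = 0

    def __post_init__(self):
        grid = tuple(float(d) for d in self.dose_grid)
        if any(d <= 0 for d in grid) or any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("dose_grid must be strictly increasing and positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        truths = tuple(tuple(float(v) for v in t) for t in self.fourpl_truth)
        for top, bottom, hill, ic50 in truths:
            if not 0 <= bottom < top:
                raise ValueError("each truth needs 0 <= bottom < top")
            if ic50 <= 0 or hill <= 0:
                raise ValueError("ic50 and hill must be positive")
        object.__setattr__(self, "dose_grid", grid)
        object.__setattr__(self, "fourpl_truth", truths)


def gen_dose_plate(scenario: ScreenScenario, pdo_index: int) -> DosePlate:
    """Simulate one PDO's plate from its 4PL truth.

    viability(d) = 4PL(d; truth) + N(0, noise_sd) per replicate, clipped at 0.
    """
    if not 0 <= pdo_index < len(scenario.fourpl_truth):
        raise IndexError(f"pdo_index {pdo_index} outside fourpl_truth")
    top, bottom, hill, ic50 = scenario.fourpl_truth[pdo_index]
    rng = _rng(scenario.seed, pdo_index)
    doses = np.asarray(scenario.dose_grid)
    clean = fourpl(doses, top, bottom, hill, ic50)[:, np.newaxis]
    noise = rng.normal(0.0, scenario.noise_sd, size=(doses.size, scenario.n_replicates))
    viability = np.clip(clean + noise, 0.0, None)
    return DosePlate(f"PDO{pdo_index:03d}", "oxaliplatin", doses, viability)


@dataclass(frozen=True)
class CountScenario:
    """Two-group RNA-seq count structure with planted differential features.

    Group A is labeled OS, group B OR; a planted feature's group-B mean is
    the group-A mean times 2**planted_log2fc.  Counts are negative binomial
    with variance mu + dispersion * mu^2; dispersion 0 degenerates to
    Poisson.  Library sizes vary by per-sample multipliers drawn uniformly
    from size_factor_range.
    """

    n_group_a: int = 8
    n_group_b: int = 8
    n_features: int = 2000
    planted_idx: tuple = ()
    planted_log2fc: float | tuple = 3.0  # scalar or one effect per planted feature
    baseline_mean: float = 100.0
    dispersion: float = 0.1
    size_factor_range: tuple = (0.7, 1.4)
    seed: int = 0

    def __post_init__(self):
        for name in ("n_group_a", "n_group_b", "n_features"):
            v = getattr(self, name)
            if int(v) != v:
                raise ValueError(f"{name} must be an integer")
        if self.n_group_a < 2 or self.n_group_b < 2:
            raise ValueError("group sizes must be >= 2")
        idx = tuple(int(i) for i in self.planted_idx)
        if any(not 0 <= i < self.n_features for i in idx):
            raise ValueError("planted_idx must index [0, n_features)")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        lo, hi = self.size_factor_range
        if not 0 < lo <= hi:
            raise ValueError("size_factor_range must be positive and ordered")
        fc = self.planted_log2fc
        if np.ndim(fc) > 0:
            fc = tuple(float(v) for v in fc)
            if len(fc) != len(idx):
                raise ValueError("planted_log2fc must be scalar or one value per planted feature")
            object.__setattr__(self, "planted_log2fc", fc)
        object.__setattr__(self, "planted_idx", idx)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion  # NB "number of successes" parameter
    return rng.negative_binomial(size, size / (size + mean))


def gen_counts(scenario: CountScenario) -> CountMatrix:
    """Simulate the OR/OS count matrix (features x samples)."""
    rng = _rng(scenario.seed, 1)
    na, nb, nf = scenario.n_group_a, scenario.n_group_b, scenario.n_features
    # per-feature baseline means spread over ~2 decades around baseline_mean
    base = scenario.baseline_mean * rng.lognormal(0.0, 1.0, size=nf)
    mean_a = np.tile(base[:, np.newaxis], (1, na))
    mean_b = np.tile(base[:, np.newaxis], (1, nb))
    if scenario.planted_idx:
        idx = np.array(scenario.planted_idx)
        fc = np.broadcast_to(np.atleast_1d(scenario.planted_log2fc), idx.shape)
        mean_b[idx] *= (2.0 ** fc)[:, np.newaxis]
    sf = rng.uniform(*scenario.size_factor_range, size=na + nb)
    mu = np.hstack([mean_a, mean_b]) * sf[np.newaxis, :]
    counts = _nb_draw(rng, mu, scenario.dispersion).astype(np.int64)
    features = [f"F{i:05d}" for i in range(nf)]
    samples = [f"OS{i + 1:02d}" for i in range(na)] + [f"OR{i + 1:02d}" for i in range(nb)]
    labels = ["OS"] * na + ["OR"] * nb
    return CountMatrix(features, samples, counts, labels)


@dataclass(frozen=True)
class XenoScenario:
    """Exponential xenograft growth with a treatment effect on the rate.

    Volumes follow V(t) = V0 * exp(rate * t) * (1 + eps), eps ~ N(0, noise_cv)
    per measurement; V0 is uniform over v0_range (mm^3).  The default design
    is 5 mice per arm measured at 3-day intervals over the dosing period.
    """

    n_per_arm: int = 5
    v0_range: tuple = (80.0, 100.0)
    growth_rate_control: float = 0.12  # per day
    growth_rate_treated: float = 0.04
    measurement_days: tuple = tuple(range(0, 28, 3))
    noise_cv: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_per_arm < 1:
            raise ValueError("n_per_arm must be >= 1")
        lo, hi = self.v0_range
        if not 0 < lo <= hi:
            raise ValueError("v0_range must be positive and ordered")
        days = tuple(float(d) for d in self.measurement_days)
        if not days:
            raise ValueError("measurement_days must be non-empty")
        if days[0] != 0 or any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("measurement_days must be sorted and start at 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        object.__setattr__(self, "measurement_days", days)


def gen_xeno_course(scenario: XenoScenario) -> TumorCourse:
    """Simulate paired control/treated volume series."""
    rng = _rng(scenario.seed, 2)
    days = np.asarray(scenario.measurement_days)
    records = []
    for arm, rate in (
        ("control", scenario.growth_rate_control),
        ("treated", scenario.growth_rate_treated),
    ):
        v0 = rng.uniform(*scenario.v0_range, size=scenario.n_per_arm)
        eps = rng.normal(0.0, scenario.noise_cv, size=(scenario.n_per_arm, days.size))
        vol = v0[:, np.newaxis] * np.exp(rate * days)[np.newaxis, :] * (1.0 + eps)
        vol = np.maximum(vol, 1e-3)  # volumes stay positive
        for m in range(scenario.n_per_arm):
            for j, day in enumerate(days):
                records.append((f"{arm[0].upper()}{m + 1}", arm, day, vol[m, j]))
    return TumorCourse(pd.DataFrame(records, columns=["mouse_id", "arm", "day", "volume_mm3"]))


@dataclass(frozen=True)
class CohortScenario:
    """Patient cohort with class-conditional clinical response probabilities."""

    n_patients: int = 17
    p_class_sensitive: float = 9 / 17
    p_respond_given_sensitive: float = 0.78
    p_respond_given_resistant: float = 0.37
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in ("p_class_sensitive", "p_respond_given_sensitive", "p_respond_given_resistant"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


def gen_cohort(scenario: CohortScenario) -> pd.DataFrame:
    """Per-patient (pdo_class, outcome) table; collapse via Cohort2x2.from_patients."""
    rng = _rng(scenario.seed, 3)
    sensitive = rng.random(scenario.n_patients) < scenario.p_class_sensitive
    p_resp = np.where(
        sensitive, scenario.p_respond_given_sensitive, scenario.p_respond_given_resistant
    )
    responder = rng.random(scenario.n_patients) < p_resp
    return pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:03d}" for i in range(scenario.n_patients)],
            "pdo_class": np.where(sensitive, "OS", "OR"),
            "outcome": np.where(responder, "responder", "non-responder"),
        }
    )


def cohort_table(scenario: CohortScenario) -> Cohort2x2:
    """Generate and collapse a cohort in one step."""
    return Cohort2x2.from_patients(gen_cohort(scenario))
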