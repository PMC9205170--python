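import numpy as np
import pytest

import organodx as ox


@pytest.fixture(scope="session")
def fig3b_table():
    """The 17-patient cohort: OS PDOs 7 responders + 2 non, OR PDOs 3 + 5."""
    return ox.Cohort2x2(a=7, b=2, c=3, d=5)


@pytest.fixture(scope="session")
def recurrence_trend():
    """Recurrence counts across ordered in vitro response categories."""
    return ox.TrendTable(
        categories=("non", "minor", "moderate", "strong"),
        events=(3, 2, 1, 1),
        n=(4, 4, 5, 4),
        scores=(0.0, 1.0, 2.0, 3.0),
    )


@pytest.fixture(scope="session")
def planted_counts():
    """8-vs-8 count matrix, 2000 features, 20 planted at |log2FC| = 3.

    Low dispersion (0.01) makes the planted features near-deterministic
    separators, the regime the recovery checks assume.
    """
    rng = np.random.default_rng(0)
    planted = tuple(sorted(int(i) for i in rng.choice(2000, 20, replace=False)))
    scenario = ox.CountScenario(
        n_features=2000, planted_idx=planted, planted_log2fc=3.0, dispersion=0.01, seed=0
    )
    cm = ox.gen_counts(scenario)
    return cm, [cm.feature_ids[i] for i in planted]


def make_noiseless_plate(top, bottom, hill, ic50, grid=ox.PAPER_DOSE_GRID, n_rep=4):
    scen = ox.ScreenScenario(
        fourpl_truth=((top, bottom, hill, ic50),), dose_grid=grid,
        n_replicates=n_rep, noise_sd=0.0, seed=0,
    )
    return ox.gen_dose_plate(scen, 0)
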