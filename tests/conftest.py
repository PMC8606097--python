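"""Shared fixtures: the three worked clinical-trial summaries.

GOPCABE (off- vs on-pump bypass grafting in the elderly) is the
non-fragile example, EXCEL (PCI vs CABG for left main disease) the
moderately fragile one, and the Gold et al. arterial-pressure trial the
very fragile one.  All counts come from the published 2x3 summaries.
"""

import numpy as np
import pytest

from ltfu_fragility import (
    ArmObservation,
    TrialTable,
    joint_predictive,
    posterior_predictive_pmf,
    significance_grid,
    solve_s,
)


@pytest.fixture(scope="session")
def gopcabe() -> TrialTable:
    return TrialTable(
        control=ArmObservation(154, 1025, 12, label="off-pump"),
        treatment=ArmObservation(167, 1024, 21, label="on-pump"),
    )


@pytest.fixture(scope="session")
def excel() -> TrialTable:
    return TrialTable(
        control=ArmObservation(203, 681, 64, label="PCI"),
        treatment=ArmObservation(176, 686, 95, label="CABG"),
    )


@pytest.fixture(scope="session")
def gold() -> TrialTable:
    return TrialTable(
        control=ArmObservation(32, 69, 23, label="Low MAP"),
        treatment=ArmObservation(18, 73, 33, label="High MAP"),
    )


def _joint(trial):
    s_c = solve_s(trial.control.p_hat)
    s_t = solve_s(trial.treatment.p_hat)
    return joint_predictive(
        posterior_predictive_pmf(trial.control, s_c),
        posterior_predictive_pmf(trial.treatment, s_t),
    )


@pytest.fixture(scope="session")
def excel_joint(excel):
    return _joint(excel)


@pytest.fixture(scope="session")
def excel_grid(excel):
    return significance_grid(excel, alpha=0.05)


@pytest.fixture(scope="session")
def gold_joint(gold):
    return _joint(gold)


@pytest.fixture(scope="session")
def gold_grid(gold):
    return significance_grid(gold, alpha=0.05)


@pytest.fixture(scope="session")
def gopcabe_joint(gopcabe):
    return _joint(gopcabe)


@pytest.fixture(scope="session")
def gopcabe_grid(gopcabe):
    return significance_grid(gopcabe, alpha=0.05)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)
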