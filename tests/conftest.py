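"""Shared fixtures.

Expensive objects (known-good oscillating parameter sets, the study
archives used by the scaled replication tests) are computed once per
session and shared across test modules.  Fixture searches are cached on
disk keyed by architecture/seed/version, so repeated local runs are fast.
"""

import warnings

import pytest

import clockarch as ca

SEED = 1

# Scaled-down study conditions: same windows, bounds and thresholds as the
# full study; only the archive size and search budget are reduced so the
# whole comparison fits a desk-scale run.
N_SOLUTIONS = 15
_BUDGET = dict(
    n_solutions=N_SOLUTIONS,
    random_phase_trials=250,
    population_size=40,
    max_generations=80,
    seed=SEED,
)
# the weakly-asymmetric redundant regime is the hardest to seed (fragile
# oscillations), so its random phase gets a larger trial budget
_HARD_BUDGET = dict(_BUDGET, random_phase_trials=2000)

STUDY_CONDITIONS = {
    "single": dict(_BUDGET, architecture="single"),
    "dual_rho99": dict(_BUDGET, architecture="dual", rho=99.0),
    "dual_rho1": dict(_BUDGET, architecture="dual", rho=1.0),
    "dual_rho0.1": dict(_BUDGET, architecture="dual", rho=0.1),
    "dual_rho0.01": dict(_BUDGET, architecture="dual", rho=0.01),
    "dual_rho0": dict(_BUDGET, architecture="dual", rho=0.0),
    "redundant_rho99": dict(_BUDGET, architecture="redundant", rho=99.0),
    "redundant_rho0.1": dict(_HARD_BUDGET, architecture="redundant", rho=0.1),
    "redundant_rho0.01": dict(
        _HARD_BUDGET, architecture="redundant", rho=0.01
    ),
    "redundant_rho0": dict(_BUDGET, architecture="redundant", rho=0.0),
    "semi_dual_lo": dict(
        _BUDGET, architecture="semi_dual", y_level_constraint=(0.0, 10.0)
    ),
    "semi_dual_mid": dict(
        _BUDGET, architecture="semi_dual", y_level_constraint=(10.0, 200.0)
    ),
    "semi_dual_hi": dict(
        _BUDGET,
        architecture="semi_dual",
        y_level_constraint=(200.0, float("inf")),
    ),
}


def run_condition(label: str) -> ca.SolutionArchive:
    cfg = ca.SearchConfig(**STUDY_CONDITIONS[label])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ca.run_tps(cfg)


@pytest.fixture(scope="session")
def study_archives():
    """TPS archives for every study condition (computed once)."""
    return {label: run_condition(label) for label in STUDY_CONDITIONS}


@pytest.fixture(scope="session")
def study_qmps(study_archives):
    """QMPS tables for every study archive."""
    from clockarch.robustness import archive_qmps

    return {
        label: archive_qmps(arc) for label, arc in study_archives.items()
    }


@pytest.fixture(scope="session")
def single_oscillator():
    """One known-good single-model circadian parameter set."""
    params, feats = ca.fixture_oscillator("single", seed=SEED)
    return params, feats


@pytest.fixture(scope="session")
def single_model(single_oscillator):
    params, _ = single_oscillator
    return ca.build_model("single", params)


@pytest.fixture(scope="session")
def single_trajectory(single_model):
    traj = ca.integrate(single_model)
    assert traj is not None
    return traj
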