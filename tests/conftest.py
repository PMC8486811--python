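"""Shared fixtures.

The expensive simulation ensembles are session-scoped and shared between the
physics tests and the acceptance suite.  All simulations here run at "CI
scale": the same force field, switching rates and confinement as the desk-
scale study conditions, but shorter runs -- long enough for the tested
effects, short enough for a routine test run.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from chromodyn.dynamics import SimulationConfig, run_ensemble
from chromodyn.fibre import build_toy_fibre, preset_fibre, reference_toy_fibre
from chromodyn.transcription import per_run_activity_matrix

WT_BASE_SEED = 101
N_WT_RUNS = 10


@pytest.fixture(scope="session")
def wt_fibre():
    return reference_toy_fibre()


@pytest.fixture(scope="session")
def ci_config():
    """Wild-type CI-scale protocol: 300 push-off + 700 equilibration +
    5000 tau_B production, sampled every 100 tau_B.

    Activity estimates are limited by the slow cluster dynamics (residence
    times of hundreds of tau_B), so precision scales with production time;
    denser sampling adds essentially no information."""
    return SimulationConfig(warmup_pushoff=300.0, warmup_equil=700.0,
                            production=5000.0)


@pytest.fixture(scope="session")
def arm_config(ci_config):
    """Perturbation-arm protocol: identical warm-up to the wild type (so the
    paired comparison windows match exactly), shorter production."""
    return replace(ci_config, production=1200.0)


@pytest.fixture(scope="session")
def wt_results(wt_fibre, ci_config):
    """Reference wild-type ensemble: 10 runs, seeds 101..110."""
    return run_ensemble(wt_fibre, ci_config, WT_BASE_SEED, N_WT_RUNS, "wt")


@pytest.fixture(scope="session")
def wt_activity(wt_results):
    """(run x TU) per-run mean activity matrix of the wild-type ensemble."""
    return per_run_activity_matrix([r.record for r in wt_results])


@pytest.fixture(scope="session")
def het_island_results(arm_config):
    """Heterochromatin-island mutant (beads 901-940 non-binding), paired seeds."""
    return run_ensemble(preset_fibre("toy-het-island"), arm_config,
                        WT_BASE_SEED, N_WT_RUNS, "het")


@pytest.fixture(scope="session")
def ko930_results(arm_config):
    """Knockout of TU bead 930, paired seeds with the wild type."""
    return run_ensemble(preset_fibre("toy-ko-930"), arm_config,
                        WT_BASE_SEED, N_WT_RUNS, "ko930")


@pytest.fixture(scope="session")
def tiny_fibre():
    """Small chain for cheap engine-level tests."""
    return build_toy_fibre(M=120, n_tu=8, seed=7)


@pytest.fixture(scope="session")
def tiny_config():
    from chromodyn.params import Confinement

    return SimulationConfig(n_tf=6, confinement=Confinement.sphere(12.0),
                            warmup_pushoff=100.0, warmup_equil=100.0,
                            production=400.0)


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
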