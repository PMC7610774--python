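import numpy as np
import pytest

from dgnet.afferents import generate_trajectory
from dgnet.experiment import ExperimentConfig, run_experiment
from dgnet.neuron import bc_base_model, gc_base_model
from dgnet.populations import load_valid_population

# scaled network conditions shared by the network-level tests: a reduced
# 20 GC / 3 BC circuit driven by a 100 s traversal of the arena
SCALED_KW = dict(n_gc=20, n_bc=3, duration_s=100.0)
TRAJ_SEED = 3


@pytest.fixture(scope="session")
def gc_base():
    return gc_base_model()


@pytest.fixture(scope="session")
def bc_base():
    return bc_base_model()


@pytest.fixture(scope="session")
def gc_pop():
    return load_valid_population("GC")


@pytest.fixture(scope="session")
def bc_pop():
    return load_valid_population("BC")


@pytest.fixture(scope="session")
def gc_base_measurements(gc_base):
    from dgnet.ephys import measure_all
    return measure_all(gc_base)


@pytest.fixture(scope="session")
def trajectory_100s():
    return generate_trajectory(100.0, seed=TRAJ_SEED)


@pytest.fixture(scope="session")
def scaled_results(gc_pop, bc_pop, trajectory_100s):
    """Base + BK-knockout runs for the mature and fully-immature networks.

    One shared simulation set for the calibration-band and robustness
    checks; every run consumes the identical frozen trajectory.
    """
    out = {}
    for preset in ("mature-identical", "fully-immature"):
        for ko in (None, ("BK", "GC")):
            cfg = ExperimentConfig(preset=preset, knockout=ko, **SCALED_KW)
            out[(preset, ko)] = run_experiment(cfg, gc_pop, bc_pop,
                                               trajectory=trajectory_100s)
    return out
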