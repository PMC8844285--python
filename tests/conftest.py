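import numpy as np
import pytest

from mtpef.experiment import build_sweep_scene, simulate_sweep
from mtpef.pipeline import run_analysis


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def sweep_run():
    """One full cumulative 45-300 V sweep simulation plus its analysis report.

    Session-scoped because the simulation is the expensive shared resource;
    several modules assert different qualitative features of the same run.
    """
    design = build_sweep_scene(seed=11)
    stack, truth = simulate_sweep(design, seed=11)
    report = run_analysis(stack, design.protocols, regions=design.regions)
    return design, stack, truth, report
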