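import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ganglimark import pipeline
from ganglimark.containers import PipelineConfig
from ganglimark.simulate import SimulationConfig, simulate_experiment, toy_fixture

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy():
    """The committed 20-gene x 15-sample fixture."""
    return toy_fixture()


@pytest.fixture(scope="session")
def default_sim():
    """One draw of the default synthetic experiment (5 ganglia x 3 reps,
    5000 genes, planted markers at |log2fc| >= 3)."""
    return simulate_experiment(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_run(default_sim):
    """Full pipeline result on the default simulation (nboot 100)."""
    cm, sd, ga, _ = default_sim
    cfg = PipelineConfig(nboot=100, seed=1)
    return pipeline.run_pipeline(cm, sd, ga, cfg)


@pytest.fixture(scope="session")
def toy_run(toy):
    """Full pipeline result on the toy fixture (small nboot)."""
    cm, sd, ga = toy
    cfg = PipelineConfig(nboot=20, seed=3)
    res = pipeline.run_pipeline(cm, sd, ga, cfg)
    return {"res": res, "counts": cm, "design": sd, "annot": ga, "config": cfg}


@pytest.fixture(scope="session")
def toy_markers_run(toy_run):
    from ganglimark.simulate import TOY_MARKERS

    return toy_run["res"].markers, TOY_MARKERS


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
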