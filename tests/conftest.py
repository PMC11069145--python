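import pytest

from mitoresolve.synthetic import SimulationConfig, simulate_all, simulate_mitogenome


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic mitogenome shared by read-only tests."""
    config = SimulationConfig(seed=101)
    genome, graph, annotations, truth = simulate_mitogenome(config)
    return config, genome, graph, annotations, truth


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory):
    """A full on-disk synthetic dataset (files + truth.json)."""
    out = tmp_path_factory.mktemp("sim")
    return simulate_all(SimulationConfig(seed=202), out)


def light_config(seed: int, **overrides) -> SimulationConfig:
    """A featureless study configuration for structure-only experiments."""
    defaults = dict(
        seed=seed, genes=(), ssrs=(), tandems=(), dispersed=(),
        mtpts=(), editing=(),
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)
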