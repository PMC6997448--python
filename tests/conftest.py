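import pytest

from methmotif import SimulationConfig, gen_fixture
from methmotif.io import write_fixture_dir


def small_config(seed: int = 7) -> SimulationConfig:
    """A fixture small enough for fast unit tests but with real signal."""
    return SimulationConfig(
        n_cpgs=600,
        n_samples=30,
        planted_motifs=[("TGACTCA", 0.1, 0.5, 0.01)],
        n_hyper=80,
        n_hypo=80,
        tf_db_size=10,
        n_targets_per_tf=5,
        n_tumor=25,
        n_normal=25,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_fixture():
    return gen_fixture(small_config())


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, small_fixture):
    d = tmp_path_factory.mktemp("fixture")
    write_fixture_dir(small_fixture, d)
    return d
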