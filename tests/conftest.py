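import numpy as np
import pytest

from dropfreeze import FreezingAssay, make_fixture_suite


@pytest.fixture()
def four_droplet_assay() -> FreezingAssay:
    """The canonical worked example: four droplets, none censored."""
    return FreezingAssay("tiny", [-30.0, -32.0, -34.0, -36.0])


@pytest.fixture(scope="session")
def suite_manifest(tmp_path_factory):
    """Deterministic six-assay fixture suite (water, buffer, 4 concentrations)."""
    out = tmp_path_factory.mktemp("suite")
    return make_fixture_suite(out, seed=20260, n_droplets=300)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260)
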