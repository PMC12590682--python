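import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from microcat import generate_catalogue, simulate_sample

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: community used by the recovery fixtures (sums to 1)
TRUE_ABUNDANCES = {
    "msp_0001": 0.40,
    "msp_0002": 0.25,
    "msp_0003": 0.18,
    "msp_0004": 0.12,
    "msp_0005": 0.05,
}


@pytest.fixture(scope="session")
def catalogue_bundle(tmp_path_factory):
    """5-MSP x 120-gene catalogue with 20 unclustered genes, written to disk."""
    directory = tmp_path_factory.mktemp("catalogue")
    cat, truth = generate_catalogue(directory, seed=7)
    return cat, truth, directory


@pytest.fixture(scope="session")
def catalogue(catalogue_bundle):
    return catalogue_bundle[0]


@pytest.fixture(scope="session")
def catalogue_dir(catalogue_bundle):
    return catalogue_bundle[2]


@pytest.fixture(scope="session")
def sample_bundle(catalogue_bundle, tmp_path_factory):
    """One 10,000-read sample from the session catalogue, with truth."""
    cat, cat_truth, _ = catalogue_bundle
    sam = tmp_path_factory.mktemp("sample") / "sample_01.sam"
    truth = simulate_sample(
        cat,
        TRUE_ABUNDANCES,
        sam,
        n_reads=10_000,
        homolog_map=cat_truth.homolog_map,
        seed=1,
    )
    return sam, truth


def make_rng(seed=0):
    return np.random.default_rng(seed)
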