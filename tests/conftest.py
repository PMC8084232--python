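import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sweepscan import simulate
from sweepscan.model import MISSING, GenotypeMatrix

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_matrix(rng, n_variants=50, n_samples=8, n_chroms=2, missing_rate=0.1):
    """Small random genotype matrix for unit tests."""
    chrom = rng.choice([f"chr{i + 1}" for i in range(n_chroms)], size=n_variants)
    pos = np.zeros(n_variants, dtype=np.int64)
    for c in np.unique(chrom):
        m = chrom == c
        pos[m] = np.sort(rng.choice(10_000, size=m.sum(), replace=False)) + 1
    gt = rng.integers(0, 3, size=(n_variants, n_samples)).astype(np.int8)
    gt[rng.random(gt.shape) < missing_rate] = MISSING
    ref = np.full(n_variants, "A")
    alt = np.full(n_variants, "T")
    samples = [f"s{i}" for i in range(n_samples)]
    return GenotypeMatrix(chrom, pos, ref, alt, samples, gt)


@pytest.fixture(scope="session")
def default_sim_config():
    return simulate.SimConfig(seed=1)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, default_sim_config):
    """The default strong-sweep fixture bundle, written once per session."""
    out = tmp_path_factory.mktemp("fixture")
    paths = simulate.write_fixture(out, default_sim_config)
    return paths


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
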