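import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from rlsep import LabeledDataset, SynthConfig, generate_cohort
from rlsep.datamodel import FeatureInfo


def make_dataset(X, y, blocks=None, crp=None, sites=None):
    X = np.asarray(X, float)
    n = X.shape[1]
    blocks = blocks or ["phenotypic"] * n
    sites = sites or [None] * n
    feats = [
        FeatureInfo(f"f{i}", blocks[i],
                    site=sites[i] or (f"s{i}" if blocks[i] == "genetic" else None))
        for i in range(n)
    ]
    return LabeledDataset(X=X, y=np.asarray(y, int), features=feats, crp=crp)


@pytest.fixture
def toy_1d():
    """G+ = {(2)}, G- = {(0)}: separable with margin 1 at w=1, theta=1."""
    return make_dataset([[2.0], [0.0]], [1, -1])


@pytest.fixture
def xor_2d():
    """Classic non-separable XOR layout."""
    return make_dataset([[0, 0], [1, 1], [0, 1], [1, 0]], [1, 1, -1, -1])


@pytest.fixture(scope="session")
def wide_margin_cohort():
    """Feature 0 alone separates with a wide margin; features 1..9 are
    standard-normal noise."""
    rng = np.random.default_rng(7)
    m = 30
    y = np.array([1] * 15 + [-1] * 15)
    X = rng.normal(size=(m, 10))
    X[:, 0] = 4.0 * y + rng.uniform(-0.5, 0.5, m)
    return make_dataset(X, y)


@pytest.fixture(scope="session")
def mixed_cohort():
    """Small mixed-block cohort with marginal signal in both blocks."""
    cfg = SynthConfig(m_pos=25, m_neg=25, n_phenotypic=6, n_sites=5,
                      informative_phenotypic=(0, 1), phenotypic_effect=2.0,
                      informative_sites=(0, 1), allele_freq_shift=0.5, seed=11)
    ds, truth = generate_cohort(cfg)
    return ds, truth


@pytest.fixture(scope="session")
def complementary_cohort():
    """Reference complementary-mode cohort: neither block separable alone,
    the combined space separable."""
    cfg = SynthConfig(m_pos=40, m_neg=40, n_phenotypic=8, n_sites=8,
                      informative_phenotypic=(0,), informative_sites=(0, 1, 2, 3),
                      complementary=True, seed=3)
    ds, truth = generate_cohort(cfg)
    return ds, truth
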