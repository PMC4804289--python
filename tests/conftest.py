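import warnings

import numpy as np
import pytest

from cocageo import explore, synthetic_data as sd, tshc
from cocageo.explore import SuperclusterNode

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def region_params():
    return sd.load_region_params()


@pytest.fixture(scope="session")
def params_by_name(region_params):
    return {p.region_name: p for p in region_params}


@pytest.fixture(scope="session")
def default_dataset():
    """The full default synthetic collection (N = 572)."""
    return sd.simulate_dataset(seed=0)


@pytest.fixture(scope="session")
def small_dataset():
    """Five well-separated regions, 40 samples each — fast TSHC fixtures."""
    counts = {"Chapare": 40, "Arauca": 40, "Vichada": 40, "Amazonas": 40,
              "UHV": 40}
    return sd.simulate_dataset(per_region_n=counts, seed=3)


@pytest.fixture(scope="session")
def small_tree():
    """Hand-built supercluster tree over the small dataset's labels."""
    def leaf(n):
        return SuperclusterNode((n,))

    left = SuperclusterNode(("Chapare", "UHV"), [leaf("Chapare"), leaf("UHV")])
    right = SuperclusterNode(("Amazonas", "Vichada"),
                             [leaf("Amazonas"), leaf("Vichada")])
    return SuperclusterNode(("Amazonas", "Arauca", "Chapare", "UHV", "Vichada"),
                            [left, leaf("Arauca"), right])


@pytest.fixture(scope="session")
def small_model(small_dataset, small_tree):
    return tshc.fit(small_dataset, small_tree)


@pytest.fixture(scope="session")
def default_model(default_dataset):
    """TSHC trained on the full default collection (data-derived tree)."""
    _, X = explore.preprocess_features(default_dataset)
    tree = explore.mbc_superclusters(X, default_dataset.regions.to_numpy(), seed=0)
    return tshc.fit(default_dataset, tree)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
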