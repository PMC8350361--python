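import numpy as np
import pandas as pd
import pytest

from recland import synthetic_data as sd
from recland.genome_model import RegionScheme


@pytest.fixture(scope="session")
def scheme() -> RegionScheme:
    return sd.default_region_scheme()


@pytest.fixture(scope="session")
def small_scheme() -> RegionScheme:
    """One 10 Mb chromosome with round region boundaries."""
    return RegionScheme({"1A": pd.DataFrame(
        {"start": [0, 2_000_000, 4_500_000, 5_500_000, 8_000_000],
         "end": [2_000_000, 4_500_000, 5_500_000, 8_000_000, 10_000_000],
         "label": ["R1", "R2a", "C", "R2b", "R3"]})})


@pytest.fixture(scope="session")
def ril_bundle(scheme):
    """Moderate RIL simulation reused by several tests."""
    true_map = sd.simulate_true_map(scheme, seed=101)
    geno, truth = sd.simulate_ril_population(
        true_map, scheme, n_markers_per_chrom=1200, n_ril=200, seed=7)
    return geno, truth


def intervals_frame(chrom, bounds):
    bounds = np.asarray(bounds)
    return pd.DataFrame({"chrom": chrom, "start": bounds[:-1], "end": bounds[1:]})
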