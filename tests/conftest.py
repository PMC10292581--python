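import numpy as np
import pytest

from leafqtl import linkage_map, qtl_scan, synthetic_data as synth


@pytest.fixture(scope="session")
def cross94():
    """A clean simulated pseudo-testcross population: 94 F1s, 3 groups per
    parent, 8 markers per group at 10 cM (Haldane), no missing data."""
    return synth.simulate_pseudo_testcross(
        n_f1=94, groups_per_parent=3, markers_per_group=8, spacing_cM=10.0,
        map_function="haldane", missing_rate=0.0, seed=11)


@pytest.fixture(scope="session")
def gmap94(cross94):
    return linkage_map.build_maps(cross94.genotypes)


@pytest.fixture(scope="session")
def probs94(cross94, gmap94):
    return qtl_scan.genotype_probabilities(gmap94, cross94.genotypes)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
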