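import numpy as np
import pandas as pd
import pytest

from slipir.reference import RefEntry, ReferenceSet
from slipir.simulate import SimConfig, default_barcodes, gen_fragment_reads, gen_parent_references


@pytest.fixture(scope="session")
def small_sim_config():
    """Small read-level study: 3 samples, short parents, modest depth."""
    return SimConfig(
        seed=11,
        n_reads_per_sample=400,
        parent_lengths={"P28S": 900, "P18S": 600, "P5.8S": 157, "P5S": 121},
    )


@pytest.fixture(scope="session")
def parents(small_sim_config):
    return gen_parent_references(small_sim_config)


@pytest.fixture(scope="session")
def barcodes(small_sim_config):
    return default_barcodes(3, seed=small_sim_config.seed)


@pytest.fixture(scope="session")
def read_pairs(parents, small_sim_config, barcodes):
    return gen_fragment_reads(parents, small_sim_config, barcodes)


@pytest.fixture(scope="session")
def planted_matrix():
    """Case/control matrix with 5 planted features among 55, strong effect."""
    from slipir.simulate import gen_count_matrix

    cfg = SimConfig(
        seed=9,
        n_samples_per_class=25,
        planted_log2fc=2.0,
        n_features_per_type={"mRNA": 55},
        de_fraction=5 / 55,
    )
    return gen_count_matrix(cfg)


@pytest.fixture
def tiny_reference():
    return ReferenceSet(
        [
            RefEntry("tsRNA-1", "tsRNA", "ACGTACGTACGTACGTT"),
            RefEntry("tsRNA-2", "tsRNA", "GGGCCCAAATTTGGGCC"),
            RefEntry("tsRNA-3", "tsRNA", "TTTTACGTACGTACGTACGTTAAAA"),
        ]
    )
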