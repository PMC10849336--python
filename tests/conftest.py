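import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from lpimpute import HaplotypePanel, ReadSimConfig, SiteList, generate_panel


@pytest.fixture(scope="session")
def small_panel() -> HaplotypePanel:
    """40 haplotypes x 2000 sites: the default desk-scale panel."""
    return generate_panel(40, 2000, seed=11)


@pytest.fixture()
def tiny_panel() -> HaplotypePanel:
    """Hand-built 4-haplotype, 3-site panel for exact checks."""
    sites = SiteList.from_records(
        [("1", 100, "A", "C"), ("1", 200, "G", "T"), ("1", 300, "T", "A")])
    alleles = np.array([
        [0, 0, 1],
        [1, 0, 0],
        [0, 1, 1],
        [1, 1, 0],
    ], dtype=np.uint8)
    return HaplotypePanel(sites=sites, alleles=alleles,
                          genetic_dist=np.ones(2))


@pytest.fixture()
def default_config() -> ReadSimConfig:
    return ReadSimConfig(nominal_coverage=0.8)
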