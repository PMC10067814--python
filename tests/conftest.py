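"""Shared synthetic fixtures.

Session-scoped simulations are generated once at the study-condition
defaults (library mixed 100:5:1 with eight-barcode controls; landscape
of 500 regions averaging ten 20-nt windows) and reused by the unit,
property and acceptance tests.
"""

import numpy as np
import pytest

from chancexpr import pipeline, simulate


@pytest.fixture(scope="session")
def chance_sample():
    """A chance promoter activity sample (REL scale) at model defaults."""
    return simulate.ActivityModel().sample(2000, seed=10)


@pytest.fixture(scope="session")
def barcode_sim():
    """Reporter library sequenced in both environments."""
    design = simulate.LibraryDesign(n_promoters=1500)
    truth = simulate.build_library(design, seed=42)
    reads, pairs = simulate.gen_barcode_reads(design, truth, seed=43)
    return design, truth, reads, pairs


@pytest.fixture(scope="session")
def barcode_arm(barcode_sim):
    design, truth, reads, _ = barcode_sim
    return pipeline.barcode_arm(reads, truth, s=design.positive_control_rel)


@pytest.fixture(scope="session")
def null_landscape(chance_sample):
    """Landscape with no functional windows and no readthrough: every
    window draws its REL from the chance sample."""
    design = simulate.LandscapeDesign(
        n_regions=500, region_length_range=(60, 340),
        functional_fraction=0.0, readthrough_scale=0.0, replicates=3,
    )
    return simulate.gen_intergenic_landscape(design, chance_sample, seed=11)


@pytest.fixture(scope="session")
def null_arm(null_landscape):
    return pipeline.landscape_arm(null_landscape)


@pytest.fixture(scope="session")
def functional_landscape(chance_sample):
    """Landscape with 5% functional regions (one segment elevated to 4x
    the chance sample's 99th percentile, in one environment only)."""
    design = simulate.LandscapeDesign(
        n_regions=500, region_length_range=(60, 340),
        functional_fraction=0.05, readthrough_scale=0.0,
    )
    return simulate.gen_intergenic_landscape(design, chance_sample, seed=21)


@pytest.fixture(scope="session")
def functional_arm(functional_landscape):
    return pipeline.landscape_arm(functional_landscape)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
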