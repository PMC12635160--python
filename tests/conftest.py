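import pytest

from coastrisk.synth import RegionConfig, make_region, make_sites_and_demographics


def small_config(**overrides) -> RegionConfig:
    """Compact region: ~200x133 DEM cells, fast enough to rebuild in tests."""
    kw = dict(
        seed=11,
        extent_m=(12000.0, 8000.0),
        cell_m=60.0,
        n_counties=4,
        n_blockgroups=40,
        slr_samples=200,
    )
    kw.update(overrides)
    return RegionConfig(**kw)


@pytest.fixture(scope="session")
def region():
    """One fully populated synthetic region shared across read-only tests."""
    return make_sites_and_demographics(make_region(small_config()))


@pytest.fixture(scope="session")
def degenerate_region():
    """Region whose SLR distributions are single atoms (exact-truth checks)."""
    return make_sites_and_demographics(make_region(small_config(seed=12, slr_spread=0.0)))
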