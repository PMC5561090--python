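import numpy as np
import pytest

from ringwue import AtmosphericRecord, StandConfig, TreeRecord, generate_atmosphere


def make_tree(**kw) -> TreeRecord:
    """A valid mid-canopy beech record, overridable field by field."""
    base = dict(
        tree_id="T1",
        species="Fagus sylvatica",
        site_id="BW",
        forest_type="temperate",
        sampling_year=2015,
        age_years=40,
        dbh_cm=22.0,
        height_m=14.0,
        cii_class="3a",
        d13c_outer_permil=-26.5,
    )
    base.update(kw)
    return TreeRecord(**base)


@pytest.fixture()
def tree_factory():
    return make_tree


@pytest.fixture(scope="session")
def constant_atmos() -> AtmosphericRecord:
    return AtmosphericRecord.constant_preindustrial()


@pytest.fixture(scope="session")
def preindustrial_span() -> AtmosphericRecord:
    """Tabulated constant atmosphere covering 1700-1900."""
    return generate_atmosphere("constant_preindustrial", 1700, 1900)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20170818)


@pytest.fixture()
def noise_free_stand_config() -> StandConfig:
    """Stand whose true Wi is exactly linear in height (no light effect, no noise)."""
    return StandConfig(
        beta_light_ppm_per_step=0.0,
        sigma_ppm=0.0,
        height_noise_sd=0.0,
        cii_noise_sd=0.0,
        seed=7,
    )
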