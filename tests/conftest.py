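import numpy as np
import pandas as pd
import pytest

from soiln2o import (
    CovariateClassifier,
    EFGeneratorConfig,
    assign_locations,
    generate_ef_observations,
    worked_example_grid,
)


@pytest.fixture(scope="session")
def grid():
    """Deterministic 400-cell grid carrying the global-2000 strata totals."""
    return worked_example_grid()


@pytest.fixture(scope="session")
def observations():
    """Synthetic EF observation table (normal effects), n=848."""
    return generate_ef_observations(EFGeneratorConfig(seed=42))


@pytest.fixture(scope="session")
def classified(observations):
    """Classified observations with location ids, ready for model fitting."""
    df = CovariateClassifier().transform(observations)
    df["location_id"] = assign_locations(df)
    return df


def raw_record(**overrides):
    """One fully-populated raw observation row (retained by default)."""
    base = {
        "record_id": "R1",
        "reference_id": "ref_a",
        "latitude": 45.0,
        "longitude": 5.0,
        "region": "Europe",
        "climate_zone": "temperate_boreal",
        "annual_precip_mm": 800.0,
        "pet_ratio": 1.2,
        "n2o_treatment": 2.0,
        "n2o_control": 1.0,
        "n_input": 100.0,
        "fertilizer_description": "urea",
        "fertilizer_synthetic": True,
        "fertilizer_organic": False,
        "organic_state": "unspecified",
        "land_cover_raw": "annual_crop",
        "usda_texture": "loam",
        "soil_c_pct": 1.5,
        "soil_ph": 6.5,
        "length_days": 150.0,
        "irrigated": False,
        "flooded_rice": False,
        "grazed_excreta": False,
        "enhanced_efficiency": False,
        "organic_soil": False,
        "lab_or_model": False,
        "peer_reviewed": True,
    }
    base.update(overrides)
    return base


@pytest.fixture()
def make_records():
    def _make(*rows):
        return pd.DataFrame([raw_record(**r) for r in rows])
    return _make


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
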