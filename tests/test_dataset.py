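"""EF computation, inclusion filters, covariate classification, locations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst

from soiln2o import (
    CovariateClassifier,
    ExclusionReason,
    StudyFilter,
    assign_locations,
    classify_climate,
    classify_covariates,
    classify_fertilizer_form,
    compute_ef,
    filter_studies,
    summarize_dataset,
)
from soiln2o.dataset import (
    FACTOR_COLUMNS,
    classify_alkalinity,
    classify_land_cover,
    classify_length,
    classify_n_rate,
    classify_soil_c,
    classify_texture,
    read_observations,
)


# ---------------------------------------------------------------------------
# compute_ef
# ---------------------------------------------------------------------------
@pytest.mark.parametrize(
    "t,c,n,expected",
    [
        (2.0, 1.0, 100.0, 0.01),
        (1.37, 1.37, 250.0, 0.0),          # treatment equals control
        (0.34, 1.94, 100.0, -0.016),        # negative EF (net uptake)
    ],
)
def test_compute_ef_examples(t, c, n, expected):
    assert compute_ef(t, c, n) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("n", [0.0, -10.0, np.nan])
def test_compute_ef_rejects_bad_n_input(n):
    with pytest.raises(ValueError, match="n_input"):
        compute_ef(2.0, 1.0, n)


def test_compute_ef_rejects_missing_control():
    with pytest.raises(ValueError, match="control"):
        compute_ef(2.0, np.nan, 100.0)


@settings(max_examples=100, derandomize=True)
@given(
    t=hst.floats(-5, 5),
    c=hst.floats(-5, 5),
    n=hst.floats(1, 2000),
    k=hst.floats(0.1, 10),
)
def test_compute_ef_linear_and_antisymmetric(t, c, n, k):
    base = compute_ef(t, c, n)
    # linear in the treatment flux
    assert compute_ef(t * k, c * k, n) == pytest.approx(k * base, abs=1e-9)
    # swapping treatment and control flips the sign
    assert compute_ef(c, t, n) == pytest.approx(-base, abs=1e-12)


# ---------------------------------------------------------------------------
# study filters
# ---------------------------------------------------------------------------
def test_filter_studies_reason_codes(make_records):
    df = make_records(
        {"record_id": "keep"},
        {"record_id": "rice", "flooded_rice": True},
        {"record_id": "lab", "lab_or_model": True},
        {"record_id": "grey", "peer_reviewed": False},
        {"record_id": "graze", "grazed_excreta": True},
        {"record_id": "eenf", "enhanced_efficiency": True},
        {"record_id": "peat", "organic_soil": True},
        {"record_id": "noctl", "n2o_control": np.nan},
        {"record_id": "non", "n_input": 0.0},
    )
    retained, log = filter_studies(df)
    assert retained["record_id"].tolist() == ["keep"]
    reasons = dict(zip(log["record_id"], log["reason"]))
    assert reasons == {
        "rice": ExclusionReason.FLOODED_RICE.value,
        "lab": ExclusionReason.LAB_STUDY.value,
        "grey": ExclusionReason.NOT_PEER_REVIEWED.value,
        "graze": ExclusionReason.GRAZED_EXCRETA.value,
        "eenf": ExclusionReason.ENHANCED_EFFICIENCY.value,
        "peat": ExclusionReason.ORGANIC_SOIL.value,
        "noctl": ExclusionReason.NO_CONTROL.value,
        "non": ExclusionReason.NONPOSITIVE_N_INPUT.value,
    }
    # conservation: retained + excluded = input, retained rows unmodified
    assert len(retained) + len(log) == len(df)
    pd.testing.assert_frame_equal(
        retained, df[df["record_id"] == "keep"], check_like=True
    )


def test_filter_studies_empty_input():
    retained, log = filter_studies(pd.DataFrame(columns=["record_id"]))
    assert retained.empty and log.empty


def test_missing_provenance_flag_passes_with_warning(make_records):
    df = make_records({"record_id": "unk", "flooded_rice": np.nan})
    with pytest.warns(UserWarning, match="flooded_rice"):
        retained, log = filter_studies(df)
    assert retained["record_id"].tolist() == ["unk"]


def test_study_filter_transformer(make_records):
    df = make_records({"record_id": "a"}, {"record_id": "b", "flooded_rice": True})
    f = StudyFilter()
    out = f.fit_transform(df)
    assert out["record_id"].tolist() == ["a"]
    assert f.exclusion_log_["record_id"].tolist() == ["b"]


# ---------------------------------------------------------------------------
# per-factor classification
# ---------------------------------------------------------------------------
@pytest.mark.parametrize(
    "zone,precip,pet,expected",
    [
        ("tropical", 900.0, None, "dry"),
        ("tropical", 1500.0, None, "wet"),
        ("tropical", 1000.0, None, "wet"),       # boundary -> wetter class
        ("temperate_boreal", None, 1.2, "wet"),
        ("temperate_boreal", None, 0.7, "dry"),
        ("temperate_boreal", None, 1.0, "wet"),  # boundary -> wetter class
        ("tropical", None, 1.2, None),           # missing required covariate
        ("temperate_boreal", 900.0, None, None),
    ],
)
def test_classify_climate(zone, precip, pet, expected):
    assert classify_climate(zone, precip, pet) == expected


def test_climate_boundary_rule_is_configurable():
    assert classify_climate("temperate_boreal", None, 1.0, boundary="dry") == "dry"
    assert classify_climate("tropical", 1000.0, None, boundary="dry") == "dry"


@pytest.mark.parametrize(
    "syn,org,expected",
    [
        (True, False, "synthetic_mixed"),   # e.g. urea
        (False, True, "organic"),           # e.g. animal slurry
        (True, True, "synthetic_mixed"),    # mixture grouped with synthetic
        (False, False, None),
    ],
)
def test_classify_fertilizer_form(syn, org, expected):
    assert classify_fertilizer_form(syn, org) == expected


@pytest.mark.parametrize(
    "fn,value,expected",
    [
        (classify_n_rate, 100.0, "(0;100]"),      # right-closed boundary
        (classify_n_rate, 100.1, "(100;200]"),
        (classify_n_rate, 250.0, "(200;300]"),
        (classify_n_rate, 500.0, ">300"),
        (classify_n_rate, np.nan, None),
        (classify_texture, "silty clay", "fine"),
        (classify_texture, "clay", "fine"),
        (classify_texture, "silty clay loam", "medium_coarse"),
        (classify_texture, "sand", "medium_coarse"),
        (classify_texture, np.nan, None),
        (classify_soil_c, 2.0, "high"),            # boundary inclusive
        (classify_soil_c, 1.99, "low_medium"),
        (classify_alkalinity, 7.0, "basic"),
        (classify_alkalinity, 6.99, "acid"),
        (classify_land_cover, "annual_crop", "annual_bare"),
        (classify_land_cover, "bare_soil", "annual_bare"),
        (classify_land_cover, "undefined", "annual_bare"),
        (classify_land_cover, "grassland", "perennial"),
        (classify_land_cover, "tree_plantation", "perennial"),
        (classify_length, 120.0, "<=120"),
        (classify_length, 180.0, "(120;180]"),
        (classify_length, 301.0, ">300"),
        (classify_length, np.nan, None),
    ],
)
def test_covariate_classes(fn, value, expected):
    assert fn(value) == expected


def test_unknown_texture_and_land_cover_raise():
    with pytest.raises(ValueError):
        classify_texture("volcanic ash")
    with pytest.raises(ValueError):
        classify_land_cover("wetland")


def test_classify_covariates_missing_is_per_factor(make_records):
    obs = make_records({"usda_texture": np.nan, "soil_ph": np.nan}).iloc[0]
    labels = classify_covariates(obs)
    assert labels["texture"] is None and labels["alkalinity"] is None
    # the observation still classifies under every other factor
    assert labels["climate"] == "wet"
    assert labels["n_rate"] == "(0;100]"
    assert labels["soil_c"] == "low_medium"


def test_irrigation_class_defined_for_dry_climate_only(make_records):
    dry = make_records({"pet_ratio": 0.5, "irrigated": True}).iloc[0]
    wet = make_records({"pet_ratio": 1.5, "irrigated": True}).iloc[0]
    assert classify_covariates(dry)["irrigation"] == "irrigated"
    assert classify_covariates(wet)["irrigation"] is None


def test_classifier_partitions_are_exhaustive_and_disjoint(classified):
    """Each observation gets exactly one label per factor whose covariate
    exists, and none where it is missing."""
    assert len(classified) == 848
    for factor, col in FACTOR_COLUMNS.items():
        labels = classified[col]
        if factor == "irrigation":
            assert labels.notna().equals(classified["cls_climate"] == "dry")
            continue
        if factor == "soil_c":
            assert labels.isna().equals(classified["soil_c_pct"].isna())
        else:
            assert labels.notna().all(), factor
    # merge maps rewrite labels after classification
    merged = CovariateClassifier(
        merge_maps={"texture": {"fine": "all", "medium_coarse": "all"}}
    ).transform(classified)
    assert set(merged["cls_texture"].dropna()) == {"all"}


# ---------------------------------------------------------------------------
# locations
# ---------------------------------------------------------------------------
def test_assign_locations_rules(make_records):
    df = make_records(
        # same coordinates, different crops -> same location
        {"record_id": "a", "latitude": 1.0, "longitude": 2.0,
         "land_cover_raw": "annual_crop", "reference_id": "r1"},
        {"record_id": "b", "latitude": 1.0, "longitude": 2.0,
         "land_cover_raw": "grassland", "reference_id": "r2"},
        # no coordinates, same reference + soil + land cover -> same location
        {"record_id": "c", "latitude": np.nan, "longitude": np.nan,
         "reference_id": "r3", "usda_texture": "loam",
         "land_cover_raw": "annual_crop"},
        {"record_id": "d", "latitude": np.nan, "longitude": np.nan,
         "reference_id": "r3", "usda_texture": "loam",
         "land_cover_raw": "annual_crop"},
        # different reference, different coordinates -> distinct
        {"record_id": "e", "latitude": 9.0, "longitude": 9.0,
         "reference_id": "r4"},
    )
    loc = assign_locations(df)
    assert loc.iloc[0] == loc.iloc[1]
    assert loc.iloc[2] == loc.iloc[3]
    assert len({loc.iloc[0], loc.iloc[2], loc.iloc[4]}) == 3


def test_assign_locations_transitive_closure(make_records):
    """A-B joined by coordinates, B-C by reference rule -> one location."""
    df = make_records(
        {"record_id": "a", "latitude": 1.0, "longitude": 2.0,
         "reference_id": "rA", "usda_texture": "sand"},
        {"record_id": "b", "latitude": 1.0, "longitude": 2.0,
         "reference_id": "rB", "usda_texture": "loam"},
        {"record_id": "c", "latitude": 3.0, "longitude": 4.0,
         "reference_id": "rB", "usda_texture": "loam"},
    )
    loc = assign_locations(df)
    assert loc.nunique() == 1


def test_assign_locations_stable_under_row_order(make_records):
    df = make_records(
        {"record_id": "a", "latitude": 1.0, "longitude": 2.0},
        {"record_id": "b", "latitude": 1.0, "longitude": 2.0},
        {"record_id": "c", "reference_id": "other", "latitude": 5.0,
         "longitude": 5.0},
    )
    loc1 = assign_locations(df)
    shuffled = df.iloc[[2, 0, 1]].reset_index(drop=True)
    loc2 = assign_locations(shuffled)
    assert sorted(loc1.unique()) == sorted(loc2.unique())


# ---------------------------------------------------------------------------
# summaries and I/O
# ---------------------------------------------------------------------------
def test_summarize_empty_dataset():
    tables = summarize_dataset(pd.DataFrame())
    assert all(t.empty for t in tables.values())


def test_summarize_counts_match_construction(classified):
    tables = summarize_dataset(classified)
    climate = tables["climate"]
    assert climate.to_numpy().sum() == 848
    # the generator states a 76% wet-climate share
    wet_share = climate["wet"].sum() / 848
    assert wet_share == pytest.approx(0.76, abs=0.02)


def test_read_observations_requires_mandatory_columns(tmp_path):
    p = tmp_path / "bad.csv"
    pd.DataFrame({"record_id": ["r"], "n_input": [1.0]}).to_csv(p, index=False)
    with pytest.raises(ValueError, match="n2o_treatment"):
        read_observations(p)
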