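"""Emission-factor observation handling.

One row = one fertilization experiment with cumulative N2O fluxes on a
treated and an unfertilized control plot.  The per-experiment emission
factor is

    EF1_i = (N2O_T_i - N2O_C_i) / N_i

with fluxes in kg N2O-N ha-1 over the experimental period and N_i the N
applied (kg N ha-1) over the same period.  Negative EF values are valid
(net uptake relative to the control).

The module applies the meta-analysis inclusion filters, classifies each
observation into the controlling-factor classes (climate, fertilizer form,
N rate, irrigation, land cover, texture, soil C, alkalinity, experiment
length), and assigns location identifiers for the mixed-model random effect.
Fluxes are accepted in kg N2O-N ha-1 period-1 only; converting from g m-2 or
from N2O molecular mass is the caller's responsibility.
"""

from __future__ import annotations

import enum
import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "OBSERVATION_COLUMNS",
    "FACTOR_COLUMNS",
    "ExclusionReason",
    "StudyFilter",
    "CovariateClassifier",
    "compute_ef",
    "filter_studies",
    "classify_climate",
    "classify_fertilizer_form",
    "classify_n_rate",
    "classify_land_cover",
    "classify_texture",
    "classify_soil_c",
    "classify_alkalinity",
    "classify_length",
    "classify_irrigation",
    "classify_covariates",
    "assign_locations",
    "summarize_dataset",
    "read_observations",
    "write_observations",
    "write_exclusion_log",
]

# CSV schema: one column per field, decimal point, UTF-8, empty string = NA.
OBSERVATION_COLUMNS: tuple[str, ...] = (
    "record_id",
    "reference_id",
    "latitude",
    "longitude",
    "region",
    "climate_zone",          # temperate_boreal | tropical
    "annual_precip_mm",
    "pet_ratio",
    "n2o_treatment",         # kg N2O-N ha-1 period-1
    "n2o_control",           # kg N2O-N ha-1 period-1
    "n_input",               # kg N ha-1 period-1
    "fertilizer_description",
    "fertilizer_synthetic",  # bool form flags
    "fertilizer_organic",
    "organic_state",         # liquid | solid | unspecified
    "land_cover_raw",
    "usda_texture",
    "soil_c_pct",
    "soil_ph",
    "length_days",
    "irrigated",
    "flooded_rice",
    "grazed_excreta",
    "enhanced_efficiency",
    "organic_soil",
    "lab_or_model",
    "peer_reviewed",
)

_BOOL_COLUMNS = (
    "fertilizer_synthetic",
    "fertilizer_organic",
    "irrigated",
    "flooded_rice",
    "grazed_excreta",
    "enhanced_efficiency",
    "organic_soil",
    "lab_or_model",
    "peer_reviewed",
)

_MANDATORY_COLUMNS = ("record_id", "n2o_treatment", "n2o_control", "n_input")

USDA_TEXTURES = frozenset(
    {
        "sand",
        "loamy sand",
        "sandy loam",
        "loam",
        "silt loam",
        "silt",
        "sandy clay loam",
        "clay loam",
        "silty clay loam",
        "sandy clay",
        "silty clay",
        "clay",
    }
)
FINE_TEXTURES = frozenset({"sandy clay", "silty clay", "clay"})

LAND_COVERS = frozenset(
    {
        "annual_crop",
        "bare_soil",
        "perennial_crop",
        "grassland",
        "agroforestry",
        "tree_plantation",
        "managed_forest",
        "undefined",
    }
)
_ANNUAL_BARE = frozenset({"annual_crop", "bare_soil", "undefined"})

# classified-label columns added by CovariateClassifier, keyed by factor name
FACTOR_COLUMNS: dict[str, str] = {
    "climate": "cls_climate",
    "fertilizer_form": "cls_fertilizer_form",
    "n_rate": "cls_n_rate",
    "irrigation": "cls_irrigation",
    "land_cover": "cls_land_cover",
    "texture": "cls_texture",
    "soil_c": "cls_soil_c",
    "alkalinity": "cls_alkalinity",
    "length": "cls_length",
}


# ---------------------------------------------------------------------------
# EF computation
# ---------------------------------------------------------------------------
def compute_ef(n2o_treatment, n2o_control, n_input):
    """Per-experiment emission factor (treatment - control) / N applied.

    All three arguments in kg N ha-1 over the same experimental period.
    Vectorized; raises on non-positive or missing ``n_input`` and on a
    missing control flux (an observation without a control plot cannot yield
    an EF and must be filtered out, never defaulted to zero).
    """
    t = np.asarray(n2o_treatment, dtype=float)
    c = np.asarray(n2o_control, dtype=float)
    n = np.asarray(n_input, dtype=float)
    if np.any(np.isnan(n)) or np.any(n <= 0):
        raise ValueError("n_input must be present and > 0 for every observation")
    if np.any(np.isnan(c)):
        raise ValueError("missing control flux: observation cannot yield an EF")
    if np.any(np.isnan(t)):
        raise ValueError("missing treatment flux")
    out = (t - c) / n
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# study inclusion filters
# ---------------------------------------------------------------------------
class ExclusionReason(str, enum.Enum):
    NOT_PEER_REVIEWED = "NOT_PEER_REVIEWED"
    LAB_STUDY = "LAB_STUDY"
    FLOODED_RICE = "FLOODED_RICE"
    GRAZED_EXCRETA = "GRAZED_EXCRETA"
    ENHANCED_EFFICIENCY = "ENHANCED_EFFICIENCY"
    ORGANIC_SOIL = "ORGANIC_SOIL"
    NO_CONTROL = "NO_CONTROL"
    NONPOSITIVE_N_INPUT = "NONPOSITIVE_N_INPUT"


def _flag(df: pd.DataFrame, col: str, default: bool) -> pd.Series:
    """Boolean provenance flag; missing values pass with a warning."""
    if col not in df.columns:
        warnings.warn(f"provenance flag {col!r} absent; treated as not-excluded")
        return pd.Series(default, index=df.index)
    s = df[col]
    if s.isna().any():
        warnings.warn(
            f"{int(s.isna().sum())} record(s) missing provenance flag {col!r}; "
            "treated as not-excluded"
        )
    return s.map(lambda v: default if pd.isna(v) else bool(v))


def filter_studies(records: pd.DataFrame):
    """Apply the meta-analysis inclusion rules.

    Removes records that are non-peer-reviewed, laboratory/greenhouse or
    modeling studies, flooded-rice experiments, grazed urine/dung
    depositions, enhanced-efficiency fertilizers, drained/managed organic
    soils, or that lack a control plot or a positive N input.

    Returns ``(retained, exclusion_log)`` where the log has one machine-
    readable reason code per dropped record.  Retained records are returned
    unmodified.  An empty input yields two empty frames.
    """
    df = records
    if df.empty:
        return df.copy(), pd.DataFrame(columns=["record_id", "reason"])

    # precedence follows the published exclusion list order
    checks = [
        (~_flag(df, "peer_reviewed", True), ExclusionReason.NOT_PEER_REVIEWED),
        (_flag(df, "lab_or_model", False), ExclusionReason.LAB_STUDY),
        (_flag(df, "flooded_rice", False), ExclusionReason.FLOODED_RICE),
        (_flag(df, "grazed_excreta", False), ExclusionReason.GRAZED_EXCRETA),
        (_flag(df, "enhanced_efficiency", False), ExclusionReason.ENHANCED_EFFICIENCY),
        (_flag(df, "organic_soil", False), ExclusionReason.ORGANIC_SOIL),
        (df["n2o_control"].isna(), ExclusionReason.NO_CONTROL),
        (df["n_input"].isna() | (df["n_input"] <= 0), ExclusionReason.NONPOSITIVE_N_INPUT),
    ]
    reason = pd.Series(pd.NA, index=df.index, dtype=object)
    for mask, code in checks:
        hit = mask & reason.isna()
        reason[hit] = code.value
    excluded = reason.notna()
    log = pd.DataFrame(
        {"record_id": df.loc[excluded, "record_id"].values,
         "reason": reason[excluded].values}
    )
    return df.loc[~excluded].copy(), log


class StudyFilter(BaseEstimator, TransformerMixin):
    """sklearn-style transformer around :func:`filter_studies`.

    ``transform`` returns the retained observations; the exclusion log of
    the last transform is stored on ``exclusion_log_``.
    """

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        retained, log = filter_studies(X)
        self.exclusion_log_ = log
        return retained


# ---------------------------------------------------------------------------
# per-factor classification rules
# ---------------------------------------------------------------------------
def classify_climate(zone, annual_precip=None, pet_ratio=None, boundary="wet"):
    """IPCC wet/dry climate class.

    Temperate/boreal zones are wet where annual precipitation:PET > 1;
    tropical zones are wet where annual precipitation > 1000 mm.  Values
    exactly at the threshold are assigned to the class named by ``boundary``
    (default ``"wet"``: ties break toward the wetter class).  A missing
    required covariate returns ``None`` (unclassifiable).
    """
    if boundary not in ("wet", "dry"):
        raise ValueError("boundary must be 'wet' or 'dry'")
    if pd.isna(zone):
        return None
    if zone == "tropical":
        if annual_precip is None or pd.isna(annual_precip):
            return None
        if annual_precip == 1000.0:
            return boundary
        return "wet" if annual_precip > 1000.0 else "dry"
    if zone == "temperate_boreal":
        if pet_ratio is None or pd.isna(pet_ratio):
            return None
        if pet_ratio == 1.0:
            return boundary
        return "wet" if pet_ratio > 1.0 else "dry"
    raise ValueError(f"unknown climate zone {zone!r}")


def classify_fertilizer_form(synthetic, organic):
    """Fertilizer form class.

    Pure organic forms -> ``organic``; synthetic forms and any mixture of
    synthetic and organic forms -> ``synthetic_mixed`` (the two were shown
    to behave alike and are kept merged).  No flag set -> ``None``.
    """
    syn = bool(synthetic) if not pd.isna(synthetic) else False
    org = bool(organic) if not pd.isna(organic) else False
    if syn:
        return "synthetic_mixed"
    if org:
        return "organic"
    return None


N_RATE_BINS = ((0.0, 100.0), (100.0, 200.0), (200.0, 300.0))
N_RATE_LABELS = ("(0;100]", "(100;200]", "(200;300]", ">300")

LENGTH_BINS = ((0.0, 120.0), (120.0, 180.0), (180.0, 240.0), (240.0, 300.0))
LENGTH_LABELS = ("<=120", "(120;180]", "(180;240]", "(240;300]", ">300")


def _bin_left_open(x, bins, labels):
    if pd.isna(x):
        return None
    for (lo, hi), lab in zip(bins, labels):
        if lo < x <= hi:
            return lab
    return labels[-1] if x > bins[-1][1] else None


def classify_n_rate(n_input):
    """N application rate bin, left-open right-closed: (0;100], (100;200],
    (200;300], >300 kg N ha-1 period-1."""
    return _bin_left_open(n_input, N_RATE_BINS, N_RATE_LABELS)


def classify_length(length_days):
    """Experiment length bin: <=120, (120;180], (180;240], (240;300],
    >300 days."""
    if pd.isna(length_days):
        return None
    if length_days <= 0:
        return None
    return _bin_left_open(length_days, LENGTH_BINS, LENGTH_LABELS)


def classify_land_cover(land_cover_raw):
    """Annual croplands and bare soils vs perennial systems.

    ``undefined`` raw crops are grouped with annual/bare, matching how the
    source databases were aggregated.
    """
    if pd.isna(land_cover_raw):
        return None
    if land_cover_raw not in LAND_COVERS:
        raise ValueError(f"unknown land cover {land_cover_raw!r}")
    return "annual_bare" if land_cover_raw in _ANNUAL_BARE else "perennial"


def classify_texture(usda_texture):
    """USDA texture grouped as fine (sandy clay, silty clay, clay) vs
    medium/coarse (the other nine classes)."""
    if pd.isna(usda_texture):
        return None
    t = str(usda_texture).strip().lower()
    if t not in USDA_TEXTURES:
        raise ValueError(f"unknown USDA texture class {usda_texture!r}")
    return "fine" if t in FINE_TEXTURES else "medium_coarse"


def classify_soil_c(soil_c_pct):
    """Topsoil C content: high (>=2%) vs low-medium (<2%)."""
    if pd.isna(soil_c_pct):
        return None
    return "high" if soil_c_pct >= 2.0 else "low_medium"


def classify_alkalinity(soil_ph):
    """Soil alkalinity: acid (pH < 7) vs basic (pH >= 7)."""
    if pd.isna(soil_ph):
        return None
    return "basic" if soil_ph >= 7.0 else "acid"


def classify_irrigation(irrigated, climate_class):
    """Irrigation class, defined for dry-climate observations only."""
    if climate_class != "dry" or pd.isna(irrigated):
        return None
    return "irrigated" if bool(irrigated) else "rainfed"


def classify_covariates(obs: Mapping) -> dict[str, str | None]:
    """Classify one observation into every factor class.

    Missing covariates yield ``None`` for that factor only; the observation
    still participates in the other factors' models.
    """
    climate = classify_climate(
        obs.get("climate_zone"),
        obs.get("annual_precip_mm"),
        obs.get("pet_ratio"),
    )
    return {
        "climate": climate,
        "fertilizer_form": classify_fertilizer_form(
            obs.get("fertilizer_synthetic"), obs.get("fertilizer_organic")
        ),
        "n_rate": classify_n_rate(obs.get("n_input")),
        "irrigation": classify_irrigation(obs.get("irrigated"), climate),
        "land_cover": classify_land_cover(obs.get("land_cover_raw")),
        "texture": classify_texture(obs.get("usda_texture")),
        "soil_c": classify_soil_c(obs.get("soil_c_pct")),
        "alkalinity": classify_alkalinity(obs.get("soil_ph")),
        "length": classify_length(obs.get("length_days")),
    }


class CovariateClassifier(BaseEstimator, TransformerMixin):
    """Add per-factor class-label columns (``cls_*``) to an observation table.

    Parameters
    ----------
    climate_boundary
        Class assigned when precipitation:PET or annual precipitation sits
        exactly at its wet/dry threshold.
    merge_maps
        Optional ``{factor_name: {fine_label: merged_label}}`` applied after
        the base classification (the class-merging workflow).
    compute_ef_column
        If True (default), (re)derive the ``ef`` column from the fluxes.
    """

    def __init__(self, climate_boundary="wet", merge_maps=None,
                 compute_ef_column=True):
        self.climate_boundary = climate_boundary
        self.merge_maps = merge_maps
        self.compute_ef_column = compute_ef_column

    def fit(self, X, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        df = X.copy()
        if self.compute_ef_column:
            df["ef"] = compute_ef(
                df["n2o_treatment"], df["n2o_control"], df["n_input"]
            )
        climate = [
            classify_climate(z, p, r, boundary=self.climate_boundary)
            for z, p, r in zip(
                df.get("climate_zone", pd.Series(index=df.index, dtype=object)),
                df.get("annual_precip_mm", pd.Series(index=df.index, dtype=float)),
                df.get("pet_ratio", pd.Series(index=df.index, dtype=float)),
            )
        ]
        df["cls_climate"] = climate
        df["cls_fertilizer_form"] = [
            classify_fertilizer_form(s, o)
            for s, o in zip(df["fertilizer_synthetic"], df["fertilizer_organic"])
        ]
        df["cls_n_rate"] = df["n_input"].map(classify_n_rate)
        df["cls_irrigation"] = [
            classify_irrigation(i, c) for i, c in zip(df["irrigated"], climate)
        ]
        df["cls_land_cover"] = df["land_cover_raw"].map(classify_land_cover)
        df["cls_texture"] = df["usda_texture"].map(classify_texture)
        df["cls_soil_c"] = df["soil_c_pct"].map(classify_soil_c)
        df["cls_alkalinity"] = df["soil_ph"].map(classify_alkalinity)
        df["cls_length"] = df["length_days"].map(classify_length)
        if self.merge_maps:
            for factor, mapping in self.merge_maps.items():
                col = FACTOR_COLUMNS[factor]
                df[col] = df[col].map(lambda v: mapping.get(v, v))
        return df


# ---------------------------------------------------------------------------
# location identifiers
# ---------------------------------------------------------------------------
def assign_locations(df: pd.DataFrame) -> pd.Series:
    """Assign a location identifier per observation.

    Two observations share a location when they have an identical
    coordinate, or when they come from the same bibliographic reference with
    the same soil type (USDA texture) and the same raw land cover; the
    location partition is the transitive closure of the two rules, with
    coordinate identity taking precedence.  Identifiers are stable across
    runs and input orderings: each group is labelled by the smallest
    record_id it contains.
    """
    order = df["record_id"].astype(str)
    idx = list(df.index)
    parent = {i: i for i in idx}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    # rule 1: identical coordinates (both present, exactly equal)
    has_coord = df["latitude"].notna() & df["longitude"].notna()
    coord_groups: dict[tuple, list] = {}
    for i in df.index[has_coord]:
        key = (float(df.at[i, "latitude"]), float(df.at[i, "longitude"]))
        coord_groups.setdefault(key, []).append(i)
    # rule 2: same reference + soil type + land cover (NA matches NA)
    ref_groups: dict[tuple, list] = {}
    for i in idx:
        ref = df.at[i, "reference_id"]
        if pd.isna(ref):
            continue
        key = (ref, df.at[i, "usda_texture"], df.at[i, "land_cover_raw"])
        ref_groups.setdefault(key, []).append(i)
    for members in list(coord_groups.values()) + list(ref_groups.values()):
        for j in members[1:]:
            union(members[0], j)

    roots: dict = {}
    for i in idx:
        roots.setdefault(find(i), []).append(i)
    labels = pd.Series(index=df.index, dtype=object)
    for members in roots.values():
        rep = min(order.loc[members])
        labels.loc[members] = f"loc_{rep}"
    return labels


# ---------------------------------------------------------------------------
# descriptive summaries
# ---------------------------------------------------------------------------
def summarize_dataset(df: pd.DataFrame, factors: Iterable[str] | None = None,
                      region_col: str = "region") -> dict[str, pd.DataFrame]:
    """Contingency counts per region x class, one table per factor."""
    factors = list(factors) if factors is not None else list(FACTOR_COLUMNS)
    out = {}
    for factor in factors:
        col = FACTOR_COLUMNS[factor]
        if df.empty or col not in df.columns:
            out[factor] = pd.DataFrame()
            continue
        out[factor] = pd.crosstab(df[region_col], df[col])
    return out


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------
def read_observations(path) -> pd.DataFrame:
    """Read an observation CSV (empty string = missing, booleans literal)."""
    df = pd.read_csv(path)
    missing = [c for c in _MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"observation CSV missing mandatory column(s): {missing}")
    for col in _BOOL_COLUMNS:
        if col in df.columns and df[col].dtype == object:
            df[col] = df[col].map(
                {"True": True, "False": False, True: True, False: False}
            )
    return df


def write_observations(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_exclusion_log(log: pd.DataFrame, path) -> None:
    log.to_csv(path, index=False)
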