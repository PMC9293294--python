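"""Tier 1 N2O inventory over gridded fertilizer-N inputs.

Each grid cell carries synthetic-fertilizer and manure N masses (Gg N), a
wet/dry climate class and a country code; flooded-rice N is assumed already
removed.  Emissions per component are N x EF(climate, component).  Point
estimates use the triangular mode; uncertainty is propagated by Monte Carlo:
each iteration draws ONE EF per distinct triangular distribution, shared
across every cell and stratum using that distribution (fully correlated
within, independent across), and the 95% CI is the 2.5/97.5 empirical
quantile of the per-iteration aggregates.  Per-cell independent draws would average out and collapse the
global CI far below the published Tier 1 ranges; the shared draw reproduces
them.

All N masses are Gg N; emissions are Gg N2O-N (multiply by 44/28 for Gg N2O
via :func:`to_n2o_mass` — never applied by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schemes import COMPONENTS, EFScheme, MissingStratumError

__all__ = [
    "GRID_COLUMNS",
    "UNKNOWN_COUNTRY",
    "N2O_N_TO_N2O",
    "EmissionEstimate",
    "read_grid",
    "write_grid",
    "validate_grid",
    "sample_ef",
    "cell_emission",
    "run_inventory",
    "compare_schemes",
    "difference_map",
    "to_n2o_mass",
]

GRID_COLUMNS = (
    "cell_id",
    "country_code",     # ISO-3166 alpha-3
    "climate",          # wet | dry
    "n_synthetic_gg",   # Gg N
    "n_manure_gg",      # Gg N
    "rice_excluded",    # True: the cell's flooded-rice N was already removed
)

UNKNOWN_COUNTRY = "XXX"
N2O_N_TO_N2O = 44.0 / 28.0

_COMPONENT_COL = {"synthetic": "n_synthetic_gg", "manure": "n_manure_gg"}


@dataclass(frozen=True)
class EmissionEstimate:
    """Point estimate and 95% CI of an N2O-N emission at one scope."""

    scope: str          # cell | country | global
    name: str           # cell_id, country code, or "global"
    component: str      # synthetic | manure | total
    point: float        # Gg N2O-N (mode-EF arithmetic)
    ci_low: float       # 2.5% quantile, Gg N2O-N
    ci_high: float      # 97.5% quantile, Gg N2O-N
    n_draws: int
    seed: int


# ---------------------------------------------------------------------------
# grid I/O and validation
# ---------------------------------------------------------------------------
def read_grid(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in GRID_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"grid CSV missing column(s): {missing}")
    if df["rice_excluded"].dtype == object:
        df["rice_excluded"] = df["rice_excluded"].map(
            {"True": True, "False": False, True: True, False: False}
        )
    return validate_grid(df)


def write_grid(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def validate_grid(df: pd.DataFrame) -> pd.DataFrame:
    """Check invariants and normalize unknown country codes to a sentinel."""
    if df.empty:
        raise ValueError("empty grid")
    if (df["n_synthetic_gg"] < 0).any() or (df["n_manure_gg"] < 0).any():
        raise ValueError("negative N mass in grid")
    bad = ~df["climate"].isin(("wet", "dry"))
    if bad.any():
        raise ValueError(
            f"invalid climate class in cells {df.loc[bad, 'cell_id'].tolist()[:5]}"
        )
    out = df.copy()
    unknown = out["country_code"].isna() | (out["country_code"].astype(str).str.len() != 3)
    if unknown.any():
        warnings.warn(
            f"{int(unknown.sum())} cell(s) with missing/invalid country code "
            f"collected under {UNKNOWN_COUNTRY!r}"
        )
        out.loc[unknown, "country_code"] = UNKNOWN_COUNTRY
    if not out["rice_excluded"].fillna(False).all():
        warnings.warn(
            "grid contains cells with rice_excluded=False; the Tier 1 EF1 "
            "does not cover flooded rice"
        )
    return out


# ---------------------------------------------------------------------------
# sampling and per-cell arithmetic
# ---------------------------------------------------------------------------
def sample_ef(scheme: EFScheme, n_draws: int, seed) -> pd.DataFrame:
    """EF draws, one column per stratum, one row per Monte Carlo iteration.

    The sampling unit is the *distinct EF distribution*: strata that map to
    the same triangular parameters (e.g. every stratum under GL2006, or the
    dry-climate synthetic and manure strata under MR2019) share a single
    draw each iteration, while distinct distributions are drawn
    independently.  Within a stratum the draw is shared by every cell.  This
    correlation structure is what makes the aggregated CI equal N x the EF
    quantile for a scheme with one distribution, matching the published
    Tier 1 uncertainty ranges; fully independent draws would shrink them.
    Reproducible given the seed (columns ordered by sorted stratum key,
    distributions drawn in sorted parameter order).
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    by_dist: dict[tuple, list] = {}
    for s in sorted(scheme.strata):
        d = scheme.strata[s]
        by_dist.setdefault((d.lower, d.mode, d.upper), []).append(s)
    cols = {}
    from .triangular import TriangularEF

    for params in sorted(by_dist):
        draw = TriangularEF(*params, allow_negative=True).sample(n_draws, rng)
        for s in by_dist[params]:
            cols[s] = draw
    return pd.DataFrame(cols)


def cell_emission(cell, ef_by_stratum) -> dict[str, float]:
    """Component emissions (Gg N2O-N) of one cell for a fixed EF mapping."""
    climate = cell["climate"]
    out = {}
    for comp in COMPONENTS:
        key = (climate, comp)
        if key not in ef_by_stratum:
            raise MissingStratumError(
                f"no EF for climate={climate!r}, component={comp!r}"
            )
        out[comp] = float(cell[_COMPONENT_COL[comp]]) * float(ef_by_stratum[key])
    out["total"] = out["synthetic"] + out["manure"]
    return out


# ---------------------------------------------------------------------------
# the Monte Carlo inventory
# ---------------------------------------------------------------------------
def _stratum_totals(grid: pd.DataFrame, index_col: str) -> dict[str, pd.DataFrame]:
    """Per-component N totals by (index_col x climate)."""
    out = {}
    for comp, col in _COMPONENT_COL.items():
        out[comp] = grid.pivot_table(
            index=index_col, columns="climate", values=col,
            aggfunc="sum", fill_value=0.0,
        )
    return out


def run_inventory(grid: pd.DataFrame, scheme: EFScheme, n_draws: int = 100_000,
                  seed: int | None = None, include_cells: bool = True,
                  return_draws: bool = False):
    """Monte Carlo Tier 1 inventory at cell, country and global scopes.

    Point estimates use the mode EF of each stratum; CIs are the 2.5/97.5
    empirical quantiles of per-iteration aggregated emissions.  Country
    totals are summed from member cells each iteration and the global total
    from countries, so conservation holds draw by draw.

    Returns a DataFrame of :class:`EmissionEstimate` rows; with
    ``return_draws=True`` also returns ``{"stratum_draws", "country",
    "global"}`` per-iteration arrays for auditing.
    """
    if seed is None:
        raise ValueError("seed is mandatory for the Monte Carlo inventory")
    grid = validate_grid(grid)
    needed = {(c, comp) for c in grid["climate"].unique() for comp in COMPONENTS}
    for key in sorted(needed):
        scheme.ef_for(*key)  # raises MissingStratumError if absent

    draws = sample_ef(scheme, n_draws, seed)  # (n_draws, strata)
    modes = scheme.mode_map()

    country_n = _stratum_totals(grid, "country_code")
    countries = sorted(grid["country_code"].unique())

    # per-iteration country emissions per component: N (countries x climates)
    # times draws (n_draws x climates)^T
    comp_country_draws = {}
    comp_country_point = {}
    for comp in COMPONENTS:
        nmat = country_n[comp].reindex(index=countries).fillna(0.0)
        climates = list(nmat.columns)
        D = np.column_stack([draws[(cl, comp)].to_numpy() for cl in climates])
        comp_country_draws[comp] = nmat.to_numpy() @ D.T  # (countries, n_draws)
        comp_country_point[comp] = nmat.to_numpy() @ np.array(
            [modes[(cl, comp)] for cl in climates]
        )
    comp_country_draws["total"] = (
        comp_country_draws["synthetic"] + comp_country_draws["manure"]
    )
    comp_country_point["total"] = (
        comp_country_point["synthetic"] + comp_country_point["manure"]
    )

    rows: list[EmissionEstimate] = []

    def _append(scope, name, comp, point, vec):
        lo, hi = np.quantile(vec, [0.025, 0.975])
        rows.append(EmissionEstimate(scope, name, comp, float(point),
                                     float(lo), float(hi), n_draws, seed))

    components = list(COMPONENTS) + ["total"]
    glob = {}
    for comp in components:
        gvec = comp_country_draws[comp].sum(axis=0)
        glob[comp] = gvec
        _append("global", "global", comp, comp_country_point[comp].sum(), gvec)
    for i, ctry in enumerate(countries):
        for comp in components:
            _append("country", ctry, comp, comp_country_point[comp][i],
                    comp_country_draws[comp][i])

    if include_cells:
        cell_rows = _cell_estimates(grid, draws, modes, n_draws, seed)
        rows.extend(cell_rows)

    est = pd.DataFrame([r.__dict__ for r in rows])
    if return_draws:
        audit = {
            "stratum_draws": draws,
            "country": {c: comp_country_draws["total"][i]
                        for i, c in enumerate(countries)},
            "global": glob["total"],
        }
        return est, audit
    return est


def _cell_estimates(grid, draws, modes, n_draws, seed, chunk=64):
    """Cell-scope estimates, chunked to bound memory at ~chunk x n_draws."""
    rows = []
    q = [0.025, 0.975]
    for start in range(0, len(grid), chunk):
        block = grid.iloc[start:start + chunk]
        for comp in ("synthetic", "manure", "total"):
            if comp == "total":
                nsyn = block["n_synthetic_gg"].to_numpy()[:, None]
                nman = block["n_manure_gg"].to_numpy()[:, None]
                dsyn = np.column_stack(
                    [draws[(cl, "synthetic")].to_numpy() for cl in block["climate"]]
                ).T
                dman = np.column_stack(
                    [draws[(cl, "manure")].to_numpy() for cl in block["climate"]]
                ).T
                vec = nsyn * dsyn + nman * dman
                point = (
                    block["n_synthetic_gg"].to_numpy()
                    * np.array([modes[(cl, "synthetic")] for cl in block["climate"]])
                    + block["n_manure_gg"].to_numpy()
                    * np.array([modes[(cl, "manure")] for cl in block["climate"]])
                )
            else:
                nmass = block[_COMPONENT_COL[comp]].to_numpy()[:, None]
                d = np.column_stack(
                    [draws[(cl, comp)].to_numpy() for cl in block["climate"]]
                ).T
                vec = nmass * d
                point = block[_COMPONENT_COL[comp]].to_numpy() * np.array(
                    [modes[(cl, comp)] for cl in block["climate"]]
                )
            lo, hi = np.quantile(vec, q, axis=1)
            for cid, pt, l, h in zip(block["cell_id"], point, lo, hi):
                rows.append(EmissionEstimate("cell", str(cid), comp, float(pt),
                                             float(l), float(h), n_draws, seed))
    return rows


# ---------------------------------------------------------------------------
# scheme comparison
# ---------------------------------------------------------------------------
def _round_half_away(x):
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def compare_schemes(est_a, est_b):
    """Differences between two estimate sets (``a`` relative to ``b``).

    ``est_a``/``est_b`` are estimate frames from :func:`run_inventory` (or
    single :class:`EmissionEstimate` objects) with matching scope/name/
    component rows; ``b`` is the reference scheme.  Returns absolute
    difference (Gg N2O-N), full-precision percent difference and the
    nearest-integer percent used in summary tables; percent is undefined
    (NaN) where the reference point is 0.
    """
    if isinstance(est_a, EmissionEstimate):
        est_a = pd.DataFrame([est_a.__dict__])
    if isinstance(est_b, EmissionEstimate):
        est_b = pd.DataFrame([est_b.__dict__])
    on = ["scope", "name", "component"]
    merged = est_a.merge(est_b, on=on, suffixes=("_a", "_b"))
    if len(merged) != len(est_a) or len(merged) != len(est_b):
        raise ValueError("estimate sets do not cover matching scopes/components")
    out = merged[on].copy()
    out["point_a"] = merged["point_a"]
    out["point_b"] = merged["point_b"]
    out["abs_diff_gg"] = merged["point_a"] - merged["point_b"]
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * out["abs_diff_gg"] / merged["point_b"]
    pct = pct.where(merged["point_b"] != 0.0, np.nan)
    out["pct_diff"] = pct
    out["pct_diff_rounded"] = _round_half_away(pct)
    return out


def difference_map(grid: pd.DataFrame, scheme_a: EFScheme,
                   scheme_b: EFScheme) -> pd.DataFrame:
    """Per-cell mode-EF emission difference layers (``a`` minus ``b``).

    Returns one row per input cell (same order) with per-component emissions
    under both schemes, absolute differences (Gg N2O-N) and percent
    differences (NaN/masked where the reference emission is 0).
    """
    grid = validate_grid(grid)
    modes_a, modes_b = scheme_a.mode_map(), scheme_b.mode_map()
    needed = {(c, comp) for c in grid["climate"].unique() for comp in COMPONENTS}
    for key in sorted(needed):
        scheme_a.ef_for(*key)
        scheme_b.ef_for(*key)
    out = grid[["cell_id", "country_code", "climate"]].copy()
    totals = {"a": 0.0, "b": 0.0}
    for comp in COMPONENTS:
        n = grid[_COMPONENT_COL[comp]].to_numpy()
        ef_a = np.array([modes_a[(cl, comp)] for cl in grid["climate"]])
        ef_b = np.array([modes_b[(cl, comp)] for cl in grid["climate"]])
        out[f"emission_{comp}_a"] = n * ef_a
        out[f"emission_{comp}_b"] = n * ef_b
        totals["a"] = totals["a"] + n * ef_a
        totals["b"] = totals["b"] + n * ef_b
    out["emission_total_a"] = totals["a"]
    out["emission_total_b"] = totals["b"]
    for comp in list(COMPONENTS) + ["total"]:
        a = out[f"emission_{comp}_a"]
        b = out[f"emission_{comp}_b"]
        out[f"abs_diff_{comp}_gg"] = a - b
        with np.errstate(divide="ignore", invalid="ignore"):
            pct = 100.0 * (a - b) / b
        out[f"pct_diff_{comp}"] = pct.where(b != 0.0, np.nan)
    return out


def to_n2o_mass(estimates: pd.DataFrame) -> pd.DataFrame:
    """Convert Gg N2O-N columns to Gg N2O (x 44/28). Opt-in, never default."""
    out = estimates.copy()
    for col in ("point", "ci_low", "ci_high"):
        if col in out.columns:
            out[col] = out[col] * N2O_N_TO_N2O
    return out
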