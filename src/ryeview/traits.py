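"""Image-derived growth traits and their link to manual measurements.

The detections feed three traits per plant:

* **base area** (W0) — projected area in cm² directly after a cut;
* **regrowth** — outgrowth area (W1, one week later) minus base area,
  optionally normalized per growing degree day;
* **first-year lateral expansion** — the OLS slope of base area against
  cumulative thermal time over the first season's cuts, requiring at
  least three valid observations.

Thermal time accumulates the daily mean of min/max temperature above a base
temperature (0 °C by default), clipped at zero.  Genotype values are means
over the (up to three) clonal replicates, and trait-trait association is
Pearson correlation on those genotype means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PlantObservation",
    "TemperatureDay",
    "GrowthSummary",
    "RegrowthResult",
    "pixels_to_area",
    "thermal_time",
    "regrowth",
    "lateral_expansion",
    "leaf_growth",
    "genotype_means",
    "pearson_correlation",
    "trait_tables",
]


@dataclass(frozen=True)
class PlantObservation:
    """One plant area record: genotype x replicate x time point x week."""

    genotype_id: str
    replicate: int
    timepoint: str          # e.g. "Y1C2"
    week: str               # "W0" (directly after cutting) or "W1" (1 week later)
    area_cm2: float
    valid: bool = True

    def __post_init__(self) -> None:
        if self.week not in ("W0", "W1"):
            raise ValueError("week must be 'W0' or 'W1'")
        if self.valid and self.area_cm2 < 0:
            raise ValueError("area_cm2 must be non-negative")


@dataclass(frozen=True)
class TemperatureDay:
    date: object
    tmin: float
    tmax: float

    def __post_init__(self) -> None:
        if self.tmin > self.tmax:
            raise ValueError("tmin must not exceed tmax")


@dataclass(frozen=True)
class GrowthSummary:
    genotype_id: str
    lateral_expansion: float | None   # cm^2 per degree-day; None if < 3 valid obs
    intercept: float | None
    n_obs: int


@dataclass(frozen=True)
class RegrowthResult:
    regrowth_cm2: float | None
    regrowth_rate: float | None       # cm^2 per degree-day, None without a GDD window
    valid: bool


def pixels_to_area(count: int, scale: float) -> float:
    """Convert a pixel count to cm² given the scale in pixels per cm."""
    if scale <= 0:
        raise ValueError("scale must be positive (pixels per cm)")
    return count / scale**2


def thermal_time(days: Iterable[TemperatureDay], t_base: float = 0.0) -> float:
    """Accumulated growing degree days: sum of max(0, (tmin+tmax)/2 - t_base)."""
    total = 0.0
    n = 0
    for d in days:
        total += max(0.0, (d.tmin + d.tmax) / 2.0 - t_base)
        n += 1
    if n == 0:
        raise ValueError("thermal_time requires at least one day")
    return total


def regrowth(
    w0: PlantObservation,
    w1: PlantObservation,
    gdd_week: float | None = None,
) -> RegrowthResult:
    """Outgrowth area minus base area for the same cut.

    Negative regrowth is retained (cut damage and segmentation noise are
    real) but reported as-is for the caller to flag.  Either observation
    being invalid makes the result invalid.
    """
    if (w0.genotype_id, w0.replicate, w0.timepoint) != (
        w1.genotype_id,
        w1.replicate,
        w1.timepoint,
    ):
        raise ValueError("regrowth requires matching genotype, replicate, timepoint")
    if w0.week != "W0" or w1.week != "W1":
        raise ValueError("regrowth requires a W0 and a W1 observation")
    if not (w0.valid and w1.valid):
        return RegrowthResult(None, None, valid=False)
    diff = w1.area_cm2 - w0.area_cm2
    rate = diff / gdd_week if gdd_week is not None else None
    return RegrowthResult(diff, rate, valid=True)


def lateral_expansion(
    obs: Sequence[PlantObservation],
    gdd_at_obs: Sequence[float],
) -> GrowthSummary:
    """OLS slope of base area (W0) versus cumulative thermal time.

    Only valid observations enter the fit; fewer than three valid points
    yield a summary without an estimate rather than an error.
    """
    if len(obs) != len(gdd_at_obs):
        raise ValueError("obs and gdd_at_obs must align")
    if any(o.week != "W0" for o in obs):
        raise ValueError("lateral expansion uses base-area (W0) observations only")
    gdd = np.asarray(gdd_at_obs, dtype=np.float64)
    if np.any(np.diff(gdd) <= 0):
        raise ValueError("thermal-time axis must be strictly increasing")
    keep = np.array([o.valid for o in obs], dtype=bool)
    genotype = obs[0].genotype_id if obs else ""
    n_valid = int(keep.sum())
    if n_valid < 3:
        return GrowthSummary(genotype, None, None, n_valid)
    y = np.array([o.area_cm2 for o in obs], dtype=np.float64)[keep]
    x = gdd[keep]
    slope, intercept = np.polyfit(x, y, 1)
    return GrowthSummary(genotype, float(slope), float(intercept), n_valid)


def leaf_growth(height_cm: float, gdd_two_weeks: float) -> float:
    """Leaf growth per growing degree day from the 2-week plant height."""
    if gdd_two_weeks <= 0:
        raise ValueError("gdd_two_weeks must be positive")
    return height_cm / gdd_two_weeks


def genotype_means(
    records: pd.DataFrame,
    value_cols: Sequence[str],
    genotype_col: str = "genotype_id",
    valid_col: str | None = "valid",
) -> pd.DataFrame:
    """Per-genotype means over the clonal replicates.

    Invalid rows (``valid_col`` false) are dropped before averaging, so a
    missing replicate leaves the mean of the available ones.  Genotypes with
    zero valid rows disappear from the output.
    """
    df = records
    if valid_col is not None and valid_col in df.columns:
        df = df[df[valid_col].astype(bool)]
    out = df.groupby(genotype_col, sort=True)[list(value_cols)].mean().reset_index()
    return out


def _cumulative_gdd(temperatures: pd.DataFrame, t_base: float) -> pd.Series:
    """Daily GDD series indexed by date (clipped mean of tmin/tmax)."""
    t = temperatures.copy()
    t["date"] = pd.to_datetime(t["date"])
    t = t.sort_values("date").set_index("date")
    return ((t["tmin"] + t["tmax"]) / 2.0 - t_base).clip(lower=0.0)


def trait_tables(
    detections: pd.DataFrame,
    temperatures: pd.DataFrame,
    cut_dates: pd.DataFrame,
    t_base: float = 0.0,
    regrowth_days: int = 7,
    manual: pd.DataFrame | None = None,
    height_window_days: int = 14,
) -> dict[str, pd.DataFrame]:
    """Derive the growth-trait tables from a per-image detection table.

    Parameters
    ----------
    detections
        Per-image rows with ``genotype_id, replicate, timepoint, week,
        area_cm2, valid`` (the batch driver's output).
    temperatures
        Daily records with ``date, tmin, tmax``.
    cut_dates
        Mapping ``timepoint -> date`` of each cut.
    manual
        Optional manual measurements ``genotype_id, replicate, timepoint,
        tiller_number, height_cm`` (height taken ``height_window_days``
        after the cut); enables the trait-trait correlation table.

    Returns
    -------
    dict of DataFrames: ``observations`` (per-plant W0/W1 areas with the
    thermal-time axis), ``regrowth`` (per plant and cut, cm² and per
    degree-day), ``lateral_expansion`` (per-plant OLS slope), ``genotype``
    (genotype means over replicates) and, with manual data,
    ``correlations`` (Pearson r and p on genotype means).
    """
    daily = _cumulative_gdd(temperatures, t_base)
    cuts = cut_dates.copy()
    cuts["date"] = pd.to_datetime(cuts["date"])
    cuts = cuts.sort_values("date").reset_index(drop=True)
    t0 = cuts["date"].iloc[0]

    def window_gdd(start, days):
        sel = daily.loc[(daily.index >= start) & (daily.index < start + pd.Timedelta(days=days))]
        return float(sel.sum())

    gdd_at_cut = {
        row["timepoint"]: float(daily.loc[(daily.index >= t0) & (daily.index <= row["date"])].sum())
        for _, row in cuts.iterrows()
    }
    gdd_week = {
        row["timepoint"]: window_gdd(row["date"], regrowth_days) for _, row in cuts.iterrows()
    }

    obs = detections.copy()
    obs = obs[obs["timepoint"].isin(gdd_at_cut)]
    obs["gdd_at_cut"] = obs["timepoint"].map(gdd_at_cut)
    obs["valid"] = obs["valid"].astype(bool)

    wide = obs.pivot_table(
        index=["genotype_id", "replicate", "timepoint", "gdd_at_cut"],
        columns="week",
        values=["area_cm2", "valid"],
        aggfunc="first",
    )
    regrow_rows = []
    for key, row in wide.iterrows():
        genotype, rep, tp, gdd = key
        a0 = row.get(("area_cm2", "W0"), np.nan)
        a1 = row.get(("area_cm2", "W1"), np.nan)
        v0 = bool(row.get(("valid", "W0"), False))
        v1 = bool(row.get(("valid", "W1"), False))
        ok = v0 and v1 and np.isfinite(a0) and np.isfinite(a1)
        diff = a1 - a0 if ok else np.nan
        gw = gdd_week[tp]
        regrow_rows.append(
            {
                "genotype_id": genotype,
                "replicate": rep,
                "timepoint": tp,
                "regrowth_cm2": diff,
                "gdd_week": gw,
                "regrowth_rate": diff / gw if ok and gw > 0 else np.nan,
                "valid": ok,
                "negative": bool(ok and diff < 0),
            }
        )
    regrow = pd.DataFrame(regrow_rows)

    expansion_rows = []
    w0 = obs[obs["week"] == "W0"].sort_values("gdd_at_cut")
    for (genotype, rep), g in w0.groupby(["genotype_id", "replicate"]):
        gg = g[g["valid"]]
        n = len(gg)
        slope = np.nan
        if n >= 3:
            slope = float(np.polyfit(gg["gdd_at_cut"], gg["area_cm2"], 1)[0])
        expansion_rows.append(
            {
                "genotype_id": genotype,
                "replicate": rep,
                "lateral_expansion": slope,
                "n_obs": n,
                "valid": n >= 3,
            }
        )
    expansion = pd.DataFrame(expansion_rows)

    per_plant = (
        w0[w0["valid"]]
        .groupby(["genotype_id", "replicate"])["area_cm2"]
        .mean()
        .rename("base_area_cm2")
        .reset_index()
        .assign(valid=True)
    )
    per_plant = per_plant.merge(
        regrow[regrow["valid"]]
        .groupby(["genotype_id", "replicate"])["regrowth_rate"]
        .mean()
        .reset_index(),
        how="left",
    )
    per_plant = per_plant.merge(
        expansion[expansion["valid"]][["genotype_id", "replicate", "lateral_expansion"]],
        how="left",
    )
    genotype = genotype_means(
        per_plant, ["base_area_cm2", "regrowth_rate", "lateral_expansion"]
    )

    tables = {
        "observations": obs,
        "regrowth": regrow,
        "lateral_expansion": expansion,
        "genotype": genotype,
    }

    if manual is not None:
        man = manual.copy()
        man["gdd_two_weeks"] = man["timepoint"].map(
            {tp: window_gdd(d, height_window_days) for tp, d in zip(cuts["timepoint"], cuts["date"])}
        )
        man["leaf_growth"] = man["height_cm"] / man["gdd_two_weeks"]
        man_plant = (
            man.groupby(["genotype_id", "replicate"])[["tiller_number", "leaf_growth"]]
            .mean()
            .reset_index()
            .assign(valid=True)
        )
        man_geno = genotype_means(man_plant, ["tiller_number", "leaf_growth"])
        merged = genotype.merge(man_geno, on="genotype_id", how="inner")
        corr_rows = []
        for x, y in (
            ("leaf_growth", "regrowth_rate"),
            ("tiller_number", "base_area_cm2"),
        ):
            try:
                r, p = pearson_correlation(merged[x], merged[y])
            except ValueError:
                r, p = np.nan, np.nan
            corr_rows.append({"x": x, "y": y, "r": r, "p": p, "n": len(merged)})
        tables["correlations"] = pd.DataFrame(corr_rows)
        tables["manual_genotype"] = man_geno
    return tables


def pearson_correlation(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Pearson r with a two-sided p-value, pairwise-complete over NaNs."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("x and y must align")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least three complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in a variable")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
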