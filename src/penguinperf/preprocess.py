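"""Raw monitoring parameters -> standardized indices and categorized predictors.

The modelling scale for penguin performance is a z-score per
(parameter, species, site) group, oriented so that larger is always better:
clutch-initiation dates become days prior to 31 December, foraging-trip
durations become hours short of 60 h, and proportion-type parameters
(relative cohort strength, post-hatch breeding success) are logit-transformed
before standardization.

Predictors are categorized with fixed thresholds: ONI at +/-0.5 degC (three
bins), SAM by sign, LKB at 1 Mt, LHR at 0.01 and 0.1.  The 3 x 2 x 3
category combinations map bijectively onto bins 1..18.
"""

from __future__ import annotations

import datetime as dt
import math
from collections.abc import Iterable

import numpy as np
import pandas as pd

# -- categorical thresholds -------------------------------------------------

ONI_THRESHOLD_C = 0.5          #: |ONI| defining La Nina / El Nino events (degC)
LKB_THRESHOLD_T = 1.0e6        #: biomass split, 1 Mt
LHR_THRESHOLDS = (0.01, 0.1)   #: harvest-rate splits (low / mid / high)

ONI_LEVELS = ("low", "mid", "high")
LKB_LEVELS = ("low", "high")
LHR_LEVELS = ("low", "mid", "high")
SAM_LEVELS = ("neg", "pos")

#: (site, species) -> stratum whose LKB/LHR the colony experiences,
#: from multi-year tracking of foraging locations.  Cape Shirreff gentoos
#: forage in the Bransfield Strait; chinstraps there use the Drake Passage.
DEFAULT_SITE_STRATUM_MAP: dict[tuple[str, str], str] = {
    ("Copacabana", "Adelie"): "Bransfield",
    ("Copacabana", "gentoo"): "Bransfield",
    ("Cape Shirreff", "chinstrap"): "Drake",
    ("Cape Shirreff", "gentoo"): "Bransfield",
}

#: Hoyt's empirical egg-volume coefficient: V (cm^3) = c * L * W^2 with L, W in mm
EGG_VOLUME_COEF = 0.000507


# -- per-parameter transforms ----------------------------------------------

def transform_clutch_date(date: dt.date) -> float:
    """Days prior to 31 December of the split year (earlier = better).

    ``date`` must fall in the October-January breeding window; January dates
    count against 31 December of the *previous* calendar year and therefore
    come out negative.
    """
    if date.month in (10, 11, 12):
        ref = dt.date(date.year, 12, 31)
    elif date.month == 1:
        ref = dt.date(date.year - 1, 12, 31)
    else:
        raise ValueError(f"clutch-initiation date {date} outside the Oct-Jan breeding window")
    return float((ref - date).days)


def clutch_date_from_season_day(season_day: float, year: int) -> dt.date:
    """Map a 1-based day-of-breeding-season (day 1 = 1 Oct of year-1) to a date."""
    return dt.date(year - 1, 10, 1) + dt.timedelta(days=round(season_day) - 1)


def transform_trip_duration(hours: float) -> float:
    """Hours short of 60 h (shorter trips = better); negative values allowed."""
    if hours <= 0:
        raise ValueError(f"trip duration must be positive, got {hours}")
    return 60.0 - hours


def logit_transform(proportion: float, n: int | None = None, eps: float = 1e-3) -> float:
    """Logit of a proportion with boundary handling.

    With a known trial count ``n`` the empirical-logit adjustment
    ``q = (x + 0.5) / (n + 1)`` (x = successes) is used; otherwise the
    proportion is clamped to ``[eps, 1 - eps]``.
    """
    if not 0.0 <= proportion <= 1.0:
        raise ValueError(f"proportion {proportion} outside [0, 1]")
    if n is not None:
        q = (proportion * n + 0.5) / (n + 1)
    else:
        q = min(max(proportion, eps), 1.0 - eps)
    return math.log(q / (1.0 - q))


def egg_density(
    eggs: Iterable[tuple[float, float, float]],
    volume_coef: float = EGG_VOLUME_COEF,
) -> float:
    """Mean egg density (g/cm^3) of a 2-egg clutch.

    Each egg is (mass g, max length mm, max width mm); volume comes from the
    empirical relationship V = c * L * W^2.
    """
    eggs = list(eggs)
    if len(eggs) != 2:
        raise ValueError(f"egg density is defined for 2-egg clutches, got {len(eggs)} eggs")
    if any(m <= 0 or length <= 0 or w <= 0 for m, length, w in eggs):
        raise ValueError("egg measurements must all be positive")
    total_mass = sum(m for m, _, _ in eggs)
    total_volume = sum(volume_coef * length * w**2 for _, length, w in eggs)
    return total_mass / total_volume


#: parameter-name -> orientation/scale transform applied before standardization
TRANSFORM_REGISTRY = {
    "clutch_initiation_day": "clutch_day",   # day of season -> days prior to 31 Dec
    "trip_duration_h": "trip",
    "cohort_strength": "logit",
    "breeding_success": "logit",
}


def apply_parameter_transform(df: pd.DataFrame, eps: float = 1e-3) -> pd.DataFrame:
    """Apply the per-parameter orientation transforms to a performance table."""
    out = df.copy()
    for param, kind in TRANSFORM_REGISTRY.items():
        mask = out["parameter"] == param
        if not mask.any():
            continue
        vals = out.loc[mask, "value"]
        if kind == "clutch_day":
            years = out.loc[mask, "year"]
            dates = [clutch_date_from_season_day(v, y) for v, y in zip(vals, years)]
            out.loc[mask, "value"] = [transform_clutch_date(d) for d in dates]
        elif kind == "trip":
            out.loc[mask, "value"] = 60.0 - vals
        elif kind == "logit":
            q = vals.clip(eps, 1.0 - eps)
            out.loc[mask, "value"] = np.log(q / (1.0 - q))
    return out


# -- standardization --------------------------------------------------------

def standardize(values) -> np.ndarray:
    """z-scores with the sample (n-1) standard deviation, order preserved."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2 or np.unique(arr).size < 2:
        raise ValueError("standardization needs >= 2 distinct values")
    sd = arr.std(ddof=1)
    return (arr - arr.mean()) / sd


def standardize_performance(df: pd.DataFrame) -> pd.DataFrame:
    """Standardize each (parameter, species, site) group to mean 0, variance 1."""
    out = df.copy()
    for key, idx in out.groupby(["parameter", "species", "site"]).groups.items():
        vals = out.loc[idx, "value"]
        try:
            out.loc[idx, "value"] = standardize(vals)
        except ValueError as e:
            raise ValueError(f"group {key}: {e}") from None
    return out


# -- climate ---------------------------------------------------------------

def seasonal_climate(climate: pd.DataFrame, index: str, season: str, year: int) -> float:
    """Seasonal mean of a monthly climate index.

    Summer of split year Y averages Oct (Y-1) through Mar (Y); winter of Y
    averages Apr-Sep of calendar year Y.  All six months must be present.
    """
    if season == "summer":
        months = [(year - 1, m) for m in (10, 11, 12)] + [(year, m) for m in (1, 2, 3)]
    elif season == "winter":
        months = [(year, m) for m in (4, 5, 6, 7, 8, 9)]
    else:
        raise ValueError(f"unknown season {season!r}")
    sub = climate[climate["index"] == index].set_index(["year", "month"])["value"]
    vals, missing = [], []
    for ym in months:
        if ym in sub.index:
            vals.append(float(sub.loc[ym]))
        else:
            missing.append(ym)
    if missing:
        raise ValueError(f"{index} {season} {year}: missing months {missing}")
    return float(np.mean(vals))


# -- categorization ---------------------------------------------------------

def categorize_oni(oni: float, threshold: float = ONI_THRESHOLD_C) -> str:
    """La Nina (low, <= -0.5 degC), neutral (mid), El Nino (high, >= 0.5 degC)."""
    if not math.isfinite(oni):
        raise ValueError("ONI must be finite")
    if oni <= -threshold:
        return "low"
    if oni >= threshold:
        return "high"
    return "mid"


def sam_sign(sam: float) -> str:
    """Sign of the SAM; exactly 0 counts as the positive phase."""
    if not math.isfinite(sam):
        raise ValueError("SAM must be finite")
    return "neg" if sam < 0 else "pos"


def compute_lhr(catch_t: float, lkb_t: float) -> float:
    """Local harvest rate: stratum catch over stratum krill biomass."""
    if lkb_t <= 0:
        raise ValueError(f"LKB must be positive, got {lkb_t}")
    if catch_t < 0:
        raise ValueError(f"catch must be >= 0, got {catch_t}")
    return catch_t / lkb_t


def categorize_lkb(lkb_t: float, threshold: float = LKB_THRESHOLD_T) -> str:
    """low iff LKB <= 1 Mt, else high."""
    if lkb_t <= 0:
        raise ValueError(f"LKB must be positive, got {lkb_t}")
    return "low" if lkb_t <= threshold else "high"


def categorize_lhr(lhr: float, thresholds: tuple[float, float] = LHR_THRESHOLDS) -> str:
    """low iff LHR <= 0.01; high iff LHR >= 0.1; mid between."""
    if lhr < 0:
        raise ValueError(f"LHR must be >= 0, got {lhr}")
    lo, hi = thresholds
    if lhr <= lo:
        return "low"
    if lhr >= hi:
        return "high"
    return "mid"


def bin_label(oni_cat: str, lkb_cat: str, lhr_cat: str) -> int:
    """Bijection from the 3 x 2 x 3 category triple onto bins 1..18."""
    try:
        o = ONI_LEVELS.index(oni_cat)
        b = LKB_LEVELS.index(lkb_cat)
        h = LHR_LEVELS.index(lhr_cat)
    except ValueError:
        raise ValueError(f"invalid category triple ({oni_cat!r}, {lkb_cat!r}, {lhr_cat!r})") from None
    return o * 6 + b * 3 + h + 1


def bin_to_categories(bin_id: int) -> tuple[str, str, str]:
    """Inverse of :func:`bin_label`."""
    if not 1 <= bin_id <= 18:
        raise ValueError(f"bin {bin_id} outside 1..18")
    k = bin_id - 1
    return ONI_LEVELS[k // 6], LKB_LEVELS[(k % 6) // 3], LHR_LEVELS[k % 3]


# -- predictor assembly ------------------------------------------------------

def build_predictors(
    climate: pd.DataFrame,
    survey: pd.DataFrame,
    catch: pd.DataFrame,
    years: tuple[int, int],
    strata: tuple[str, ...] = ("Bransfield", "Drake"),
) -> pd.DataFrame:
    """Assemble one PredictorRecord per stratum x season x year.

    Duplicate surveys within a season are averaged on the tonne scale.
    LKB, LHR and the bin label are left missing (NaN) where no survey exists;
    the imputation model fills summer gaps later.  Seasons with no reported
    catch get catch 0 (no fishing).
    """
    lkb = (
        survey.groupby(["stratum", "season", "year"])["biomass_t"]
        .mean()
        .to_dict()
    )
    catches = catch.groupby(["stratum", "season", "year"])["catch_t"].sum().to_dict()
    rows = []
    for year in range(years[0], years[1] + 1):
        for season in ("summer", "winter"):
            oni = seasonal_climate(climate, "ONI", season, year)
            sam = seasonal_climate(climate, "SAM", season, year)
            for stratum in strata:
                lkb_t = lkb.get((stratum, season, year), np.nan)
                catch_t = catches.get((stratum, season, year), 0.0)
                if np.isfinite(lkb_t):
                    lhr = compute_lhr(catch_t, lkb_t)
                    lkb_cat = categorize_lkb(lkb_t)
                    lhr_cat = categorize_lhr(lhr)
                    b = bin_label(categorize_oni(oni), lkb_cat, lhr_cat)
                else:
                    lhr, lkb_cat, lhr_cat, b = np.nan, None, None, np.nan
                rows.append(
                    dict(
                        stratum=stratum,
                        season=season,
                        year=year,
                        oni=oni,
                        oni_cat=categorize_oni(oni),
                        sam=sam,
                        sam_sign=sam_sign(sam),
                        lkb_t=lkb_t,
                        catch_t=catch_t,
                        lhr=lhr,
                        lkb_cat=lkb_cat,
                        lhr_cat=lhr_cat,
                        bin=b,
                    )
                )
    return pd.DataFrame(rows)


def match_and_pool(
    observations: pd.DataFrame,
    predictors: pd.DataFrame,
    site_stratum_map: dict[tuple[str, str], str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join standardized observations to their stratum's predictor record.

    Returns ``(analysis_table, exclusions)``.  Observations whose
    season-year has observed LKB get their bin attached; summer
    observations without LKB are kept (flagged ``imputable``) because the
    biomass model can impute them; winter observations without LKB cannot
    be imputed and land in the exclusion report.
    """
    smap = DEFAULT_SITE_STRATUM_MAP if site_stratum_map is None else site_stratum_map
    pred = predictors.set_index(["stratum", "season", "year"])
    rows, excluded = [], []
    for rec in observations.to_dict("records"):
        key = (rec["site"], rec["species"])
        if key not in smap:
            raise KeyError(f"no stratum mapping for site/species {key}")
        stratum = smap[key]
        pkey = (stratum, rec["season"], rec["year"])
        if pkey not in pred.index:
            excluded.append({**rec, "stratum": stratum, "reason": "no predictor record"})
            continue
        p = pred.loc[pkey]
        row = {
            **rec,
            "stratum": stratum,
            "oni_cat": p["oni_cat"],
            "sam_sign": p["sam_sign"],
            "lkb_t": p["lkb_t"],
            "catch_t": p["catch_t"],
            "lhr": p["lhr"],
            "lkb_cat": p["lkb_cat"],
            "lhr_cat": p["lhr_cat"],
            "bin": p["bin"],
        }
        if not np.isfinite(p["lkb_t"]):
            if rec["season"] == "summer":
                row["imputable"] = True
                rows.append(row)
            else:
                excluded.append({**rec, "stratum": stratum, "reason": "winter without LKB (not imputable)"})
            continue
        row["imputable"] = False
        rows.append(row)
    analysis = pd.DataFrame(rows)
    exclusions = pd.DataFrame(excluded)
    return analysis, exclusions
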