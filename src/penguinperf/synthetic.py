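"""Synthetic studies with the statistical structure the analysis assumes.

The generator emulates the real monitoring design: two strata (Bransfield
Strait, Drake Passage) over split-years 1982-2016; acoustic surveys only in
summers 1996-2011 and winters 2012/2014/2015; log-normal biomass varying by
stratum x SAM sign across roughly three orders of magnitude (1e4-1e7 t);
krill catches of at most ~1e5 t treated as known, with a low-catch era
(~34,000 t/yr before 2010) and a high, winter-concentrated era
(~121,000 t/yr from 2010); and 20 performance indices (parameter x species
x site) whose standardized values follow the sum-to-zero ANOVA.

Every latent quantity (true biomass, true bin, generating parameters) is
recorded so that parameter recovery can be verified end to end.  Raw-scale
emission exercises the preprocess transforms: clutch dates are emitted as
day-of-season, trip durations as hours, proportion-type indices as
proportions in (0, 1).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from penguinperf.anova import AnovaParams, encode_design, expected_performance
from penguinperf.imputation import LOWER_FLOOR_T, UPPER_TRUNCATION_T, sample_truncated_lognormal
from penguinperf.preprocess import (
    DEFAULT_SITE_STRATUM_MAP,
    bin_label,
    categorize_lhr,
    categorize_lkb,
    categorize_oni,
    sam_sign,
    seasonal_climate,
)

#: (parameter, season, back-transform loc, scale) — raw = f(loc + scale * z)
INDEX_PARAMS = [
    ("clutch_initiation_day", "winter", 45.0, 6.0),     # day of season, 1 = 1 Oct
    ("cohort_strength", "winter", -2.0, 0.7),            # logit scale -> proportion
    ("trip_duration_h", "summer", 10.0, 8.0),            # hours short of 60
    ("fledgling_mass", "summer", 3200.0, 250.0),         # g, identity
    ("breeding_success", "summer", 0.0, 0.8),            # logit scale -> proportion
]

_COLONIES = [("Copacabana", "Adelie"), ("Copacabana", "gentoo"),
             ("Cape Shirreff", "chinstrap"), ("Cape Shirreff", "gentoo")]


@dataclass(frozen=True)
class GeneratorConfig:
    """Ground-truth configuration of one synthetic study."""

    seed: int = 0
    years: tuple[int, int] = (1982, 2016)
    true_params: AnovaParams = field(
        default_factory=lambda: AnovaParams(
            alpha=0.0,
            # mid-ONI and high-LHR depress performance most; high LKB barely
            beta=(-0.35, -0.20, -0.05, -0.10, -0.40),
            sigma=0.9,
            omega=1.0,
        )
    )
    #: expected ln biomass (t) per (stratum, SAM sign)
    K: dict = field(
        default_factory=lambda: {
            ("Bransfield", "neg"): 14.5,
            ("Bransfield", "pos"): 13.5,
            ("Drake", "neg"): 14.2,
            ("Drake", "pos"): 13.2,
        }
    )
    phi: float = 1.2
    #: maximum fraction of the local standing stock the fishery removes in a
    #: season: tiny while catches were circumpolar and low, much larger once
    #: effort concentrated in winter hotspots
    catch_cap_low_era: float = 0.008
    catch_cap_high_summer: float = 0.05
    catch_cap_high_winter: float = 0.35
    #: mean annual catch (t) in the two eras, and the 2010 era break
    catch_low_era_t: float = 3.4e4
    catch_high_era_t: float = 1.21e5
    era_break_year: int = 2010
    #: season/stratum allocation of the annual catch per era
    catch_split_low: dict = field(
        default_factory=lambda: {("Bransfield", "summer"): 0.35, ("Drake", "summer"): 0.35,
                                 ("Bransfield", "winter"): 0.20, ("Drake", "winter"): 0.10}
    )
    catch_split_high: dict = field(
        default_factory=lambda: {("Bransfield", "summer"): 0.18, ("Drake", "summer"): 0.17,
                                 ("Bransfield", "winter"): 0.40, ("Drake", "winter"): 0.25}
    )
    summer_survey_years: tuple[int, int] = (1996, 2011)
    winter_survey_years: tuple[int, ...] = (2012, 2014, 2015)
    #: monthly climate model: AR(1) coefficient and innovation SDs
    oni_ar: float = 0.85
    oni_sd: float = 0.45
    sam_sd: float = 1.2


@dataclass
class SyntheticStudy:
    """The four input tables plus the generating truth."""

    config: GeneratorConfig
    performance: pd.DataFrame
    survey: pd.DataFrame
    catch: pd.DataFrame
    climate: pd.DataFrame
    truth: dict


def generate_climate(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Monthly ONI and SAM series covering every season of the study range.

    Re-draws (up to 100 times, reseeding from the generator stream) until
    the seasonal means cover all three ONI categories and both SAM signs.
    """
    y0, y1 = config.years
    months = [(y, m) for y in range(y0 - 1, y1 + 1) for m in range(1, 13)]
    for _ in range(100):
        n = len(months)
        oni = np.empty(n)
        oni[0] = rng.normal(0.0, config.oni_sd / math.sqrt(1 - config.oni_ar**2))
        for t in range(1, n):
            oni[t] = config.oni_ar * oni[t - 1] + rng.normal(0.0, config.oni_sd)
        sam = rng.normal(0.0, config.sam_sd, size=n)
        climate = pd.DataFrame(
            [
                {"index": "ONI", "year": y, "month": m, "value": oni[t]}
                for t, (y, m) in enumerate(months)
            ]
            + [
                {"index": "SAM", "year": y, "month": m, "value": sam[t]}
                for t, (y, m) in enumerate(months)
            ]
        )
        oni_cats, sam_signs = set(), set()
        for year in range(y0, y1 + 1):
            for season in ("summer", "winter"):
                oni_cats.add(categorize_oni(seasonal_climate(climate, "ONI", season, year)))
                sam_signs.add(sam_sign(seasonal_climate(climate, "SAM", season, year)))
        if oni_cats == {"low", "mid", "high"} and sam_signs == {"neg", "pos"}:
            return climate
    raise RuntimeError("could not achieve ONI-bin and SAM-sign coverage in 100 attempts")


def generate_biomass_catch(
    config: GeneratorConfig, climate: pd.DataFrame, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Latent biomass and catches for every stratum-season-year.

    The latent biomass is drawn from the stratum x SAM-sign log-normal;
    the catch is an era-dependent allocation with modest log-normal noise,
    capped at a fraction of the local standing stock (the fishery cannot
    remove krill it does not find), so the catch never exceeds the biomass
    and harvest rates above 0.1 arise only once winter effort concentrates.
    Survey rows are emitted only for the designated years.

    Returns (survey, catch, latent) tables; ``latent`` carries every true
    biomass, harvest rate, and bin.
    """
    y0, y1 = config.years
    survey_rows, catch_rows, latent_rows = [], [], []
    for year in range(y0, y1 + 1):
        low_era = year < config.era_break_year
        annual = config.catch_low_era_t if low_era else config.catch_high_era_t
        split = config.catch_split_low if low_era else config.catch_split_high
        for season in ("summer", "winter"):
            oni = seasonal_climate(climate, "ONI", season, year)
            sam = seasonal_climate(climate, "SAM", season, year)
            sign = sam_sign(sam)
            if low_era:
                cap = config.catch_cap_low_era
            else:
                cap = config.catch_cap_high_summer if season == "summer" else config.catch_cap_high_winter
            for stratum in ("Bransfield", "Drake"):
                biomass = float(
                    sample_truncated_lognormal(
                        rng,
                        config.K[(stratum, sign)],
                        config.phi,
                        LOWER_FLOOR_T,
                        UPPER_TRUNCATION_T,
                    )
                )
                catch_t = min(
                    annual * split[(stratum, season)] * rng.lognormal(0.0, 0.3),
                    cap * biomass,
                )
                lhr = catch_t / biomass
                surveyed = (
                    season == "summer"
                    and config.summer_survey_years[0] <= year <= config.summer_survey_years[1]
                ) or (season == "winter" and year in config.winter_survey_years)
                if surveyed:
                    survey_rows.append(
                        dict(stratum=stratum, season=season, year=year, biomass_t=biomass)
                    )
                catch_rows.append(dict(stratum=stratum, season=season, year=year, catch_t=catch_t))
                latent_rows.append(
                    dict(
                        stratum=stratum,
                        season=season,
                        year=year,
                        sam_sign=sign,
                        oni_cat=categorize_oni(oni),
                        biomass_t=biomass,
                        catch_t=catch_t,
                        lhr=lhr,
                        surveyed=surveyed,
                        bin=bin_label(categorize_oni(oni), categorize_lkb(biomass), categorize_lhr(lhr)),
                    )
                )
    return pd.DataFrame(survey_rows), pd.DataFrame(catch_rows), pd.DataFrame(latent_rows)


def generate_performance(
    config: GeneratorConfig, latent: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Raw-scale performance table from the true bins.

    Each of the 20 parameter x species x site indices gets one value per
    study year, drawn as z ~ N(P_true, sigma_true^2) with P_true from the
    true design vector of the matched stratum-season-year, then mapped to
    its native scale (day of season, hours, proportion, or grams).
    """
    lat = latent.set_index(["stratum", "season", "year"])
    rows = []
    for site, species in _COLONIES:
        stratum = DEFAULT_SITE_STRATUM_MAP[(site, species)]
        for param, season, loc, scale in INDEX_PARAMS:
            for year in range(config.years[0], config.years[1] + 1):
                rec = lat.loc[(stratum, season, year)]
                design = encode_design(
                    rec["oni_cat"],
                    categorize_lkb(rec["biomass_t"]),
                    categorize_lhr(rec["lhr"]),
                )
                z = rng.normal(
                    expected_performance(config.true_params, design), config.true_params.sigma
                )
                raw = loc + scale * z
                if param in ("cohort_strength", "breeding_success"):
                    raw = 1.0 / (1.0 + math.exp(-raw))   # inverse logit
                elif param == "trip_duration_h":
                    raw = 60.0 - raw                     # better = shorter trip
                elif param == "clutch_initiation_day":
                    raw = loc - scale * z                # better = earlier date
                rows.append(
                    dict(site=site, species=species, parameter=param, season=season,
                         year=year, value=float(raw), z=float(z))
                )
    df = pd.DataFrame(rows)
    return df


def generate_study(config: GeneratorConfig) -> SyntheticStudy:
    """Generate a complete synthetic study; bit-identical for equal configs."""
    rng = np.random.default_rng(config.seed)
    climate = generate_climate(config, rng)
    survey, catch, latent = generate_biomass_catch(config, climate, rng)
    perf_full = generate_performance(config, latent, rng)
    performance = perf_full.drop(columns="z")
    truth = {
        "params": config.true_params.as_dict(),
        "K": {f"{k[0]},{k[1]}": v for k, v in config.K.items()},
        "phi": config.phi,
        "bins": {
            f"{r.stratum},{r.season},{r.year}": int(r.bin)
            for r in latent.itertuples()
        },
        "latent_biomass_t": {
            f"{r.stratum},{r.season},{r.year}": float(r.biomass_t)
            for r in latent.itertuples()
        },
    }
    study = SyntheticStudy(config, performance, survey, catch, climate, truth)
    study.latent = latent
    study.z_scores = perf_full
    return study


def effective_truth(study: SyntheticStudy) -> dict[str, float]:
    """Generating parameters mapped onto the analysis (standardized) scale.

    Each index group is standardized with its own sample mean and SD, so the
    parameters that generated the latent z-scores correspond, after
    standardization, to

        alpha_eff  = mean_g[(alpha - m_g) / s_g]
        beta_eff   = beta  * mean_g[1 / s_g]
        sigma_eff  = sigma * sqrt(mean_g[1 / s_g^2])

    with m_g, s_g the realized mean and sample SD of the group's latent
    z-scores.  Posterior coverage of the generating values is assessed
    against these, since the model only ever sees the standardized data.
    """
    tp = study.config.true_params
    inv_s, inv_s2, a_eff = [], [], []
    for _, grp in study.z_scores.groupby(["parameter", "species", "site"]):
        z = grp["z"].to_numpy(float)
        m, s = z.mean(), z.std(ddof=1)
        inv_s.append(1.0 / s)
        inv_s2.append(1.0 / s**2)
        a_eff.append((tp.alpha - m) / s)
    out = {"alpha": float(np.mean(a_eff)), "sigma": float(tp.sigma * math.sqrt(np.mean(inv_s2)))}
    scale = float(np.mean(inv_s))
    for i, b in enumerate(tp.beta, start=1):
        out[f"beta{i}"] = b * scale
    return out


def write_study(study: SyntheticStudy, outdir: str | Path) -> dict[str, Path]:
    """Write the four CSVs plus truth.json to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in ("performance", "survey", "catch", "climate"):
        p = outdir / f"{name}.csv"
        getattr(study, name).to_csv(p, index=False, float_format="%.17g")
        paths[name] = p
    tp = outdir / "truth.json"
    tp.write_text(json.dumps(study.truth, indent=1))
    paths["truth"] = tp
    return paths
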