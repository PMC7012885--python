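"""Truncated log-normal model of local krill biomass (LKB).

Summer LKB in stratum i under summer-SAM sign j is modelled as

    LKB_ij ~ log-Normal(K_ij, phi^2),  truncated to [catch_i, 100 Mt]

so an imputed biomass can never be less than the krill actually caught in
that stratum and season, nor implausibly larger than the regional standing
stock.  Survey summaries give the priors

    K_ij ~ U(0.1 kbar_ij, 10 kbar_ij),   phi_ij ~ U(0.1 s_ij, 10 s_ij)

with kbar_ij / s_ij the mean / SD of ln biomass over the surveys in cell
(i, j).  Missing summer harvest rates follow as LHR* = catch / LKB*.
Winter biomass is never imputed.

phi grouping: the likelihood is written with a single phi while its prior is
subscripted per cell; the default here is one phi per (stratum, SAM-sign)
cell, with ``phi_grouping="shared"`` available for a single phi whose prior
uses the pooled log-scale SD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: upper truncation bound: 100 Mt, roughly twice the regional standing-stock estimate
UPPER_TRUNCATION_T = 1.0e8
#: lower truncation floor when no krill was caught (log-normal support excludes 0)
LOWER_FLOOR_T = 1.0

_SQRT2 = math.sqrt(2.0)
_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


def _std_norm_cdf(z: float) -> float:
    return 0.5 * (1.0 + math.erf(z / _SQRT2))


@dataclass(frozen=True)
class SurveySummary:
    """Log-scale survey moments for one (stratum, SAM-sign) cell."""

    stratum: str
    sam_sign: str
    kbar: float  #: mean ln(biomass in t)
    s: float     #: sample SD of ln(biomass in t)
    n: int       #: number of surveyed seasons in the cell

    @property
    def k_support(self) -> tuple[float, float]:
        """Uniform prior support for K in this cell."""
        return 0.1 * self.kbar, 10.0 * self.kbar

    @property
    def phi_support(self) -> tuple[float, float]:
        """Uniform prior support for phi in this cell."""
        return 0.1 * self.s, 10.0 * self.s


def survey_summary(predictors: pd.DataFrame) -> dict[tuple[str, str], SurveySummary]:
    """Log-scale mean/SD of observed summer LKB per (stratum, SAM-sign) cell.

    Every cell that will anchor a prior needs at least two surveyed summers,
    otherwise the log-scale SD is undefined.
    """
    obs = predictors[(predictors["season"] == "summer") & predictors["lkb_t"].notna()]
    out: dict[tuple[str, str], SurveySummary] = {}
    for (stratum, sign), grp in obs.groupby(["stratum", "sam_sign"]):
        logs = np.log(grp["lkb_t"].to_numpy(float))
        if len(logs) < 2:
            raise ValueError(
                f"cell (stratum={stratum}, sam_sign={sign}) has {len(logs)} survey(s); "
                "need >= 2 to form the log-scale SD"
            )
        out[(stratum, sign)] = SurveySummary(
            stratum, sign, float(logs.mean()), float(logs.std(ddof=1)), len(logs)
        )
    return out


def pooled_phi_support(summaries: dict[tuple[str, str], SurveySummary]) -> tuple[float, float]:
    """Prior support for a single shared phi, from the pooled log-scale SD."""
    # pooled within-cell variance, weighted by cell degrees of freedom
    num = sum((s.n - 1) * s.s**2 for s in summaries.values())
    den = sum(s.n - 1 for s in summaries.values())
    pooled = math.sqrt(num / den)
    return 0.1 * pooled, 10.0 * pooled


def truncated_lognormal_logpdf(
    x: float, K: float, phi: float, lower: float, upper: float = UPPER_TRUNCATION_T
) -> float:
    """Log-density of a log-normal(K, phi^2) truncated to [lower, upper].

    Returns -inf outside the bounds.  ``lower`` must be positive (use the
    1 t floor when the catch is zero).
    """
    if not (0.0 < lower < upper):
        raise ValueError(f"invalid truncation bounds [{lower}, {upper}]")
    if phi <= 0:
        raise ValueError(f"phi must be positive, got {phi}")
    if x < lower or x > upper:
        return -math.inf
    lx = math.log(x)
    z = (lx - K) / phi
    a = (math.log(lower) - K) / phi
    b = (math.log(upper) - K) / phi
    mass = _std_norm_cdf(b) - _std_norm_cdf(a)
    if mass <= 0.0:
        return -math.inf
    return -_LOG_SQRT_2PI - math.log(phi) - lx - 0.5 * z * z - math.log(mass)


def sample_truncated_lognormal(
    rng: np.random.Generator,
    K: float,
    phi: float,
    lower: float,
    upper: float = UPPER_TRUNCATION_T,
    size: int | None = None,
):
    """Inverse-CDF draw(s) from the truncated log-normal.

    Exact (no rejection): maps uniforms through the normal quantile
    restricted to [Phi(a), Phi(b)] on the log scale.
    """
    if not (0.0 < lower < upper):
        raise ValueError(f"invalid truncation bounds [{lower}, {upper}]")
    a = (math.log(lower) - K) / phi
    b = (math.log(upper) - K) / phi
    fa, fb = stats.norm.cdf(a), stats.norm.cdf(b)
    u = rng.uniform(fa, fb, size=size)
    z = stats.norm.ppf(u)
    x = np.exp(K + phi * z)
    return np.clip(x, lower, upper)


@dataclass(frozen=True)
class ImputedBiomass:
    """One posterior draw of a missing summer biomass and its harvest rate."""

    stratum: str
    year: int
    lkb_star_t: float
    lhr_star: float


def draw_lkb_star(
    rng: np.random.Generator,
    K: float,
    phi: float,
    stratum: str,
    year: int,
    catch_t: float,
    season: str = "summer",
) -> ImputedBiomass:
    """Impute one summer LKB* and the implied LHR* = catch / LKB*.

    The draw is truncated below at the season's catch (floor 1 t when no
    krill was caught) and above at 100 Mt, so LHR* always lies in (0, 1].
    """
    if season != "winter" and season != "summer":
        raise ValueError(f"unknown season {season!r}")
    if season == "winter":
        raise ValueError("no winter imputation: winter biomass is never imputed")
    if catch_t < 0:
        raise ValueError(f"catch must be >= 0, got {catch_t}")
    lower = max(catch_t, LOWER_FLOOR_T)
    lkb = float(sample_truncated_lognormal(rng, K, phi, lower))
    return ImputedBiomass(stratum, year, lkb, catch_t / lkb)


def imputation_log_posterior(
    K: dict[tuple[str, str], float],
    phi: dict[tuple[str, str], float],
    biomasses: list[tuple[tuple[str, str], float, float]],
    summaries: dict[tuple[str, str], SurveySummary],
    phi_grouping: str = "per_cell",
    shared_phi_support: tuple[float, float] | None = None,
) -> float:
    """Joint log-density of the biomass block.

    Parameters
    ----------
    K, phi
        Current expected ln-LKB and log-scale SD per (stratum, sign) cell.
        Under ``phi_grouping="shared"`` every cell must carry the same phi
        value and ``shared_phi_support`` gives its prior bounds.
    biomasses
        Triplets ``(cell, lkb_t, lower_bound_t)`` for every summer
        stratum-year in the likelihood -- surveyed seasons contribute their
        observed biomass, unsurveyed seasons their current latent LKB*.
    summaries
        Survey summaries supplying the uniform prior supports.
    """
    total = 0.0
    for cell, summ in summaries.items():
        klo, khi = summ.k_support
        if not klo <= K[cell] <= khi:
            return -math.inf
        if phi_grouping == "per_cell":
            plo, phi_hi = summ.phi_support
            if not plo <= phi[cell] <= phi_hi:
                return -math.inf
            total -= math.log(khi - klo) + math.log(phi_hi - plo)
        else:
            total -= math.log(khi - klo)
    if phi_grouping == "shared":
        if shared_phi_support is None:
            raise ValueError("shared phi grouping needs shared_phi_support")
        plo, phi_hi = shared_phi_support
        shared = next(iter(phi.values()))
        if not plo <= shared <= phi_hi:
            return -math.inf
        total -= math.log(phi_hi - plo)
    for cell, lkb_t, lower in biomasses:
        total += truncated_lognormal_logpdf(lkb_t, K[cell], phi[cell], lower)
        if total == -math.inf:
            return -math.inf
    return total
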