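"""Sum-to-zero ANOVA of standardized penguin performance.

Expected performance for a predictor-category combination is

    P = alpha + beta1*o1 + beta2*o2 + beta3*b + beta4*h1 + beta5*h2
    p ~ N(P, sigma^2)

where (o1, o2) code the three ONI categories, b the two LKB categories and
(h1, h2) the three LHR categories as sum-to-zero contrasts, so alpha is the
grand mean across category combinations.  Priors: alpha and each beta are
N(0, 1e4) (variance 1e4, i.e. SD 100); sigma has a half-Cauchy prior with
scale omega; omega ~ U(0, 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

PRIOR_VARIANCE = 1.0e4
OMEGA_UPPER = 2.0

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)

#: contrast codes per category level
_O1 = {"low": -1, "mid": 1, "high": 0}
_O2 = {"low": -1, "mid": 0, "high": 1}
_B = {"low": -1, "high": 1}
_H1 = {"low": -1, "mid": 1, "high": 0}
_H2 = {"low": -1, "mid": 0, "high": 1}


def encode_design(oni_cat: str, lkb_cat: str, lhr_cat: str) -> tuple[int, int, int, int, int]:
    """Sum-to-zero contrast codes (o1, o2, b, h1, h2) for a category triple."""
    try:
        return (_O1[oni_cat], _O2[oni_cat], _B[lkb_cat], _H1[lhr_cat], _H2[lhr_cat])
    except KeyError as e:
        raise ValueError(f"unknown category label {e.args[0]!r}") from None


@dataclass
class AnovaParams:
    """Sampled parameters of the performance component."""

    alpha: float
    beta: tuple[float, float, float, float, float]
    sigma: float
    omega: float

    def as_dict(self) -> dict[str, float]:
        d = {"alpha": self.alpha, "sigma": self.sigma, "omega": self.omega}
        d.update({f"beta{i + 1}": b for i, b in enumerate(self.beta)})
        return d


def expected_performance(params: AnovaParams, design: tuple[int, int, int, int, int]) -> float:
    """P = alpha + beta . design."""
    b = params.beta
    d = design
    return params.alpha + b[0] * d[0] + b[1] * d[1] + b[2] * d[2] + b[3] * d[3] + b[4] * d[4]


def log_likelihood(values: np.ndarray, designs: np.ndarray, params: AnovaParams) -> float:
    """Normal log-likelihood of pooled z-scores given their bins' expectations.

    ``designs`` is (n, 5) of contrast codes aligned with ``values``.
    """
    if params.sigma <= 0:
        return -math.inf
    beta = np.asarray(params.beta, dtype=float)
    P = params.alpha + designs @ beta
    resid = np.asarray(values, dtype=float) - P
    n = resid.size
    return float(-n * (_LOG_SQRT_2PI + math.log(params.sigma)) - (resid @ resid) / (2.0 * params.sigma**2))


def half_cauchy_logpdf(x: float, scale: float) -> float:
    """log of 2 / (pi * scale * (1 + (x/scale)^2)) on x > 0."""
    if x <= 0 or scale <= 0:
        return -math.inf
    return math.log(2.0 / (math.pi * scale)) - math.log1p((x / scale) ** 2)


def log_prior(params: AnovaParams, prior_variance: float = PRIOR_VARIANCE) -> float:
    """Joint log-prior: N(0, 1e4) effects, half-Cauchy(omega) sigma, U(0,2) omega."""
    if params.sigma <= 0 or not (0.0 < params.omega < OMEGA_UPPER):
        return -math.inf
    total = -math.log(OMEGA_UPPER)  # uniform hyperprior on omega
    for x in (params.alpha, *params.beta):
        total += -_LOG_SQRT_2PI - 0.5 * math.log(prior_variance) - x * x / (2.0 * prior_variance)
    total += half_cauchy_logpdf(params.sigma, params.omega)
    return total


def joint_log_posterior(
    params: AnovaParams,
    values: np.ndarray,
    designs: np.ndarray,
    imputation_logp: float = 0.0,
) -> float:
    """log prior + performance log-likelihood + biomass-block log-density.

    ``designs`` must already reflect the current LKB*/LHR* categories for
    imputed season-years; ``imputation_logp`` is the value of
    :func:`penguinperf.imputation.imputation_log_posterior` at the current
    biomass-block state.
    """
    lp = log_prior(params)
    if lp == -math.inf or imputation_logp == -math.inf:
        return -math.inf
    return lp + log_likelihood(values, designs, params) + imputation_logp
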