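"""Scenario comparisons: marginal effects and comparison probabilities.

A scenario is a predictor-category triple.  The "best case" is La Nina
conditions with low biomass and negligible fishing (ONI <= -0.5 degC,
LKB <= 1 Mt, LHR <= 0.01); the "worst case" is neutral ONI with high
biomass and heavy fishing (-0.5 < ONI < 0.5, LKB > 1 Mt, LHR >= 0.1).
Marginal scenarios vary one factor from the best case while holding the
others at best-case levels.

For each retained posterior draw the expected performance P of a scenario
follows from the fitted contrasts; pairwise comparison probabilities are
Monte-Carlo fractions over draws, and predictive probabilities add one
simulated observation of residual noise per draw.  The "long-term mean" is
exactly 0 on the standardized performance scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from penguinperf.anova import encode_design
from penguinperf.mcmc import PosteriorDraws

LONG_TERM_MEAN = 0.0


@dataclass(frozen=True)
class Scenario:
    name: str
    oni_cat: str
    lkb_cat: str
    lhr_cat: str

    @property
    def design(self) -> tuple[int, int, int, int, int]:
        return encode_design(self.oni_cat, self.lkb_cat, self.lhr_cat)


#: named presets; marginal scenarios hold unvaried factors at best-case levels
SCENARIOS: dict[str, Scenario] = {
    "best_case": Scenario("best_case", "low", "low", "low"),
    "mid_oni": Scenario("mid_oni", "mid", "low", "low"),
    "high_oni": Scenario("high_oni", "high", "low", "low"),
    "high_lkb": Scenario("high_lkb", "low", "high", "low"),
    "mid_lhr": Scenario("mid_lhr", "low", "low", "mid"),
    "high_lhr": Scenario("high_lhr", "low", "low", "high"),
    "worst_case": Scenario("worst_case", "mid", "high", "high"),
}

#: display labels matching the published comparison table
SCENARIO_LABELS = {
    "best_case": "Best case",
    "mid_oni": "-0.5 degC < ONI < 0.5 degC",
    "high_oni": "ONI >= 0.5 degC",
    "high_lkb": "LKB > 1 Mt",
    "mid_lhr": "0.01 < LHR < 0.10",
    "high_lhr": "LHR >= 0.1",
    "worst_case": "Worst case",
}

_TABLE_ROWS = ["best_case", "mid_oni", "high_oni", "high_lkb", "mid_lhr", "high_lhr", "worst_case"]
_TABLE_COLS = ["best_case", "mid_oni", "high_oni"]


def _resolve(s: Scenario | str) -> Scenario:
    if isinstance(s, Scenario):
        return s
    try:
        return SCENARIOS[s]
    except KeyError:
        raise ValueError(f"unknown scenario {s!r}; known: {sorted(SCENARIOS)}") from None


def scenario_P(draws: PosteriorDraws, scenario: Scenario | str) -> np.ndarray:
    """Per-draw expected performance of a scenario (all chains pooled)."""
    s = _resolve(scenario)
    d = s.design
    out = draws.flat("alpha").copy()
    for i in range(5):
        out += d[i] * draws.flat(f"beta{i + 1}")
    return out


def prob_less(draws: PosteriorDraws, a: Scenario | str, b: Scenario | str) -> float:
    """Posterior probability that scenario ``a``'s expected performance is
    below scenario ``b``'s.  Identical scenarios give 0 (strict inequality)."""
    sa, sb = _resolve(a), _resolve(b)
    pa, pb = scenario_P(draws, sa), scenario_P(draws, sb)
    return float(np.mean(pa < pb))


def prob_below_longterm_mean(
    draws: PosteriorDraws,
    scenario: Scenario | str,
    predictive: bool = False,
    rng: np.random.Generator | None = None,
) -> float:
    """Probability that performance under a scenario falls below the
    long-term mean (0 on the standardized scale).

    Posterior mode compares the expected performance P; predictive mode
    simulates one new observation ~ N(P, sigma^2) per draw, so residual
    noise pulls the probability toward 0.5.
    """
    P = scenario_P(draws, scenario)
    if not predictive:
        return float(np.mean(P < LONG_TERM_MEAN))
    if rng is None:
        rng = np.random.default_rng(0)
    sim = P + draws.flat("sigma") * rng.standard_normal(P.size)
    return float(np.mean(sim < LONG_TERM_MEAN))


def table1(draws: PosteriorDraws, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Comparison matrix of posterior (and predictive) probabilities.

    Rows are scenarios; columns are the best case, the two warm-ONI
    marginals, and the long-term mean.  Every cell is computed; the
    ``*_predictive`` columns carry the posterior-predictive versions of the
    long-term-mean comparison.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    rows = []
    for rname in _TABLE_ROWS:
        row: dict[str, float | str] = {"scenario": SCENARIO_LABELS[rname]}
        for cname in _TABLE_COLS:
            if rname == cname:
                row[SCENARIO_LABELS[cname]] = np.nan
            else:
                # P(row scenario's expected performance < column scenario's)
                row[SCENARIO_LABELS[cname]] = prob_less(draws, rname, cname)
        row["Long-term mean"] = prob_below_longterm_mean(draws, rname)
        row["Long-term mean (predictive)"] = prob_below_longterm_mean(
            draws, rname, predictive=True, rng=rng
        )
        rows.append(row)
    return pd.DataFrame(rows)


def fig2_summary(draws: PosteriorDraws) -> pd.DataFrame:
    """Five-number summary of per-draw expected performance per scenario.

    Includes the best-case median and the long-term mean (0) as reference
    values for plotting.
    """
    recs = []
    best_median = float(np.median(scenario_P(draws, "best_case")))
    for name in _TABLE_ROWS:
        P = scenario_P(draws, name)
        recs.append(
            dict(
                scenario=name,
                median=float(np.median(P)),
                q25=float(np.quantile(P, 0.25)),
                q75=float(np.quantile(P, 0.75)),
                min=float(P.min()),
                max=float(P.max()),
                best_case_median=best_median,
                long_term_mean=LONG_TERM_MEAN,
            )
        )
    return pd.DataFrame(recs)
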