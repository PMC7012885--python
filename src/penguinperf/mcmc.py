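"""Adaptive Metropolis-within-Gibbs engine and convergence diagnostics.

One random-walk Metropolis block per scalar parameter.  Proposal scales are
tuned only during the adaptation phase (targeting acceptance in the 20-50%
band) and frozen afterwards, so the post-adaptation kernel is a valid
time-homogeneous Markov chain.  Positive parameters are updated on the log
scale with the appropriate Jacobian.

Diagnostics (split R-hat, autocorrelation-based ESS) are computed with
arviz behind thin wrappers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: acceptance-rate band targeted during adaptation
ACCEPT_BAND = (0.20, 0.50)
_ACCEPT_TARGET = 0.35
_BATCH = 50


@dataclass(frozen=True)
class SamplerConfig:
    """Chain schedule.

    ``n_keep_iterations`` are post-burn-in iterations of which every
    ``thin``-th is retained, so each chain keeps
    ``n_keep_iterations // thin`` draws.
    """

    n_chains: int = 3
    n_adapt: int = 5_000
    n_burnin: int = 20_000
    n_keep_iterations: int = 5_000
    thin: int = 5
    seed: int = 0

    def __post_init__(self):
        for name in ("n_chains", "n_adapt", "n_burnin", "n_keep_iterations", "thin"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_keep_iterations % self.thin:
            raise ValueError("n_keep_iterations must be a multiple of thin")

    @property
    def n_retained(self) -> int:
        return self.n_keep_iterations // self.thin


def paper_schedule(seed: int = 0) -> SamplerConfig:
    """The published schedule: 3 chains, 250k adapt, 500k burn-in, 5000 draws
    retained from every 25th of a further 125k iterations."""
    return SamplerConfig(3, 250_000, 500_000, 125_000, 25, seed)


def desk_schedule(seed: int = 0) -> SamplerConfig:
    """Default small schedule for interactive work and tests."""
    return SamplerConfig(3, 5_000, 20_000, 5_000, 5, seed)


@dataclass
class PosteriorDraws:
    """Retained draws: array (n_chains, n_retained, n_params)."""

    names: list[str]
    draws: np.ndarray
    acceptance: dict[str, list[float]] = field(default_factory=dict)
    proposal_scales: dict[str, list[float]] = field(default_factory=dict)

    def __post_init__(self):
        self._index = {n: i for i, n in enumerate(self.names)}

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_retained(self) -> int:
        return self.draws.shape[1]

    def get(self, name: str) -> np.ndarray:
        """(n_chains, n_retained) array for one parameter."""
        return self.draws[:, :, self._index[name]]

    def flat(self, name: str) -> np.ndarray:
        return self.get(name).reshape(-1)

    def to_dataframe(self) -> pd.DataFrame:
        """Long format: chain, iteration, parameter, value."""
        chains, iters, _ = self.draws.shape
        recs = []
        for c in range(chains):
            for j, name in enumerate(self.names):
                recs.append(
                    pd.DataFrame(
                        {
                            "chain": c,
                            "iteration": np.arange(iters),
                            "parameter": name,
                            "value": self.draws[c, :, j],
                        }
                    )
                )
        return pd.concat(recs, ignore_index=True)

    def to_arviz(self):
        import arviz as az

        return az.convert_to_dataset({n: self.get(n) for n in self.names})


class AdaptiveScales:
    """Per-block proposal scales with batched Robbins-Monro adaptation."""

    def __init__(self, names: list[str], initial: dict[str, float] | float = 0.5):
        self.names = list(names)
        if isinstance(initial, dict):
            self.scale = {n: float(initial[n]) for n in names}
        else:
            self.scale = {n: float(initial) for n in names}
        self._accepts = {n: 0 for n in names}
        self._tries = {n: 0 for n in names}
        self._batch_no = 0
        self.frozen = False
        self.total_accepts = {n: 0 for n in names}
        self.total_tries = {n: 0 for n in names}

    def record(self, name: str, accepted: bool) -> None:
        self._tries[name] += 1
        self.total_tries[name] += 1
        if accepted:
            self._accepts[name] += 1
            self.total_accepts[name] += 1
        if not self.frozen and self._tries[name] >= _BATCH:
            self._batch_no += 1
            rate = self._accepts[name] / self._tries[name]
            delta = min(0.25, 2.0 / math.sqrt(self._batch_no))
            if rate > _ACCEPT_TARGET:
                self.scale[name] *= math.exp(delta)
            else:
                self.scale[name] /= math.exp(delta)
            self._accepts[name] = 0
            self._tries[name] = 0

    def freeze(self) -> None:
        self.frozen = True
        for n in self.names:
            self.total_accepts[n] = 0
            self.total_tries[n] = 0
            self._accepts[n] = 0
            self._tries[n] = 0

    def rates(self) -> dict[str, float]:
        return {
            n: (self.total_accepts[n] / self.total_tries[n]) if self.total_tries[n] else math.nan
            for n in self.names
        }


def run_chains(
    log_posterior,
    inits: list[np.ndarray],
    config: SamplerConfig,
    param_names: list[str] | None = None,
    log_scale: np.ndarray | None = None,
    initial_scales: float | np.ndarray = 0.5,
) -> PosteriorDraws:
    """Generic component-wise adaptive random-walk Metropolis sampler.

    Parameters
    ----------
    log_posterior
        Callable mapping a parameter vector to a log-density (may return
        ``-inf``).
    inits
        One starting vector per chain; the log-posterior must be finite at
        each.
    log_scale
        Boolean mask of parameters updated on the log scale (positive
        parameters); the Jacobian is handled internally.
    """
    dim = len(inits[0])
    names = param_names or [f"p{i}" for i in range(dim)]
    if len(inits) != config.n_chains:
        raise ValueError(f"need {config.n_chains} initial vectors, got {len(inits)}")
    logmask = np.zeros(dim, bool) if log_scale is None else np.asarray(log_scale, bool)
    ss = np.random.SeedSequence(config.seed)
    chain_seeds = ss.spawn(config.n_chains)
    all_draws = np.empty((config.n_chains, config.n_retained, dim))
    acceptance: dict[str, list[float]] = {n: [] for n in names}
    scales_out: dict[str, list[float]] = {n: [] for n in names}

    init_sc = np.full(dim, initial_scales, float) if np.isscalar(initial_scales) else np.asarray(initial_scales, float)
    total = config.n_adapt + config.n_burnin + config.n_keep_iterations
    for c in range(config.n_chains):
        rng = np.random.default_rng(chain_seeds[c])
        x = np.array(inits[c], float)
        lp = log_posterior(x)
        if not np.isfinite(lp):
            raise ValueError(f"chain {c}: initial log-posterior is not finite ({lp})")
        scales = AdaptiveScales(names, {n: init_sc[j] for j, n in enumerate(names)})
        kept = 0
        for it in range(total):
            if it == config.n_adapt:
                for n in names:
                    if scales.total_tries[n] and scales.total_accepts[n] == 0:
                        warnings.warn(
                            f"chain {c}: block {n} accepted nothing during adaptation "
                            f"(scale {scales.scale[n]:.3g}); diagnostics: {scales.rates()}"
                        )
                scales.freeze()
            for j in range(dim):
                name = names[j]
                step = scales.scale[name] * rng.standard_normal()
                xp = x.copy()
                if logmask[j]:
                    xp[j] = x[j] * math.exp(step)
                    jac = step  # d log x
                else:
                    xp[j] = x[j] + step
                    jac = 0.0
                lpp = log_posterior(xp)
                if math.log(rng.random()) < lpp - lp + jac:
                    x, lp = xp, lpp
                    scales.record(name, True)
                else:
                    scales.record(name, False)
            if it >= config.n_adapt + config.n_burnin:
                k = it - config.n_adapt - config.n_burnin
                if (k + 1) % config.thin == 0:
                    all_draws[c, kept] = x
                    kept += 1
        assert kept == config.n_retained
        rates = scales.rates()
        for n in names:
            acceptance[n].append(rates[n])
            scales_out[n].append(scales.scale[n])
    return PosteriorDraws(names, all_draws, acceptance, scales_out)


# -- diagnostics ------------------------------------------------------------

def gelman_rubin(draws: PosteriorDraws, parameter: str) -> float:
    """Split-chain potential scale reduction factor (rank-normalized R-hat).

    Requires at least two chains and ten retained draws per chain; returns
    NaN for degenerate (constant) chains.
    """
    arr = draws.get(parameter)
    if arr.shape[0] < 2:
        raise ValueError("R-hat needs >= 2 chains")
    if arr.shape[1] < 10:
        raise ValueError("R-hat needs >= 10 retained draws per chain")
    import arviz as az

    if np.allclose(arr, arr.flat[0]):
        return math.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.rhat(az.convert_to_dataset(arr))["x"].values)


def effective_sample_size(draws: PosteriorDraws, parameter: str) -> float:
    """Autocorrelation-based ESS, capped at the total number of draws."""
    arr = draws.get(parameter)
    if arr.shape[1] < 100:
        raise ValueError("ESS needs >= 100 retained draws per chain")
    import arviz as az

    if np.allclose(arr, arr.flat[0]):
        return math.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ess = float(az.ess(az.convert_to_dataset(arr))["x"].values)
    return min(ess, float(arr.size))


def diagnostics_summary(draws: PosteriorDraws) -> dict:
    """R-hat, ESS, and per-block acceptance rates for every parameter."""
    out: dict[str, dict] = {"parameters": {}, "acceptance": draws.acceptance}
    for name in draws.names:
        entry: dict[str, float] = {}
        try:
            entry["rhat"] = gelman_rubin(draws, name)
        except ValueError:
            entry["rhat"] = math.nan
        try:
            entry["ess"] = effective_sample_size(draws, name)
        except ValueError:
            entry["ess"] = math.nan
        out["parameters"][name] = entry
    return out
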