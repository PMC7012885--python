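"""Joint posterior of the performance ANOVA and the biomass-imputation block.

The two model components are sampled in a single Metropolis-within-Gibbs
chain so that uncertainty in imputed biomass (LKB*) and harvest rate (LHR*)
propagates into the performance effects: every update of an LKB* value can
flip the LKB/LHR categories of its season-year across the 1 Mt / 0.01 / 0.1
thresholds, re-binning that season's observations on the fly.

The performance likelihood is evaluated from per-bin sufficient statistics
(count, sum, sum of squares over the 18 predictor bins), which makes each
Metropolis block O(18) regardless of the number of observations.  A latent
LKB* update only touches the bin statistics of its own season-year.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from penguinperf.anova import (
    OMEGA_UPPER,
    PRIOR_VARIANCE,
    AnovaParams,
    encode_design,
    half_cauchy_logpdf,
    log_prior,
)
from penguinperf.imputation import (
    LOWER_FLOOR_T,
    UPPER_TRUNCATION_T,
    SurveySummary,
    imputation_log_posterior,
    pooled_phi_support,
    sample_truncated_lognormal,
)
from penguinperf.mcmc import _ACCEPT_TARGET, _BATCH, PosteriorDraws, SamplerConfig
from penguinperf.preprocess import (
    bin_label,
    bin_to_categories,
    categorize_lhr,
    categorize_lkb,
)

_SQRT2 = math.sqrt(2.0)
_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


def _ncdf(z: float) -> float:
    return 0.5 * (1.0 + math.erf(z / _SQRT2))


@dataclass
class LatentSummer:
    """One unsurveyed summer stratum-year whose LKB is imputed."""

    stratum: str
    year: int
    cell: tuple[str, str]        # (stratum, summer-SAM sign)
    oni_cat: str
    catch_t: float
    lower_t: float               # max(catch, 1 t)
    n: float                     # attached performance observations
    s: float                     # ... their sum
    q: float                     # ... their sum of squares


class JointModel:
    """Assembled data + parameters for the joint sampler.

    Parameters
    ----------
    analysis
        Output of :func:`penguinperf.preprocess.match_and_pool` (first
        element): standardized observations with bins where LKB is
        observed and ``imputable=True`` rows for unsurveyed summers.
    predictors
        Full predictor table (one row per stratum x season x year).
    summaries
        Survey summaries per (stratum, summer-SAM sign) cell.
    phi_grouping
        ``"per_cell"`` (one log-scale SD per cell, the default) or
        ``"shared"``.
    impute_years
        Years eligible for summer imputation; default: every summer in the
        predictor table lacking a survey.
    """

    def __init__(
        self,
        analysis: pd.DataFrame,
        predictors: pd.DataFrame,
        summaries: dict[tuple[str, str], SurveySummary],
        phi_grouping: str = "per_cell",
        impute_years: tuple[int, int] | None = None,
    ):
        if phi_grouping not in ("per_cell", "shared"):
            raise ValueError(f"unknown phi_grouping {phi_grouping!r}")
        self.phi_grouping = phi_grouping
        self.summaries = summaries
        self.cells = sorted(summaries)
        self.shared_phi_support = pooled_phi_support(summaries) if phi_grouping == "shared" else None

        # 18 x 5 design matrix of contrast codes, row = bin - 1
        self.D = np.array([encode_design(*bin_to_categories(b)) for b in range(1, 19)], float)

        # fixed-bin sufficient statistics
        self.base_stats = np.zeros((18, 3))
        fixed = analysis[~analysis["imputable"].astype(bool)]
        for b, grp in fixed.groupby(fixed["bin"].astype(int)):
            v = grp["value"].to_numpy(float)
            self.base_stats[b - 1] = [v.size, v.sum(), (v * v).sum()]
        self.n_obs_total = int(fixed.shape[0])

        # latent summers
        imputable = analysis[analysis["imputable"].astype(bool)]
        obs_by_sy = {
            (stratum, year): grp["value"].to_numpy(float)
            for (stratum, year), grp in imputable.groupby(["stratum", "year"])
        }
        self.latents: list[LatentSummer] = []
        missing = predictors[(predictors["season"] == "summer") & predictors["lkb_t"].isna()]
        if impute_years is not None:
            missing = missing[(missing["year"] >= impute_years[0]) & (missing["year"] <= impute_years[1])]
        for rec in missing.sort_values(["stratum", "year"]).to_dict("records"):
            cell = (rec["stratum"], rec["sam_sign"])
            if cell not in summaries:
                raise ValueError(f"no survey summary for cell {cell}; cannot impute {rec['stratum']} {rec['year']}")
            v = obs_by_sy.get((rec["stratum"], rec["year"]), np.empty(0))
            self.latents.append(
                LatentSummer(
                    rec["stratum"],
                    int(rec["year"]),
                    cell,
                    rec["oni_cat"],
                    float(rec["catch_t"]),
                    max(float(rec["catch_t"]), LOWER_FLOOR_T),
                    float(v.size),
                    float(v.sum()),
                    float((v * v).sum()),
                )
            )
        self.n_obs_total += int(sum(lat.n for lat in self.latents))

        # observed summer biomass terms entering the K/phi likelihood
        obs_summer = predictors[(predictors["season"] == "summer") & predictors["lkb_t"].notna()]
        self.obs_terms: dict[tuple[str, str], list[tuple[float, float]]] = {c: [] for c in self.cells}
        for rec in obs_summer.to_dict("records"):
            cell = (rec["stratum"], rec["sam_sign"])
            if cell in self.obs_terms:
                lower = max(float(rec["catch_t"]), LOWER_FLOOR_T)
                self.obs_terms[cell].append((math.log(float(rec["lkb_t"])), math.log(lower)))
        self.latents_by_cell = {
            c: [m for m, lat in enumerate(self.latents) if lat.cell == c] for c in self.cells
        }
        self.log_upper = math.log(UPPER_TRUNCATION_T)

    # -- parameter bookkeeping ---------------------------------------------

    @property
    def param_names(self) -> list[str]:
        names = ["alpha", "beta1", "beta2", "beta3", "beta4", "beta5", "sigma", "omega"]
        names += [f"K[{c[0]},{c[1]}]" for c in self.cells]
        if self.phi_grouping == "per_cell":
            names += [f"phi[{c[0]},{c[1]}]" for c in self.cells]
        else:
            names += ["phi"]
        names += [f"lkb_star[{lat.stratum},{lat.year}]" for lat in self.latents]
        names += [f"lhr_star[{lat.stratum},{lat.year}]" for lat in self.latents]
        return names

    def latent_bin(self, lat: LatentSummer, lkb_t: float) -> int:
        lhr = lat.catch_t / lkb_t
        return bin_label(lat.oni_cat, categorize_lkb(lkb_t), categorize_lhr(lhr)) - 1

    # -- full joint log posterior (reference path, used by the sampler only
    #    for initialization checks and by tests for regression) -------------

    def joint_log_posterior(self, params: AnovaParams, K: dict, phi: dict, lkb: np.ndarray) -> float:
        lp = log_prior(params)
        if lp == -math.inf:
            return -math.inf
        biomasses = []
        for cell in self.cells:
            for lx, ll in self.obs_terms[cell]:
                biomasses.append((cell, math.exp(lx), math.exp(ll)))
        for m, lat in enumerate(self.latents):
            biomasses.append((lat.cell, float(lkb[m]), lat.lower_t))
        imp = imputation_log_posterior(
            K, phi, biomasses, self.summaries, self.phi_grouping, self.shared_phi_support
        )
        if imp == -math.inf:
            return -math.inf
        stats = self._bin_stats(lkb)
        beta = np.asarray(params.beta)
        P = params.alpha + self.D @ beta
        ssr = float(stats[:, 2].sum() - 2.0 * (P @ stats[:, 1]) + (P * P) @ stats[:, 0])
        n = stats[:, 0].sum()
        lik = -n * (_LOG_SQRT_2PI + math.log(params.sigma)) - ssr / (2.0 * params.sigma**2)
        return lp + lik + imp

    def _bin_stats(self, lkb: np.ndarray) -> np.ndarray:
        stats = self.base_stats.copy()
        for m, lat in enumerate(self.latents):
            if lat.n:
                b = self.latent_bin(lat, float(lkb[m]))
                stats[b] += (lat.n, lat.s, lat.q)
        return stats

    # -- initialization -----------------------------------------------------

    def initial_state(self, rng: np.random.Generator, chain: int):
        """Dispersed but in-support starting point for one chain."""
        offset = 0.2 * (chain - 1)
        alpha = float(rng.normal(offset, 1.0))
        beta = tuple(float(rng.normal(offset, 1.0)) for _ in range(5))
        sigma = float(rng.uniform(0.5, 1.5))
        omega = float(rng.uniform(0.5, 1.5))
        K, phi = {}, {}
        for cell in self.cells:
            summ = self.summaries[cell]
            klo, khi = summ.k_support
            K[cell] = float(np.clip(summ.kbar * rng.uniform(0.85, 1.15), klo, khi))
        if self.phi_grouping == "per_cell":
            for cell in self.cells:
                plo, phi_hi = self.summaries[cell].phi_support
                phi[cell] = float(np.clip(self.summaries[cell].s * rng.uniform(0.8, 1.25), plo, phi_hi))
        else:
            plo, phi_hi = self.shared_phi_support
            shared = float(np.clip(math.sqrt(plo * phi_hi) * rng.uniform(0.8, 1.25), plo, phi_hi))
            phi = {cell: shared for cell in self.cells}
        lkb = np.empty(len(self.latents))
        for m, lat in enumerate(self.latents):
            lkb[m] = sample_truncated_lognormal(rng, K[lat.cell], phi[lat.cell], lat.lower_t)
        return AnovaParams(alpha, beta, sigma, omega), K, phi, lkb


# -- the specialized sampler -------------------------------------------------

#: initial proposal scales per block family
_INIT_SCALES = {"theta": 0.2, "sigma": 0.2, "omega": 0.4, "K": 0.4, "phi": 0.3, "lkb": 1.0}


def _cell_loglik(model: JointModel, cell, K: float, phi: float, log_lkb: np.ndarray) -> float:
    """Biomass log-likelihood of one (stratum, sign) cell up to constants in x."""
    lu = model.log_upper
    total = 0.0
    lphi = math.log(phi)
    for lx, ll in model.obs_terms[cell]:
        z = (lx - K) / phi
        mass = _ncdf((lu - K) / phi) - _ncdf((ll - K) / phi)
        if mass <= 0.0:
            return -math.inf
        total += -lphi - 0.5 * z * z - math.log(mass)
    for m in model.latents_by_cell[cell]:
        lat = model.latents[m]
        lx = log_lkb[m]
        z = (lx - K) / phi
        mass = _ncdf((lu - K) / phi) - _ncdf((math.log(lat.lower_t) - K) / phi)
        if mass <= 0.0:
            return -math.inf
        total += -lphi - 0.5 * z * z - math.log(mass)
    return total


def fit_joint(model: JointModel, config: SamplerConfig) -> PosteriorDraws:
    """Sample the joint posterior; fully reproducible given ``config.seed``."""
    ss = np.random.SeedSequence(config.seed)
    chain_seeds = ss.spawn(config.n_chains)
    names = model.param_names
    dim = len(names)
    all_draws = np.empty((config.n_chains, config.n_retained, dim))
    acceptance: dict[str, list[float]] = {}
    scales_out: dict[str, list[float]] = {}

    for c in range(config.n_chains):
        rng = np.random.default_rng(chain_seeds[c])
        params, K, phi, lkb = model.initial_state(rng, c)
        lp0 = model.joint_log_posterior(params, K, phi, lkb)
        if not np.isfinite(lp0):
            raise ValueError(f"chain {c}: initial log-posterior not finite ({lp0})")
        draws = _run_one_chain(model, config, rng, params, K, phi, lkb, c)
        all_draws[c] = draws["draws"]
        for k, v in draws["acceptance"].items():
            acceptance.setdefault(k, []).append(v)
        for k, v in draws["scales"].items():
            scales_out.setdefault(k, []).append(v)
    return PosteriorDraws(names, all_draws, acceptance, scales_out)


def _run_one_chain(model, config, rng, params, K, phi, lkb, chain_id):
    D = model.D
    cells = model.cells
    n_cells = len(cells)
    latents = model.latents
    n_lat = len(latents)
    shared_phi = model.phi_grouping == "shared"

    theta = [params.alpha, *params.beta]
    sigma, omega = params.sigma, params.omega
    Kv = [K[c] for c in cells]
    phiv = [phi[c] for c in cells]
    log_lkb = np.log(np.asarray(lkb, float))
    lat_bins = [model.latent_bin(lat, float(lkb[m])) for m, lat in enumerate(latents)]

    # bin sufficient statistics as mutable lists
    stats = model.base_stats.copy()
    for m, lat in enumerate(latents):
        if lat.n:
            stats[lat_bins[m]] += (lat.n, lat.s, lat.q)
    Nb, Sb, Qb = stats[:, 0].copy(), stats[:, 1].copy(), stats[:, 2].copy()
    N_tot = float(Nb.sum())
    Q_tot = float(Qb.sum())

    beta_arr = np.array(theta[1:], float)
    P = theta[0] + D @ beta_arr

    def ssr_of(Pvec):
        return float(Q_tot - 2.0 * (Pvec @ Sb) + (Pvec * Pvec) @ Nb)

    ssr = ssr_of(P)

    cell_ll = [_cell_loglik(model, cells[i], Kv[i], phiv[i], log_lkb) for i in range(n_cells)]

    # proposal-scale bookkeeping
    block_names = (
        ["alpha", "beta1", "beta2", "beta3", "beta4", "beta5", "sigma", "omega"]
        + [f"K[{c[0]},{c[1]}]" for c in cells]
        + ([f"phi[{c[0]},{c[1]}]" for c in cells] if not shared_phi else ["phi"])
        + [f"lkb_star[{lat.stratum},{lat.year}]" for lat in latents]
    )
    fam = {}
    for n in block_names:
        fam[n] = n.split("[")[0] if "[" in n else ("theta" if n.startswith(("alpha", "beta")) else n)
        if fam[n] not in _INIT_SCALES:
            fam[n] = "theta"
    scale = {n: _INIT_SCALES[fam[n]] for n in block_names}
    acc = {n: 0 for n in block_names}
    tries = {n: 0 for n in block_names}
    tot_acc = {n: 0 for n in block_names}
    tot_tries = {n: 0 for n in block_names}
    batch_no = {n: 0 for n in block_names}
    frozen = False

    def record(name, accepted):
        nonlocal frozen
        tries[name] += 1
        tot_tries[name] += 1
        if accepted:
            acc[name] += 1
            tot_acc[name] += 1
        if not frozen and tries[name] >= _BATCH:
            batch_no[name] += 1
            rate = acc[name] / tries[name]
            delta = min(0.25, 2.0 / math.sqrt(batch_no[name]))
            if rate > _ACCEPT_TARGET:
                # cap: near-flat bounded conditionals (reflected LKB* blocks)
                # otherwise inflate the scale without ever lowering acceptance
                scale[name] = min(scale[name] * math.exp(delta), 100.0)
            else:
                scale[name] /= math.exp(delta)
            acc[name] = 0
            tries[name] = 0

    two_pv = 2.0 * PRIOR_VARIANCE
    kept = 0
    total_iters = config.n_adapt + config.n_burnin + config.n_keep_iterations
    out = np.empty((config.n_retained, len(model.param_names)))
    theta_names = block_names[:6]

    for it in range(total_iters):
        if it == config.n_adapt and not frozen:
            for n in block_names:
                if tot_tries[n] and tot_acc[n] == 0:
                    warnings.warn(
                        f"chain {chain_id}: block {n} accepted nothing during adaptation "
                        f"(final scale {scale[n]:.3g})"
                    )
            frozen = True
            for n in block_names:
                tot_acc[n] = 0
                tot_tries[n] = 0

        # -- grand mean and contrast effects --------------------------------
        for j in range(6):
            name = theta_names[j]
            d = scale[name] * rng.standard_normal()
            old = theta[j]
            new = old + d
            if j == 0:
                Pp = P + d
            else:
                Pp = P + d * D[:, j - 1]
            ssr_p = ssr_of(Pp)
            dlp = -(ssr_p - ssr) / (2.0 * sigma * sigma) - (new * new - old * old) / two_pv
            if dlp >= 0.0 or math.log(rng.random()) < dlp:
                theta[j] = new
                P = Pp
                ssr = ssr_p
                record(name, True)
            else:
                record(name, False)

        # -- residual SD (log scale) ----------------------------------------
        step = scale["sigma"] * rng.standard_normal()
        sig_p = sigma * math.exp(step)
        dlp = (
            -N_tot * (math.log(sig_p) - math.log(sigma))
            - ssr / 2.0 * (1.0 / (sig_p * sig_p) - 1.0 / (sigma * sigma))
            + half_cauchy_logpdf(sig_p, omega)
            - half_cauchy_logpdf(sigma, omega)
            + step
        )
        if dlp >= 0.0 or math.log(rng.random()) < dlp:
            sigma = sig_p
            record("sigma", True)
        else:
            record("sigma", False)

        # -- half-Cauchy scale ------------------------------------------------
        om_p = omega + scale["omega"] * rng.standard_normal()
        if 0.0 < om_p < OMEGA_UPPER:
            dlp = half_cauchy_logpdf(sigma, om_p) - half_cauchy_logpdf(sigma, omega)
            ok = dlp >= 0.0 or math.log(rng.random()) < dlp
        else:
            ok = False
        record("omega", ok)
        if ok:
            omega = om_p

        # -- expected ln-biomass per cell ------------------------------------
        for i in range(n_cells):
            name = block_names[8 + i]
            kp = Kv[i] + scale[name] * rng.standard_normal()
            klo, khi = model.summaries[cells[i]].k_support
            if klo <= kp <= khi:
                llp = _cell_loglik(model, cells[i], kp, phiv[i], log_lkb)
                dlp = llp - cell_ll[i]
                if dlp >= 0.0 or math.log(rng.random()) < dlp:
                    Kv[i] = kp
                    cell_ll[i] = llp
                    record(name, True)
                    continue
            record(name, False)

        # -- log-scale SD of biomass -----------------------------------------
        if shared_phi:
            name = "phi"
            pp = phiv[0] + scale[name] * rng.standard_normal()
            plo, phih = model.shared_phi_support
            if plo <= pp <= phih:
                lls = [_cell_loglik(model, cells[i], Kv[i], pp, log_lkb) for i in range(n_cells)]
                dlp = sum(lls) - sum(cell_ll)
                if dlp >= 0.0 or math.log(rng.random()) < dlp:
                    phiv = [pp] * n_cells
                    cell_ll = lls
                    record(name, True)
                else:
                    record(name, False)
            else:
                record(name, False)
        else:
            for i in range(n_cells):
                name = block_names[8 + n_cells + i]
                pp = phiv[i] + scale[name] * rng.standard_normal()
                plo, phih = model.summaries[cells[i]].phi_support
                if plo <= pp <= phih:
                    llp = _cell_loglik(model, cells[i], Kv[i], pp, log_lkb)
                    dlp = llp - cell_ll[i]
                    if dlp >= 0.0 or math.log(rng.random()) < dlp:
                        phiv[i] = pp
                        cell_ll[i] = llp
                        record(name, True)
                        continue
                record(name, False)

        # -- latent summer biomasses (log scale, reflected at bounds) --------
        lkb_name_base = 8 + n_cells + (1 if shared_phi else n_cells)
        for m in range(n_lat):
            lat = latents[m]
            name = block_names[lkb_name_base + m]
            i = cells.index(lat.cell)
            lo, hi = math.log(lat.lower_t), model.log_upper
            y = log_lkb[m]
            yp = y + scale[name] * rng.standard_normal()
            # reflect into [lo, hi]: closed-form triangle-wave fold so huge
            # adapted steps cost O(1) instead of one bounce per period
            span = hi - lo
            if yp < lo or yp > hi:
                t = (yp - lo) % (2.0 * span)
                yp = lo + (span - abs(t - span))
            Kc, pc = Kv[i], phiv[i]
            z_old = (y - Kc) / pc
            z_new = (yp - Kc) / pc
            dlp = 0.5 * (z_old * z_old - z_new * z_new)
            if lat.n:
                b_old = lat_bins[m]
                b_new = model.latent_bin(lat, math.exp(yp))
                if b_new != b_old:
                    Po, Pn = P[b_old], P[b_new]
                    d_old = -(lat.q - 2.0 * Po * lat.s + lat.n * Po * Po)
                    d_new = -(lat.q - 2.0 * Pn * lat.s + lat.n * Pn * Pn)
                    dlp += (d_new - d_old) / (2.0 * sigma * sigma)
            else:
                b_new = None
            if dlp >= 0.0 or math.log(rng.random()) < dlp:
                if lat.n:
                    b_old = lat_bins[m]
                    if b_new is None:
                        b_new = model.latent_bin(lat, math.exp(yp))
                    if b_new != b_old:
                        Nb[b_old] -= lat.n
                        Sb[b_old] -= lat.s
                        Qb[b_old] -= lat.q
                        Nb[b_new] += lat.n
                        Sb[b_new] += lat.s
                        Qb[b_new] += lat.q
                        lat_bins[m] = b_new
                        ssr = ssr_of(P)
                else:
                    lat_bins[m] = model.latent_bin(lat, math.exp(yp))
                log_lkb[m] = yp
                # the cell's z-term changed; refresh its cached loglik
                cell_ll[i] += 0.5 * (z_old * z_old - z_new * z_new)
                record(name, True)
            else:
                record(name, False)

        # guard against float drift in the incremental SSR / cell logliks
        if it % 2000 == 1999:
            ssr = ssr_of(P)
            cell_ll = [_cell_loglik(model, cells[i], Kv[i], phiv[i], log_lkb) for i in range(n_cells)]

        if it >= config.n_adapt + config.n_burnin and (it - config.n_adapt - config.n_burnin + 1) % config.thin == 0:
            lkb_t = np.exp(log_lkb)
            row = theta + [sigma, omega] + Kv
            row += phiv if not shared_phi else [phiv[0]]
            row += list(lkb_t)
            row += [latents[m].catch_t / lkb_t[m] for m in range(n_lat)]
            out[kept] = row
            kept += 1

    rates = {n: (tot_acc[n] / tot_tries[n] if tot_tries[n] else math.nan) for n in block_names}
    return {"draws": out, "acceptance": rates, "scales": dict(scale)}


def draws_to_anova_params(draws: PosteriorDraws) -> list[AnovaParams]:
    """Convenience view of the retained performance-block draws."""
    a = draws.flat("alpha")
    b = [draws.flat(f"beta{i}") for i in range(1, 6)]
    s = draws.flat("sigma")
    w = draws.flat("omega")
    return [
        AnovaParams(float(a[k]), tuple(float(b[i][k]) for i in range(5)), float(s[k]), float(w[k]))
        for k in range(a.size)
    ]
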