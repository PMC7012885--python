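"""End-to-end orchestration: ingest -> preprocess -> joint fit -> reports.

A single YAML config drives the run; every analysis constant (category
thresholds, truncation bound, sampler schedule) is surfaced there with the
standard values as defaults.  A run writes seven result tables plus a
manifest sufficient to reproduce it bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from penguinperf import __version__, dataset, preprocess
from penguinperf.imputation import survey_summary
from penguinperf.joint import JointModel, fit_joint
from penguinperf.mcmc import PosteriorDraws, SamplerConfig, desk_schedule, diagnostics_summary, paper_schedule
from penguinperf.scenarios import fig2_summary, table1

RHAT_LIMIT = 1.1

DEFAULT_CONFIG = {
    "paths": {
        "performance": "performance.csv",
        "survey": "survey.csv",
        "catch": "catch.csv",
        "climate": "climate.csv",
    },
    "study": {
        "years": [1982, 2016],
        # "site|species": stratum
        "site_stratum_map": {
            "Copacabana|Adelie": "Bransfield",
            "Copacabana|gentoo": "Bransfield",
            "Cape Shirreff|chinstrap": "Drake",
            "Cape Shirreff|gentoo": "Bransfield",
        },
    },
    "thresholds": {
        "oni_c": 0.5,
        "lkb_t": 1.0e6,
        "lhr": [0.01, 0.1],
        "upper_truncation_t": 1.0e8,
    },
    "model": {"phi_grouping": "per_cell"},
    "sampler": {"schedule": "desk", "seed": 0},
    "output": "results",
}


class ConvergenceError(RuntimeError):
    """Raised when any monitored parameter fails the R-hat check."""


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Defaults, overlaid with the YAML file, overlaid with overrides."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for section, vals in user.items():
            if isinstance(vals, dict):
                cfg.setdefault(section, {}).update(vals)
            else:
                cfg[section] = vals
    for section, vals in (overrides or {}).items():
        if isinstance(vals, dict):
            cfg.setdefault(section, {}).update(vals)
        else:
            cfg[section] = vals
    return cfg


def _site_map(cfg: dict) -> dict[tuple[str, str], str]:
    return {
        tuple(k.split("|")): v for k, v in cfg["study"]["site_stratum_map"].items()
    }


def sampler_config(cfg: dict) -> SamplerConfig:
    s = cfg["sampler"]
    base = paper_schedule(s.get("seed", 0)) if s.get("schedule") == "paper" else desk_schedule(s.get("seed", 0))
    kw = {
        k: s[k]
        for k in ("n_chains", "n_adapt", "n_burnin", "n_keep_iterations", "thin")
        if k in s
    }
    if kw:
        base = SamplerConfig(
            n_chains=kw.get("n_chains", base.n_chains),
            n_adapt=kw.get("n_adapt", base.n_adapt),
            n_burnin=kw.get("n_burnin", base.n_burnin),
            n_keep_iterations=kw.get("n_keep_iterations", base.n_keep_iterations),
            thin=kw.get("thin", base.thin),
            seed=base.seed,
        )
    return base


def validate_inputs(cfg: dict, base_dir: str | Path = ".") -> dict[str, pd.DataFrame]:
    """Read and validate all four input tables; fail before any output."""
    base = Path(base_dir)
    years = tuple(cfg["study"]["years"])
    tables = {}
    for name in ("performance", "survey", "catch", "climate"):
        path = base / cfg["paths"][name]
        tables[name] = dataset.read_table(
            path, name, year_range=years if name == "performance" else None
        )
    return tables


def prepare(cfg: dict, tables: dict[str, pd.DataFrame]):
    """Transform, standardize, assemble predictors, match and pool."""
    years = tuple(cfg["study"]["years"])
    perf = preprocess.apply_parameter_transform(tables["performance"])
    perf = preprocess.standardize_performance(perf)
    predictors = preprocess.build_predictors(
        tables["climate"], tables["survey"], tables["catch"], years
    )
    analysis, exclusions = preprocess.match_and_pool(perf, predictors, _site_map(cfg))
    return analysis, exclusions, predictors


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_analysis(
    config_path: str | Path | None = None,
    config: dict | None = None,
    base_dir: str | Path = ".",
    allow_nonconverged: bool = False,
) -> Path:
    """Run the full analysis; returns the output directory.

    Writes analysis_table.csv, exclusions.csv, draws.csv, diagnostics.json,
    imputations.csv, table1.csv, fig2_summary.csv, and manifest.json.
    Raises :class:`ConvergenceError` (after writing diagnostics) if any
    core parameter has split R-hat above 1.1, unless ``allow_nonconverged``.
    """
    t0 = time.time()
    cfg = config if config is not None else load_config(config_path)
    base = Path(base_dir)
    outdir = base / cfg["output"]
    tables = validate_inputs(cfg, base)

    analysis, exclusions, predictors = prepare(cfg, tables)
    summaries = survey_summary(predictors)
    model = JointModel(
        analysis, predictors, summaries, phi_grouping=cfg["model"]["phi_grouping"]
    )
    sconf = sampler_config(cfg)
    draws = fit_joint(model, sconf)
    diag = diagnostics_summary(draws)

    outdir.mkdir(parents=True, exist_ok=True)
    analysis.to_csv(outdir / "analysis_table.csv", index=False, float_format="%.17g")
    exclusions.to_csv(outdir / "exclusions.csv", index=False)
    draws.to_dataframe().to_csv(outdir / "draws.csv", index=False, float_format="%.17g")
    with open(outdir / "diagnostics.json", "w") as fh:
        json.dump(diag, fh, indent=1, default=float)

    core = [n for n in draws.names if not n.startswith(("lkb_star", "lhr_star"))]
    bad = {
        n: diag["parameters"][n]["rhat"]
        for n in core
        if np.isfinite(diag["parameters"][n]["rhat"]) and diag["parameters"][n]["rhat"] > RHAT_LIMIT
    }
    if bad and not allow_nonconverged:
        raise ConvergenceError(f"split R-hat above {RHAT_LIMIT} for: {bad}")

    # imputations: one row per retained draw per imputed summer
    imp_rows = []
    lkb_names = [n for n in draws.names if n.startswith("lkb_star")]
    for name in lkb_names:
        key = name[len("lkb_star["):-1]
        stratum, year = key.split(",")
        lkb = draws.flat(name)
        lhr = draws.flat(f"lhr_star[{key}]")
        imp_rows.append(
            pd.DataFrame(
                {
                    "stratum": stratum,
                    "year": int(year),
                    "draw_index": np.arange(lkb.size),
                    "lkb_star_t": lkb,
                    "lhr_star": lhr,
                }
            )
        )
    if imp_rows:
        pd.concat(imp_rows, ignore_index=True).to_csv(
            outdir / "imputations.csv", index=False, float_format="%.17g"
        )

    rng = np.random.default_rng(np.random.SeedSequence([sconf.seed, 2027]))
    table1(draws, rng=rng).to_csv(outdir / "table1.csv", index=False, float_format="%.6g")
    fig2_summary(draws).to_csv(outdir / "fig2_summary.csv", index=False, float_format="%.6g")

    manifest = {
        "package_version": __version__,
        "seed": sconf.seed,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "config": cfg,
        "input_checksums": {n: _sha256(base / cfg["paths"][n]) for n in tables},
        "sampler_schedule": {
            "n_chains": sconf.n_chains,
            "n_adapt": sconf.n_adapt,
            "n_burnin": sconf.n_burnin,
            "n_keep_iterations": sconf.n_keep_iterations,
            "thin": sconf.thin,
            "n_retained_per_chain": sconf.n_retained,
        },
        "n_observations_modeled": int(model.n_obs_total),
        "n_observations_excluded": int(len(exclusions)),
        "n_imputed_summers": len(model.latents),
        "outputs": sorted(p.name for p in outdir.iterdir()),
        "wall_time_s": round(time.time() - t0, 2),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return outdir


def draws_from_csv(path: str | Path) -> PosteriorDraws:
    """Rebuild a :class:`PosteriorDraws` from a long-format draws.csv."""
    df = pd.read_csv(path)
    names = list(df["parameter"].drop_duplicates())
    chains = sorted(df["chain"].unique())
    n_iter = df["iteration"].max() + 1
    arr = np.empty((len(chains), n_iter, len(names)))
    for j, name in enumerate(names):
        sub = df[df["parameter"] == name]
        for c in chains:
            arr[c, :, j] = sub[sub["chain"] == c].sort_values("iteration")["value"].to_numpy()
    return PosteriorDraws(names, arr)
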