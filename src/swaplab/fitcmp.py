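"""Fit driver, information-criterion comparison, and the analysis pipeline.

Ties together the generator, the swap estimators, the Monte Carlo predictor
and the two generative models: fit every model to every dataset, compare by
AIC/BIC, and run the whole chain from a YAML config with cached, idempotent
stages.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__, interference, mc_predictor, nbm, swapest, taskgen

__all__ = ["aic", "bic", "FitResult", "compare", "run_pipeline",
           "fit_model", "PIPELINE_STAGES"]

log = logging.getLogger("swaplab")

MODEL_ORDER = ("nbm", "im_full", "im_partial")  # fixed tie-break order


def aic(loglik: float, k: int) -> float:
    """Akaike information criterion: 2k - 2 loglik."""
    if k < 0:
        raise ValueError("k must be nonnegative")
    return 2.0 * k - 2.0 * loglik


def bic(loglik: float, k: int, n: int) -> float:
    """Bayesian information criterion: k ln(n) - 2 loglik."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if k < 0:
        raise ValueError("k must be nonnegative")
    return k * np.log(n) - 2.0 * loglik


@dataclass
class FitResult:
    """One model fit to one dataset, with information criteria."""

    model: str
    params: dict
    loglik: float
    n_params: int
    n_obs: int
    seed: Optional[int] = None
    converged: bool = True
    aic: float = field(init=False)
    bic: float = field(init=False)

    def __post_init__(self):
        self.aic = aic(self.loglik, self.n_params)
        self.bic = bic(self.loglik, self.n_params, self.n_obs)


def fit_model(records, model: str, seed: int = 0, **kwargs) -> FitResult:
    """Fit one named model ('nbm', 'im_full' or 'im_partial') to records."""
    rng = np.random.default_rng(seed)
    if model == "nbm":
        res = nbm.fit_nbm(records, rng=rng, **kwargs)
        params = {"kappa_loc": res.params.kappa_loc,
                  "kappa_feat": res.params.kappa_feat,
                  "gain": res.params.gain,
                  "conjunction": dict(res.params.conjunction)}
        return FitResult(model=model, params=params, loglik=res.loglik,
                         n_params=res.n_params, n_obs=res.n_obs, seed=seed,
                         converged=res.converged)
    if model in ("im_full", "im_partial"):
        variant = model.split("_", 1)[1]
        res = interference.fit_im(records, variant=variant, rng=rng, **kwargs)
        params = {str(k): dataclasses.asdict(c["params"])
                  for k, c in res.cells.items()}
        fr = FitResult(model=model, params=params, loglik=res.loglik,
                       n_params=res.n_params, n_obs=res.n_obs, seed=seed,
                       converged=res.converged)
        fr.bic = res.bic  # per-cell n for the BIC penalty
        return fr
    raise ValueError(f"unknown model {model!r}")


def compare(fits: Dict[str, List[FitResult]]) -> dict:
    """AIC/BIC comparison across datasets.

    ``fits`` maps dataset name -> list of FitResult (same models for every
    dataset).  Returns a table of per-dataset deltas to the best model and
    per-model counts of datasets won under each criterion.  Ties are broken
    by the fixed model order and logged.
    """
    datasets = sorted(fits)
    if not datasets:
        raise ValueError("no fits to compare")
    models = [f.model for f in fits[datasets[0]]]
    for ds in datasets:
        if [f.model for f in fits[ds]] != models:
            raise ValueError(f"dataset {ds!r} missing some models")

    order = {m: (MODEL_ORDER.index(m) if m in MODEL_ORDER else len(MODEL_ORDER))
             for m in models}
    rows = []
    best_counts = {m: {"aic": 0, "bic": 0} for m in models}
    for ds in datasets:
        byname = {f.model: f for f in fits[ds]}
        for crit in ("aic", "bic"):
            vals = {m: getattr(byname[m], crit) for m in models}
            lo = min(vals.values())
            winners = [m for m in models if vals[m] <= lo + 1e-9]
            if len(winners) > 1:
                log.info("tie on %s for %s between %s; keeping %s order",
                         crit, ds, winners, MODEL_ORDER)
            best = min(winners, key=lambda m: order[m])
            best_counts[best][crit] += 1
            for m in models:
                rows.append({"dataset": ds, "model": m, "criterion": crit,
                             "value": vals[m], "delta": vals[m] - lo,
                             "best": m == best})
    table = pd.DataFrame(rows)
    summary = pd.DataFrame(
        [{"model": m,
          "mean_delta_aic": table.query("model == @m and criterion == 'aic'")["delta"].mean(),
          "mean_delta_bic": table.query("model == @m and criterion == 'bic'")["delta"].mean(),
          "n_best_aic": best_counts[m]["aic"],
          "n_best_bic": best_counts[m]["bic"]}
         for m in models])
    return {"table": table, "summary": summary}


# ---------------------------------------------------------------------------
# Pipeline

PIPELINE_STAGES = ("simulate", "estimate", "predict", "fit", "compare")

DEFAULT_CONFIG = {
    "seed": 0,
    "experiment": "exp1",
    "n_trials_per_level": 120,
    "generator": {
        "model": "nbm",
        "kappa_loc": 10.0, "kappa_feat": 5.0, "gain": 40.0,
        "conjunction": {"low": 0.3, "medium": 0.6, "high": 0.9},
    },
    "estimate": {"n_iter_expected": 200, "mixture_restarts": 5},
    "predict": {"n_iter": 1000},
    "fit": {"models": ["nbm", "im_full", "im_partial"],
            "nbm": {"maxiter": 300, "n_rounds": 2},
            "im": {"n_restarts": 2, "maxiter": 800}},
}


def _write_tsv(frame: pd.DataFrame, path: Path, seed: int) -> None:
    with open(path, "w") as fh:
        fh.write(f"# swaplab {__version__} seed={seed}\n")
        frame.to_csv(fh, sep="\t", index=False)


def _read_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def _experiment_config(cfg: dict, condition: str) -> taskgen.ExperimentConfig:
    name = cfg.get("experiment", "exp1")
    n = cfg.get("n_trials_per_level", 120)
    seed = cfg.get("seed", 0)
    if name == "exp1":
        return taskgen.exp1_config(condition, n_trials_per_level=n, seed=seed)
    if name == "exp2":
        cond = condition if condition != "orientation-report" else "direction-report"
        return taskgen.exp2_config(cond, n_trials_per_level=n, seed=seed)
    raise ValueError(f"pipeline supports exp1/exp2 generators, got {name!r}")


def _generator_params(cfg: dict):
    g = dict(cfg.get("generator", DEFAULT_CONFIG["generator"]))
    model = g.pop("model", "nbm")
    if model == "nbm":
        return model, nbm.NBMParams(kappa_loc=g["kappa_loc"],
                                    kappa_feat=g["kappa_feat"],
                                    gain=g["gain"],
                                    conjunction=dict(g["conjunction"]))
    if model == "mixture":
        return model, taskgen.MixtureGenParams(**g)
    raise ValueError(f"unsupported generator model {model!r}")


def _stage_simulate(cfg, outdir, rng):
    model, params = _generator_params(cfg)
    for condition in ("location-report", "orientation-report"):
        econf = _experiment_config(cfg, condition)
        trials = taskgen.generate_trials(econf)
        recs = taskgen.simulate_responses(trials, model, params, rng)
        taskgen.write_responses(recs, outdir / f"responses_{condition}.tsv")
    log.info("simulate: wrote response tables")


def _load_responses(outdir, condition):
    return taskgen.read_responses(outdir / f"responses_{condition}.tsv")


def _stage_estimate(cfg, outdir, rng):
    opts = cfg.get("estimate", DEFAULT_CONFIG["estimate"])
    econf = _experiment_config(cfg, "location-report")
    constraints = swapest.GeneratorConstraints(min_sep_rep=econf.min_sep_rep)
    rows = []
    for condition in ("location-report", "orientation-report"):
        recs = _load_responses(outdir, condition)
        by_level: dict = {}
        for r in recs:
            by_level.setdefault(r.trial.level, []).append(r)
        for level, sub in sorted(by_level.items()):
            est, _ = swapest.nearest_item_swaps(sub)
            rows.append({"condition": condition, "level": level,
                         "method": "nearest_item", "proportion": est.proportion,
                         "n": est.n_trials})
            mix = swapest.fit_mixture(sub, n_restarts=opts.get("mixture_restarts", 5),
                                      rng=rng)
            rows.append({"condition": condition, "level": level,
                         "method": "mixture", "proportion": mix.p_nontarget,
                         "n": mix.n_trials})
            rv = swapest.resultant_vector_estimate(sub, constraints)
            rows.append({"condition": condition, "level": level,
                         "method": "resultant_vector",
                         "proportion": rv["p_nontarget"], "n": rv["n_trials"]})
    _write_tsv(pd.DataFrame(rows), outdir / "estimates.tsv", cfg.get("seed", 0))
    log.info("estimate: wrote estimates.tsv")


def _stage_predict(cfg, outdir, rng):
    opts = cfg.get("predict", DEFAULT_CONFIG["predict"])
    report_recs = _load_responses(outdir, "orientation-report")
    pools: dict = {}
    for r in report_recs:
        pools.setdefault(r.trial.level, []).append(r.error_to_target)
    pool_objs = mc_predictor.pools_from_errors(pools)
    loc_recs = _load_responses(outdir, "location-report")
    trials = [r.trial for r in loc_recs]
    pred = mc_predictor.predict_swaps(trials, pool_objs,
                                      n_iter=opts.get("n_iter", 1000), rng=rng)
    rows = [{"level": lvl, **vals} for lvl, vals in sorted(pred.items())]
    _write_tsv(pd.DataFrame(rows), outdir / "predictions.tsv", cfg.get("seed", 0))
    log.info("predict: wrote predictions.tsv")


def _stage_fit(cfg, outdir, rng):
    opts = cfg.get("fit", DEFAULT_CONFIG["fit"])
    recs = (_load_responses(outdir, "location-report")
            + _load_responses(outdir, "orientation-report"))
    seed = cfg.get("seed", 0)
    results = {}
    for model in opts.get("models", ["nbm", "im_full", "im_partial"]):
        kwargs = dict(opts.get("nbm", {})) if model == "nbm" else dict(opts.get("im", {}))
        res = fit_model(recs, model, seed=seed, **kwargs)
        results[model] = dataclasses.asdict(res)
        log.info("fit %s: loglik %.2f aic %.1f bic %.1f", model, res.loglik,
                 res.aic, res.bic)
    with open(outdir / "fits.json", "w") as fh:
        json.dump({"seed": seed, "version": __version__, "fits": results}, fh,
                  indent=2, default=str)


def _stage_compare(cfg, outdir, rng):
    with open(outdir / "fits.json") as fh:
        payload = json.load(fh)
    fits = {"dataset": [
        FitResult(model=m, params=d["params"], loglik=d["loglik"],
                  n_params=d["n_params"], n_obs=d["n_obs"], seed=d["seed"],
                  converged=d["converged"])
        for m, d in payload["fits"].items()]}
    # keep the stored (per-cell) BIC rather than the recomputed pooled one
    for fr, (m, d) in zip(fits["dataset"], payload["fits"].items()):
        fr.bic = d["bic"]
    out = compare(fits)
    _write_tsv(out["summary"], outdir / "comparison.tsv", cfg.get("seed", 0))
    log.info("compare: wrote comparison.tsv")


_STAGE_FUNCS = {"simulate": _stage_simulate, "estimate": _stage_estimate,
                "predict": _stage_predict, "fit": _stage_fit,
                "compare": _stage_compare}

_STAGE_OUTPUTS = {
    "simulate": ["responses_location-report.tsv",
                 "responses_orientation-report.tsv"],
    "estimate": ["estimates.tsv"],
    "predict": ["predictions.tsv"],
    "fit": ["fits.json"],
    "compare": ["comparison.tsv"],
}


def run_pipeline(config, outdir) -> Path:
    """Run simulate -> estimate -> predict -> fit -> compare.

    ``config`` is a dict or a path to a YAML file; missing keys fall back
    to the demo defaults.  Stages whose outputs already exist are skipped,
    but once any stage runs, everything downstream is recomputed, so
    deleting one intermediate invalidates only later stages.  A failure
    aborts the remaining stages with the stage name in the raised error.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    log.info("pipeline start: swaplab %s seed=%s", __version__, cfg["seed"])

    rng = np.random.default_rng(cfg["seed"])
    dirty = False
    try:
        for stage in PIPELINE_STAGES:
            outputs = [outdir / f for f in _STAGE_OUTPUTS[stage]]
            if not dirty and all(p.exists() for p in outputs):
                log.info("%s: cached, skipping", stage)
                continue
            dirty = True
            try:
                _STAGE_FUNCS[stage](cfg, outdir, rng)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()
    return outdir
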