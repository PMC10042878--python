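"""End-to-end orchestration: coding -> covariates -> dependence -> model.

`assemble_model_data` is the workhorse: it codes the raw table, attaches
covariates, intersects with the tree, drops societies with any missing
model variable (no imputation — rows incomplete for the chosen response or
covariates are excluded, mirroring the study's pruning), and returns
aligned design inputs.  `run_pipeline` wraps it per response and writes
machine-readable summaries plus a reproducibility manifest.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .coding import MAIN_FUNCTIONS, code_table, count_report, filter_societies
from .covariates import farming_propensity
from .dependence import (
    LabelledCovariance,
    MaternParams,
    brownian_vcv,
    matern_cov,
    prune_and_match,
    scale_covariance,
)
from .io import file_sha256, write_fit_json
from .model import (
    McmcConfig,
    Priors,
    bayes_r2,
    build_design,
    fit_model,
    flag_effects,
    variance_components,
)

__all__ = ["attach_covariates", "assemble_model_data", "fit_response", "run_pipeline"]

RESPONSES = ("positive_care", "negative_treatment", "personhood")
COVARIATE_NAMES = ("farming_propensity", "husbandry", "temperature", "paragraph_count")


def attach_covariates(raw: pd.DataFrame, coded: pd.DataFrame, *, pca_runs: int = 500,
                      seed: int = 7) -> tuple[pd.DataFrame, dict]:
    """Add farming propensity and husbandry midpoint to a coded table."""
    fp = farming_propensity(raw, n_runs=pca_runs, rng=seed)
    out = coded.copy()
    out["farming_propensity"] = fp.scores.to_numpy()
    out["husbandry"] = (
        raw["dep_husbandry_lo"].to_numpy(float) + raw["dep_husbandry_hi"].to_numpy(float)
    ) / 2.0
    pca_report = {
        "n_runs": fp.n_runs,
        "seed": fp.seed,
        "mean_agriculture_loading": fp.mean_agriculture_loading,
        "sd_agriculture_loading": fp.sd_agriculture_loading,
        "mean_variance_explained": fp.mean_variance_explained,
        "sd_variance_explained": fp.sd_variance_explained,
    }
    return out, pca_report


def assemble_model_data(
    table: pd.DataFrame,
    tree,
    response: str,
    predictors,
    *,
    matern: MaternParams | None = None,
    metric: str = "euclidean",
    covariance_scaling: str = "unit_diagonal_max",
):
    """Aligned (data, X, names, y, C_phylo, C_spatial) for one response model.

    Societies must have all five mains coded, a tree tip, and non-missing
    values for the response and every predictor.
    """
    if response not in RESPONSES:
        raise ValueError(f"unknown response {response!r}")
    sub = filter_societies(table, "all_mains_non_missing")
    sub = sub[sub[response] != "missing"]
    for p in predictors:
        if p in MAIN_FUNCTIONS or p == "n_functions":
            continue
        sub = sub[pd.to_numeric(sub[p], errors="coerce").notna()]
    pruned_tree, sub, dropped = prune_and_match(tree, sub)
    sub = sub.reset_index(drop=True)

    y = (sub[response] == "present").astype(float).to_numpy()
    work = sub.copy()
    if "n_functions" in predictors:
        work["n_functions"] = pd.to_numeric(work["n_functions"])
    for c in COVARIATE_NAMES:
        if c in predictors:
            work[c] = pd.to_numeric(work[c])
    X, names = build_design(work, predictors)

    C_phylo = scale_covariance(
        brownian_vcv(pruned_tree), covariance_scaling
    )
    tip_to_sid = dict(zip(sub["tip_label"], sub["society_id"]))
    C_phylo = LabelledCovariance(
        labels=[tip_to_sid[l] for l in C_phylo.labels],
        matrix=C_phylo.matrix, kind="phylogenetic", params=C_phylo.params,
    ).reorder(sub["society_id"].tolist())
    C_spatial = scale_covariance(
        matern_cov(sub[["latitude", "longitude"]].astype(float),
                   matern or MaternParams(), metric=metric,
                   labels=sub["society_id"].tolist()),
        covariance_scaling,
    )
    return sub, X, names, y, C_phylo, C_spatial


def fit_response(
    table, tree, response, predictors, *, matern=None, metric="euclidean",
    priors: Priors = Priors(), mcmc: McmcConfig = McmcConfig(),
) -> dict:
    """Fit one response model and summarise it as a JSON-ready dict."""
    sub, X, names, y, Cp, Cs = assemble_model_data(
        table, tree, response, predictors, matern=matern, metric=metric
    )
    fit = fit_model(y, X, names, Cp, Cs, priors=priors, mcmc=mcmc)
    draws = fit.flat(fit.beta)
    flags = flag_effects(fit)
    coef = []
    for j, name in enumerate(names):
        d = draws[:, j]
        coef.append({
            "parameter": name,
            "mean": float(d.mean()),
            "q2.5": float(np.percentile(d, 2.5)),
            "q50": float(np.percentile(d, 50)),
            "q97.5": float(np.percentile(d, 97.5)),
            "posterior_mass_above_zero": flags[j].posterior_mass_above_zero,
            "flag": flags[j].flag,
        })
    return {
        "response": response,
        "n": int(len(y)),
        "predictors": list(predictors),
        "coefficients": coef,
        "variance_components": variance_components(fit),
        "r2": {
            "marginal": bayes_r2(fit, "marginal"),
            "conditional": bayes_r2(fit, "conditional"),
        },
        "diagnostics": {
            "max_rhat": float(fit.diagnostics["rhat"].max()),
            "min_ess": float(fit.diagnostics["ess"].min()),
            "ok": fit.diagnostics_ok(),
            "accept_rate": fit.accept_rate,
        },
        "seed": fit.seed,
    }


def run_pipeline(config: dict, *, raw=None, tree=None) -> dict:
    """Execute the full pipeline per the config; write reports and manifest.

    ``raw``/``tree`` may be passed directly (already loaded) or read from
    the paths in the config.
    """
    from .io import read_newick, read_society_csv

    t0 = time.time()
    out_dir = Path(config.get("output_dir", "."))
    out_dir.mkdir(parents=True, exist_ok=True)
    if raw is None:
        raw = read_society_csv(config["data_csv"])
    if tree is None:
        tree = read_newick(config["tree_newick"])

    coded = code_table(raw)
    counts = count_report(coded)
    seed = int(config.get("seed", 7))
    table, pca_report = attach_covariates(
        raw, coded, pca_runs=int(config.get("pca_runs", 500)), seed=seed
    )

    matern_cfg = config.get("matern", {})
    matern = MaternParams(
        smoothness=float(matern_cfg.get("smoothness", 1.0)),
        variance=float(matern_cfg.get("variance", 1.0)),
        range_=float(matern_cfg.get("range", 1.0)),
    )
    mcmc_cfg = config.get("mcmc", {})
    mcmc = McmcConfig(
        chains=int(mcmc_cfg.get("chains", 4)),
        iterations=int(mcmc_cfg.get("iterations", 2000)),
        seed=seed,
    )
    priors_cfg = config.get("priors", {})
    priors = Priors(
        beta_scale=float(priors_cfg.get("beta_scale", 5.0)),
        sigma_rate=float(priors_cfg.get("sigma_rate", 1.0)),
    )
    predictors = config.get(
        "predictors", ["n_functions", *COVARIATE_NAMES]
    )
    responses = config.get("responses", list(RESPONSES))

    fits = {}
    for resp in responses:
        fits[resp] = fit_response(
            table, tree, resp, predictors,
            matern=matern, metric=config.get("metric", "euclidean"),
            priors=priors, mcmc=mcmc,
        )
        write_fit_json(fits[resp], out_dir / f"fit_{resp}.json")

    summary = {"counts": counts, "pca": pca_report, "fits": fits}
    write_fit_json(summary, out_dir / "summary.json")
    manifest = {
        "version": __version__,
        "seed": seed,
        "config": {k: v for k, v in config.items()},
        "inputs": {
            k: file_sha256(config[k])
            for k in ("data_csv", "tree_newick")
            if isinstance(config.get(k), (str, Path)) and Path(config[k]).exists()
        },
        "runtime_seconds": round(time.time() - t0, 2),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return summary
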