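"""End-to-end pipeline: simulate -> screen -> fit -> infer -> recover.

Driven by one config dict (or YAML file); every stage logs its seed, writes
plain-text artifacts under the output directory, and a failure in any stage
halts with the stage name while partial outputs remain on disk.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import gibbs, inference, io, synthetic
from .models import MCMCConfig, ModelSpec, PriorConfig

log = logging.getLogger("trapme")


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        return wrapped
    return deco


def _simulation_config(cfg: dict, seed: int) -> synthetic.SimulationConfig:
    sim = dict(cfg.get("simulate", {}))
    sim.setdefault("seed", seed)
    for key in ("Sigma_Z", "Sigma_e", "beta_expo", "error_cov"):
        if key in sim and isinstance(sim[key], list):
            sim[key] = np.asarray(sim[key], dtype=float)
    if "pollutants" in sim:
        sim["pollutants"] = tuple(sim["pollutants"])
    return synthetic.SimulationConfig(**sim)


def run_pipeline(config: dict | str, out_dir) -> dict:
    """Run the configured stages; returns a dict of artifact paths.

    Config keys: ``seed``, ``simulate`` (generator settings or ``data: path``
    to load an existing dataset), ``screen`` ({pollutant, threshold}),
    ``fit`` ({variant, features, pollutants, priors, mcmc}), ``infer``
    ({level}), ``recover`` (bool — compare posteriors against the synthetic
    truth and report bias/coverage/interval widths).
    """
    if not isinstance(config, dict):
        config = io.load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    log.info("pipeline start (seed=%d, out=%s)", seed, out)
    artifacts: dict = {}

    # --- simulate or load -------------------------------------------------
    truth = None
    if "data" in config.get("simulate", {}):
        ds = _stage("simulate")(io.read_dataset)(config["simulate"]["data"])
    else:
        sim_cfg = _simulation_config(config, seed)
        ds, truth = _stage("simulate")(synthetic.simulate_dataset)(sim_cfg)
        log.info("simulated %d records x %d features (seed=%d)",
                 ds.n_records, len(ds.feature_ids), sim_cfg.seed)
    artifacts.update(_stage("simulate")(io.write_dataset)(ds, out / "data", truth))

    # --- screen -----------------------------------------------------------
    scr = config.get("screen")
    features = ds.feature_ids
    if scr:
        features = _stage("screen")(inference.screen_features)(
            ds, scr["pollutant"], scr.get("threshold", 0.5)
        )
        pd.Series(features, name="feature_id").to_csv(out / "screened_features.csv", index=False)
        artifacts["screened_features"] = str(out / "screened_features.csv")
        log.info("screen kept %d/%d features", len(features), len(ds.feature_ids))

    # --- fit --------------------------------------------------------------
    fit_cfg = config.get("fit", {})
    variant = fit_cfg.get("variant", "naive_uni")
    pollutants = list(fit_cfg.get("pollutants", [ds.pollutants[0]]))
    fit_features = list(fit_cfg.get("features", features))
    if variant.endswith("_uni"):
        fit_features = fit_features[:1]
    max_f = fit_cfg.get("max_features")
    if max_f:
        fit_features = fit_features[:max_f]
    priors = PriorConfig(**fit_cfg.get("priors", {}))
    mcmc = MCMCConfig(**{"seed": seed, **fit_cfg.get("mcmc", {})})
    spec = ModelSpec(
        variant=variant, feature_ids=fit_features, pollutant_ids=pollutants, priors=priors
    )
    log.info("fitting %s on %d feature(s) x %d pollutant(s) (seed=%d)",
             variant, len(fit_features), len(pollutants), mcmc.seed)
    draws = _stage("fit")(gibbs.fit)(ds, spec, mcmc)
    artifacts.update(_stage("fit")(io.write_draws)(draws, out / "draws"))

    # --- infer ------------------------------------------------------------
    level = config.get("infer", {}).get("level", 0.05)
    table = _stage("infer")(inference.summarize)(draws, level)
    table.to_csv(out / "association.csv", index=False)
    artifacts["association"] = str(out / "association.csv")
    diag = _stage("infer")(inference.diagnostics)(draws)
    diag.to_csv(out / "diagnostics.csv", index=False)
    diag.to_json(out / "diagnostics.json", orient="records", indent=1)
    artifacts["diagnostics"] = str(out / "diagnostics.csv")

    # --- recover ----------------------------------------------------------
    if config.get("recover") and truth is not None:
        rep = _stage("recover")(recovery_report)(draws, ds, truth)
        rep.to_csv(out / "recovery.csv", index=False)
        artifacts["recovery"] = str(out / "recovery.csv")

    artifacts["manifest"] = io.write_manifest(
        out, config, seed, inputs={k: v for k, v in artifacts.items() if str(v).endswith(".csv")}
    )
    log.info("pipeline done: %d artifacts", len(artifacts))
    return artifacts


def recovery_report(draws, ds, truth) -> pd.DataFrame:
    """Posterior-vs-truth comparison: bias, coverage and CrI width per coefficient."""
    rows = []
    pol_index = {p: i for i, p in enumerate(truth.pollutants)}
    feat_index = {f: i for i, f in enumerate(ds.feature_ids)}
    for pi, pol in enumerate(draws.pollutant_ids):
        for fi, f in enumerate(draws.feature_ids):
            b = draws.stacked("beta_expo")[:, pi, fi]
            true_b = truth.beta_expo[feat_index[f], pol_index[pol]]
            lo, hi = np.quantile(b, [0.025, 0.975])
            rows.append(
                {
                    "feature_id": f,
                    "pollutant_id": pol,
                    "model_variant": draws.spec.variant,
                    "true_beta": true_b,
                    "posterior_mean": float(b.mean()),
                    "bias": float(b.mean() - true_b),
                    "cri_lower_95": float(lo),
                    "cri_upper_95": float(hi),
                    "cri_width": float(hi - lo),
                    "covered": bool(lo <= true_b <= hi),
                }
            )
    return pd.DataFrame(rows)


def plot_coefficients(tables: dict[str, pd.DataFrame], path) -> None:
    """Interval plot of exposure coefficients for one or more model variants."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    offset = 0.0
    for label, tab in tables.items():
        ypos = np.arange(len(tab)) + offset
        ax.errorbar(
            tab["posterior_mean"], ypos,
            xerr=[tab["posterior_mean"] - tab["cri_lower_95"],
                  tab["cri_upper_95"] - tab["posterior_mean"]],
            fmt="o", capsize=3, label=label,
        )
        offset += 0.2
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_yticks(np.arange(len(next(iter(tables.values())))))
    ax.set_yticklabels(
        next(iter(tables.values()))["feature_id"] + ":" +
        next(iter(tables.values()))["pollutant_id"]
    )
    ax.set_xlabel("exposure coefficient (95% CrI)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
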