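"""Scenario-grid orchestration and tidy summary tables.

``run_grid`` expands a configuration into a grid of collapse scenarios
(ancestral size x bottleneck size x migration rate), simulates each with
:func:`erosim.engine.run_scenario`, and returns one tidy row per scenario x
replicate x time bin together with per-scenario summaries (means and 95%
percentile intervals).  Change columns (percentage diversity loss, increase
in F_ROH, relative increase in realized load) are computed against the same
replicate's historical bin, and the closed-form drift expectation
``expected_loss_pct`` is attached to every row for comparison.
"""

from __future__ import annotations

import itertools
import logging
from copy import deepcopy

import numpy as np
import pandas as pd
import yaml

from . import drift_debt
from .demography import BIN_LABELS, Scenario, Timeline
from .engine import run_scenario
from .genome_model import ConfigurationError, DFESpec, GenomeArchitecture

__all__ = ["DEFAULT_CONFIG", "load_config", "run_grid", "summarize_grid", "plot_grid_summary"]

log = logging.getLogger("erosim")

#: stable, versioned output schema
SCHEMA_VERSION = "1"

DEFAULT_CONFIG: dict = {
    "grid": {
        "n_anc": [12_000],
        "n_bot": [1000, 100, 50],
        "migration_rate": [0.02],
    },
    "scenario": {
        "decline_generations": 15,
        "n_demes": 3,
        "post_decline_generations": 35,
        "decline_shape": "exponential",
    },
    "genome": {
        "template": "exome",
        "n_genes": 30_000,
        "gene_length": 400,
        "boundary_crossover_prob": 1e-4,
    },
    "dfe": {
        "mutation_rate_per_bp": 2.30e-9,
        "p_deleterious": 2.3 / 3.3,
        "gamma_shape": 0.186,
        "gamma_mean_s": -0.01315,
        "dominance_rule": "inverse",
    },
    "timeline": {"generation_time": 3.4, "onset_year": 1948},
    "init": {"mode": "analytic", "rescale_lambda": 1.0, "burn_in_generations": None},
    "sampling": {
        "sample_size": 20,
        "replicates": 20,
        "bins": list(BIN_LABELS),
        "compute_roh": True,
    },
    "seed": 0,
}


def _merge(base: dict, override: dict) -> dict:
    out = deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | None = None, overrides: dict | None = None) -> dict:
    """Defaults, optionally overridden by a YAML file and/or a dict."""
    cfg = deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            cfg = _merge(cfg, yaml.safe_load(fh) or {})
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def build_objects(cfg: dict):
    """(architecture, dfe, timeline) from a resolved configuration."""
    gcfg = dict(cfg["genome"])
    template = gcfg.pop("template", "exome")
    if template != "exome":
        raise ConfigurationError(
            f"genome template {template!r} requires a user-supplied annotation; "
            "only the uniform exome template is bundled"
        )
    arch = GenomeArchitecture(**gcfg)
    dfe = DFESpec(**cfg["dfe"])
    timeline = Timeline(**cfg["timeline"])
    return arch, dfe, timeline


def run_grid(cfg: dict, seed: int | None = None):
    """Run the scenario grid; returns (rows, summary) DataFrames.

    Invalid scenario combinations are logged and skipped.  ``seed``
    overrides ``cfg['seed']``.
    """
    arch, dfe, timeline = build_objects(cfg)
    master = np.random.default_rng(cfg["seed"] if seed is None else seed)
    scen_cfg = cfg["scenario"]
    samp = cfg["sampling"]
    init = cfg["init"]
    combos = list(
        itertools.product(
            cfg["grid"]["n_anc"], cfg["grid"]["n_bot"], cfg["grid"]["migration_rate"]
        )
    )
    frames = []
    for (n_anc, n_bot, m), rng in zip(combos, master.spawn(len(combos))):
        try:
            scenario = Scenario(
                n_anc=n_anc, n_bot=n_bot, migration_rate=m, **scen_cfg
            )
        except (ConfigurationError, ValueError) as exc:
            log.warning(
                "skipping scenario n_anc=%s n_bot=%s m=%s: %s", n_anc, n_bot, m, exc
            )
            continue
        log.info("running scenario n_anc=%s n_bot=%s m=%s", n_anc, n_bot, m)
        df = run_scenario(
            scenario,
            timeline,
            arch,
            dfe,
            sample_size=samp["sample_size"],
            replicates=samp["replicates"],
            rng=rng,
            init_mode=init["mode"],
            rescale_lambda=init.get("rescale_lambda", 1.0),
            burn_in_generations=init.get("burn_in_generations"),
            bins=tuple(samp["bins"]),
            compute_roh=samp.get("compute_roh", True),
        )
        df["n_anc"] = n_anc
        df["n_bot"] = n_bot
        df["migration_rate"] = m
        for key, val in scen_cfg.items():
            df[key] = val
        df["expected_loss_pct"] = df["bin"].map(
            lambda b: drift_debt.expected_loss_for_scenario(scenario, timeline, b)
        )
        frames.append(df)
    if not frames:
        raise ConfigurationError("no valid scenario in the grid")
    rows = pd.concat(frames, ignore_index=True)

    # change columns relative to the same replicate's historical bin
    keys = ["n_anc", "n_bot", "migration_rate", "replicate"]
    hist = (
        rows[rows["bin"] == "historical"]
        .set_index(keys)[["f_roh", "realized_load"]]
        .rename(columns={"f_roh": "_f0", "realized_load": "_r0"})
    )
    rows = rows.join(hist, on=keys)
    rows["d_froh"] = rows["f_roh"] - rows["_f0"]
    with np.errstate(divide="ignore", invalid="ignore"):
        rows["d_realized_load_pct"] = np.where(
            rows["_r0"] > 0,
            100.0 * (rows["realized_load"] - rows["_r0"]) / rows["_r0"],
            np.nan,
        )
    rows = rows.drop(columns=["_f0", "_r0"])
    rows["schema_version"] = SCHEMA_VERSION
    return rows, summarize_grid(rows)


def summarize_grid(rows: pd.DataFrame) -> pd.DataFrame:
    """Per scenario x bin means and 95% percentile intervals over replicates."""
    metrics = [
        "pct_loss",
        "d_froh",
        "d_realized_load_pct",
        "lethal_equivalents",
        "mean_H",
        "f_roh",
        "realized_load",
        "masked_load",
        "expected_loss_pct",
    ]
    keys = ["n_anc", "n_bot", "migration_rate", "bin"]

    def agg(group: pd.DataFrame) -> pd.Series:
        out = {}
        for mcol in metrics:
            vals = group[mcol].dropna().to_numpy()
            out[f"{mcol}_mean"] = vals.mean() if vals.size else np.nan
            out[f"{mcol}_lo"] = np.percentile(vals, 2.5) if vals.size else np.nan
            out[f"{mcol}_hi"] = np.percentile(vals, 97.5) if vals.size else np.nan
        out["n_replicates"] = group["replicate"].nunique()
        return pd.Series(out)

    summary = (
        rows.groupby(keys, sort=False).apply(agg, include_groups=False).reset_index()
    )
    summary["schema_version"] = SCHEMA_VERSION
    return summary


def plot_grid_summary(summary: pd.DataFrame, path: str | None = None):
    """Three-panel summary figure: diversity loss, dF_ROH and realized-load
    increase across time bins, one line per scenario."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    panels = [
        ("pct_loss_mean", "% diversity loss"),
        ("d_froh_mean", "increase in F_ROH"),
        ("d_realized_load_pct_mean", "% increase in realized load"),
    ]
    order = [b for b in BIN_LABELS if b in set(summary["bin"])]
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5), sharex=True)
    for ax, (col, label) in zip(axes, panels):
        for (n_anc, n_bot, m), grp in summary.groupby(
            ["n_anc", "n_bot", "migration_rate"]
        ):
            grp = grp.set_index("bin").reindex(order)
            ax.plot(order, grp[col], marker="o", label=f"{n_anc}→{n_bot}, m={m}")
        ax.set_ylabel(label)
        ax.set_xlabel("time bin")
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
    return fig
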