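"""End-to-end pipeline orchestration and report rendering.

``run_pipeline`` chains validate -> call -> rates -> control -> model ->
contrasts -> render, persisting every stage's output, and aborts with the
stage name on the first hard error.  ``render_report`` draws the per-brood
smoothed-rate panels (both treatments overlaid with replicate-variability
bands, asterisks at significant temperature contrasts) and exports the
mixed-model ANOVA as CSV.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import control as ctl
from . import crossovers as xod
from . import io as gio
from . import rates as rt
from .model import PlasticityModel
from .simulate import SimConfig, simulate_experiment

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str, artifacts: dict | None = None):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.artifacts = dict(artifacts or {})


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_pipeline(config: dict) -> dict:
    """Run the whole analysis from a run-config mapping.

    The config supplies exactly one of:

    * ``data``: {"marker_map": path, "genotypes": path}
    * ``sim``: keyword arguments for :class:`recplast.simulate.SimConfig`

    plus optional keys ``out_dir`` (default "recplast_out"), ``seed``
    (overrides the sim seed), ``adjust`` ("bh"|"none"),
    ``mask_tight_doubles`` (bool, default True), ``aggregate`` (mapping of
    brood -> period label), ``bins_cM`` (list of bin edges),
    ``min_informative_fraction``.

    Returns a dict of artifact paths.
    """
    artifacts: dict = {}
    out_dir = Path(config.get("out_dir", "recplast_out"))
    out_dir.mkdir(parents=True, exist_ok=True)

    def fail(stage, exc):
        raise PipelineError(stage, str(exc), artifacts) from exc

    has_data = "data" in config
    has_sim = "sim" in config
    if has_data == has_sim:
        raise PipelineError("config", "supply exactly one of 'data' or 'sim'")

    # persist the fully resolved configuration (including defaults taken for
    # every unspecified option) so each run is auditable
    resolved = {
        "input_mode": "data" if has_data else "sim",
        "adjust": config.get("adjust", "bh"),
        "mask_tight_doubles": bool(config.get("mask_tight_doubles", True)),
        "min_informative_fraction": float(config.get("min_informative_fraction", 0.5)),
        "aggregate": config.get("aggregate"),
        "bins_cM": config.get("bins_cM"),
    }
    if has_data:
        resolved["data"] = {k: str(v) for k, v in config["data"].items()}
    else:
        sim_kwargs_resolved = dict(config["sim"])
        if "seed" in config:
            sim_kwargs_resolved["seed"] = int(config["seed"])
        resolved["sim"] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(SimConfig(**sim_kwargs_resolved)).items()
            if k != "marker_map"
        }
    config_path = out_dir / "run_config.json"
    config_path.write_text(
        json.dumps(resolved, indent=2, sort_keys=True, default=_json_default) + "\n",
        encoding="utf-8",
    )
    artifacts["config"] = str(config_path)

    # --- load or simulate -------------------------------------------------
    try:
        if has_data:
            map_path = Path(config["data"]["marker_map"])
            geno_path = Path(config["data"]["genotypes"])
            for p in (map_path, geno_path):
                if not p.exists():
                    raise FileNotFoundError(f"input file not found: {p}")
            mmap = gio.read_marker_map(map_path)
            table = gio.read_progeny_table(geno_path, mmap)
        else:
            sim_kwargs = dict(config["sim"])
            if "seed" in config:
                sim_kwargs["seed"] = int(config["seed"])
            sim = simulate_experiment(SimConfig(**sim_kwargs))
            paths = sim.write(out_dir / "sim")
            artifacts.update({f"sim_{k}": str(v) for k, v in paths.items()})
            mmap, table = sim.marker_map, sim.progeny_table
    except PipelineError:
        raise
    except Exception as exc:
        fail("load", exc)

    # --- validate ---------------------------------------------------------
    try:
        report = gio.validation_report(mmap, table)
        val_path = out_dir / "validation.txt"
        val_path.write_text(report + "\n", encoding="utf-8")
        artifacts["validation"] = str(val_path)
    except Exception as exc:
        fail("validate", exc)

    # --- call crossovers --------------------------------------------------
    try:
        if config.get("mask_tight_doubles", True):
            calls, geno, n_flagged = xod.apply_tight_double_filter(table)
        else:
            calls, geno, n_flagged = xod.call_all(table), table.genotypes, 0
        xo_path = out_dir / "crossovers.csv"
        xod.crossover_table(calls).to_csv(xo_path, index=False)
        artifacts["crossovers"] = str(xo_path)
    except Exception as exc:
        fail("call", exc)

    # --- rates ------------------------------------------------------------
    try:
        minf = float(config.get("min_informative_fraction", 0.5))
        counts = xod.count_recombinants(table, genotypes=geno, min_informative_fraction=minf)
        rates = rt.estimate_rates(counts)
        if config.get("aggregate"):
            scheme = {int(k): v for k, v in config["aggregate"].items()}
            rates_out = rt.aggregate_broods(rates, scheme)
        else:
            rates_out = rates
        rates_path = out_dir / "rates.csv"
        gio.write_rate_table(rates_out, rates_path)
        artifacts["rates"] = str(rates_path)
        curves = rt.loess_neighbours(rates_out)
        curves_path = out_dir / "curves.csv"
        curves.sort_values(["treatment", "brood", "midpoint_mb"]).to_csv(
            curves_path, index=False, float_format="%.17g"
        )
        artifacts["curves"] = str(curves_path)
    except Exception as exc:
        fail("rates", exc)

    # --- crossover control ------------------------------------------------
    try:
        pooled = (
            counts.groupby("interval")[["n_recombinant", "n_total"]].sum().sort_index()
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            pooled_cM = (100.0 * pooled["n_recombinant"] / pooled["n_total"]).fillna(0.0).to_numpy()
        bins = config.get("bins_cM")
        control = ctl.control_report(
            table, calls, mmap.intervals(), pooled_cM,
            None if bins is None else np.asarray(bins, float),
        )
        control_path = out_dir / "control.json"
        control_path.write_text(
            json.dumps(control, indent=2, sort_keys=True, default=_json_default) + "\n",
            encoding="utf-8",
        )
        artifacts["control"] = str(control_path)
    except Exception as exc:
        fail("control", exc)

    # --- mixed model ------------------------------------------------------
    try:
        model = PlasticityModel.from_rate_table(rates_out)
        res = model.fit()
        lrt_stat, lrt_df, lrt_p = res.lrt_vs_null()
        fit_info = {
            "sigma2": res.sigma2,
            "sigma2_rep": res.sigma2_rep,
            "llf_reml": res.llf_reml,
            "llf_ml": res.llf_ml,
            "boundary": res.boundary,
            "lrt": {"statistic": lrt_stat, "df": lrt_df, "p_value": lrt_p},
            "fe_params": res.fe_params.to_dict(),
        }
        fit_path = out_dir / "fit.json"
        fit_path.write_text(
            json.dumps(fit_info, indent=2, sort_keys=True, default=_json_default) + "\n",
            encoding="utf-8",
        )
        artifacts["fit"] = str(fit_path)
        anova = res.anova()
        anova_path = out_dir / "anova.csv"
        anova.rename(
            columns={
                "sum_sq": "sum of squares",
                "mean_sq": "mean square",
                "num_df": "numerator d.f.",
                "den_df": "denominator d.f.",
                "p_value": "P",
            }
        ).to_csv(anova_path, float_format="%.17g")
        artifacts["anova"] = str(anova_path)
        contrasts = res.contrasts(adjust=config.get("adjust", "bh"))
        contrasts_path = out_dir / "contrasts.csv"
        contrasts.to_csv(contrasts_path, index=False, float_format="%.17g")
        artifacts["contrasts"] = str(contrasts_path)
    except Exception as exc:
        fail("model", exc)

    # --- render -----------------------------------------------------------
    try:
        fig_path = render_report(curves, contrasts, control, anova, out_dir)
        artifacts["figure"] = str(fig_path)
    except Exception as exc:
        fail("render", exc)
    return artifacts


def render_report(curves: pd.DataFrame, contrasts: pd.DataFrame, control: dict,
                  anova: pd.DataFrame, out_dir, alpha: float = 0.05) -> Path:
    """Draw the per-brood smoothed-rate panels with contrast flags.

    One panel per brood (or aggregated period): both treatments' smoothed
    cM/Mb curves with +-SE replicate-variability bands, and an asterisk at
    every position whose adjusted temperature contrast is below ``alpha``.
    Returns the figure path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    broods = sorted(curves["brood"].unique()) if len(curves) else []
    n_panels = max(len(broods), 1)
    fig, axes = plt.subplots(
        1, n_panels, figsize=(4 * n_panels, 3.2), sharey=True, squeeze=False
    )
    colors = {}
    palette = ["#1f77b4", "#d62728", "#2ca02c", "#9467bd"]
    for ax, brood in zip(axes[0], broods or [None]):
        if brood is None:
            ax.set_title("no data")
            continue
        sub = curves[curves["brood"] == brood]
        for trt, tsub in sub.groupby("treatment"):
            colors.setdefault(trt, palette[len(colors) % len(palette)])
            tsub = tsub.sort_values("midpoint_mb")
            ax.plot(tsub["midpoint_mb"], tsub["smoothed"], label=str(trt), color=colors[trt])
            ax.fill_between(
                tsub["midpoint_mb"],
                tsub["smoothed"] - tsub["se"],
                tsub["smoothed"] + tsub["se"],
                alpha=0.25,
                color="grey",
                linewidth=0,
            )
        if len(contrasts):
            flagged = contrasts[
                (contrasts["day"] == brood)
                & contrasts["estimable"]
                & (contrasts["p_adjusted"] < alpha)
            ]
            ymax = sub["smoothed"].max() if len(sub) else 1.0
            for pos in flagged["position"]:
                ax.annotate("*", (pos, ymax), ha="center", fontsize=14)
        ax.set_title(f"brood {brood}")
        ax.set_xlabel("position (Mb)")
    axes[0][0].set_ylabel("recombination rate (cM/Mb)")
    if broods:
        axes[0][0].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig_path = out_dir / "report.png"
    fig.savefig(fig_path, dpi=150, metadata={"Software": None})
    plt.close(fig)
    return fig_path
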