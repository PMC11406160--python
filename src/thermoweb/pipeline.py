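"""End-to-end temperature sweep: multilayer assembly, hypothesis tests, reports.

A sweep builds one feasibility network per temperature on a sorted grid,
tracks per-consumer degree, guild generality, connectance, and the edge
turnover between adjacent layers, and evaluates three directional
hypotheses about warming-driven trophic niche contraction:

* H1 — warming decreases the generality of the consumer guild;
* H2 — warming decreases the degree of individual consumers;
* H3 — the magnitude of degree loss differs among consumers (it depends on
  their baseline bite forces).

Trends are summarised with Spearman rank correlations (robust to the
step-shaped degree series); verdicts are sign-based with the statistic
attached, and no p-values are attached by default because the series are
deterministic functions of the traits.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .biomech import TemperatureSizeRule
from .community import Consumer, Resource, write_community
from .metrics import connectance, degrees, generality, link_turnover, robustness
from .network import FeasibilityNetwork, build_network, write_edge_list

__all__ = ["SweepResult", "temperature_sweep", "evaluate_hypotheses", "generate_report"]


@dataclass
class SweepResult:
    """Multilayer stack of feasibility networks over a temperature grid."""

    temperatures: np.ndarray
    networks: list[FeasibilityNetwork]
    per_consumer_degree: pd.DataFrame  # index: temperature, columns: consumer ids
    generality_series: pd.Series
    connectance_series: pd.Series
    turnover_series: pd.Series  # indexed by the hotter layer of each adjacent pair
    baseline_bite_forces: dict[str, float] = field(default_factory=dict)
    hypothesis_verdicts: Optional[dict] = None

    @property
    def collapse_temperature(self) -> Optional[float]:
        """First grid temperature with an empty edge set, if any."""
        for t, net in zip(self.temperatures, self.networks):
            if len(net.edges) == 0:
                return float(t)
        return None


def temperature_sweep(
    consumers: Sequence[Consumer],
    resources: Sequence[Resource],
    t_grid: Sequence[float],
    rule: TemperatureSizeRule,
) -> SweepResult:
    """Build one feasibility network per grid temperature and collect metrics.

    The grid must be sorted ascending.  Under shrinkage (alpha < 1) with a
    positive allometric exponent, consecutive layers are nested, so every
    degree series and the generality series are non-increasing.
    """
    t_grid = np.asarray(list(t_grid), dtype=float)
    if t_grid.size == 0:
        raise ValueError("temperature grid is empty")
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("temperature grid must be sorted in strictly ascending order")

    networks = [build_network(consumers, resources, t, rule) for t in t_grid]
    degree_rows = [degrees(net) for net in networks]
    per_consumer = pd.DataFrame(degree_rows, index=pd.Index(t_grid, name="temperature_c"))
    gen = pd.Series(
        [generality(net) for net in networks], index=per_consumer.index, name="generality"
    )
    conn = pd.Series(
        [connectance(net) for net in networks], index=per_consumer.index, name="connectance"
    )
    turnover = pd.Series(
        [link_turnover(a, b) for a, b in zip(networks, networks[1:])],
        index=pd.Index(t_grid[1:], name="temperature_c"),
        name="link_turnover",
    )
    return SweepResult(
        temperatures=t_grid,
        networks=networks,
        per_consumer_degree=per_consumer,
        generality_series=gen,
        connectance_series=conn,
        turnover_series=turnover,
        baseline_bite_forces={c.id: c.baseline_bite_force for c in consumers},
    )


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho; nan for constant series instead of a warning."""
    if np.all(y == y[0]) or np.all(x == x[0]):
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = stats.spearmanr(x, y).statistic
    return float(rho)


def evaluate_hypotheses(sweep: SweepResult) -> dict:
    """Sign-based verdicts for the three niche-contraction hypotheses.

    H1 is supported when generality correlates negatively with temperature
    (Spearman rho < 0).  H2 is supported when every consumer whose degree
    series is not constant shows a negative correlation, and at least one
    such consumer exists.  H3 is supported when total degree loss over the
    sweep differs among consumers (range of losses > 0); per-consumer
    losses are reported alongside baseline bite forces so the dependence on
    initial bite force is inspectable.
    """
    if len(sweep.temperatures) < 3:
        raise ValueError("hypothesis evaluation requires at least 3 grid points")

    t = sweep.temperatures
    rho_gen = _spearman(t, sweep.generality_series.to_numpy())
    h1 = bool(not np.isnan(rho_gen) and rho_gen < 0)

    per_consumer_rho = {
        cid: _spearman(t, sweep.per_consumer_degree[cid].to_numpy())
        for cid in sweep.per_consumer_degree.columns
    }
    nonconstant = {cid: r for cid, r in per_consumer_rho.items() if not np.isnan(r)}
    h2 = bool(nonconstant) and all(r < 0 for r in nonconstant.values())
    frac_declining = (
        sum(r < 0 for r in nonconstant.values()) / len(per_consumer_rho)
        if per_consumer_rho
        else 0.0
    )

    losses = {
        cid: int(sweep.per_consumer_degree[cid].iloc[0] - sweep.per_consumer_degree[cid].iloc[-1])
        for cid in sweep.per_consumer_degree.columns
    }
    loss_values = list(losses.values())
    loss_range = max(loss_values) - min(loss_values) if loss_values else 0
    h3 = bool(loss_range > 0)

    def _num(x: float) -> Optional[float]:
        return None if np.isnan(x) else float(x)

    return {
        "H1_generality_declines": {
            "supported": h1,
            "statistic": _num(rho_gen),
            "statistic_name": "spearman_rho_generality_vs_temperature",
        },
        "H2_individual_degrees_decline": {
            "supported": h2,
            "statistic": frac_declining,
            "statistic_name": "fraction_of_consumers_with_declining_degree",
            "per_consumer_rho": {c: _num(r) for c, r in per_consumer_rho.items()},
        },
        "H3_degree_loss_differs_by_baseline_bite_force": {
            "supported": h3,
            "statistic": float(loss_range),
            "statistic_name": "range_of_per_consumer_degree_losses",
            "per_consumer_loss": losses,
            "baseline_bite_force_mn": {
                c: float(b) for c, b in sweep.baseline_bite_forces.items()
            },
        },
    }


def _metrics_long(sweep: SweepResult) -> pd.DataFrame:
    rows = []
    for t in sweep.temperatures:
        rows.append((t, "generality", "network", sweep.generality_series.loc[t]))
        rows.append((t, "connectance", "network", sweep.connectance_series.loc[t]))
        for cid in sweep.per_consumer_degree.columns:
            rows.append((t, "degree", cid, float(sweep.per_consumer_degree.loc[t, cid])))
    for t, v in sweep.turnover_series.items():
        rows.append((t, "link_turnover_vs_previous_layer", "network", v))
    return pd.DataFrame(rows, columns=["temperature_c", "metric", "scope", "value"])


def generate_report(
    sweep: SweepResult,
    out_dir: str | Path,
    manifest_extra: Optional[dict] = None,
    robustness_settings: Optional[dict] = None,
    consumers: Optional[Sequence[Consumer]] = None,
    resources: Optional[Sequence[Resource]] = None,
    make_plot: bool = True,
) -> dict[str, Path]:
    """Write the sweep's outputs to ``out_dir`` and return the file map.

    Outputs: long-format ``metrics.csv``; one edge-list TSV per layer;
    ``turnover.csv``; ``hypotheses.json``; a ``manifest.json`` recording the
    configuration and software version so the run can be reproduced; a
    niche-contraction summary plot; optional per-layer robustness curves;
    and a human-readable ``summary.txt`` (which flags the complete niche
    collapse temperature, if reached, and whether any rewiring occurred).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    metrics_path = out / "metrics.csv"
    _metrics_long(sweep).to_csv(metrics_path, index=False)
    files["metrics"] = metrics_path

    for t, net in zip(sweep.temperatures, sweep.networks):
        path = out / f"edges_T{t:g}.tsv"
        write_edge_list(net, path)
        files[f"edges_T{t:g}"] = path

    turnover_path = out / "turnover.csv"
    sweep.turnover_series.rename_axis("temperature_c").to_frame().to_csv(turnover_path)
    files["turnover"] = turnover_path

    verdicts = sweep.hypothesis_verdicts or evaluate_hypotheses(sweep)
    sweep.hypothesis_verdicts = verdicts
    hyp_path = out / "hypotheses.json"
    hyp_path.write_text(json.dumps(verdicts, indent=2, sort_keys=True) + "\n")
    files["hypotheses"] = hyp_path

    if robustness_settings is not None:
        curve_rows = []
        r_rows = []
        for t, net in zip(sweep.temperatures, sweep.networks):
            if len(net.edges) == 0:
                continue
            res = robustness(net, **robustness_settings)
            r_rows.append((t, res.removal_strategy, res.robustness_r))
            for step, (f, s) in enumerate(
                zip(res.removal_fractions, res.surviving_fraction)
            ):
                curve_rows.append((t, step, f, s))
        rob_path = out / "robustness.csv"
        pd.DataFrame(
            r_rows, columns=["temperature_c", "strategy", "robustness_r"]
        ).to_csv(rob_path, index=False)
        files["robustness"] = rob_path
        curves_path = out / "robustness_curves.csv"
        pd.DataFrame(
            curve_rows,
            columns=["temperature_c", "step", "removal_fraction", "surviving_fraction"],
        ).to_csv(curves_path, index=False)
        files["robustness_curves"] = curves_path

    if consumers is not None and resources is not None:
        ctab, rtab = out / "consumers.csv", out / "resources.csv"
        write_community(consumers, resources, ctab, rtab)
        files["consumers"], files["resources"] = ctab, rtab

    manifest = {
        "software": {"name": "thermoweb", "version": __version__},
        "t_grid": [float(t) for t in sweep.temperatures],
        "n_consumers": int(sweep.per_consumer_degree.shape[1]),
        "n_resources": int(sweep.networks[0].n_resources),
        "robustness": robustness_settings,
    }
    if manifest_extra:
        manifest.update(manifest_extra)
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    files["manifest"] = manifest_path

    if make_plot:
        files["plot"] = _plot_sweep(sweep, out / "niche_contraction.png")

    lines = [
        f"thermoweb sweep over {sweep.temperatures[0]:g}-{sweep.temperatures[-1]:g} C "
        f"({len(sweep.temperatures)} layers)",
        f"generality: {sweep.generality_series.iloc[0]:.3f} -> "
        f"{sweep.generality_series.iloc[-1]:.3f}",
        f"connectance: {sweep.connectance_series.iloc[0]:.3f} -> "
        f"{sweep.connectance_series.iloc[-1]:.3f}",
    ]
    if sweep.collapse_temperature is not None:
        lines.append(
            f"complete niche collapse (no feasible links) at "
            f"{sweep.collapse_temperature:g} C"
        )
    if len(sweep.turnover_series) and (sweep.turnover_series > 0).any():
        lines.append(
            f"rewiring detected: mean interlayer link turnover "
            f"{sweep.turnover_series.mean():.3f}"
        )
    else:
        lines.append("no rewiring detected: all layers share the same edge set")
    for name, verdict in verdicts.items():
        lines.append(f"{name}: {'supported' if verdict['supported'] else 'not supported'}")
    summary_path = out / "summary.txt"
    summary_path.write_text("\n".join(lines) + "\n")
    files["summary"] = summary_path

    return files


def _plot_sweep(sweep: SweepResult, path: Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.6), constrained_layout=True)
    t = sweep.temperatures
    for cid in sweep.per_consumer_degree.columns:
        ax1.step(t, sweep.per_consumer_degree[cid], where="post", label=cid, alpha=0.8)
    ax1.set_xlabel("temperature (°C)")
    ax1.set_ylabel("consumer degree")
    ax1.set_title("Per-consumer trophic niche")
    if sweep.per_consumer_degree.shape[1] <= 8:
        ax1.legend(fontsize="small")
    ax2.plot(t, sweep.generality_series, marker="o", ms=3)
    ax2.set_xlabel("temperature (°C)")
    ax2.set_ylabel("generality (mean degree)")
    ax2.set_title("Guild-level niche contraction")
    fig.savefig(path, dpi=150, metadata={"Software": None})
    plt.close(fig)
    return path
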