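"""Minimal figures: group thermogram curves, difference plots, box charts."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt

from .features import METRIC_NAMES
from .groups import DifferenceCurve, GroupSummary

_GROUP_COLORS = {
    "control": "black",
    "LSIL": "tab:red",
    "HSIL": "tab:green",
    "StageI": "tab:blue",
    "StageII_IV": "tab:cyan",
}


def plot_group_curves(
    summaries: list[GroupSummary],
    differences: list[DifferenceCurve] | None = None,
    path=None,
):
    """Mean, SD and (optionally) difference curves per clinical group."""
    n_panels = 3 if differences else 2
    fig, axes = plt.subplots(1, n_panels, figsize=(4 * n_panels, 3.2))
    for s in summaries:
        color = _GROUP_COLORS.get(s.group)
        axes[0].plot(s.temperatures, s.mean_curve, label=s.group, color=color)
        axes[1].plot(s.temperatures, s.sd_curve, label=s.group, color=color)
    axes[0].set_ylabel("excess Cp (cal/°C·g)")
    axes[1].set_ylabel("SD (cal/°C·g)")
    if differences:
        for d in differences:
            axes[2].plot(
                d.temperatures, d.values, label=d.group,
                color=_GROUP_COLORS.get(d.group),
            )
        axes[2].axhline(0.0, lw=0.5, color="grey")
        axes[2].set_ylabel("Δ excess Cp vs control")
    for ax in axes:
        ax.set_xlabel("temperature (°C)")
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_metric_boxes(metrics, group_order=None, path=None):
    """Box charts of the eight thermogram metrics across groups."""
    groups = group_order or sorted(metrics["group"].unique())
    fig, axes = plt.subplots(2, 4, figsize=(13, 6))
    for ax, metric in zip(axes.ravel(), METRIC_NAMES):
        data = [
            metrics.loc[metrics["group"] == g, metric].dropna() for g in groups
        ]
        ax.boxplot(data, tick_labels=groups, whis=(5, 95))
        ax.set_title(metric, fontsize=9)
        ax.tick_params(axis="x", rotation=45, labelsize=7)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_dpca_scores(result, path=None):
    """2-D discriminant-score scatter, one marker colour per group."""
    fig, ax = plt.subplots(figsize=(4.5, 4))
    for g in sorted(set(result.groups)):
        idx = [i for i, lab in enumerate(result.groups) if lab == g]
        ax.scatter(result.scores[idx, 0], result.scores[idx, 1], label=g, s=30)
    ax.set_xlabel("D1")
    ax.set_ylabel("D2")
    ax.legend(fontsize=8)
    ax.set_title(f"dPCA scores (purity {result.purity:.2f})", fontsize=9)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
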