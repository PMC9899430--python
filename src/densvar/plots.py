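"""Figure analogues of the simulation study summaries.

Three views of the experiment results: empirical stationary variance
against density-dependence strength (boxplots), the fitted density-
dependent variance share phi_dd under both models (boxplots), and mean
phi_dd with 95% intervals against the analytic prediction beta^2.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = [
    "plot_stationary_variance",
    "plot_phi_dd_boxplots",
    "plot_phi_dd_vs_beta_sq",
]

_MODEL_COLORS = {"gompertz": "goldenrod", "ricker": "steelblue", "known": "gray"}


def _boxplot_by_beta(ax, df: pd.DataFrame, col: str, model: str) -> None:
    betas = sorted(df["beta_true"].unique())
    data = [
        df[(df["beta_true"] == b) & (df["model"] == model)][col].to_numpy()
        for b in betas
    ]
    ax.boxplot(
        data,
        tick_labels=[f"{b:g}" for b in betas],
        patch_artist=True,
        boxprops=dict(facecolor=_MODEL_COLORS.get(model, "lightgray")),
        medianprops=dict(color="black"),
    )


def plot_stationary_variance(df: pd.DataFrame, path: str | Path) -> Path:
    """Boxplots of per-replicate empirical v_inf by beta, one panel per
    environmental variance level."""
    sigmas = sorted(df["sigma2_true"].unique())
    fig, axes = plt.subplots(
        1, len(sigmas), figsize=(3.2 * len(sigmas), 3.4), sharey=True, squeeze=False
    )
    for ax, s2 in zip(axes[0], sigmas):
        _boxplot_by_beta(ax, df[df["sigma2_true"] == s2], "v_inf", "known")
        ax.set_title(f"$\\sigma^2$ = {s2:g}")
        ax.set_xlabel(r"$\beta$")
    axes[0][0].set_ylabel(r"empirical $v_\infty$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_phi_dd_boxplots(df: pd.DataFrame, path: str | Path) -> Path:
    """Boxplots of fitted phi_dd by beta for each fitted model, one panel
    per environmental variance level."""
    sigmas = sorted(df["sigma2_true"].unique())
    models = [m for m in ("gompertz", "ricker") if (df["model"] == m).any()]
    fig, axes = plt.subplots(
        len(models),
        len(sigmas),
        figsize=(3.2 * len(sigmas), 3.0 * len(models)),
        sharey=True,
        squeeze=False,
    )
    for row, model in enumerate(models):
        for ax, s2 in zip(axes[row], sigmas):
            _boxplot_by_beta(ax, df[df["sigma2_true"] == s2], "phi_dd", model)
            if row == 0:
                ax.set_title(f"$\\sigma^2$ = {s2:g}")
            if row == len(models) - 1:
                ax.set_xlabel(r"$\beta$")
        axes[row][0].set_ylabel(rf"$\varphi_{{dd}}$ ({model} fit)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_phi_dd_vs_beta_sq(summary: pd.DataFrame, path: str | Path) -> Path:
    """Mean fitted phi_dd with 95% percentile intervals against beta, with
    the analytic beta^2 overlaid, per environmental variance level."""
    df = summary[summary["model"] == "gompertz"]
    sigmas = sorted(df["sigma2_true"].unique())
    fig, axes = plt.subplots(
        1, len(sigmas), figsize=(3.2 * len(sigmas), 3.4), sharey=True, squeeze=False
    )
    for ax, s2 in zip(axes[0], sigmas):
        sub = df[df["sigma2_true"] == s2].sort_values("beta_true")
        b = sub["beta_true"].to_numpy()
        mean = sub["phi_dd_mean"].to_numpy()
        lo = mean - sub["phi_dd_p2.5"].to_numpy()
        hi = sub["phi_dd_p97.5"].to_numpy() - mean
        ax.errorbar(b, mean, yerr=[lo, hi], fmt="o", color="royalblue",
                    capsize=3, label=r"mean $\hat\varphi_{dd}$ (95% int.)")
        ax.plot(b, sub["beta_sq"], "D", color="darkorange", label=r"$\beta^2$")
        ax.set_title(f"$\\sigma^2$ = {s2:g}")
        ax.set_xlabel(r"$\beta$")
    axes[0][0].set_ylabel(r"$\varphi_{dd}$")
    axes[0][0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
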