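"""Diagnostic figures: GOF panels, VPC bands, NPDE summaries, EBE scatters."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["plot_gof", "plot_vpc", "plot_npde", "plot_cl_covariates"]


def _identity_panel(ax, x, y, xlabel, ylabel):
    ax.scatter(x, y, s=12, alpha=0.6, edgecolor="none")
    lim = [0, max(np.max(x), np.max(y)) * 1.05]
    ax.plot(lim, lim, "k--", lw=1)
    ax.set_xlim(lim); ax.set_ylim(lim)
    ax.set_xlabel(xlabel); ax.set_ylabel(ylabel)


def plot_gof(table: pd.DataFrame, path) -> None:
    """Four-panel goodness of fit: DV~IPRED, DV~PRED, CWRES~PRED, CWRES~TAD."""
    fig, axes = plt.subplots(2, 2, figsize=(9, 8))
    _identity_panel(axes[0, 0], table["IPRED"], table["DV"],
                    "Individual prediction (mg/L)", "Observed (mg/L)")
    _identity_panel(axes[0, 1], table["PRED"], table["DV"],
                    "Population prediction (mg/L)", "Observed (mg/L)")
    for ax, xcol, xlabel in ((axes[1, 0], "PRED", "Population prediction (mg/L)"),
                             (axes[1, 1], "TAD", "Time after dose (h)")):
        ax.scatter(table[xcol], table["CWRES"], s=12, alpha=0.6, edgecolor="none")
        ax.axhline(0, color="k", lw=1)
        for y in (-2, 2):
            ax.axhline(y, color="grey", lw=0.8, ls=":")
        ax.set_xlabel(xlabel); ax.set_ylabel("CWRES")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_vpc(vpc_table: pd.DataFrame, observations: pd.DataFrame | None, path) -> None:
    """Observed percentile curves over the simulated 95% CI bands."""
    fig, ax = plt.subplots(figsize=(7, 5))
    for pct, color in ((5.0, "#7799cc"), (50.0, "#cc5555"), (95.0, "#7799cc")):
        sub = vpc_table[vpc_table["percentile"] == pct].sort_values("tad_mid")
        ax.fill_between(sub["tad_mid"], sub["sim_ci_lower"], sub["sim_ci_upper"],
                        color=color, alpha=0.25)
        ax.plot(sub["tad_mid"], sub["observed"], color="red" if pct == 50 else "firebrick",
                lw=1.5, marker="o", ms=3,
                label=f"observed P{int(pct)}")
    if observations is not None:
        ax.scatter(observations["TAD"], observations["DV"], s=8, color="grey",
                   alpha=0.4, edgecolor="none", zorder=0)
    ax.set_xlabel("Time after dose (h)")
    ax.set_ylabel("Concentration (mg/L)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_npde(npde_values: np.ndarray, table: pd.DataFrame, path) -> None:
    """Histogram, QQ plot, and NPDE vs time / vs DV panels."""
    fig, axes = plt.subplots(2, 2, figsize=(9, 8))
    x = np.linspace(-3.5, 3.5, 200)
    axes[0, 0].hist(npde_values, bins=20, density=True, alpha=0.7)
    axes[0, 0].plot(x, stats.norm.pdf(x), "k-", lw=1)
    axes[0, 0].set_xlabel("NPDE"); axes[0, 0].set_ylabel("density")
    stats.probplot(npde_values, dist="norm", plot=axes[0, 1])
    axes[0, 1].set_title("")
    for ax, xcol, xlabel in ((axes[1, 0], "TAD", "Time after dose (h)"),
                             (axes[1, 1], "DV", "Observed (mg/L)")):
        ax.scatter(table[xcol], npde_values, s=12, alpha=0.6, edgecolor="none")
        ax.axhline(0, color="k", lw=1)
        ax.set_xlabel(xlabel); ax.set_ylabel("NPDE")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_cl_covariates(ebe: pd.DataFrame, path) -> None:
    """Empirical-Bayes clearance vs Scr and DFI, split by diuretic use."""
    fig, axes = plt.subplots(1, 2, figsize=(10, 4.5))
    for ax, xcol, xlabel in ((axes[0], "SCR", "Serum creatinine (umol/L)"),
                             (axes[1], "DFI", "Daily fluid input (mL)")):
        for da, marker, label in ((0.0, "o", "no diuretics"), (1.0, "^", "diuretics")):
            sub = ebe[ebe["DA"] == da]
            ax.scatter(sub[xcol], sub["CL"], marker=marker, s=20, alpha=0.7,
                       facecolors="none", edgecolors="C0" if da == 0 else "C3",
                       label=label)
        ax.set_xlabel(xlabel); ax.set_ylabel("CL (L/h)")
        ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
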