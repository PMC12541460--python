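"""Matplotlib figures for run reports: trace panels, heat map, survival."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .kinetics import EfretHeatmap, SurvivalCurve
from .trace import SpotTrace

__all__ = ["plot_trace_panels", "plot_heatmap", "plot_survival"]


def plot_trace_panels(trace: SpotTrace, efret=None, threshold=None):
    """Stacked per-channel panels for one spot (red, green, FRET, total, E)."""
    fig, axes = plt.subplots(5, 1, sharex=True, figsize=(7, 7))
    t = trace.time_s
    axes[0].plot(t, trace.I_AexAem, color="red", lw=0.8)
    axes[0].set_ylabel("Aex,Aem")
    axes[1].plot(t, trace.I_DexDem, color="green", lw=0.8)
    axes[1].set_ylabel("Dex,Dem")
    axes[2].plot(t, trace.I_DexAem, color="magenta", lw=0.8)
    axes[2].set_ylabel("Dex,Aem")
    axes[3].plot(t, trace.donor_total, color="black", lw=0.8)
    axes[3].set_ylabel("Dex total")
    if efret is not None:
        axes[4].plot(t, efret, ".", color="tab:blue", ms=3)
    if threshold is not None:
        axes[4].axhline(threshold, ls="--", color="black", lw=0.8)
    axes[4].set_ylabel("E_FRET")
    axes[4].set_ylim(-0.2, 1.2)
    axes[4].set_xlabel("time (s)")
    fig.suptitle(trace.spot_id)
    fig.tight_layout()
    return fig


def plot_heatmap(hm: EfretHeatmap):
    """E_FRET density vs time since Mcm2-7 arrival, with remaining fraction."""
    fig, (ax, axf) = plt.subplots(
        2, 1, sharex=True, figsize=(7, 5), height_ratios=[3, 1]
    )
    masked = np.ma.masked_invalid(hm.density)
    ax.pcolormesh(hm.time_edges_s, hm.e_edges, masked, cmap="viridis")
    ax.set_ylabel("E_FRET")
    tc = 0.5 * (hm.time_edges_s[:-1] + hm.time_edges_s[1:])
    axf.plot(tc, hm.remaining_fraction, color="tab:blue")
    axf.fill_between(tc, hm.ci_low, hm.ci_high, color="orange", alpha=0.4)
    axf.set_ylabel("remaining")
    axf.set_xlabel("time after Mcm2-7 arrival (s)")
    axf.set_ylim(0, 1.05)
    fig.tight_layout()
    return fig


def plot_survival(curves: dict[str, SurvivalCurve]):
    """Step survival curves with bootstrap 95% CI shading."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, sc in curves.items():
        ax.step(sc.time, sc.survival, where="post", label=f"{label} (n={sc.n})")
        ax.fill_between(sc.time, sc.ci_low, sc.ci_high, step="post", alpha=0.3)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("fraction surviving")
    ax.set_ylim(0, 1.05)
    ax.legend()
    fig.tight_layout()
    return fig
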