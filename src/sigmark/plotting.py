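"""Optional figures: KM curves per stratum, set-Z scatter, GSEA profile.

Kept separate from the statistics so headless runs never touch matplotlib
unless a figure is requested. All functions save to a path and return it.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .enrichment import ZComparison
from .survival import SurvivalCurve

__all__ = ["plot_km_strata", "plot_z_comparison", "plot_gsea_profile"]


def _step_xy(curve: SurvivalCurve) -> tuple[np.ndarray, np.ndarray]:
    x = np.concatenate([[0.0], np.repeat(curve.times, 2)])
    y = np.concatenate([[1.0, 1.0], np.repeat(curve.survival, 2)[:-1]])
    return x, y


def plot_km_strata(curves: dict[str, SurvivalCurve], path: str | Path,
                   title: str = "Survival by prognostic score") -> Path:
    """One Kaplan-Meier step curve per stratum with censoring ticks."""
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for label, curve in curves.items():
        x, y = _step_xy(curve)
        (line,) = ax.plot(x, y, label=label, lw=1.6)
        if len(curve.censor_times):
            ax.plot(curve.censor_times,
                    [curve.survival_at(t) for t in curve.censor_times],
                    "|", color=line.get_color(), ms=7, mew=1.2)
    ax.set_xlabel("time (months)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_z_comparison(comp: ZComparison, path: str | Path,
                      xlabel: str = "set Z (experiment A)",
                      ylabel: str = "set Z (experiment B)") -> Path:
    """Scatter of the two experiments' set-Z vectors with the Pearson r."""
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.axhline(0, color="0.8", lw=0.8)
    ax.axvline(0, color="0.8", lw=0.8)
    ax.scatter(comp.z_a, comp.z_b, s=14, alpha=0.7, edgecolors="none")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.set_title(f"r = {comp.r:+.3f} (p = {comp.p:.2g}, n = {comp.n})")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_gsea_profile(profile, hit_positions, path: str | Path,
                      title: str = "enrichment running sum") -> Path:
    """Running-sum deviation with hit tick marks underneath."""
    profile = np.asarray(profile, dtype=float)
    fig, (ax, axh) = plt.subplots(
        2, 1, figsize=(6, 3.5), sharex=True,
        gridspec_kw={"height_ratios": [5, 1], "hspace": 0.05})
    ax.plot(np.arange(1, len(profile) + 1), profile, lw=1.2)
    ax.axhline(0, color="0.8", lw=0.8)
    ax.set_ylabel("P_hit − P_miss")
    ax.set_title(title)
    axh.vlines(hit_positions, 0, 1, lw=0.6)
    axh.set_yticks([])
    axh.set_xlabel("rank position")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
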