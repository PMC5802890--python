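"""Standard run output: tables, summary JSON and the four diagnostic figures.

A run directory is self-describing: it contains the echoed configuration,
a log with seeds and package versions, the scan table as CSV, a JSON
summary, and four figures — (1) the cut-off scan plot (percent vs
-log10 p, optimal and median cuts marked), (2) the trait boxplot with
distribution-outlier flags, (3) the resampled scan plot (overlaid
subsample curves, median cut in blue, outlier boundary in red), and
(4) a Kaplan-Meier plot (Cox mode) or a 2x2 mosaic (Fisher mode).
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from . import __version__
from .robustness import OutlierThreshold, ResampleProfile
from .scan import CutoffScan, OptimalCutoff

__all__ = ["write_scan_outputs", "plot_scan", "plot_boxplot",
           "plot_resampled", "plot_km", "plot_mosaic"]


def _save(fig, outdir: Path, stem: str):
    for ext in ("png", "svg"):
        fig.savefig(outdir / f"{stem}.{ext}", dpi=150, bbox_inches="tight")
    plt.close(fig)


def plot_scan(scan: CutoffScan, best: OptimalCutoff, raw_p: bool = False):
    fig, ax = plt.subplots(figsize=(6, 4))
    p = scan.p_values
    y = p if raw_p else -np.log10(p)
    ax.plot(scan.percents, y, "-", color="0.3", lw=1.2)
    for pct, color, label in ((best.percent, "tab:green", f"optimal ({best.percent}%)"),
                              (50, "tab:blue", "median")):
        ax.axvline(pct, color=color, ls="--", lw=1, label=label)
    ax.set_xlabel("cut-off percentile")
    ax.set_ylabel("p value" if raw_p else "-log10 p")
    ax.set_title(f"{scan.trait_name}: {scan.test_kind} cut-off scan (n={scan.n})")
    ax.legend(frameon=False, fontsize=8)
    return fig


def plot_boxplot(values: np.ndarray, outliers: OutlierThreshold, name: str = "trait"):
    fig, ax = plt.subplots(figsize=(3.2, 4))
    ax.boxplot(values, widths=0.5, showfliers=False)
    jitter = 1 + 0.08 * np.random.default_rng(0).standard_normal(values.size)
    ax.scatter(jitter[~outliers.flags], values[~outliers.flags], s=8, color="0.5", alpha=0.6)
    if outliers.flags.any():
        ax.scatter(jitter[outliers.flags], values[outliers.flags], s=12, color="tab:red",
                   label=f"> 2 MAD ({int(outliers.flags.sum())})")
        ax.legend(frameon=False, fontsize=8)
    ax.set_ylabel(name)
    ax.set_xticks([])
    return fig


def plot_resampled(profile: ResampleProfile, outliers: OutlierThreshold | None = None,
                   raw_p: bool = False):
    fig, ax = plt.subplots(figsize=(6, 4))
    for percents, p in profile.curves:
        y = p if raw_p else -np.log10(p)
        ax.plot(percents, y, color="0.6", lw=0.4, alpha=0.4)
    ax.axvline(50, color="tab:blue", lw=1.2, label="median")
    if outliers is not None and np.isfinite(outliers.upper_percentile):
        ax.axvline(outliers.upper_percentile, color="tab:red", lw=1.2,
                   label="outlier boundary")
    opt = profile.optimal_percents[~np.isnan(profile.optimal_percents)]
    if opt.size:
        ax2 = ax.twinx()
        ax2.hist(opt, bins=np.arange(0.5, 100, 1), color="tab:green", alpha=0.35)
        ax2.set_ylabel("resample optima (count)", fontsize=8)
    ax.set_xlabel("cut-off percentile")
    ax.set_ylabel("p value" if raw_p else "-log10 p")
    ax.set_title(f"resampled scan ({profile.n_resamples} x {profile.fraction:.0%})")
    ax.legend(frameon=False, fontsize=8)
    return fig


def plot_km(summary, name: str = "trait"):
    fig, ax = plt.subplots(figsize=(5, 4))
    for g, df in summary.km_curves.items():
        ax.step(df["time"], df["survival"], where="post", label=f"{name} {g}")
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False, fontsize=8)
    return fig


def plot_mosaic(label_group: np.ndarray, ref_group: np.ndarray, name: str = "trait"):
    """2x2 mosaic of the optimal dichotomy against the reference status."""
    fig, ax = plt.subplots(figsize=(4, 4))
    n = label_group.size
    widths = [np.mean(label_group == 0), np.mean(label_group == 1)]
    x0 = 0.0
    for j, w in enumerate(widths):
        sel = label_group == j
        frac1 = (ref_group[sel] == 1).mean() if sel.any() else 0.0
        ax.bar(x0 + w / 2, frac1, width=w * 0.96, bottom=0, color="tab:orange")
        ax.bar(x0 + w / 2, 1 - frac1, width=w * 0.96, bottom=frac1, color="tab:blue")
        ax.text(x0 + w / 2, -0.06, ("low", "high")[j], ha="center", fontsize=9)
        x0 += w
    ax.set_ylim(0, 1)
    ax.set_xlim(0, 1)
    ax.set_xticks([])
    ax.set_ylabel("fraction reference = 1 / 0")
    ax.set_title(f"{name}: optimal split vs reference (n={n})")
    return fig


def write_scan_outputs(outdir, *, config: dict, scan: CutoffScan, best: OptimalCutoff,
                       outliers: OutlierThreshold, profile: ResampleProfile | None = None,
                       clusters=None, fdr=None, survival=None, mosaic=None,
                       trait_values: np.ndarray | None = None, raw_p: bool = False) -> dict:
    """Write every table/figure for one run; returns the summary dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(json.dumps(config, indent=2, default=str))
    scan.to_frame().to_csv(outdir / "scan.csv", index=False)
    summary = {
        "trait": scan.trait_name,
        "test_kind": scan.test_kind,
        "n": scan.n,
        "optimal_percent": best.percent,
        "p": best.p_value,
        "effect": best.effect,
        "effect_ci": [best.ci_low, best.ci_high],
        "median_p": None if np.isnan(best.median_p) else best.median_p,
        "search_range": list(best.search_range),
        "flags": list(best.flags),
        "outlier_upper_percentile": None if np.isnan(outliers.upper_percentile)
        else outliers.upper_percentile,
    }
    if fdr is not None:
        summary["fdr_ac"] = fdr.fdr_ac
        summary["fdr_range"] = fdr.fdr_range
        summary["n_permutations"] = fdr.n_permutations
    if clusters is not None:
        summary["n_subgroups"] = clusters.n_subgroups
        summary["robust_flag"] = clusters.robust
        summary["recurring_clusters"] = [list(c) for c in clusters.recurring]
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))

    _save(plot_scan(scan, best, raw_p), outdir, "scan_plot")
    if trait_values is not None:
        _save(plot_boxplot(trait_values, outliers, scan.trait_name), outdir, "boxplot")
    if profile is not None:
        np.savetxt(outdir / "resample_optima.csv",
                   profile.optimal_percents, fmt="%.1f", header="optimal_percent",
                   comments="")
        _save(plot_resampled(profile, outliers, raw_p), outdir, "resampled_plot")
    if survival is not None:
        survival.to_frame().to_csv(outdir / "km_curves.csv", index=False)
        survival.hazard_ratios.to_csv(outdir / "hazard_ratios.csv")
        _save(plot_km(survival, scan.trait_name), outdir, "outcome_plot")
    elif mosaic is not None:
        _save(plot_mosaic(*mosaic, scan.trait_name), outdir, "outcome_plot")

    log_lines = [
        f"cutscan {__version__}",
        f"python {platform.python_version()}",
        f"numpy {np.__version__}",
        f"seed {config.get('seed')}",
    ]
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return summary
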