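"""Optional figures: time-course fits and QD histogram overlays."""

from __future__ import annotations

import numpy as np

from .kinetics import LogisticFit, logistic_value


def plot_timecourse_fits(summary, fits, path):
    """Mean +- s.e.m. per ligand with the fitted sigmoid overlaid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    t_max = float(summary["time_min"].max())
    grid = np.linspace(0, 1.05 * t_max, 300)
    for _, row in fits.iterrows():
        fit = LogisticFit(row["a1"], row["a2"], row["x0"], p=row.get("p"),
                          dx=row.get("dx"), family=row["family"])
        g = summary[summary["ligand"] == row["ligand"]]
        eb = ax.errorbar(g["time_min"], g["mean"], yerr=g["sem"], fmt="o", capsize=3,
                         label=f"{row['ligand']} (t1/2 = {row['t_half']:.1f} min)")
        ax.plot(grid, logistic_value(fit, grid), color=eb[0].get_color())
    ax.set_xlabel("time at 37 °C (min)")
    ax.set_ylabel("QD interior / QD total")
    ax.set_ylim(0, 1.05)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_qd_histogram_overlay(tables_by_time, path, channel: str = "qd"):
    """Log-intensity histograms of the gated QD signal, one per timepoint."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for t in sorted(tables_by_time):
        x = np.log10(np.maximum(tables_by_time[t][channel].to_numpy(float), 1e-6))
        ax.hist(x, bins=80, histtype="step", density=True, label=f"{t:g} min")
    ax.set_xlabel("log10 QD intensity")
    ax.set_ylabel("density")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
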