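"""Schematic plots of distributions, hazards and model-prediction curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .design import FPDistribution
from .hazard import HazardFunction


def plot_distribution_with_hazard(
    dist: FPDistribution, hazards: list[HazardFunction], ax=None
):
    """Foreperiod pmf (bars, binned support of the first hazard) with hazard traces."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    ax.bar(dist.support, dist.pmf, width=dist.grid_ms, color="0.8", label="pmf")
    ax2 = ax.twinx()
    for h in hazards:
        ax2.plot(h.support, h.values, label=h.variant)
    ax.set_xlabel("foreperiod [ms]")
    ax.set_ylabel("probability mass")
    ax2.set_ylabel("hazard")
    ax2.legend(loc="upper left", fontsize=8)
    return ax


def plot_prediction_curves(curves, value_col="predicted_latency_ms", ax=None):
    """Overlay model-prediction curves (frames from the prep_models module)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    for frame in curves:
        ax.plot(
            frame["fp_bin_center_ms"], frame[value_col],
            label=str(frame["model_name"].iloc[0]),
        )
    ax.set_xlabel("foreperiod bin center [ms]")
    ax.set_ylabel(value_col.replace("_", " "))
    ax.legend(fontsize=8)
    return ax


def plot_binned_latency(binned, ax=None):
    """Bin-mean latency with SE whiskers against foreperiod."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    se = binned["sd"] / binned["n"].pow(0.5)
    ax.errorbar(binned["fp_bin"], binned["mean"], yerr=se, fmt="o", ms=4)
    ax.set_xlabel("foreperiod bin [ms]")
    ax.set_ylabel("mean latency [ms]")
    return ax
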