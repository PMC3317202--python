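"""Optional histogram export for simulated dose-metric distributions."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .population import PopulationDataset

__all__ = ["export_histogram"]

_LABELS = {"cass": "CAss (ug/L)", "ram": "RAM (ug/h per L liver)"}


def export_histogram(
    pop: PopulationDataset, metric: str, path: str | Path, bins: int = 80
) -> Path:
    """Overlay per-subpopulation histograms of one dose metric.

    Requires matplotlib (imported lazily).  Counts are plotted on a log
    y-scale so sparse subgroups such as neonates remain visible next to the
    whole population.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    values = pop.metric(metric)
    edges = np.histogram_bin_edges(values, bins=bins)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.hist(values, bins=edges, histtype="step", lw=2, color="black", label=pop.label)
    for name, part in pop.samples.groupby("subpop", sort=False):
        ax.hist(part[metric], bins=edges, histtype="step", lw=1, label=str(name))
    ax.set_xlabel(_LABELS.get(metric, metric))
    ax.set_ylabel("individuals")
    ax.set_yscale("log")
    ax.legend(fontsize=7)
    ax.set_title(f"{pop.chemical}: {metric} in {pop.label}")
    path = Path(path)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path
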