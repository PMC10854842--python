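"""Optional quick-look plots (requires matplotlib, the ``plot`` extra)."""

from __future__ import annotations

from typing import Mapping, Sequence

from .profiles import AlkaneProfile


def plot_profiles(components: Sequence[AlkaneProfile], ax=None, log: bool = True):
    """Grouped bar chart of component alkane fingerprints (mg/kg DM)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    markers = components[0].markers
    width = 0.8 / len(components)
    for k, p in enumerate(components):
        xs = [i + k * width for i in range(len(markers))]
        ax.bar(xs, p.vector(markers), width=width, label=p.component_name)
    ax.set_xticks([i + 0.4 - width / 2 for i in range(len(markers))])
    ax.set_xticklabels([i.label for i in markers])
    if log:
        ax.set_yscale("log")
    ax.set_ylabel("concentration (mg/kg DM)")
    ax.legend()
    return ax


def plot_predictions(proportions: Mapping[str, float], truth: Mapping[str, float],
                     ax=None):
    """Estimated vs true plant proportion, one point per animal."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    xs = [truth[a] for a in proportions]
    ys = [proportions[a] for a in proportions]
    ax.scatter(xs, ys, alpha=0.6)
    lim = max(max(xs, default=0.01), max(ys, default=0.01)) * 1.1
    ax.plot([0, lim], [0, lim], ls="--", c="gray")
    ax.set_xlabel("true plant fraction")
    ax.set_ylabel("estimated plant fraction")
    return ax
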