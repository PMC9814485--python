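"""Plot helpers: calibrated 12-lead ECG panels and lead-CC maps."""

from __future__ import annotations

import numpy as np

from .leads import LEAD_NAMES
from .sources import PotentialTraces


def plot_12lead(traces: PotentialTraces, ax_grid=None, color="k", label=None):
    """3x4 panel of the 12-lead ECG with standard calibration.

    Grid squares correspond to 40 ms (width) and 0.5 mV (height).
    Returns the matplotlib figure.
    """
    import matplotlib.pyplot as plt

    if ax_grid is None:
        fig, axes = plt.subplots(3, 4, figsize=(12, 7), sharex=True, sharey=True)
    else:
        axes = ax_grid
        fig = axes.ravel()[0].figure
    for ax, name in zip(axes.ravel(), LEAD_NAMES):
        ax.plot(traces.times, traces.channel(name), color=color, lw=1.0, label=label)
        ax.set_title(name, fontsize=9)
        ax.set_xticks(np.arange(0, traces.times[-1] + 1, 40.0), minor=False)
        ax.set_yticks(np.arange(-3.0, 3.01, 0.5), minor=False)
        ax.grid(True, which="major", color="mistyrose", lw=0.6)
        ax.tick_params(labelsize=7)
    fig.supxlabel("time (ms)")
    fig.supylabel("potential (mV)")
    fig.tight_layout()
    return fig


def plot_lead_cc_map(lead_cc_map, anatomy, location=None):
    """Electrode-position scatter coloured by mean per-lead CC (size = SD)."""
    import matplotlib.pyplot as plt

    df = lead_cc_map
    if location is not None:
        df = df[df["location"] == location]
    order = {lab: i for i, lab in enumerate(anatomy.electrode_labels)}
    df = df.sort_values("lead", key=lambda s: s.map(order))
    pos = anatomy.electrode_positions[[order[l] for l in df["lead"]]]
    fig, ax = plt.subplots(figsize=(6, 7))
    sd = np.nan_to_num(df["std"].to_numpy(), nan=0.0)
    sc = ax.scatter(
        pos[:, 0], pos[:, 2], c=df["mean"], s=30 + 400 * sd, cmap="viridis",
        vmin=0.6, vmax=1.0, edgecolor="k", lw=0.3,
    )
    fig.colorbar(sc, ax=ax, label="mean per-lead CC")
    ax.set_xlabel("x (mm, patient left)")
    ax.set_ylabel("z (mm, cranial)")
    ax.set_title(location or "all locations")
    return fig
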