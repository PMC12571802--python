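"""Waveform overlay plots (optional; requires matplotlib)."""

from __future__ import annotations

import numpy as np

from .cohort import PairedRecord


def plot_reconstruction(record: PairedRecord, estimate: np.ndarray, path=None):
    """Overlay the measured aortic waveform, the estimate, and the radial input.

    Returns the matplotlib figure; saves to ``path`` when given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = record.aortic.times
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.plot(t, record.radial.values, color="0.6", lw=0.8, label="radial (input)")
    ax.plot(t, record.aortic.values, color="C0", lw=1.2, label="aortic (measured)")
    ax.plot(t, np.asarray(estimate), color="C3", lw=1.2, ls="--",
            label="aortic (estimated)")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("pressure (mmHg)")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
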