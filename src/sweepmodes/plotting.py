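"""Minimal likelihood-profile plotting helper."""

from __future__ import annotations

import pandas as pd

_AXIS_LABELS = {
    "selected_sites": "Position",
    "sels": "Selection coefficient",
    "migs": "Migration rate",
    "times": "Standing time (generations)",
    "gs": "Standing frequency",
}


def profile_plot(prof: pd.DataFrame, axis: str, out: str | None = None, ax=None):
    """Plot a per-model composite-likelihood profile (relative to neutral).

    ``prof`` is the output of :func:`sweepmodes.fit.profile` for ``axis``.
    Returns the matplotlib Axes; saves to ``out`` when given.
    """
    import matplotlib
    if out is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for model, sub in prof.groupby("model", sort=False):
        ax.plot(sub[axis], sub["mcle"], marker="o", label=model)
    ax.set_xlabel(_AXIS_LABELS.get(axis, axis))
    ax.set_ylabel("Composite log-likelihood (vs neutral)")
    ax.legend(fontsize=8)
    if out is not None:
        ax.figure.savefig(out, dpi=150, bbox_inches="tight")
    return ax
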