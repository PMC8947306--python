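"""Optional matplotlib renderings of TDS curves and canonical series."""

from __future__ import annotations

import numpy as np

from .curves import DominanceCurveSet, SignificanceLevels


def plot_dominance_curves(
    curves: DominanceCurveSet,
    levels: SignificanceLevels | None = None,
    ax=None,
):
    """One line per attribute over normalized time, with optional chance and
    significance levels drawn as horizontal guides."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for i, attr in enumerate(curves.vocabulary.attributes):
        ax.plot(curves.grid.instants, curves.proportions[i], label=attr)
    if levels is not None:
        ax.axhline(levels.chance_level, color="grey", ls=":", lw=1,
                   label="chance")
        ax.axhline(levels.significance_level, color="grey", ls="--", lw=1,
                   label="significance")
    ax.set_xlabel("normalized time")
    ax.set_ylabel("dominance proportion")
    ax.set_ylim(0, 1)
    ax.set_title(curves.vocabulary.category_label)
    ax.legend(fontsize="small", ncol=2)
    return ax


def plot_canonical_series(instants, u, v, ax=None):
    """Canonical variates u_j(t) (solid) and v_j(t) (dashed) over time."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    u = np.asarray(u)
    v = np.asarray(v)
    for j in range(u.shape[1]):
        line, = ax.plot(instants, u[:, j], label=f"u{j + 1}")
        ax.plot(instants, v[:, j], ls="--", color=line.get_color(),
                label=f"v{j + 1}")
    ax.set_xlabel("normalized time")
    ax.set_ylabel("canonical value")
    ax.legend(fontsize="small", ncol=2)
    return ax
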