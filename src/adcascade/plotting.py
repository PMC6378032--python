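"""Basic trajectory figures.

Curves are rendered with a display floor of 0.05: levels below the minimal
graphed biomarker level are drawn at 0.05 so that sigmoids with different
onset delays remain visually comparable.  The floor is cosmetic only — it
never enters the dynamics or any analysis.
"""

from __future__ import annotations

import numpy as np

from adcascade.simulation import Trajectory

__all__ = ["PLOT_FLOOR", "plot_risk_pair"]

PLOT_FLOOR = 0.05

_STYLES = {
    "a_beta": ("tab:red", "amyloid"),
    "tau_total": ("tab:blue", "total tau"),
    "n_deg": ("tab:olive", "neurodegeneration"),
}


def plot_risk_pair(low: Trajectory, high: Trajectory, ax=None, floor: float = PLOT_FLOOR):
    """Plot amyloid, total tau, neurodegeneration, and both cognition curves."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for name, (color, label) in _STYLES.items():
        ax.plot(low.ages, np.maximum(low.series(name), floor), color=color, label=label)
    ax.plot(low.ages, np.maximum(low.cog, floor), color="tab:green", ls="--", label="cognition (low risk)")
    ax.plot(high.ages, np.maximum(high.cog, floor), color="tab:green", label="cognition (high risk)")
    ax.set_xlabel("age (years)")
    ax.set_ylabel("normalized biomarker level")
    ax.set_ylim(0, 1.05)
    ax.legend(loc="upper left", fontsize=8)
    return ax
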