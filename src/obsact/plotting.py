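"""Quarter-circle BIAS vs sqrt(VAR) plot (equal-RMSE arcs)."""

from __future__ import annotations

import numpy as np

__all__ = ["bias_sqrtvar_plot"]


def bias_sqrtvar_plot(points, ax=None, n_arcs: int = 4):
    """Scatter (bias, sqrt_var) points with dashed equal-RMSE quarter circles.

    `points` is an iterable of (label, bias, sqrt_var).  Returns the axes.
    Requires matplotlib (optional dependency).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    pts = [(str(lab), float(b), float(v)) for lab, b, v in points]
    rmax = max((np.hypot(b, v) for _, b, v in pts), default=1.0)
    theta = np.linspace(0, np.pi / 2, 100)
    for r in np.linspace(rmax / n_arcs, rmax * 1.1, n_arcs):
        ax.plot(r * np.cos(theta), r * np.sin(theta), "--", color="0.8", lw=0.8, zorder=0)
    for lab, b, v in pts:
        ax.plot(b, v, "o", label=lab)
    ax.set_xlabel("BIAS")
    ax.set_ylabel(r"$\sqrt{\mathrm{VAR}}$")
    ax.set_xlim(left=0)
    ax.set_ylim(bottom=0)
    ax.set_aspect("equal")
    ax.legend(frameon=False, fontsize=8)
    return ax
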