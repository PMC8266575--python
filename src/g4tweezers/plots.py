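"""Minimal plotting helpers (histogram-with-fit panels)."""

from __future__ import annotations

import numpy as np

from .bell import ramp_pdf
from .mixture import MixtureFit


def plot_force_histogram(forces, fit: MixtureFit | None = None, path=None, bin_width: float = 2.0):
    """Rupture-force histogram with the fitted mixture density overlaid.

    Returns the matplotlib figure; saves to ``path`` if given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    forces = np.asarray(forces, dtype=float)
    fig, ax = plt.subplots(figsize=(5, 3.2))
    lo = fit.protocol.f_start if fit is not None else forces.min()
    hi = fit.protocol.f_end if fit is not None else forces.max()
    edges = np.arange(lo, hi + bin_width, bin_width)
    ax.hist(forces, bins=edges, density=True, color="0.75", edgecolor="0.4")
    if fit is not None:
        grid = np.linspace(lo, hi, 400)
        total = np.zeros_like(grid)
        for comp in fit.components:
            pdf = comp.weight * ramp_pdf(grid, comp.to_state(), fit.protocol)
            total += pdf
            ax.plot(grid, pdf, lw=1, ls="--")
        ax.plot(grid, total, lw=1.8, color="crimson")
    ax.set_xlabel("unfolding force (pN)")
    ax.set_ylabel("probability density (pN$^{-1}$)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
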