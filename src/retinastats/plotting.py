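"""Minimal figures: orientation rose plots and power-spectrum contours."""

from __future__ import annotations

import numpy as np

from .edges import orientation_histogram


def rose_plot(angles_deg, n_bins: int = 36, ax=None, **kwargs):
    """Polar rose of an orientation distribution (mirrored onto the full circle)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    density, edges = orientation_histogram(np.asarray(angles_deg), n_bins)
    centers = np.radians((edges[:-1] + edges[1:]) / 2.0)
    width = np.radians(180.0 / n_bins)
    for offset in (0.0, np.pi):  # axial data: show both half-circles
        ax.bar(centers + offset, density, width=width, **kwargs)
    ax.set_yticklabels([])
    return ax


def spectrum_contour(ps, levels=(0.5, 0.7, 0.9), ax=None, **kwargs):
    """Contours of cumulative log-power percentiles of a power spectrum."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    u, v = ps.freq_grids()
    logp = np.full_like(ps.power, -np.inf)
    np.log(ps.power, out=logp, where=ps.power > 0)
    finite = np.isfinite(logp)
    vals = np.quantile(logp[finite], levels)
    ax.contour(u, v, np.where(finite, logp, np.nan), levels=sorted(vals), **kwargs)
    ax.set_xlabel("u (cycles/px)")
    ax.set_ylabel("v (cycles/px)")
    ax.set_aspect("equal")
    return ax
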