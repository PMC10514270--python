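"""Basic diagnostic figures."""

from __future__ import annotations

import numpy as np

from .network import DomainGeometry, VesselNetwork

__all__ = ["plot_network", "plot_fluctuations"]


def plot_network(network: VesselNetwork, domain: DomainGeometry | None = None,
                 t: float = 0.0, ax=None, color="k", dead_color="0.8",
                 linewidth=0.6):
    """Draw the vessel skeleton (dead segments in light grey)."""
    import matplotlib.pyplot as plt
    from matplotlib.collections import LineCollection

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for alive, c in ((True, color), (False, dead_color)):
        mask = network.seg_alive == alive
        seg = network.segments[mask]
        if len(seg):
            lines = np.stack([network.coords[seg[:, 0]], network.coords[seg[:, 1]]], axis=1)
            ax.add_collection(LineCollection(lines, colors=c, linewidths=linewidth))
    if domain is not None:
        R = domain.radius(t)
        th = np.linspace(0, np.pi, 200)
        ax.plot(R * np.cos(th), R * np.sin(th), "--", color="0.5", lw=0.8)
        ax.plot([-R, R], [0, 0], "--", color="0.5", lw=0.8)
    ax.set_aspect("equal")
    ax.autoscale()
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    return ax


def plot_fluctuations(result, ax=None):
    """log SD vs log mean window mass with the fitted slope."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.loglog(result.means, result.sds, "o")
    x = np.array([result.means.min(), result.means.max()])
    c = result.sds[0] / result.means[0] ** result.alpha
    ax.loglog(x, c * x ** result.alpha, "-",
              label=f"alpha = {result.alpha:.2f} +/- {result.stderr:.2f}")
    ax.set_xlabel("mean window mass (um)")
    ax.set_ylabel("SD of window mass (um)")
    ax.legend()
    return ax
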