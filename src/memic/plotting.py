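"""Profile plots: moving-median line with an interquartile band."""

from __future__ import annotations

import numpy as np

from .profiling import SpatialProfile

__all__ = ["plot_profile"]


def plot_profile(profile: SpatialProfile, ax=None, label: str | None = None, color=None):
    """Plot a spatial profile as a median line over a shaded IQR band.

    Unpopulated windows appear as gaps. Returns the axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    mask = profile.populated
    x = np.where(mask, profile.centers, np.nan)
    ax.fill_between(x, profile.q25, profile.q75, alpha=0.3, color=color, linewidth=0)
    ax.plot(x, profile.median, color=color, label=label)
    ax.set_xlabel("distance from opening (µm)")
    ax.set_ylabel("intensity (a.u.)")
    if label:
        ax.legend(frameon=False)
    return ax
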