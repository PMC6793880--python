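"""Convenience figures: the d13C-d15N biplot with standard ellipses."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib
import numpy as np

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402
from matplotlib.patches import Ellipse  # noqa: E402

from .records import IsotopeRecord


def _ellipse_patch(xy: np.ndarray, **kwargs) -> Ellipse:
    """1-sigma ellipse of a point cloud's sample covariance."""
    mean = xy.mean(axis=0)
    cov = np.cov(xy, rowvar=False)
    vals, vecs = np.linalg.eigh(cov)
    angle = np.degrees(np.arctan2(vecs[1, -1], vecs[0, -1]))
    return Ellipse(mean, 2 * np.sqrt(vals[-1]), 2 * np.sqrt(vals[0]),
                   angle=angle, fill=False, **kwargs)


def plot_biplot(records: Sequence[IsotopeRecord],
                path: str | Path | None = None,
                by: str = "species"):
    """Scatter of fish in isotope space with a 1-sigma ellipse per group.

    Groups by species (default) or by area; returns the figure.
    """
    fig, ax = plt.subplots(figsize=(6, 5))
    groups: dict[str, list] = {}
    for r in records:
        groups.setdefault(getattr(r, by), []).append((r.d13c, r.d15n))
    cmap = plt.get_cmap("tab10")
    for i, (label, pts) in enumerate(sorted(groups.items())):
        xy = np.asarray(pts)
        color = cmap(i % 10)
        ax.scatter(xy[:, 0], xy[:, 1], s=14, color=color, label=label, alpha=0.7)
        if len(xy) >= 3:
            ax.add_patch(_ellipse_patch(xy, edgecolor=color, linewidth=1.2))
    ax.set_xlabel("$\\delta^{13}$C (‰)")
    ax.set_ylabel("$\\delta^{15}$N (‰)")
    ax.legend(fontsize=8, frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
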