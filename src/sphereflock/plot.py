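"""Minimal static snapshot plotter (convenience only)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .simulator import SwarmState


def plot_snapshot(state: SwarmState, r: float, path: str | Path, elev: float = 20.0, azim: float = 30.0) -> None:
    """3-D scatter of agent positions with a wireframe sphere."""
    fig = plt.figure(figsize=(5, 5))
    ax = fig.add_subplot(projection="3d")
    u, v = np.meshgrid(np.linspace(0, 2 * np.pi, 24), np.linspace(0, np.pi, 12))
    ax.plot_wireframe(
        r * np.cos(u) * np.sin(v), r * np.sin(u) * np.sin(v), r * np.cos(v),
        color="lightgray", linewidth=0.4,
    )
    p = state.positions
    ax.scatter(p[:, 0], p[:, 1], p[:, 2], s=4, c="crimson", depthshade=False)
    ax.set_box_aspect((1, 1, 1))
    ax.view_init(elev=elev, azim=azim)
    ax.set_axis_off()
    ax.set_title(f"step {state.step}")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
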