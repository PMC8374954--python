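"""Headless-safe figures mirroring the standard waveform-analysis panels:
B-space loops, representative beat cycle with SD ribbons, amplitude
envelopes, and time-averaged power-density curves."""

from __future__ import annotations

import os

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["comparison_figures"]


def comparison_figures(results: dict, out_dir: str | os.PathLike) -> list[str]:
    """One four-panel PNG per group; returns the written paths."""
    by_group: dict[str, list] = {}
    for r in results.values():
        by_group.setdefault(r.group or "all", []).append(r)
    written = []
    for group, rs in sorted(by_group.items()):
        fig, axes = plt.subplots(2, 2, figsize=(9, 7))
        ax = axes[0, 0]
        for r in rs[:5]:
            ax.plot(r.decomposition.coeffs[:, 0], r.decomposition.coeffs[:, 1], lw=0.5)
        ax.set_xlabel("B1")
        ax.set_ylabel("B2")
        ax.set_title(f"{group}: shape cycles in B-space")

        ax = axes[0, 1]
        b = rs[0].beat_average
        cmap = plt.get_cmap("viridis")
        for i in range(0, len(b.phase_grid), max(1, len(b.phase_grid) // 16)):
            ax.plot(b.mean_x[i], b.mean_y[i], color=cmap(b.phase_grid[i]), lw=0.8)
        ax.set_aspect("equal")
        ax.set_xlabel("x (μm)")
        ax.set_ylabel("y (μm)")
        ax.set_title("representative beat cycle")

        ax = axes[1, 0]
        amps = np.vstack([r.amplitude.amplitude for r in rs])
        for a in amps:
            ax.plot(rs[0].amplitude.arc_grid, a, color="0.7", lw=0.5)
        ax.plot(rs[0].amplitude.arc_grid, amps.mean(axis=0), color="C0", lw=2)
        ax.set_xlabel("s (μm)")
        ax.set_ylabel("amplitude / L")
        ax.set_title("amplitude envelope")

        ax = axes[1, 1]
        pbars = np.vstack([r.power.p_bar for r in rs])
        ax.plot(rs[0].power.arc_grid, pbars.mean(axis=0) * 1e8, color="C3", lw=2)
        ax.fill_between(
            rs[0].power.arc_grid,
            (pbars.mean(axis=0) - pbars.std(axis=0)) * 1e8,
            (pbars.mean(axis=0) + pbars.std(axis=0)) * 1e8,
            alpha=0.3,
            color="C3",
        )
        ax.set_xlabel("s (μm)")
        ax.set_ylabel("p̄ (10⁻⁸ W/m)")
        ax.set_title("time-averaged power density")

        fig.tight_layout()
        path = os.path.join(out_dir, f"{group}_panels.png")
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
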