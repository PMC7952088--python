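"""Optional matplotlib renders of pipeline outputs (PNG)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["plot_results"]


def plot_results(results, out_dir: str | Path) -> list[Path]:
    """Render composite histograms, the TDP and an example idealized trace."""
    out = Path(out_dir)
    written = []

    fig, ax = plt.subplots(figsize=(5, 3.2))
    for d in results.densities:
        if not d.empty:
            ax.plot(d.grid, d.density, label=f"state {d.state}")
    ax.set_xlabel("apparent FRET efficiency")
    ax.set_ylabel("density")
    ax.legend(frameon=False)
    fig.tight_layout()
    p = out / "histograms.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    written.append(p)

    if not results.tdp.empty:
        fig, ax = plt.subplots(figsize=(4, 3.6))
        g = results.tdp.grid
        ax.imshow(
            results.tdp.density.T, origin="lower",
            extent=(g[0], g[-1], g[0], g[-1]), aspect="equal", cmap="viridis",
        )
        ax.set_xlabel("initial E")
        ax.set_ylabel("final E")
        fig.tight_layout()
        p = out / "tdp.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        written.append(p)

    if results.fret_traces:
        import numpy as np

        ft = results.fret_traces[0]
        path = results.paths[0]
        ideal = results.model.means[
            path.labels.clip(min=0)
        ] * (path.labels >= 0)
        fig, ax = plt.subplots(figsize=(6, 2.6))
        t = ft.frame_dt * np.arange(len(ft.E))
        ax.plot(t, ft.E, lw=0.6, color="0.6", label="E")
        ax.plot(t, ideal, lw=1.2, color="C3", label="idealized")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("E")
        ax.set_ylim(-0.25, 1.1)
        ax.legend(frameon=False)
        fig.tight_layout()
        p = out / "example_trace.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        written.append(p)
    return written
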