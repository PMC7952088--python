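"""Composite state histograms, populations and transition density plots.

After Viterbi idealization, every frame carries a state label. Composite
FRET histograms pool all frames assigned to one state across every trace of
a condition and smooth them with a Gaussian kernel density estimate
(bandwidth 0.04 on the FRET axis). State populations are the frame-weighted
fractions over bound states; their uncertainties come from a trace-level
bootstrap. Transition density plots (TDPs) place one 2-D point per pair of
adjacent dwells at (median E of the initial dwell, median E of the final
dwell); dwells in the unbound configuration -- where no FRET efficiency is
defined -- are drawn at a sentinel value of -0.2, so binding/dissociation
events appear as peaks on the sentinel row/column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import KernelDensity

__all__ = [
    "Density",
    "TdpGrid",
    "composite_histogram",
    "state_populations",
    "transition_density",
    "exo_population_correction",
    "UNBOUND_SENTINEL",
]

UNBOUND_SENTINEL = -0.2
_GRID_LO, _GRID_HI = -0.3, 1.2


@dataclass
class Density:
    """1-D composite FRET density for one state."""

    grid: np.ndarray
    density: np.ndarray
    state: int
    n_traces: int
    n_points: int

    @property
    def empty(self) -> bool:
        return self.n_points == 0

    def peak(self) -> float:
        return float(self.grid[np.argmax(self.density)])

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


@dataclass
class TdpGrid:
    """2-D transition density over (initial E, final E)."""

    grid: np.ndarray
    density: np.ndarray
    n_transitions: int
    points: np.ndarray
    sentinel: float = UNBOUND_SENTINEL

    @property
    def empty(self) -> bool:
        return self.n_transitions == 0

    def integral(self) -> float:
        return float(
            np.trapezoid(np.trapezoid(self.density, self.grid, axis=1), self.grid)
        )


def _pooled_state_values(fret_traces, paths, state: int) -> tuple[np.ndarray, int]:
    values = []
    n_traces = 0
    for ft, path in zip(fret_traces, paths):
        sel = path.labels == state
        if sel.any():
            values.append(ft.E[sel])
            n_traces += 1
    pooled = np.concatenate(values) if values else np.empty(0)
    return pooled, n_traces


def composite_histogram(
    fret_traces,
    paths,
    state: int,
    bandwidth: float = 0.04,
    grid: np.ndarray | None = None,
) -> Density:
    """Composite KDE histogram of all E values assigned to one state.

    Gaussian kernel, bandwidth 0.04, evaluated on a 500-point grid over
    [-0.3, 1.2] by default. The returned density integrates to 1.
    """
    if grid is None:
        grid = np.linspace(_GRID_LO, _GRID_HI, 500)
    pooled, n_traces = _pooled_state_values(fret_traces, paths, state)
    if pooled.size == 0:
        return Density(
            grid=grid, density=np.zeros_like(grid), state=state,
            n_traces=0, n_points=0,
        )
    kde = KernelDensity(kernel="gaussian", bandwidth=bandwidth)
    kde.fit(pooled[:, None])
    density = np.exp(kde.score_samples(grid[:, None]))
    return Density(
        grid=grid, density=density, state=state,
        n_traces=n_traces, n_points=int(pooled.size),
    )


def state_populations(
    paths,
    states: list[int] | None = None,
    exclude_states: tuple[int, ...] = (),
    n_boot: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Frame-weighted state populations with trace-bootstrap uncertainties.

    Populations are fractions of frames per state among the counted states;
    ``exclude_states`` removes the unbound state from the denominator so
    bound-state populations sum to 1, matching how per-state histogram
    areas are reported.
    """
    if not paths:
        raise ValueError("need at least one decoded path")
    counted = []
    for path in paths:
        lab = path.labels
        keep = lab >= 0
        for s in exclude_states:
            keep &= lab != s
        counted.append(lab[keep])
    all_labels = np.concatenate(counted)
    if states is None:
        states = sorted(int(s) for s in np.unique(all_labels))
    counts = np.array([(all_labels == s).sum() for s in states], dtype=float)
    total = counts.sum()
    if total == 0:
        raise ValueError("no frames in the counted states")
    fractions = counts / total

    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, len(states)))
    n = len(counted)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        lab = np.concatenate([counted[i] for i in idx])
        c = np.array([(lab == s).sum() for s in states], dtype=float)
        boot[b] = c / max(c.sum(), 1.0)
    return pd.DataFrame(
        {
            "state": states,
            "population": fractions,
            "population_sd": boot.std(axis=0, ddof=1),
            "n_frames": counts.astype(int),
        }
    )


def _transition_points(
    fret_traces, paths, unbound_state: int | None, sentinel: float
) -> np.ndarray:
    """One (initial median E, final median E) point per adjacent dwell pair."""
    pts = []
    for ft, path in zip(fret_traces, paths):
        segs = path.segments()
        med = []
        for state, start, length in segs:
            if unbound_state is not None and state == unbound_state:
                med.append(sentinel)
            else:
                med.append(float(np.median(ft.E[start : start + length])))
        for a, b in zip(range(len(segs) - 1), range(1, len(segs))):
            sa, ia, la = segs[a]
            sb, ib, lb = segs[b]
            if ib != ia + la:  # gap in the analysis region: not adjacent
                continue
            if sa == sb:
                continue
            pts.append((med[a], med[b]))
    return np.asarray(pts, dtype=float).reshape(-1, 2)


def transition_density(
    fret_traces,
    paths,
    bandwidth: float = 0.04,
    unbound_state: int | None = None,
    unbound_sentinel: float = UNBOUND_SENTINEL,
    grid: np.ndarray | None = None,
) -> TdpGrid:
    """Transition density plot from adjacent-dwell median FRET pairs.

    ``unbound_state`` designates the model state (if any) representing
    unbound DNA; its dwells contribute the sentinel FRET value, placing
    binding and dissociation events on the sentinel column/row of the plot.
    """
    if grid is None:
        grid = np.linspace(_GRID_LO, _GRID_HI, 151)
    pts = _transition_points(fret_traces, paths, unbound_state, unbound_sentinel)
    if pts.shape[0] == 0:
        return TdpGrid(
            grid=grid, density=np.zeros((grid.size, grid.size)),
            n_transitions=0, points=pts, sentinel=unbound_sentinel,
        )
    kde = KernelDensity(kernel="gaussian", bandwidth=bandwidth).fit(pts)
    gx, gy = np.meshgrid(grid, grid, indexing="ij")
    flat = np.column_stack([gx.ravel(), gy.ravel()])
    density = np.exp(kde.score_samples(flat)).reshape(grid.size, grid.size)
    return TdpGrid(
        grid=grid, density=density, n_transitions=int(pts.shape[0]),
        points=pts, sentinel=unbound_sentinel,
    )


def exo_population_correction(
    pop_wt: float,
    pop_mut: float,
    sd_wt: float = 0.0,
    sd_mut: float = 0.0,
) -> tuple[float, float, float]:
    """Split the 0.6-FRET population into 5'-nuclease and exo contributions.

    The exonuclease site mutant (L361A) cannot bind DNA at the exo domain,
    so the drop of the 0.6-FRET population between wild type and mutant
    measures the exo-engaged fraction (state E); the remainder is the
    corrected 5'-nuclease fraction (state N). Returns
    ``(exo_fraction, corrected_n_fraction, propagated_sd)`` with the SD from
    quadrature of the two population SDs.
    """
    import warnings

    diff = pop_wt - pop_mut
    sd = float(np.hypot(sd_wt, sd_mut))
    if diff < 0 and sd > 0 and -diff > 2 * sd:
        warnings.warn(
            "mutant population exceeds wild type by more than 2 SD; the "
            "mutation appears to increase this state's population",
            RuntimeWarning,
        )
    exo = max(diff, 0.0)
    return exo, pop_wt - exo, sd
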