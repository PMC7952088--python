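"""Synthetic smFRET trace generation for the Pol I-DNA kinetic scheme.

The generator realizes a continuous-time Markov chain (CTMC) over the
configurations a Pol I-DNA complex can adopt -- unbound DNA (U), DNA engaging
the polymerase domain (P), the 5' nuclease domain (N), the proofreading
exonuclease domain (E), and the pol-engaged / 5'-nuclease-extended form (P')
-- and renders donor/acceptor intensity traces under either of the two
labeling schemes used in the study:

* scheme 1 -- donor on the DNA: a donor signal is present whether or not
  protein is bound, and binding is read out as a FRET change;
* scheme 2 -- donor on the protein: no signal at all while the protein is
  absent, FRET while bound.

Dwell times are exponential with the state's total exit rate; the next state
is chosen proportional to the outgoing rates (Gillespie realization). Frames
are produced by majority-occupancy quantization at the camera frame interval,
and rendering adds per-frame FRET jitter, per-channel Gaussian noise,
donor->acceptor leakage, additive background, and a single-step donor
photobleach after which both channels fall to background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .trace_io import IntensityTrace, TraceSet

__all__ = [
    "KineticScheme",
    "PhotophysicsModel",
    "GroundTruth",
    "simulate_state_path",
    "render_trace",
    "simulate_dataset",
    "pol1_scheme1_default",
    "binding_only_scheme",
]

#: default single-molecule total emission level, a.u.
DEFAULT_TOTAL_INTENSITY = 350.0


@dataclass
class KineticScheme:
    """Kinetic scheme: states, exchange rates and per-state FRET signatures.

    Parameters
    ----------
    state_names
        Labels, a subset of ``{"U", "P", "N", "E", "P'"}``.
    rate_matrix
        Square array; entry ``[i, j]`` is the rate constant ``k_{i->j}`` in
        1/s for ``i != j``. The diagonal is ignored.
    bound_flags
        Per state, whether the protein is DNA-bound. At most one unbound
        state is allowed.
    fret_means
        Per state, the mean apparent FRET efficiency under the labeling
        scheme being simulated.
    fret_sds
        Per state, the emission SD of the apparent FRET efficiency
        (photophysical broadening on top of channel noise).
    """

    state_names: list[str]
    rate_matrix: np.ndarray
    bound_flags: np.ndarray
    fret_means: np.ndarray
    fret_sds: np.ndarray

    def __post_init__(self) -> None:
        self.rate_matrix = np.asarray(self.rate_matrix, dtype=float)
        self.bound_flags = np.asarray(self.bound_flags, dtype=bool)
        self.fret_means = np.asarray(self.fret_means, dtype=float)
        self.fret_sds = np.asarray(self.fret_sds, dtype=float)
        n = len(self.state_names)
        if self.rate_matrix.shape != (n, n):
            raise ValueError(
                f"rate_matrix shape {self.rate_matrix.shape} does not match "
                f"{n} states"
            )
        off = self.rate_matrix[~np.eye(n, dtype=bool)]
        if np.any(off < 0):
            raise ValueError("all rate constants must be >= 0")
        if np.count_nonzero(~self.bound_flags) > 1:
            raise ValueError("at most one unbound state is allowed")
        if np.any(self.fret_means < -0.2) or np.any(self.fret_means > 1.2):
            raise ValueError("fret_means must lie in [-0.2, 1.2]")
        if np.any(self.fret_sds < 0):
            raise ValueError("fret_sds must be >= 0")

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    def exit_rates(self) -> np.ndarray:
        """Total exit rate of each state, 1/s."""
        q = self.rate_matrix.copy()
        np.fill_diagonal(q, 0.0)
        return q.sum(axis=1)

    def stationary_distribution(self) -> np.ndarray:
        """Stationary distribution of the CTMC (null space of the generator)."""
        q = self.rate_matrix.copy()
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        # solve pi Q = 0, sum(pi) = 1
        a = np.vstack([q.T, np.ones(self.n_states)])
        b = np.zeros(self.n_states + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(a, b, rcond=None)
        pi = np.clip(pi, 0.0, None)
        return pi / pi.sum()

    def unbound_index(self) -> int | None:
        idx = np.flatnonzero(~self.bound_flags)
        return int(idx[0]) if idx.size else None


@dataclass
class PhotophysicsModel:
    """Acquisition/photophysics parameters for rendering intensity traces.

    All intensities are in camera arbitrary units (a.u.); rates in 1/s.
    """

    total_intensity: float = DEFAULT_TOTAL_INTENSITY
    background_d: float = 20.0
    background_a: float = 15.0
    noise_sd: float = 10.0
    leakage_alpha: float = 0.08
    bleach_rate: float = 0.05

    def __post_init__(self) -> None:
        if self.total_intensity <= 0:
            raise ValueError("total_intensity must be > 0")
        if not 0.0 <= self.leakage_alpha <= 0.3:
            raise ValueError("leakage_alpha must lie in [0, 0.3]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.bleach_rate < 0:
            raise ValueError("bleach_rate must be >= 0")


@dataclass
class GroundTruth:
    """True state paths and parameters retained for parameter-recovery tests."""

    scheme: KineticScheme
    frame_dt: float
    seed: int
    state_paths: list[np.ndarray] = field(default_factory=list)
    bleach_indices: list[int | None] = field(default_factory=list)

    def to_frame(self):
        """Long-format table (trace_index, frame, state_label)."""
        import pandas as pd

        rows = []
        for i, path in enumerate(self.state_paths):
            rows.append(
                pd.DataFrame(
                    {
                        "trace_index": i,
                        "frame": np.arange(path.size),
                        "state": path,
                        "state_label": [self.scheme.state_names[s] for s in path],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def _gillespie_events(
    scheme: KineticScheme, duration: float, rng: np.random.Generator,
    start_state: int | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Event sequence (states, entry times) of one CTMC realization."""
    exit_rates = scheme.exit_rates()
    q = scheme.rate_matrix.copy()
    np.fill_diagonal(q, 0.0)
    if start_state is None:
        state = int(rng.choice(scheme.n_states, p=scheme.stationary_distribution()))
    else:
        state = int(start_state)
    states = [state]
    times = [0.0]
    t = 0.0
    while True:
        k = exit_rates[state]
        if k <= 0.0:  # absorbing state: occupies the rest of the trace
            break
        t += rng.exponential(1.0 / k)
        if t >= duration:
            break
        state = int(rng.choice(scheme.n_states, p=q[state] / k))
        states.append(state)
        times.append(t)
    return np.asarray(states, dtype=np.int64), np.asarray(times, dtype=float)


def _quantize_majority(
    states: np.ndarray, times: np.ndarray, duration: float, frame_dt: float,
    n_states: int,
) -> np.ndarray:
    """Assign each frame the state occupying the majority of its interval.

    Ties break toward the lower state index.
    """
    n_frames = int(round(duration / frame_dt))
    occ = np.zeros((n_frames, n_states))
    ends = np.append(times[1:], duration)
    for s, t0, t1 in zip(states, times, ends):
        f0 = int(t0 / frame_dt)
        f1 = min(int(np.ceil(t1 / frame_dt)), n_frames)
        if f1 <= f0:
            continue
        frames = np.arange(f0, f1)
        lo = np.maximum(frames * frame_dt, t0)
        hi = np.minimum((frames + 1) * frame_dt, t1)
        occ[frames, s] += np.clip(hi - lo, 0.0, None)
    return occ.argmax(axis=1).astype(np.int64)


def simulate_state_path(
    scheme: KineticScheme,
    duration: float,
    frame_dt: float,
    seed: int | np.random.Generator,
    start_state: int | None = None,
) -> np.ndarray:
    """Simulate one frame-quantized CTMC state path.

    Parameters
    ----------
    scheme
        The kinetic scheme.
    duration
        Total observation time, s.
    frame_dt
        Camera frame interval, s.
    seed
        Seed or generator for the realization.
    start_state
        Initial state index; drawn from the stationary distribution if None.

    Returns
    -------
    ndarray of int
        Per-frame state indices, length ``round(duration / frame_dt)``.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if frame_dt <= 0:
        raise ValueError("frame_dt must be > 0")
    rng = np.random.default_rng(seed)
    states, times = _gillespie_events(scheme, duration, rng, start_state)
    return _quantize_majority(states, times, duration, frame_dt, scheme.n_states)


def render_trace(
    path: np.ndarray,
    scheme: KineticScheme,
    phot: PhotophysicsModel,
    labeling_scheme: int,
    seed: int | np.random.Generator,
    frame_dt: float = 0.1,
    trace_id: str = "trace",
) -> IntensityTrace:
    """Render a frame-quantized state path into donor/acceptor intensities.

    Signal-bearing frames emit ``total_intensity`` split between the channels
    by the state's apparent FRET efficiency (with per-frame Gaussian FRET
    jitter of ``fret_sd``); under labeling scheme 2, frames in the unbound
    state carry no signal at all. Donor leakage adds ``alpha * donor`` to the
    acceptor channel; both channels then get additive background and Gaussian
    read noise. A donor bleach time is drawn ``Exponential(bleach_rate)``;
    from that frame on, both channels contain only background and noise.
    """
    if labeling_scheme not in (1, 2):
        raise ValueError("labeling_scheme must be 1 or 2")
    rng = np.random.default_rng(seed)
    path = np.asarray(path, dtype=np.int64)
    n = path.size

    e = scheme.fret_means[path] + scheme.fret_sds[path] * rng.standard_normal(n)
    signal = np.full(n, phot.total_intensity)
    if labeling_scheme == 2:
        unbound = ~scheme.bound_flags[path]
        signal[unbound] = 0.0
        e[unbound] = 0.0

    bleach_index: int | None = None
    if phot.bleach_rate > 0:
        t_bleach = rng.exponential(1.0 / phot.bleach_rate)
        idx = int(np.ceil(t_bleach / frame_dt))
        if idx < n:
            bleach_index = idx
            signal[idx:] = 0.0

    donor = signal * (1.0 - e)
    acceptor = signal * e + phot.leakage_alpha * donor
    donor = donor + phot.background_d + phot.noise_sd * rng.standard_normal(n)
    acceptor = acceptor + phot.background_a + phot.noise_sd * rng.standard_normal(n)
    return IntensityTrace(
        id=trace_id,
        donor=donor,
        acceptor=acceptor,
        frame_dt=frame_dt,
        bleach_index=bleach_index,
    )


def simulate_dataset(
    scheme: KineticScheme,
    phot: PhotophysicsModel,
    n_traces: int,
    duration: float,
    frame_dt: float,
    labeling_scheme: int,
    seed: int,
    metadata: dict | None = None,
) -> tuple[TraceSet, GroundTruth]:
    """Simulate an independent set of traces with retained ground truth.

    Per-trace randomness comes from child streams spawned deterministically
    from the master seed (`numpy.random.SeedSequence.spawn`), so the dataset
    is reproducible and each trace is independent.
    """
    if n_traces < 1:
        raise ValueError("n_traces must be >= 1")
    master = np.random.SeedSequence(seed)
    truth = GroundTruth(scheme=scheme, frame_dt=frame_dt, seed=seed)
    traces = []
    for i, child in enumerate(master.spawn(n_traces)):
        rng = np.random.default_rng(child)
        path = simulate_state_path(scheme, duration, frame_dt, rng)
        trace = render_trace(
            path, scheme, phot, labeling_scheme, rng,
            frame_dt=frame_dt, trace_id=f"trace_{i:04d}",
        )
        traces.append(trace)
        truth.state_paths.append(path)
        truth.bleach_indices.append(trace.bleach_index)
    meta = {"labeling_scheme": labeling_scheme}
    if metadata:
        meta.update(metadata)
    ts = TraceSet(traces=traces, frame_dt=frame_dt, metadata=meta)
    return ts, truth


def pol1_scheme1_default(
    k_pn: float = 1.0,
    k_np: float = 2.0,
    k_pu: float = 0.5,
    k_nu: float = 0.5,
    k_up: float = 1.0,
) -> KineticScheme:
    """Three-configuration scheme-1 default: U <-> P <-> N with dissociation.

    States (U, P, N) with apparent FRET means 0.05 / 0.8 / 0.6 and emission
    SD 0.07, the state centers of the donor-on-DNA labeling scheme.
    """
    names = ["U", "P", "N"]
    q = np.zeros((3, 3))
    q[0, 1] = k_up
    q[1, 2] = k_pn
    q[1, 0] = k_pu
    q[2, 1] = k_np
    q[2, 0] = k_nu
    return KineticScheme(
        state_names=names,
        rate_matrix=q,
        bound_flags=np.array([False, True, True]),
        fret_means=np.array([0.05, 0.8, 0.6]),
        fret_sds=np.array([0.07, 0.07, 0.07]),
    )


def binding_only_scheme(k_on: float = 0.5, k_off: float = 0.5) -> KineticScheme:
    """Two-state U <-> P binding/dissociation scheme (scheme-1 signatures)."""
    q = np.zeros((2, 2))
    q[0, 1] = k_on
    q[1, 0] = k_off
    return KineticScheme(
        state_names=["U", "P"],
        rate_matrix=q,
        bound_flags=np.array([False, True]),
        fret_means=np.array([0.05, 0.8]),
        fret_sds=np.array([0.07, 0.07]),
    )
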