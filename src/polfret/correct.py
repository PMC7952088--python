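"""Trace correction, FRET computation and quality selection.

The correction chain mirrors standard smFRET practice: the additive
background of each channel is estimated as the median signal after the
donor photobleach and subtracted; donor leakage into the acceptor channel is
removed as ``acceptor - alpha * donor``; the apparent FRET efficiency is then

    E = I_A / (I_A + I_D)

per frame from the corrected intensities. Traces are selected for analysis
when they show anti-correlated donor/acceptor fluctuations, constant total
intensity and a single-step photobleach.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from scipy.stats import pearsonr

from .trace_io import IntensityTrace, TraceSet

__all__ = [
    "FretTrace",
    "QcReport",
    "detect_photobleach",
    "subtract_background",
    "correct_leakage",
    "compute_fret",
    "qc_select",
    "correct_traceset",
]


@dataclass
class FretTrace:
    """Per-frame apparent FRET efficiency with validity/bound masks.

    ``E`` is clipped to [0, 1]; the unclipped values are kept in ``E_raw``
    for debugging. ``valid_mask`` marks finite, pre-bleach frames;
    ``bound_mask`` additionally requires detectable signal (always true for
    valid frames under labeling scheme 1, where unbound DNA still emits a
    donor signal).
    """

    E: np.ndarray
    valid_mask: np.ndarray
    bound_mask: np.ndarray
    frame_dt: float
    E_raw: np.ndarray | None = None
    trace_id: str = ""

    def __post_init__(self) -> None:
        if not (len(self.E) == len(self.valid_mask) == len(self.bound_mask)):
            raise ValueError("E and masks must have equal length")
        if np.any(~np.isfinite(self.E[self.valid_mask & self.bound_mask])):
            raise ValueError("E must be finite wherever valid and bound")

    @property
    def analysis_mask(self) -> np.ndarray:
        return self.valid_mask & self.bound_mask

    def segments(self) -> list[tuple[int, np.ndarray]]:
        """Contiguous analysis-eligible runs as (start_frame, E values).

        Returns the unclipped efficiencies when available: model fitting
        assumes Gaussian emissions, and clipping the low-FRET tail at zero
        would put a point mass there that a Gaussian cannot represent. The
        clipped ``E`` stays the reported value for histograms and exports.
        """
        values = self.E_raw if self.E_raw is not None else self.E
        mask = self.analysis_mask
        out = []
        edges = np.flatnonzero(np.diff(mask.astype(int)))
        starts = [0] if mask[0] else []
        starts += [int(e) + 1 for e in edges if mask[e + 1]]
        ends = [int(e) + 1 for e in edges if mask[e]]
        if mask[-1]:
            ends.append(len(mask))
        for s, e in zip(starts, ends):
            out.append((s, values[s:e]))
        return out


@dataclass
class QcReport:
    """Per-trace quality verdict with the three selection criteria."""

    trace_id: str
    anticorrelated: bool
    constant_total: bool
    single_bleach: bool
    bleach_index: int | None
    n_steps: int
    reasons: list[str] = field(default_factory=list)

    @property
    def accept(self) -> bool:
        return self.anticorrelated and self.constant_total and self.single_bleach


def _robust_noise_sd(total: np.ndarray) -> float:
    """Noise SD of the total-intensity signal from successive differences."""
    d = np.diff(total)
    if d.size == 0:
        return 0.0
    return 1.4826 * float(np.median(np.abs(d))) / np.sqrt(2.0)


def _down_steps(med: np.ndarray, sigma: float, window: int) -> list[int]:
    """Indices of sustained downward level changes in a smoothed signal.

    A step is a cluster of adjacent frames whose smoothed decrement exceeds
    max(5 sigma, 10% of the signal's dynamic range); consecutive significant
    frames within one smoothing window merge into a single step.
    """
    rng_ = float(med.max() - med.min())
    if rng_ <= 0:
        return []
    thresh = max(5.0 * sigma, 0.1 * rng_)
    d = np.diff(med)
    sig = np.flatnonzero(d < -thresh) + 1
    steps: list[int] = []
    for i in sig:
        if steps and i - steps[-1] <= window:
            continue
        steps.append(int(i))
    return steps


def detect_photobleach(trace: IntensityTrace, window: int = 5) -> int | None:
    """Locate the single-step donor photobleach, if any.

    Returns the index of the first frame of the final sustained drop of the
    total intensity into the background band (rolling median, threshold =
    post-drop background + 3x a robust noise estimate), or None when the
    signal persists to the end of the trace.
    """
    if len(trace) < 20:
        raise ValueError("photobleach detection requires >= 20 frames")
    total = trace.total
    med = median_filter(total, size=window, mode="nearest")
    sigma = _robust_noise_sd(total)
    background = float(np.median(med[-window:]))
    threshold = background + 3.0 * sigma + 1e-9
    # without a clear signal level above the background band there is no
    # drop to detect (otherwise noise crossings near the end masquerade as
    # a bleach when the trace never bleached)
    if float(med.max()) <= background + 6.0 * sigma:
        return None
    below = med <= threshold
    if not below[-1]:
        return None
    # first index of the final contiguous below-threshold run
    above = np.flatnonzero(~below)
    start = int(above[-1]) + 1 if above.size else 0
    if start == 0:
        return None  # no drop: the whole trace sits in the background band
    return start


def subtract_background(
    trace: IntensityTrace,
    bleach_index: int | None,
    min_post_frames: int = 10,
    static_background: tuple[float, float] | None = None,
) -> IntensityTrace:
    """Subtract the per-channel median signal after photobleaching.

    Falls back to ``static_background = (donor_offset, acceptor_offset)``
    when provided; otherwise a bleach index with at least ``min_post_frames``
    post-bleach frames is required.
    """
    if static_background is not None:
        off_d, off_a = static_background
    else:
        if bleach_index is None or len(trace) - bleach_index < min_post_frames:
            raise ValueError(
                f"trace {trace.id!r}: fewer than {min_post_frames} "
                "post-bleach frames; supply static_background=(d, a) from "
                "the configured static background instead"
            )
        off_d = float(np.median(trace.donor[bleach_index:]))
        off_a = float(np.median(trace.acceptor[bleach_index:]))
    return IntensityTrace(
        id=trace.id,
        donor=trace.donor - off_d,
        acceptor=trace.acceptor - off_a,
        frame_dt=trace.frame_dt,
        selected=trace.selected,
        bleach_index=bleach_index if bleach_index is not None else trace.bleach_index,
    )


def correct_leakage(trace: IntensityTrace, alpha: float) -> IntensityTrace:
    """Remove donor leakage: acceptor' = max(acceptor - alpha * donor, 0)."""
    if not 0.0 <= alpha < 1.0:
        raise ValueError(f"leakage alpha must lie in [0, 1), got {alpha}")
    return IntensityTrace(
        id=trace.id,
        donor=trace.donor,
        acceptor=np.clip(trace.acceptor - alpha * trace.donor, 0.0, None),
        frame_dt=trace.frame_dt,
        selected=trace.selected,
        bleach_index=trace.bleach_index,
    )


def compute_fret(
    trace: IntensityTrace,
    labeling_scheme: int = 1,
    bleach_index: int | None = None,
    signal_threshold: float | None = None,
    min_bound_run: int = 2,
) -> FretTrace:
    """Compute the apparent FRET efficiency E = I_A / (I_A + I_D) per frame.

    Frames whose total corrected intensity falls below the signal threshold
    get an undefined E; under labeling scheme 2 (donor on the protein) they
    are additionally marked unbound, and isolated signal spikes shorter than
    ``min_bound_run`` frames are not counted as binding events. The default
    threshold is half the 90th percentile of the pre-bleach total intensity.
    """
    if labeling_scheme not in (1, 2):
        raise ValueError("labeling_scheme must be 1 or 2")
    if bleach_index is None:
        bleach_index = trace.bleach_index
    n = len(trace)
    valid = np.ones(n, dtype=bool)
    if bleach_index is not None:
        valid[bleach_index:] = False
    total = trace.total
    if signal_threshold is None:
        ref = total[valid] if valid.any() else total
        signal_threshold = 0.5 * float(np.percentile(ref, 90))
    has_signal = total >= signal_threshold
    if not np.any(has_signal & valid):
        raise ValueError(
            f"trace {trace.id!r}: no frame above the signal threshold "
            f"({signal_threshold:.1f} a.u.); trace rejected"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        e_raw = np.where(has_signal, trace.acceptor / total, np.nan)
    valid &= np.isfinite(e_raw)
    if labeling_scheme == 1:
        bound = valid.copy()
    else:
        bound = has_signal & valid
        bound = _drop_short_runs(bound, min_bound_run)
    return FretTrace(
        E=np.clip(e_raw, 0.0, 1.0),
        valid_mask=valid,
        bound_mask=bound,
        frame_dt=trace.frame_dt,
        E_raw=e_raw,
        trace_id=trace.id,
    )


def _drop_short_runs(mask: np.ndarray, min_run: int) -> np.ndarray:
    if min_run <= 1:
        return mask
    out = mask.copy()
    padded = np.concatenate([[0], mask.astype(int), [0]])
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    for s, e in zip(starts, ends):
        if e - s < min_run:
            out[s:e] = False
    return out


def qc_select(
    trace: IntensityTrace,
    labeling_scheme: int = 1,
    anticorr_threshold: float = -0.2,
    cv_threshold: float = 0.25,
    window: int = 5,
) -> QcReport:
    """Apply the three trace-selection criteria.

    * anticorrelated: Pearson correlation of frame-to-frame donor and
      acceptor changes over the pre-bleach region below ``anticorr_threshold``;
    * constant_total: coefficient of variation of the pre-bleach total
      intensity below ``cv_threshold``;
    * single_bleach: exactly one sustained intensity step, ending in the
      background band.

    For labeling scheme 2 the fluctuation criteria are evaluated over
    signal-bearing frames only, and the step criterion reduces to requiring
    the final signal loss to persist to the end of the trace (a final
    unbinding is indistinguishable from a bleach in that scheme).
    """
    try:
        bleach_index = detect_photobleach(trace, window=window)
    except ValueError:
        bleach_index = None
    pre = np.arange(len(trace)) < (
        bleach_index if bleach_index is not None else len(trace)
    )
    if labeling_scheme == 2:
        thr = 0.5 * float(np.percentile(trace.total[pre] if pre.any() else trace.total, 90))
        pre &= trace.total >= thr

    reasons: list[str] = []
    d_d = np.diff(trace.donor[pre])
    d_a = np.diff(trace.acceptor[pre])
    if d_d.size >= 3 and np.std(d_d) > 0 and np.std(d_a) > 0:
        anticorrelated = bool(pearsonr(d_d, d_a)[0] < anticorr_threshold)
    else:
        anticorrelated = False
    if not anticorrelated:
        reasons.append("channel fluctuations not anti-correlated")

    total_pre = trace.total[pre]
    if total_pre.size >= 2 and np.mean(total_pre) > 0:
        constant_total = bool(
            np.std(total_pre) / np.mean(total_pre) < cv_threshold
        )
    else:
        constant_total = False
    if not constant_total:
        reasons.append("total intensity not constant")

    med = median_filter(trace.total, size=window, mode="nearest")
    sigma = _robust_noise_sd(trace.total)
    steps = _down_steps(med, sigma, window)
    if labeling_scheme == 1:
        single_bleach = bleach_index is not None and len(steps) == 1
    else:
        single_bleach = bleach_index is not None
    if not single_bleach:
        reasons.append(
            "no single-step photobleach"
            + (f" ({len(steps)} steps detected)" if len(steps) != 1 else "")
        )
    return QcReport(
        trace_id=trace.id,
        anticorrelated=anticorrelated,
        constant_total=constant_total,
        single_bleach=single_bleach,
        bleach_index=bleach_index,
        n_steps=len(steps),
        reasons=reasons,
    )


def correct_traceset(
    ts: TraceSet,
    labeling_scheme: int = 1,
    leakage_alpha: float = 0.08,
    anticorr_threshold: float = -0.2,
    cv_threshold: float = 0.25,
    static_background: tuple[float, float] | None = None,
) -> tuple[list[FretTrace], list[int], pd.DataFrame]:
    """QC-select and fully correct a trace set.

    Returns the corrected FRET traces of accepted molecules, their indices
    into ``ts``, and a per-trace QC summary table.
    """
    fret_traces: list[FretTrace] = []
    accepted: list[int] = []
    rows = []
    for i, trace in enumerate(ts):
        report = qc_select(
            trace,
            labeling_scheme=labeling_scheme,
            anticorr_threshold=anticorr_threshold,
            cv_threshold=cv_threshold,
        )
        row = {
            "trace_id": trace.id,
            "anticorrelated": report.anticorrelated,
            "constant_total": report.constant_total,
            "single_bleach": report.single_bleach,
            "bleach_index": report.bleach_index,
            "n_steps": report.n_steps,
            "accept": report.accept,
            "reasons": "; ".join(report.reasons),
        }
        if report.accept:
            try:
                corrected = subtract_background(
                    trace, report.bleach_index,
                    static_background=static_background,
                )
                corrected = correct_leakage(corrected, leakage_alpha)
                ft = compute_fret(
                    corrected,
                    labeling_scheme=labeling_scheme,
                    bleach_index=report.bleach_index,
                )
            except ValueError as exc:
                row["accept"] = False
                row["reasons"] = str(exc)
            else:
                fret_traces.append(ft)
                accepted.append(i)
        rows.append(row)
    return fret_traces, accepted, pd.DataFrame(rows)
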