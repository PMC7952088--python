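"""Global hidden Markov modeling of FRET trajectories.

A single Gaussian-emission HMM is trained on all selected traces of a
condition simultaneously (one shared set of state means, variances,
transition probabilities and initial probabilities), as is standard for
pooled smFRET data: individual traces are short, but the molecules are
assumed to share one kinetic scheme. Training is Baum-Welch EM with the
classic per-frame scaling so likelihoods of long traces do not underflow;
the E-step is vectorized across traces. Idealization uses exact Viterbi
decoding in log space.

States are canonically ordered by ascending FRET mean, so fitted models are
invariant to initialization/label permutations.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans

__all__ = ["HmmModel", "StatePath", "fit_global_hmm", "viterbi_decode",
           "viterbi_path", "select_n_states"]

_LOG_FLOOR = -745.0  # smallest representable log-probability
_PDF_FLOOR = 1e-300


@dataclass
class HmmModel:
    """Trained global Gaussian-emission HMM (means sorted ascending)."""

    means: np.ndarray
    variances: np.ndarray
    transmat: np.ndarray
    startprob: np.ndarray
    log_likelihood: float = np.nan
    converged: bool = False
    n_iter: int = 0
    ll_history: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        self.transmat = np.asarray(self.transmat, dtype=float)
        self.startprob = np.asarray(self.startprob, dtype=float)
        k = self.means.size
        if self.transmat.shape != (k, k):
            raise ValueError("transition matrix shape mismatch")
        if np.any(self.variances <= 0):
            raise ValueError("variances must be > 0")
        if not np.allclose(self.transmat.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must sum to 1")

    @property
    def n_states(self) -> int:
        return self.means.size

    def canonicalize(self) -> "HmmModel":
        """Reorder states by ascending mean (in place); returns self."""
        order = np.argsort(self.means, kind="stable")
        self.means = self.means[order]
        self.variances = self.variances[order]
        self.startprob = self.startprob[order]
        self.transmat = self.transmat[np.ix_(order, order)]
        return self

    def log_emission(self, x: np.ndarray) -> np.ndarray:
        """Log N(x | mean_k, var_k) for each frame and state, (n, K)."""
        x = np.asarray(x, dtype=float)[:, None]
        out = (
            -0.5 * np.log(2.0 * np.pi * self.variances)
            - 0.5 * (x - self.means) ** 2 / self.variances
        )
        return np.maximum(out, _LOG_FLOOR)

    def n_parameters(self) -> int:
        k = self.n_states
        return (k - 1) + k * (k - 1) + 2 * k

    def bic(self, n_obs: int) -> float:
        return -2.0 * self.log_likelihood + self.n_parameters() * np.log(n_obs)

    def to_dict(self) -> dict:
        return {
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
            "transmat": self.transmat.tolist(),
            "startprob": self.startprob.tolist(),
            "log_likelihood": float(self.log_likelihood),
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "HmmModel":
        return cls(
            means=np.asarray(d["means"]),
            variances=np.asarray(d["variances"]),
            transmat=np.asarray(d["transmat"]),
            startprob=np.asarray(d["startprob"]),
            log_likelihood=d.get("log_likelihood", np.nan),
            converged=d.get("converged", False),
            n_iter=d.get("n_iter", 0),
        )

    @classmethod
    def load(cls, path: str | Path) -> "HmmModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class StatePath:
    """Idealized per-frame state labels for one trace.

    ``labels`` covers every frame of the trace; frames outside the analysis
    region (post-bleach, unbound under labeling scheme 2) carry -1. Dwell
    segments never bridge gaps in the analysis region.
    """

    labels: np.ndarray
    frame_dt: float
    trace_id: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)

    def segments(self) -> list[tuple[int, int, int]]:
        """Maximal same-state runs as (state, start_frame, n_frames).

        Runs are computed within each contiguous labeled region, so a gap
        (label -1) always terminates a segment.
        """
        out = []
        lab = self.labels
        n = lab.size
        i = 0
        while i < n:
            if lab[i] < 0:
                i += 1
                continue
            j = i
            while j < n and lab[j] == lab[i]:
                j += 1
            out.append((int(lab[i]), i, j - i))
            i = j
        return out


def _extract_sequences(fret_traces) -> list[np.ndarray]:
    seqs: list[np.ndarray] = []
    for ft in fret_traces:
        if isinstance(ft, np.ndarray):
            if ft.size:
                seqs.append(np.asarray(ft, dtype=float))
        else:
            seqs.extend(seg for _, seg in ft.segments() if seg.size)
    return seqs


def _pad_sequences(seqs: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    t_max = max(s.size for s in seqs)
    x = np.zeros((len(seqs), t_max))
    mask = np.zeros((len(seqs), t_max), dtype=bool)
    for r, s in enumerate(seqs):
        x[r, : s.size] = s
        mask[r, : s.size] = True
    return x, mask


def _em_once(
    x: np.ndarray,
    mask: np.ndarray,
    means: np.ndarray,
    variances: np.ndarray,
    transmat: np.ndarray,
    startprob: np.ndarray,
    tol: float,
    max_iter: int,
    var_floor: float,
) -> HmmModel:
    """Scaled Baum-Welch on prefix-padded sequences (R, T)."""
    r_n, t_n = x.shape
    k = means.size
    ll_hist = []
    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # emission probabilities; padding frames emit probability 1 so the
        # scaled recursions pass through them untouched
        b = np.exp(
            -0.5 * (x[:, :, None] - means) ** 2 / variances
        ) / np.sqrt(2.0 * np.pi * variances)
        b = np.maximum(b, _PDF_FLOOR)
        b[~mask] = 1.0

        alpha = np.empty((r_n, t_n, k))
        c = np.empty((r_n, t_n))
        a0 = startprob * b[:, 0]
        c[:, 0] = a0.sum(axis=1)
        alpha[:, 0] = a0 / c[:, 0, None]
        for t in range(1, t_n):
            at = (alpha[:, t - 1] @ transmat) * b[:, t]
            c[:, t] = at.sum(axis=1)
            alpha[:, t] = at / c[:, t, None]
        ll = float(np.sum(np.log(c), where=mask))
        ll_hist.append(ll)

        beta = np.empty((r_n, t_n, k))
        beta[:, -1] = 1.0
        for t in range(t_n - 2, -1, -1):
            bb = b[:, t + 1] * beta[:, t + 1] / c[:, t + 1, None]
            beta[:, t] = bb @ transmat.T
        gamma = alpha * beta
        gamma *= mask[:, :, None]

        a_num = np.zeros((k, k))
        for t in range(t_n - 1):
            w = (b[:, t + 1] * beta[:, t + 1] / c[:, t + 1, None]) * mask[
                :, t + 1, None
            ]
            a_num += alpha[:, t].T @ w
        a_num *= transmat

        startprob = gamma[:, 0].sum(axis=0)
        startprob = startprob / startprob.sum()
        row = a_num.sum(axis=1, keepdims=True)
        transmat = np.where(row > 0, a_num / np.maximum(row, 1e-300), transmat)
        transmat /= transmat.sum(axis=1, keepdims=True)

        occ = gamma.sum(axis=(0, 1))
        degenerate = occ < 1e-8
        if np.any(degenerate):
            warnings.warn(
                "HMM state(s) with vanishing occupancy; variance floor "
                "applied and parameters frozen for those states",
                RuntimeWarning,
            )
        safe_occ = np.maximum(occ, 1e-8)
        new_means = np.einsum("rtk,rt->k", gamma, x) / safe_occ
        new_vars = (
            np.einsum("rtk,rtk->k", gamma, (x[:, :, None] - new_means) ** 2)
            / safe_occ
        )
        means = np.where(degenerate, means, new_means)
        variances = np.maximum(
            np.where(degenerate, variances, new_vars), var_floor
        )

        if ll - ll_prev < tol and np.isfinite(ll_prev):
            converged = True
            break
        ll_prev = ll

    return HmmModel(
        means=means,
        variances=variances,
        transmat=transmat,
        startprob=startprob,
        log_likelihood=ll_hist[-1],
        converged=converged,
        n_iter=it,
        ll_history=np.asarray(ll_hist),
    ).canonicalize()


def _initializations(
    pooled: np.ndarray, n_states: int, n_restarts: int,
    rng: np.random.Generator,
):
    """K-means initialization plus seeded random restarts."""
    k = n_states
    pooled_var = max(float(np.var(pooled)), 1e-4)
    inits = []
    if k == 1:
        inits.append((np.array([float(np.mean(pooled))]), np.array([pooled_var])))
    else:
        km = KMeans(
            n_clusters=k, n_init=3,
            random_state=int(rng.integers(2**31 - 1)),
        ).fit(pooled[:, None])
        centers = np.sort(km.cluster_centers_.ravel())
        lab = km.labels_
        variances = np.array(
            [
                max(float(np.var(pooled[lab == i])), 1e-4)
                if np.any(lab == i) else pooled_var
                for i in range(k)
            ]
        )
        order = np.argsort(km.cluster_centers_.ravel())
        inits.append((centers, variances[order]))
        lo, hi = np.percentile(pooled, [2, 98])
        for _ in range(n_restarts):
            means = np.sort(rng.uniform(lo, hi, size=k))
            inits.append((means, np.full(k, pooled_var / k)))
    return inits


def fit_global_hmm(
    fret_traces,
    n_states: int,
    tol: float = 1e-4,
    max_iter: int = 500,
    seed: int | np.random.Generator = 0,
    n_restarts: int = 5,
    var_floor: float = 1e-4,
    sticky: float = 0.9,
) -> HmmModel:
    """Fit one shared Gaussian-emission HMM to all traces of a condition.

    Parameters
    ----------
    fret_traces
        List of :class:`~polfret.correct.FretTrace` (their contiguous
        analysis segments are pooled) or of plain 1-D observation arrays.
    n_states
        Number of hidden states.
    tol
        EM stops when the log-likelihood improves by less than this (nats).
    max_iter
        Maximum EM iterations per initialization.
    seed
        Seed for k-means and the random restarts.
    n_restarts
        Random restarts in addition to the k-means initialization; the fit
        with the best final likelihood wins.
    var_floor
        Lower bound on emission variances.
    sticky
        Initial self-transition probability (frames are much shorter than
        dwells, so self-transitions dominate).

    Returns
    -------
    HmmModel
        Canonicalized model; ``converged`` is False when no initialization
        reached ``tol`` within ``max_iter``.
    """
    seqs = _extract_sequences(fret_traces)
    if not seqs or sum(s.size for s in seqs) < 10:
        raise ValueError("need at least one trace with >= 10 valid frames")
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    x, mask = _pad_sequences(seqs)
    pooled = np.concatenate(seqs)
    rng = np.random.default_rng(seed)

    k = n_states
    best: HmmModel | None = None
    for means, variances in _initializations(pooled, k, n_restarts, rng):
        if k == 1:
            transmat = np.ones((1, 1))
            startprob = np.ones(1)
        else:
            transmat = np.full((k, k), (1.0 - sticky) / (k - 1))
            np.fill_diagonal(transmat, sticky)
            startprob = np.full(k, 1.0 / k)
        model = _em_once(
            x, mask, means.copy(), variances.copy(), transmat, startprob,
            tol, max_iter, var_floor,
        )
        if best is None or model.log_likelihood > best.log_likelihood:
            best = model
    return best


def viterbi_path(model: HmmModel, x: np.ndarray) -> np.ndarray:
    """Most likely joint state sequence for one observation array.

    Exact max-product dynamic programming in log space; ties break toward
    the lower state index.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    log_b = model.log_emission(x)
    log_a = np.log(np.maximum(model.transmat, np.exp(_LOG_FLOOR)))
    log_pi = np.log(np.maximum(model.startprob, np.exp(_LOG_FLOOR)))
    k = model.n_states
    delta = log_pi + log_b[0]
    psi = np.zeros((n, k), dtype=np.int64)
    for t in range(1, n):
        cand = delta[:, None] + log_a
        psi[t] = cand.argmax(axis=0)
        delta = cand[psi[t], np.arange(k)] + log_b[t]
    path = np.empty(n, dtype=np.int64)
    path[-1] = int(delta.argmax())
    for t in range(n - 2, -1, -1):
        path[t] = psi[t + 1][path[t + 1]]
    return path


def viterbi_decode(model: HmmModel, fret_trace) -> StatePath:
    """Idealize a FRET trace; each contiguous analysis segment is decoded
    independently and unanalyzed frames are labeled -1."""
    labels = np.full(len(fret_trace.E), -1, dtype=np.int64)
    for start, seg in fret_trace.segments():
        labels[start : start + seg.size] = viterbi_path(model, seg)
    return StatePath(
        labels=labels,
        frame_dt=fret_trace.frame_dt,
        trace_id=fret_trace.trace_id,
    )


def select_n_states(
    fret_traces,
    candidate_counts,
    seed: int = 0,
    bic_margin: float = 10.0,
    **fit_kwargs,
):
    """Automated stand-in for choosing the state count by inspection.

    Fits every candidate count and reports BIC; the chosen model is the
    smallest count whose BIC lies within ``bic_margin`` of the minimum, so
    extra states must earn their keep. The full table is returned for human
    override.
    """
    import pandas as pd

    candidate_counts = list(candidate_counts)
    if not candidate_counts:
        raise ValueError("candidate_counts must be non-empty")
    seqs = _extract_sequences(fret_traces)
    n_obs = int(sum(s.size for s in seqs))
    rows = []
    for k in candidate_counts:
        model = fit_global_hmm(fret_traces, k, seed=seed, **fit_kwargs)
        rows.append(
            {
                "n_states": k,
                "log_likelihood": model.log_likelihood,
                "n_parameters": model.n_parameters(),
                "bic": model.bic(n_obs),
                "converged": model.converged,
            }
        )
    table = pd.DataFrame(rows).sort_values("n_states").reset_index(drop=True)
    eligible = table[table["bic"] <= table["bic"].min() + bic_margin]
    chosen = int(eligible["n_states"].iloc[0])
    return chosen, table
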