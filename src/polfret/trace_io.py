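"""Read/write per-molecule intensity traces and idealized-path exports.

HDF5 schema (one file per trace set)
------------------------------------
Root attributes: ``frame_dt`` (s), ``schema_version``, plus free-form
metadata (``labeling_scheme``, ``substrate``, ``protein``, ...).
One group per trace, named by its id, containing:

* datasets ``donor`` and ``acceptor`` -- float arrays, camera a.u.;
* optional attributes ``bleach_index`` and ``selected``.

``read_traces`` also has a permissive compat mode for externally produced
files: a user-supplied mapping renames groups/datasets, and a missing
``frame_dt`` falls back to the standard 100 ms camera integration time with
a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "IntensityTrace",
    "TraceSet",
    "write_traces",
    "read_traces",
    "export_idealized",
    "DEFAULT_FRAME_DT",
]

logger = logging.getLogger(__name__)

#: standard camera integration time, s
DEFAULT_FRAME_DT = 0.1

_SCHEMA_VERSION = 1


@dataclass
class IntensityTrace:
    """Paired donor/acceptor intensity arrays for one molecule."""

    id: str
    donor: np.ndarray
    acceptor: np.ndarray
    frame_dt: float = DEFAULT_FRAME_DT
    selected: bool | None = None
    bleach_index: int | None = None

    def __post_init__(self) -> None:
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if self.donor.shape != self.acceptor.shape or self.donor.ndim != 1:
            raise ValueError(
                f"trace {self.id!r}: donor and acceptor must be 1-D arrays "
                "of equal length"
            )
        if self.frame_dt <= 0:
            raise ValueError("frame_dt must be > 0")

    def __len__(self) -> int:
        return self.donor.size

    @property
    def total(self) -> np.ndarray:
        return self.donor + self.acceptor

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self)) * self.frame_dt


@dataclass
class TraceSet:
    """A set of traces sharing a frame interval, with free-form metadata."""

    traces: list[IntensityTrace]
    frame_dt: float = DEFAULT_FRAME_DT
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [t.id for t in self.traces]
        if len(set(ids)) != len(ids):
            raise ValueError("trace ids must be unique")
        for t in self.traces:
            if t.frame_dt != self.frame_dt:
                raise ValueError(
                    f"trace {t.id!r} frame_dt {t.frame_dt} differs from the "
                    f"set's {self.frame_dt}"
                )

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self):
        return iter(self.traces)

    def __getitem__(self, i: int) -> IntensityTrace:
        return self.traces[i]


def write_traces(ts: TraceSet, path: str | Path) -> None:
    """Write a TraceSet to an HDF5 file (see module docstring for schema)."""
    with h5py.File(path, "w") as f:
        f.attrs["frame_dt"] = ts.frame_dt
        f.attrs["schema_version"] = _SCHEMA_VERSION
        for key, value in ts.metadata.items():
            f.attrs[key] = value
        for trace in ts.traces:
            g = f.create_group(trace.id)
            g.create_dataset("donor", data=trace.donor)
            g.create_dataset("acceptor", data=trace.acceptor)
            if trace.bleach_index is not None:
                g.attrs["bleach_index"] = trace.bleach_index
            if trace.selected is not None:
                g.attrs["selected"] = trace.selected


def read_traces(
    path: str | Path,
    compat: bool = False,
    dataset_map: dict[str, str] | None = None,
) -> TraceSet:
    """Read a TraceSet from an HDF5 file.

    Parameters
    ----------
    path
        HDF5 file to read.
    compat
        Permissive mode for externally produced files: a missing ``frame_dt``
        attribute falls back to :data:`DEFAULT_FRAME_DT` (100 ms) with a
        logged warning instead of raising.
    dataset_map
        Optional mapping from the file's channel dataset names to the
        schema's (e.g. ``{"dd": "donor", "da": "acceptor"}``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trace file not found: {path}")
    rename = dataset_map or {}
    with h5py.File(path, "r") as f:
        if "frame_dt" in f.attrs:
            frame_dt = float(f.attrs["frame_dt"])
        elif compat:
            frame_dt = DEFAULT_FRAME_DT
            logger.warning(
                "%s lacks a frame_dt attribute; assuming the standard "
                "%g s integration time", path, DEFAULT_FRAME_DT,
            )
        else:
            raise KeyError(
                f"{path} lacks a frame_dt attribute (use compat=True to "
                f"assume {DEFAULT_FRAME_DT} s)"
            )
        metadata = {
            k: (v.item() if isinstance(v, np.generic) else v)
            for k, v in f.attrs.items()
            if k not in ("frame_dt", "schema_version")
        }
        traces = []
        for name in sorted(f.keys()):
            g = f[name]
            channels = {rename.get(k, k): k for k in g.keys()}
            missing = {"donor", "acceptor"} - set(channels)
            if missing:
                raise KeyError(
                    f"trace {name!r} in {path} lacks channel(s) "
                    f"{sorted(missing)}"
                )
            traces.append(
                IntensityTrace(
                    id=name,
                    donor=np.asarray(g[channels["donor"]], dtype=float),
                    acceptor=np.asarray(g[channels["acceptor"]], dtype=float),
                    frame_dt=frame_dt,
                    bleach_index=(
                        int(g.attrs["bleach_index"])
                        if "bleach_index" in g.attrs else None
                    ),
                    selected=(
                        bool(g.attrs["selected"])
                        if "selected" in g.attrs else None
                    ),
                )
            )
    return TraceSet(traces=traces, frame_dt=frame_dt, metadata=metadata)


def export_idealized(ts, fret_traces, paths, out: str | Path) -> pd.DataFrame:
    """Export idealized state paths as a tidy CSV.

    One row per valid frame with columns
    ``trace_id, frame, time_s, E, state_label``. ``fret_traces`` and
    ``paths`` must align one-to-one with the (selected) traces of ``ts``.
    """
    if not (len(ts) == len(fret_traces) == len(paths)):
        raise ValueError(
            "ts, fret_traces and paths must have matching lengths "
            f"({len(ts)}, {len(fret_traces)}, {len(paths)})"
        )
    frames = []
    for trace, ft, path in zip(ts, fret_traces, paths):
        if not (len(path.labels) == len(ft.E) == len(trace)):
            raise ValueError(
                f"trace {trace.id!r}: path length {len(path.labels)} and "
                f"FRET length {len(ft.E)} must equal trace length "
                f"{len(trace)}"
            )
        idx = np.flatnonzero(path.labels >= 0)
        frames.append(
            pd.DataFrame(
                {
                    "trace_id": trace.id,
                    "frame": idx,
                    "time_s": idx * ts.frame_dt,
                    "E": ft.E[idx],
                    "state_label": path.labels[idx],
                }
            )
        )
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=["trace_id", "frame", "time_s", "E", "state_label"]
        )
    )
    df.to_csv(out, index=False)
    return df


def read_idealized(path: str | Path, frame_dt: float = DEFAULT_FRAME_DT):
    """Re-import an idealized-path CSV written by :func:`export_idealized`.

    Returns ``(fret_traces, paths)`` with unlabeled frames carrying NaN E
    and label -1, suitable for the statistics and kinetics stages.
    """
    from .correct import FretTrace
    from .hmm import StatePath

    df = pd.read_csv(path)
    fret_traces, paths = [], []
    for trace_id, grp in df.groupby("trace_id", sort=True):
        n = int(grp["frame"].max()) + 1
        e = np.full(n, np.nan)
        labels = np.full(n, -1, dtype=np.int64)
        idx = grp["frame"].to_numpy()
        e[idx] = grp["E"].to_numpy()
        labels[idx] = grp["state_label"].to_numpy()
        mask = labels >= 0
        fret_traces.append(
            FretTrace(E=e, valid_mask=mask, bound_mask=mask.copy(),
                      frame_dt=frame_dt, trace_id=str(trace_id))
        )
        paths.append(
            StatePath(labels=labels, frame_dt=frame_dt, trace_id=str(trace_id))
        )
    return fret_traces, paths
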