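"""Reading and writing of IMU recordings and result tables.

The pipeline consumes exactly two channels of a lumbar-mounted IMU: the
anteroposterior linear acceleration (the sensor's z axis, in m/s^2) and
the angular velocity around the sagittal axis (the sensor's x axis, in
deg/s).  Recordings are accepted as column-mapped CSV or as HDF5 with
configurable dataset paths; vendor binary formats are out of scope.

Time is stored in seconds internally.  Short gaps (NaN runs up to a
configurable limit, default 3 samples) are linearly interpolated and
logged; longer gaps are rejected because the zero-phase filters downstream
assume uniform sampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError, ValidationError

__all__ = [
    "InertialRecording",
    "read_recording",
    "write_recording",
    "write_events",
    "read_events",
    "write_summary",
    "read_summary",
]

logger = logging.getLogger(__name__)

#: Default column/dataset names for recording files.
DEFAULT_COLUMN_MAP = {"time": "time_s", "acc_ap": "acc_ap", "gyro_sag": "gyro_sag"}

_HDF5_SUFFIXES = {".h5", ".hdf5", ".hdf"}


@dataclass
class InertialRecording:
    """Uniformly sampled two-channel lumbar IMU recording.

    Attributes
    ----------
    fs : float
        Sampling rate, Hz.
    t : ndarray
        Time stamps in seconds, strictly increasing, with a median step
        within 1% of ``1/fs``.
    acc_ap : ndarray
        Anteroposterior acceleration, m/s^2.
    gyro_sag : ndarray
        Angular velocity around the sagittal axis, deg/s.
    subject_id : str
        Opaque label.
    """

    fs: float
    t: np.ndarray
    acc_ap: np.ndarray
    gyro_sag: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.acc_ap = np.asarray(self.acc_ap, dtype=float)
        self.gyro_sag = np.asarray(self.gyro_sag, dtype=float)
        if self.fs <= 0:
            raise ValidationError(f"fs must be positive, got {self.fs}")
        n = len(self.t)
        if n == 0 or len(self.acc_ap) != n or len(self.gyro_sag) != n:
            raise ValidationError(
                "t, acc_ap and gyro_sag must have equal, nonzero length "
                f"(got {n}, {len(self.acc_ap)}, {len(self.gyro_sag)})"
            )
        dt = np.diff(self.t)
        if n > 1:
            if not np.all(dt > 0):
                raise ValidationError("time stamps must be strictly increasing")
            med = float(np.median(dt))
            if abs(med - 1.0 / self.fs) > 0.01 / self.fs:
                raise ValidationError(
                    f"median time step {med:.6g} s deviates more than 1% "
                    f"from 1/fs = {1.0 / self.fs:.6g} s"
                )

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Recording span in seconds (n_samples / fs)."""
        return self.n_samples / self.fs


def _interpolate_gaps(x: np.ndarray, max_gap: int, name: str) -> np.ndarray:
    """Linearly interpolate NaN runs of length <= max_gap, else raise."""
    x = np.asarray(x, dtype=float)
    bad = ~np.isfinite(x)
    if not bad.any():
        return x
    # run-length encode the bad mask
    edges = np.flatnonzero(np.diff(np.concatenate(([False], bad, [False])).astype(int)))
    starts, stops = edges[::2], edges[1::2]
    longest = int((stops - starts).max())
    if longest > max_gap:
        raise ValidationError(
            f"column '{name}' has a gap of {longest} consecutive missing "
            f"samples (limit {max_gap})"
        )
    if bad[0] or bad[-1]:
        raise ValidationError(f"column '{name}' starts or ends with missing samples")
    idx = np.arange(len(x))
    out = x.copy()
    out[bad] = np.interp(idx[bad], idx[~bad], x[~bad])
    logger.info("interpolated %d missing samples in '%s'", int(bad.sum()), name)
    return out


def read_recording(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    fs: float | None = None,
    *,
    time_unit: str = "s",
    max_gap: int = 3,
    subject_id: str = "",
    delimiter: str = ",",
) -> InertialRecording:
    """Read an IMU recording from CSV or HDF5.

    Parameters
    ----------
    path : path
        CSV file (header row) or HDF5 file (suffix .h5/.hdf5).
    column_map : mapping
        Maps the keys ``acc_ap``, ``gyro_sag`` and optionally ``time`` to
        column names (CSV) or dataset paths (HDF5).
    fs : float, optional
        Sampling rate in Hz.  Required when the file carries no time
        column; for HDF5 it falls back to a root attribute ``fs``.  When a
        time column exists, ``fs`` defaults to the inverse median step.
    time_unit : {"s", "ms"}
        Unit of the time column; ``ms`` values are converted to seconds.
    max_gap : int
        Longest NaN run (samples) that is linearly interpolated; longer
        runs raise :class:`ValidationError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    if time_unit not in ("s", "ms"):
        raise ParameterError(f"time_unit must be 's' or 'ms', got {time_unit!r}")

    if path.suffix.lower() in _HDF5_SUFFIXES:
        with h5py.File(path, "r") as f:
            missing = [k for k in ("acc_ap", "gyro_sag") if cmap[k] not in f]
            if missing:
                raise FormatError(
                    f"HDF5 file {path} lacks datasets for {missing} "
                    f"(looked for {[cmap[k] for k in missing]})"
                )
            acc = np.asarray(f[cmap["acc_ap"]], dtype=float)
            gyro = np.asarray(f[cmap["gyro_sag"]], dtype=float)
            t = (
                np.asarray(f[cmap["time"]], dtype=float)
                if cmap.get("time") and cmap["time"] in f
                else None
            )
            if fs is None:
                fs = float(f.attrs.get("fs", 0.0)) or None
    else:
        try:
            df = pd.read_csv(path, delimiter=delimiter)
        except Exception as exc:  # malformed CSV
            raise FormatError(f"could not parse {path}: {exc}") from exc
        missing = [k for k in ("acc_ap", "gyro_sag") if cmap[k] not in df.columns]
        if missing:
            raise FormatError(
                f"{path} lacks columns for {missing} "
                f"(looked for {[cmap[k] for k in missing]}; "
                f"found {list(df.columns)})"
            )
        for key in ("acc_ap", "gyro_sag"):
            if not pd.api.types.is_numeric_dtype(df[cmap[key]]):
                raise FormatError(f"column '{cmap[key]}' is not numeric")
        acc = df[cmap["acc_ap"]].to_numpy(dtype=float)
        gyro = df[cmap["gyro_sag"]].to_numpy(dtype=float)
        t = (
            df[cmap["time"]].to_numpy(dtype=float)
            if cmap.get("time") in df.columns
            else None
        )

    acc = _interpolate_gaps(acc, max_gap, "acc_ap")
    gyro = _interpolate_gaps(gyro, max_gap, "gyro_sag")

    if t is None:
        if fs is None:
            raise ParameterError(
                "fs is required when the recording has no time column"
            )
        t = np.arange(len(acc)) / float(fs)
    else:
        if time_unit == "ms":
            t = t / 1000.0
        if fs is None:
            dt = np.median(np.diff(t)) if len(t) > 1 else None
            if not dt or dt <= 0:
                raise ValidationError("cannot infer fs from the time column")
            fs = 1.0 / float(dt)

    return InertialRecording(
        fs=float(fs), t=t, acc_ap=acc, gyro_sag=gyro, subject_id=subject_id
    )


def write_recording(
    rec: InertialRecording,
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> None:
    """Write a recording as CSV (default) or HDF5 (suffix .h5/.hdf5)."""
    path = Path(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    if path.suffix.lower() in _HDF5_SUFFIXES:
        with h5py.File(path, "w") as f:
            f.create_dataset(cmap["time"], data=rec.t)
            f.create_dataset(cmap["acc_ap"], data=rec.acc_ap)
            f.create_dataset(cmap["gyro_sag"], data=rec.gyro_sag)
            f.attrs["fs"] = rec.fs
            f.attrs["subject_id"] = rec.subject_id
    else:
        df = pd.DataFrame(
            {
                cmap["time"]: rec.t,
                cmap["acc_ap"]: rec.acc_ap,
                cmap["gyro_sag"]: rec.gyro_sag,
            }
        )
        df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# events and summaries

_EVENT_COLUMNS = ["time_s", "kind", "side", "segment_id"]


def write_events(events: Sequence, path: str | Path) -> None:
    """Write gait events as CSV with columns time_s, kind, side, segment_id.

    Events must be time-ordered; an empty list produces a header-only file.
    """
    times = [e.time for e in events]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValidationError("events must be time-ordered")
    df = pd.DataFrame(
        {
            "time_s": times,
            "kind": [e.kind for e in events],
            "side": [e.side if e.side is not None else "" for e in events],
            "segment_id": [e.segment_id for e in events],
        },
        columns=_EVENT_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_events(path: str | Path) -> list:
    """Read a gait-event CSV written by :func:`write_events`."""
    from .events import GaitEvent  # deferred to avoid a cycle

    df = pd.read_csv(Path(path), keep_default_na=False)
    missing = [c for c in _EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path} lacks event columns {missing}")
    return [
        GaitEvent(
            time=float(r.time_s),
            kind=str(r.kind),
            side=(str(r.side) or None),
            segment_id=int(r.segment_id),
        )
        for r in df.itertuples()
    ]


#: Column names of the per-subject summary CSV, in output order.
SUMMARY_FIELDS = [
    "gct_s",
    "cadence_spm",
    "stance_pct",
    "swing_pct",
    "ids_pct",
    "tds_pct",
    "ds_pct",
    "n_cycles",
]


def write_summary(summary, path: str | Path) -> None:
    """Write a spatiotemporal summary as a two-column CSV (parameter, value)."""
    rows = [(name, getattr(summary, name)) for name in SUMMARY_FIELDS]
    pd.DataFrame(rows, columns=["parameter", "value"]).to_csv(path, index=False)


def read_summary(path: str | Path):
    """Read a summary CSV written by :func:`write_summary`."""
    from .spatiotemporal import SpatiotemporalSummary

    df = pd.read_csv(Path(path))
    if list(df.columns) != ["parameter", "value"]:
        raise FormatError(f"{path} is not a summary file")
    values = dict(zip(df["parameter"], df["value"]))
    missing = [f for f in SUMMARY_FIELDS if f not in values]
    if missing:
        raise FormatError(f"{path} lacks summary rows {missing}")
    kwargs = {name: float(values[name]) for name in SUMMARY_FIELDS}
    kwargs["n_cycles"] = int(kwargs["n_cycles"])
    return SpatiotemporalSummary(**kwargs)
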