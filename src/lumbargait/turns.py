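"""Turning-phase detection and straight-walk segmentation.

During a back-and-forth walking protocol the subject performs a 180-degree
turn at each end of the path.  Turns show up in the sagittal-axis angular
velocity of a lumbar sensor as high-amplitude bursts.  The detector

1. band-passes the raw angular velocity (4th-order Butterworth, 1-50 Hz,
   zero phase) to remove the offset,
2. rectifies it,
3. smooths the rectified signal with a long Savitzky-Golay filter
   (order 2, 1101-sample frame at 128 Hz, i.e. an ~8.6 s envelope), and
4. thresholds the envelope; supra-threshold windows are the turning
   phases and the complementary stretches are the straight-walk segments
   on which gait events are detected.

The per-subject threshold is chosen by a plateau scan: candidate
thresholds are swept over the 5th-95th percentile range of the envelope
and the value is taken as the midpoint of the widest contiguous candidate
run on which the number of supra-threshold windows of at least
``min_turn_s`` duration is constant and positive.  The window count is a
step function of the threshold, and the correct turn count is stable over
a wide band of thresholds, whereas spurious counts only survive on narrow
bands; when the expected number of turns is known from the protocol it
can be supplied to pin the plateau.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, ValidationError
from .filters import bandpass_butterworth, rectify, savitzky_golay, scale_frame
from .io import InertialRecording

__all__ = [
    "TurnWindow",
    "WalkingSegment",
    "smooth_angular_speed",
    "estimate_turn_threshold",
    "detect_turn_windows",
    "extract_walking_segments",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True, order=True)
class TurnWindow:
    """Half-open sample-index interval [start_idx, stop_idx) marking a turn."""

    start_idx: int
    stop_idx: int

    def __post_init__(self) -> None:
        if not 0 <= self.start_idx < self.stop_idx:
            raise ValidationError(
                f"invalid turn window [{self.start_idx}, {self.stop_idx})"
            )

    def __len__(self) -> int:
        return self.stop_idx - self.start_idx


@dataclass
class WalkingSegment:
    """A straight-walk stretch of the recording (complement of the turns)."""

    start_idx: int
    stop_idx: int
    acc_ap_slice: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return self.stop_idx - self.start_idx


def smooth_angular_speed(
    gyro: np.ndarray,
    fs: float,
    *,
    low: float = 1.0,
    high: float = 50.0,
    order: int = 4,
    sg_polyorder: int = 2,
    sg_frame: int = 1101,
) -> np.ndarray:
    """Band-pass, rectify and Savitzky-Golay-smooth the angular velocity.

    ``sg_frame`` is quoted in samples at 128 Hz and rescaled for other
    sampling rates.  The output is the nonnegative envelope used by the
    turn threshold scan.
    """
    frame = scale_frame(sg_frame, fs)
    smoothed = savitzky_golay(
        rectify(bandpass_butterworth(gyro, fs, low, high, order)),
        sg_polyorder, frame,
    )
    # the SG kernel has negative sidelobes and can undershoot; the
    # envelope is a nonnegative quantity by construction
    return np.maximum(smoothed, 0.0)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs where a boolean mask is True."""
    edges = np.flatnonzero(
        np.diff(np.concatenate(([False], mask, [False])).astype(np.int8))
    )
    return list(zip(edges[::2].tolist(), edges[1::2].tolist()))


def estimate_turn_threshold(
    s: np.ndarray,
    fs: float,
    min_turn_s: float = 1.0,
    *,
    n_candidates: int = 100,
    expected_count: int | None = None,
) -> float:
    """Plateau-scan threshold for the smoothed rectified angular speed.

    Returns the midpoint of the widest contiguous run of candidate
    thresholds (``n_candidates`` values spaced linearly between the 5th
    and 95th percentile of ``s``) over which the number of supra-threshold
    windows of duration >= ``min_turn_s`` is constant and positive.  If
    ``expected_count`` is given, plateaus with that window count are
    preferred.  When no positive-count plateau exists (e.g. an all-zero
    signal) the maximum of ``s`` is returned, which yields zero turns.
    """
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ParameterError("the smoothed rectified signal must be nonnegative")
    smax = float(np.max(s, initial=0.0))
    if smax <= 0:
        logger.warning("all-zero angular-speed envelope: no turns detectable")
        return np.inf
    lo, hi = np.percentile(s, [5.0, 95.0])
    if hi <= lo:
        return smax
    candidates = np.linspace(lo, hi, n_candidates)
    min_len = min_turn_s * fs
    counts = np.array(
        [
            sum(1 for a, b in _runs(s >= c) if b - a >= min_len)
            for c in candidates
        ]
    )

    # contiguous plateaus of constant positive count
    plateaus: list[tuple[int, int, int]] = []  # (start, stop, count) half-open
    i = 0
    while i < len(counts):
        j = i
        while j < len(counts) and counts[j] == counts[i]:
            j += 1
        if counts[i] > 0:
            plateaus.append((i, j, int(counts[i])))
        i = j
    if not plateaus:
        return smax
    if expected_count is not None:
        pinned = [p for p in plateaus if p[2] == expected_count]
        if pinned:
            plateaus = pinned
    start, stop, _ = max(plateaus, key=lambda p: p[1] - p[0])
    return float(0.5 * (candidates[start] + candidates[stop - 1]))


def detect_turn_windows(
    s: np.ndarray,
    threshold: float,
    fs: float,
    min_turn_s: float = 1.0,
    merge_gap_s: float = 0.5,
) -> list[TurnWindow]:
    """Threshold the envelope into turning-phase windows.

    Maximal runs with ``s >= threshold`` are extracted; runs separated by
    less than ``merge_gap_s`` are merged, and runs shorter than
    ``min_turn_s`` are discarded.  Returned windows are sorted and
    pairwise disjoint.
    """
    if threshold <= 0:
        raise ParameterError(f"threshold must be positive, got {threshold}")
    s = np.asarray(s, dtype=float)
    runs = _runs(s >= threshold)
    merged: list[list[int]] = []
    for a, b in runs:
        if merged and a - merged[-1][1] < merge_gap_s * fs:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    return [
        TurnWindow(a, b) for a, b in merged if b - a >= min_turn_s * fs
    ]


def extract_walking_segments(
    rec: InertialRecording,
    turns: list[TurnWindow],
    min_walk_s: float = 2.0,
) -> list[WalkingSegment]:
    """Complement of the turn windows, carrying AP-acceleration slices.

    Segments shorter than ``min_walk_s`` are dropped (they cannot contain
    a full gait cycle).
    """
    n = rec.n_samples
    for w in turns:
        if w.stop_idx > n:
            raise ValidationError(f"turn window {w} exceeds the recording ({n})")
    bounds = [0]
    for w in sorted(turns):
        bounds.extend([w.start_idx, w.stop_idx])
    bounds.append(n)
    segments = []
    for a, b in zip(bounds[::2], bounds[1::2]):
        if b - a >= min_walk_s * rec.fs:
            segments.append(WalkingSegment(a, b, rec.acc_ap[a:b]))
        elif b > a:
            logger.info(
                "dropping walking fragment [%d, %d) shorter than %.2g s",
                a, b, min_walk_s,
            )
    return segments
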