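"""Heel-strike and toe-off detection from anteroposterior acceleration.

Within a straight-walk segment the AP acceleration of a lumbar sensor
shows a repeating step pattern of two positive peaks followed by one
negative peak: the second (larger) positive peak coincides with the
heel-strike and the negative peak with the following toe-off of the
contralateral foot.

Detection proceeds in two stages, deliberately separating *where to look*
from *where the event is*:

1.  A heavy zero-phase filter cascade -- Butterworth band-pass (1-50 Hz),
    Savitzky-Golay (order 50, 801-sample frame at 128 Hz) and a running
    median (order 10) -- reduces each step to one positive and one
    negative lobe.  Its zero crossings delimit alternating-polarity
    regions of interest (ROIs); the cascade output is used for nothing
    else.
2.  The event instants are localised on the ORIGINAL, unfiltered signal:
    the heel-strike is the argmax of the raw signal inside each positive
    ROI and the toe-off is the argmin inside each negative ROI.  Locating
    extrema on the raw signal avoids the timing distortion a smoothed
    signal would introduce.

Side labels (left/right) are not observable from a single lumbar sensor;
they are assigned by alternation from a configurable starting side, and
all downstream parameters are averaged over both sides, which makes the
choice immaterial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .errors import ParameterError, SegmentTooShortError, TuningError, ValidationError
from .filters import bandpass_butterworth, median_filter, savitzky_golay, scale_frame

__all__ = [
    "Roi",
    "GaitEvent",
    "HEEL_STRIKE",
    "TOE_OFF",
    "preprocess_segment",
    "find_rois",
    "detect_events",
    "assign_sides",
    "tune_filter_parameters",
]

logger = logging.getLogger(__name__)

HEEL_STRIKE = "heel_strike"
TOE_OFF = "toe_off"

#: Filter-cascade defaults (at 128 Hz).
DEFAULT_SG_POLYORDER = 50
DEFAULT_SG_FRAME = 801
DEFAULT_MEDIAN_ORDER = 10


@dataclass(frozen=True)
class Roi:
    """Half-open same-sign run [start_idx, stop_idx) of the filtered signal."""

    start_idx: int
    stop_idx: int
    polarity: Literal["positive", "negative"]

    def __post_init__(self) -> None:
        if not 0 <= self.start_idx < self.stop_idx:
            raise ValidationError(f"invalid ROI [{self.start_idx}, {self.stop_idx})")
        if self.polarity not in ("positive", "negative"):
            raise ValidationError(f"invalid polarity {self.polarity!r}")


@dataclass(frozen=True)
class GaitEvent:
    """A timed gait event on the recording clock."""

    time: float
    kind: str  # heel_strike | toe_off
    side: str | None = None  # left | right | None (not yet assigned)
    segment_id: int = 0

    def __post_init__(self) -> None:
        if self.kind not in (HEEL_STRIKE, TOE_OFF):
            raise ValidationError(f"invalid event kind {self.kind!r}")
        if self.side not in (None, "left", "right"):
            raise ValidationError(f"invalid side {self.side!r}")


def preprocess_segment(
    acc: np.ndarray,
    fs: float,
    *,
    low: float = 1.0,
    high: float = 50.0,
    order: int = 4,
    sg_polyorder: int = DEFAULT_SG_POLYORDER,
    sg_frame: int = DEFAULT_SG_FRAME,
    median_order: int = DEFAULT_MEDIAN_ORDER,
) -> np.ndarray:
    """ROI-delimiting filter cascade: band-pass -> Savitzky-Golay -> median.

    The output has the same length as the input and is used only to place
    ROI boundaries (its zero crossings), never to localise extrema.
    Raises :class:`ParameterError` when the segment is shorter than the
    (rate-scaled) Savitzky-Golay frame; the caller should skip such
    segments.
    """
    acc = np.asarray(acc, dtype=float)
    frame = scale_frame(sg_frame, fs)
    if len(acc) < frame:
        raise SegmentTooShortError(
            f"segment of {len(acc)} samples shorter than the "
            f"Savitzky-Golay frame ({frame})"
        )
    f = bandpass_butterworth(acc, fs, low, high, order)
    f = savitzky_golay(f, sg_polyorder, frame)
    return median_filter(f, median_order)


def find_rois(f: np.ndarray) -> list[Roi]:
    """Split the filtered signal into alternating-polarity sign runs.

    Zero crossings delimit maximal same-sign runs; exact zeros attach to
    the following run.  Runs touching the segment boundaries are
    discarded (they are truncated lobes).  Fewer than two sign changes
    yield an empty list.
    """
    f = np.asarray(f, dtype=float)
    sgn = np.sign(f).astype(int)
    # exact zeros take the sign of the next nonzero sample
    nonzero = sgn != 0
    if not nonzero.any():
        return []
    idx = np.where(nonzero, np.arange(len(f)), len(f))
    nxt = np.minimum.accumulate(idx[::-1])[::-1]
    filled = np.where(nxt < len(f), sgn[np.minimum(nxt, len(f) - 1)], 0)
    # trailing zeros (no following nonzero) join the preceding run
    last = np.flatnonzero(nonzero)[-1]
    filled[last + 1 :] = sgn[last]

    change = np.flatnonzero(np.diff(filled)) + 1
    starts = np.concatenate(([0], change))
    stops = np.concatenate((change, [len(f)]))
    rois = []
    for a, b in zip(starts[1:-1], stops[1:-1]):  # drop boundary-touching runs
        rois.append(
            Roi(int(a), int(b), "positive" if filled[a] > 0 else "negative")
        )
    return rois


def detect_events(
    raw: np.ndarray,
    rois: Sequence[Roi],
    fs: float,
    t0: float = 0.0,
    segment_id: int = 0,
) -> list[GaitEvent]:
    """Localise events on the raw signal inside each ROI.

    A positive ROI yields a heel-strike at the argmax of the raw signal
    within it; a negative ROI yields a toe-off at the argmin.  Ties take
    the earliest extremal sample.  Leading and trailing toe-offs are
    trimmed so that the sequence starts and ends with a heel-strike,
    which keeps the stride anchors of the downstream cycle builder well
    defined.
    """
    raw = np.asarray(raw, dtype=float)
    events: list[GaitEvent] = []
    for roi in rois:
        if roi.stop_idx > len(raw):
            raise ValidationError(f"ROI {roi} exceeds the segment")
        window = raw[roi.start_idx : roi.stop_idx]
        if np.ptp(window) == 0:
            logger.info("flat ROI [%d, %d): taking earliest sample",
                        roi.start_idx, roi.stop_idx)
        if roi.polarity == "positive":
            i = int(np.argmax(window))
            kind = HEEL_STRIKE
        else:
            i = int(np.argmin(window))
            kind = TOE_OFF
        events.append(
            GaitEvent(
                time=t0 + (roi.start_idx + i) / fs,
                kind=kind,
                segment_id=segment_id,
            )
        )
    events.sort(key=lambda e: e.time)
    while events and events[0].kind != HEEL_STRIKE:
        events.pop(0)
    while events and events[-1].kind != HEEL_STRIKE:
        events.pop()
    return events


def assign_sides(
    events: Sequence[GaitEvent], first_side: Literal["left", "right"] = "right"
) -> list[GaitEvent]:
    """Label events with alternating sides.

    Successive heel-strikes alternate sides starting from ``first_side``.
    Each toe-off takes the side OPPOSITE to the immediately preceding
    heel-strike: during the stance that follows a heel-strike, the foot
    that leaves the ground is the contralateral one entering swing.

    The true first side is unidentifiable from a lumbar sensor; because
    all spatiotemporal parameters are averaged over both sides, the
    choice does not affect the summary.
    """
    if first_side not in ("left", "right"):
        raise ValidationError(f"invalid first_side {first_side!r}")
    out: list[GaitEvent] = []
    expected = None
    side = None
    other = {"left": "right", "right": "left"}
    for e in events:
        if expected is not None and e.kind != expected:
            raise ValidationError("event kinds must alternate HS/TO")
        if e.kind == HEEL_STRIKE:
            side = first_side if side is None else other[side]
            label = side
        else:
            if side is None:
                raise ValidationError("sequence must start with a heel-strike")
            label = other[side]
        expected = TOE_OFF if e.kind == HEEL_STRIKE else HEEL_STRIKE
        out.append(
            GaitEvent(time=e.time, kind=e.kind, side=label, segment_id=e.segment_id)
        )
    return out


def tune_filter_parameters(
    raw: np.ndarray,
    fs: float,
    grid: Sequence[tuple[int, int]],
    *,
    defaults: tuple[int, int] = (DEFAULT_SG_POLYORDER, DEFAULT_SG_FRAME),
    median_order: int = DEFAULT_MEDIAN_ORDER,
) -> tuple[int, int]:
    """Brute-force Savitzky-Golay parameter search on one segment.

    Each ``(polyorder, frame)`` grid point is scored by the coefficient of
    variation (CV) of the inter-heel-strike intervals the full detection
    produces on this segment; steady gait has near-constant step time, so
    a lower CV means a cleaner segmentation.  Grid points producing fewer
    than 3 heel-strikes are invalid; ties are broken toward ``defaults``.
    """
    if not grid:
        raise TuningError("empty parameter grid")
    scores: list[tuple[float, int, tuple[int, int]]] = []
    for rank, (polyorder, frame) in enumerate(grid):
        try:
            f = preprocess_segment(
                raw, fs, sg_polyorder=polyorder, sg_frame=frame,
                median_order=median_order,
            )
            events = detect_events(raw, find_rois(f), fs)
        except ParameterError:
            continue
        hs = [e.time for e in events if e.kind == HEEL_STRIKE]
        if len(hs) < 3:
            continue
        intervals = np.diff(hs)
        mean = float(np.mean(intervals))
        if mean <= 0:
            continue
        cv = float(np.std(intervals) / mean)
        is_default = 0 if (polyorder, frame) == tuple(defaults) else 1
        scores.append((cv, is_default, (polyorder, frame)))
    if not scores:
        raise TuningError("no grid point produced at least 3 heel-strikes")
    scores.sort(key=lambda s: (round(s[0], 12), s[1]))
    return scores[0][2]
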