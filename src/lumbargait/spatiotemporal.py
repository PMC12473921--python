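"""Per-cycle and per-subject spatiotemporal gait parameters.

A gait cycle anchored at one foot's heel-strike contains five events:

    HS_a(k) < TO_b(k) < HS_b(k) < TO_a(k) < HS_a(k+1)

where ``a`` is the anchor side and ``b`` the other.  From these:

* gait cycle time        GCT = HS_a(k+1) - HS_a(k)              [s]
* stance phase           ST  = (TO_a - HS_a) / GCT * 100        [%]
* swing phase            SW  = (HS_a(k+1) - TO_a) / GCT * 100   [%]
* initial double support IDS = (TO_b - HS_a) / GCT * 100        [%]
* terminal double support TDS = (TO_a - HS_b) / GCT * 100       [%]
* double support         DS  = IDS + TDS                        [%]

ST + SW = 100 and DS = IDS + TDS hold exactly by construction.  Cadence
is the step rate in steps/min; it is computed at the subject level from
the number of steps and the walking time rather than per cycle, and for
steady gait cadence * mean GCT ~= 120 (two steps per cycle).

Cycles are built for both anchor sides and the per-subject summary is the
unweighted mean over all cycles of both anchors, so the arbitrary choice
of the first side label drops out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import EstimationError, ParameterError
from .events import HEEL_STRIKE, TOE_OFF, GaitEvent

__all__ = [
    "GaitCycle",
    "SpatiotemporalSummary",
    "build_cycles",
    "gait_cycle_time",
    "cadence",
    "stance_percent",
    "swing_percent",
    "double_support_percent",
    "summarize_subject",
    "stride_count_and_span",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GaitCycle:
    """One anchored gait cycle (times in seconds on the recording clock).

    ``anchor`` is the side whose two successive heel-strikes bound the
    cycle; ``hs_lead``/``to_lead`` belong to the anchor side and
    ``hs_contra``/``to_contra`` to the other side.
    """

    anchor: str  # left | right
    hs_lead: float
    to_contra: float
    hs_contra: float
    to_lead: float
    hs_lead_next: float

    def __post_init__(self) -> None:
        times = (self.hs_lead, self.to_contra, self.hs_contra,
                 self.to_lead, self.hs_lead_next)
        if not all(a < b for a, b in zip(times, times[1:])):
            raise EstimationError(f"cycle events out of order: {times}")
        if self.anchor not in ("left", "right"):
            raise EstimationError(f"invalid anchor {self.anchor!r}")


@dataclass(frozen=True)
class SpatiotemporalSummary:
    """Per-subject means over all gait cycles and both sides."""

    gct_s: float
    cadence_spm: float
    stance_pct: float
    swing_pct: float
    ids_pct: float
    tds_pct: float
    ds_pct: float
    n_cycles: int

    def __post_init__(self) -> None:
        if self.gct_s <= 0:
            raise EstimationError(f"GCT must be positive, got {self.gct_s}")
        for name in ("stance_pct", "swing_pct", "ids_pct", "tds_pct", "ds_pct"):
            v = getattr(self, name)
            if not 0 < v < 100:
                raise EstimationError(f"{name} = {v} outside (0, 100)")


def build_cycles(events: Sequence[GaitEvent]) -> list[GaitCycle]:
    """Pack side-labeled, alternating events into anchored cycles.

    Every window of five consecutive events matching the pattern
    ``HS_a, TO_b, HS_b, TO_a, HS_a`` within one segment becomes a cycle
    anchored at side ``a``; both anchor sides are built.  Malformed
    windows are skipped with a log message.  Cycles never span segment
    boundaries.
    """
    cycles: list[GaitCycle] = []
    by_segment: dict[int, list[GaitEvent]] = {}
    for e in events:
        by_segment.setdefault(e.segment_id, []).append(e)
    for seg_events in by_segment.values():
        seg_events.sort(key=lambda e: e.time)
        for i in range(len(seg_events) - 4):
            w = seg_events[i : i + 5]
            kinds = [e.kind for e in w]
            if kinds != [HEEL_STRIKE, TOE_OFF, HEEL_STRIKE, TOE_OFF, HEEL_STRIKE]:
                continue
            a = w[0].side
            b = "left" if a == "right" else "right"
            if [e.side for e in w] != [a, b, b, a, a] or a is None:
                logger.info("skipping malformed cycle window at t=%.3f", w[0].time)
                continue
            try:
                cycles.append(
                    GaitCycle(
                        anchor=a,
                        hs_lead=w[0].time,
                        to_contra=w[1].time,
                        hs_contra=w[2].time,
                        to_lead=w[3].time,
                        hs_lead_next=w[4].time,
                    )
                )
            except EstimationError:
                logger.info("skipping out-of-order cycle window at t=%.3f", w[0].time)
    return cycles


def gait_cycle_time(c: GaitCycle) -> float:
    """GCT: time between the two anchoring heel-strikes [s]."""
    return c.hs_lead_next - c.hs_lead


def cadence(step_count: int, walk_time: float) -> float:
    """Step rate: 60 * steps / walking time [steps/min]."""
    if walk_time <= 0:
        raise ParameterError(f"walk_time must be positive, got {walk_time}")
    return 60.0 * step_count / walk_time


def stance_percent(c: GaitCycle) -> float:
    """Stance phase: heel-strike to toe-off of the anchor foot [% of GCT]."""
    return (c.to_lead - c.hs_lead) / gait_cycle_time(c) * 100.0


def swing_percent(c: GaitCycle) -> float:
    """Swing phase: toe-off to next heel-strike of the anchor foot [% of GCT]."""
    return (c.hs_lead_next - c.to_lead) / gait_cycle_time(c) * 100.0


def double_support_percent(c: GaitCycle) -> tuple[float, float, float]:
    """Initial, terminal and total double support [% of GCT]."""
    gct = gait_cycle_time(c)
    ids = (c.to_contra - c.hs_lead) / gct * 100.0
    tds = (c.to_lead - c.hs_contra) / gct * 100.0
    return ids, tds, ids + tds


def stride_count_and_span(events: Sequence[GaitEvent]) -> tuple[int, float]:
    """Step count and walking time from detected events.

    Segment edges are trimmed by construction (boundary ROIs and dangling
    toe-offs are discarded), so counting heel-strikes against the full
    segment duration would bias cadence low.  Instead, each segment
    contributes the time span between its first and last heel-strike and
    the number of steps completed in that span (heel-strikes minus one,
    both feet pooled).  For steady gait this makes cadence * mean GCT =
    120 exactly.
    """
    by_segment: dict[int, list[float]] = {}
    for e in events:
        if e.kind == HEEL_STRIKE:
            by_segment.setdefault(e.segment_id, []).append(e.time)
    steps = 0
    span = 0.0
    for hs in by_segment.values():
        if len(hs) < 2:
            continue
        hs.sort()
        steps += len(hs) - 1
        span += hs[-1] - hs[0]
    return steps, span


def summarize_subject(
    cycles: Sequence[GaitCycle], step_count: int, walk_time: float
) -> SpatiotemporalSummary:
    """Unweighted means over all cycles of both anchors, plus cadence."""
    if not cycles:
        raise EstimationError("cannot summarize zero gait cycles")
    gct = float(np.mean([gait_cycle_time(c) for c in cycles]))
    st = float(np.mean([stance_percent(c) for c in cycles]))
    sw = float(np.mean([swing_percent(c) for c in cycles]))
    ds_triplets = [double_support_percent(c) for c in cycles]
    ids = float(np.mean([d[0] for d in ds_triplets]))
    tds = float(np.mean([d[1] for d in ds_triplets]))
    ds = float(np.mean([d[2] for d in ds_triplets]))
    return SpatiotemporalSummary(
        gct_s=gct,
        cadence_spm=cadence(step_count, walk_time),
        stance_pct=st,
        swing_pct=sw,
        ids_pct=ids,
        tds_pct=tds,
        ds_pct=ds,
        n_cycles=len(cycles),
    )
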