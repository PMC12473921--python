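"""End-to-end pipeline: turn removal -> event detection -> parameters.

Given a recording and a :class:`~lumbargait.config.RunConfig`, the
pipeline

1. smooths the rectified, band-passed angular velocity into a turn
   envelope and thresholds it into turning windows,
2. extracts the complementary straight-walk segments of the AP
   acceleration,
3. runs the ROI filter cascade and raw-signal extremum localisation on
   each segment (segments shorter than the Savitzky-Golay frame are
   skipped and logged),
4. assigns alternating side labels per segment, and
5. builds anchored gait cycles and the per-subject summary.

Every dropped segment or skipped stage is recorded in the result's
``log`` list (dictionaries, suitable for JSON-lines serialisation); the
published protocol reports only means, so the log is the audit trail.
The pipeline is deterministic: identical inputs produce identical
outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .config import RunConfig
from .errors import EstimationError, ParameterError, SegmentTooShortError
from .events import (
    GaitEvent,
    assign_sides,
    detect_events,
    find_rois,
    preprocess_segment,
)
from .io import InertialRecording
from .spatiotemporal import (
    GaitCycle,
    SpatiotemporalSummary,
    build_cycles,
    stride_count_and_span,
    summarize_subject,
)
from .turns import (
    TurnWindow,
    WalkingSegment,
    detect_turn_windows,
    estimate_turn_threshold,
    extract_walking_segments,
    smooth_angular_speed,
)

__all__ = ["PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    turn_threshold: float
    turns: list[TurnWindow]
    segments: list[WalkingSegment]
    events: list[GaitEvent]
    cycles: list[GaitCycle]
    summary: SpatiotemporalSummary | None
    step_count: int
    walk_time: float
    log: list[dict] = field(default_factory=list)


def run_pipeline(rec: InertialRecording, config: RunConfig | None = None) -> PipelineResult:
    """Run the full detection/estimation chain on one recording.

    Returns a :class:`PipelineResult`; ``summary`` is ``None`` when no
    complete gait cycle was found (the log says why).
    """
    cfg = config or RunConfig()
    log: list[dict] = []

    envelope = smooth_angular_speed(
        rec.gyro_sag,
        rec.fs,
        low=cfg.turn_low_hz,
        high=cfg.turn_high_hz,
        order=cfg.turn_order,
        sg_polyorder=cfg.turn_sg_polyorder,
        sg_frame=cfg.turn_sg_frame,
    )
    threshold = estimate_turn_threshold(
        envelope,
        rec.fs,
        cfg.min_turn_s,
        expected_count=cfg.expected_turn_count,
    )
    turns = (
        detect_turn_windows(
            envelope, threshold, rec.fs, cfg.min_turn_s, cfg.merge_gap_s
        )
        if threshold < float("inf")
        else []
    )
    log.append(
        {
            "stage": "turns",
            "threshold": float(threshold),
            "n_turns": len(turns),
        }
    )

    segments = extract_walking_segments(rec, turns, cfg.min_walk_s)
    log.append({"stage": "segments", "n_segments": len(segments)})

    events: list[GaitEvent] = []
    for seg_id, seg in enumerate(segments):
        try:
            filtered = preprocess_segment(
                seg.acc_ap_slice,
                rec.fs,
                low=cfg.event_low_hz,
                high=cfg.event_high_hz,
                order=cfg.event_order,
                sg_polyorder=cfg.event_sg_polyorder,
                sg_frame=cfg.event_sg_frame,
                median_order=cfg.median_order,
            )
        except SegmentTooShortError as exc:
            logger.warning("skipping segment %d: %s", seg_id, exc)
            log.append(
                {
                    "stage": "events",
                    "segment_id": seg_id,
                    "skipped": True,
                    "reason": str(exc),
                }
            )
            continue
        rois = find_rois(filtered)
        seg_events = detect_events(
            seg.acc_ap_slice,
            rois,
            rec.fs,
            t0=seg.start_idx / rec.fs,
            segment_id=seg_id,
        )
        seg_events = assign_sides(seg_events, cfg.first_side)
        events.extend(seg_events)
        log.append(
            {
                "stage": "events",
                "segment_id": seg_id,
                "n_rois": len(rois),
                "n_events": len(seg_events),
            }
        )

    cycles = build_cycles(events)
    step_count, walk_time = stride_count_and_span(events)
    try:
        summary = summarize_subject(cycles, step_count, walk_time)
    except (EstimationError, ParameterError) as exc:
        logger.warning("no summary: %s", exc)
        log.append({"stage": "summary", "error": str(exc)})
        summary = None
    log.append(
        {
            "stage": "summary",
            "n_cycles": len(cycles),
            "step_count": step_count,
            "walk_time": walk_time,
        }
    )

    return PipelineResult(
        turn_threshold=float(threshold),
        turns=turns,
        segments=segments,
        events=events,
        cycles=cycles,
        summary=summary,
        step_count=step_count,
        walk_time=walk_time,
        log=log,
    )
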