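"""Ground-truth-based evaluation helpers for detector validation.

Detection performance is scored inside the detected straight-walk
segments with a one-cycle guard margin at each segment edge: boundary
regions are excluded *by design* (the detector discards truncated
boundary lobes and dangling toe-offs, and events during turning phases
are out of scope), which matches the common practice of dropping the
first and last stride of each walking bout when rating event detectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["EventMatchResult", "interior_truth_times", "match_events"]


@dataclass(frozen=True)
class EventMatchResult:
    """Per-kind matching of ground-truth to detected event times."""

    n_truth: int
    n_matched: int
    errors_samples: np.ndarray  # nearest-detection distance per truth event

    @property
    def match_rate(self) -> float:
        return self.n_matched / self.n_truth if self.n_truth else float("nan")

    @property
    def median_error(self) -> float:
        return float(np.median(self.errors_samples)) if self.n_truth else float("nan")


def interior_truth_times(
    times: Sequence[float],
    segments: Sequence,
    fs: float,
    margin_s: float,
) -> np.ndarray:
    """Ground-truth event times at least ``margin_s`` inside a segment."""
    out = []
    for t in np.asarray(times, dtype=float):
        for seg in segments:
            a = seg.start_idx / fs + margin_s
            b = seg.stop_idx / fs - margin_s
            if a <= t <= b:
                out.append(t)
                break
    return np.asarray(out)


def match_events(
    truth_times: Sequence[float],
    detected_times: Sequence[float],
    fs: float,
    tol_samples: float = 3.0,
) -> EventMatchResult:
    """Nearest-neighbour matching of truth to detections, in samples."""
    truth = np.asarray(truth_times, dtype=float)
    det = np.asarray(detected_times, dtype=float)
    if len(truth) == 0:
        return EventMatchResult(0, 0, np.empty(0))
    if len(det) == 0:
        errs = np.full(len(truth), np.inf)
        return EventMatchResult(len(truth), 0, errs)
    errs = np.min(np.abs(det[None, :] - truth[:, None]), axis=1) * fs
    return EventMatchResult(len(truth), int(np.sum(errs <= tol_samples)), errs)
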