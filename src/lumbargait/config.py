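"""Pipeline configuration with defaults matching the published algorithm
parameters at 128 Hz (Butterworth 1-50 Hz order 4; Savitzky-Golay order 2
/ frame 1101 for the turn envelope and order 50 / frame 801 for event
ROIs; median order 10).  Frame lengths are quoted at 128 Hz and rescale
with the sampling rate.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .errors import ConfigError

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class RunConfig:
    # turn-envelope filtering
    turn_low_hz: float = 1.0
    turn_high_hz: float = 50.0
    turn_order: int = 4
    turn_sg_polyorder: int = 2
    turn_sg_frame: int = 1101
    # event-ROI filtering
    event_low_hz: float = 1.0
    event_high_hz: float = 50.0
    event_order: int = 4
    event_sg_polyorder: int = 50
    event_sg_frame: int = 801
    median_order: int = 10
    # segmentation thresholds
    min_turn_s: float = 1.0
    merge_gap_s: float = 0.5
    min_walk_s: float = 2.0
    expected_turn_count: int | None = None
    # event labelling and statistics
    first_side: str = "right"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.first_side not in ("left", "right"):
            raise ConfigError(f"first_side must be left or right, got {self.first_side!r}")
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        for name in ("min_turn_s", "merge_gap_s", "min_walk_s"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")


# nested YAML layout <-> flat dataclass fields
_YAML_MAP = {
    ("filter", "turn", "low_hz"): "turn_low_hz",
    ("filter", "turn", "high_hz"): "turn_high_hz",
    ("filter", "turn", "order"): "turn_order",
    ("filter", "event", "low_hz"): "event_low_hz",
    ("filter", "event", "high_hz"): "event_high_hz",
    ("filter", "event", "order"): "event_order",
    ("sg", "turn", "polyorder"): "turn_sg_polyorder",
    ("sg", "turn", "frame"): "turn_sg_frame",
    ("sg", "event", "polyorder"): "event_sg_polyorder",
    ("sg", "event", "frame"): "event_sg_frame",
    ("median", "order"): "median_order",
    ("segmentation", "min_turn_s"): "min_turn_s",
    ("segmentation", "merge_gap_s"): "merge_gap_s",
    ("segmentation", "min_walk_s"): "min_walk_s",
    ("segmentation", "expected_turn_count"): "expected_turn_count",
    ("events", "first_side"): "first_side",
    ("stats", "alpha"): "alpha",
}


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a :class:`RunConfig` from nested YAML; keyword overrides win.

    Missing keys keep their defaults; unknown keys raise
    :class:`ConfigError` so typos do not silently fall back to defaults.
    """
    fields: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path} is not a mapping")
        flat = _flatten(raw)
        for key_path, value in flat.items():
            field = _YAML_MAP.get(key_path)
            if field is None:
                raise ConfigError(f"unknown config key {'.'.join(key_path)}")
            fields[field] = value
    fields.update(overrides)
    try:
        return RunConfig(**fields)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write the nested YAML form of a config."""
    nested: dict = {}
    flat = asdict(cfg)
    for key_path, field in _YAML_MAP.items():
        node = nested
        for part in key_path[:-1]:
            node = node.setdefault(part, {})
        node[key_path[-1]] = flat[field]
    Path(path).write_text(yaml.safe_dump(nested, sort_keys=False))


def _flatten(d: dict, prefix: tuple = ()) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, dict):
            out.update(_flatten(v, prefix + (k,)))
        else:
            out[prefix + (k,)] = v
    return out
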