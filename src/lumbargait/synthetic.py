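"""Synthetic lumbar-IMU gait recordings with exact ground truth.

The generator emulates a back-and-forth walking protocol: straight passes
along a 10 m path separated by 180-degree turns, for roughly two minutes.
It produces the two channels the pipeline consumes plus the complete
ground truth (event times with sides, turn intervals, true parameter
values), so every upstream module is testable without real data.

Signal model
------------
* AP acceleration: each step contributes two positive Gaussian bumps and
  one negative Gaussian bump -- a smaller early peak at weight
  acceptance, a larger peak centred exactly on the heel-strike instant,
  and a valley centred on the following (contralateral) toe-off.  Gaussian
  bumps have analytically known extremum locations, which makes
  event-timing error exactly measurable.  The first positive peak
  defaults to 60% of the second so the "second positive peak is the
  heel-strike" rule is exercised non-trivially.
* Sagittal-axis angular velocity: a low-amplitude oscillation at the
  stride frequency during walking, plus high-amplitude bursts during each
  turn.  Turns are executed through pivot steps, so the burst is modelled
  as a raised-cosine envelope modulating an oscillatory carrier above
  1 Hz -- a slow unmodulated ramp would be removed by the 1 Hz high-pass
  edge of the detection filter and is not what a trunk gyroscope records.
* White Gaussian noise on both channels.

Event timing is derived from the configured cycle time, stance fraction
and double-support fraction with the canonical interleaving
HS_r < TO_l < HS_l < TO_r < HS_r'.  For alternating gait the terminal
double support is structurally (stance_fraction - 0.5) of the cycle, so
the configuration must satisfy ds_fraction = 2 * stance_fraction - 1;
inconsistent fractions raise :class:`ConfigError`.  A nonzero
``asymmetry`` shifts the left heel-strikes, trading initial against
terminal double support while keeping their sum fixed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import InertialRecording
from .spatiotemporal import SpatiotemporalSummary

__all__ = ["GaitSimConfig", "SimGroundTruth", "simulate_recording", "make_paired_table"]


@dataclass(frozen=True)
class GaitSimConfig:
    """Study-protocol and signal-morphology settings.

    Defaults emulate a healthy adult on the two-minute 10 m back-and-forth
    protocol: 16 steps of ~0.63 m per pass, cycle time 1.16 s (cadence
    ~103 steps/min), stance 60% and double support 20% of the cycle, and
    2 s turns; 12 passes give 11 turns and a ~2.4 min recording.
    """

    fs: float = 128.0
    n_passes: int = 12
    n_steps_per_pass: int = 16
    gct: float = 1.16
    stance_fraction: float = 0.60
    ds_fraction: float = 0.20
    turn_duration: float = 2.0
    asymmetry: float = 0.0  # fractional L/R timing offset (of GCT)
    noise_sd: float = 0.05  # accelerometer noise, m/s^2
    gyro_noise_sd: float = 1.0  # gyroscope noise, deg/s
    peak1_amp: float = 1.2  # first (early) positive peak, m/s^2
    peak2_amp: float = 2.0  # heel-strike peak, m/s^2
    valley_amp: float = 1.5  # toe-off valley depth, m/s^2
    peak_width: float = 0.04  # Gaussian sigma of the event bumps, s
    peak1_lead: float = 0.12  # first-peak lead before heel-strike, fraction of GCT
    walk_gyro_amp: float = 12.0  # stride-frequency oscillation, deg/s
    turn_gyro_amp: float = 90.0  # turn burst amplitude, deg/s
    turn_gyro_freq: float = 1.4  # turn carrier frequency, Hz
    lead_in: float = 0.3  # quiet margin at each end of a pass, s
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.ds_fraction < self.stance_fraction < 1:
            raise ConfigError(
                "fractions must satisfy 0 < ds_fraction < stance_fraction < 1"
            )
        if abs(self.ds_fraction - (2.0 * self.stance_fraction - 1.0)) > 1e-9:
            raise ConfigError(
                "inconsistent fractions: alternating gait requires "
                "ds_fraction = 2 * stance_fraction - 1 "
                f"(got ds={self.ds_fraction}, stance={self.stance_fraction})"
            )
        if self.gct <= 0 or self.turn_duration <= 0 or self.fs <= 0:
            raise ConfigError("gct, turn_duration and fs must be positive")
        if self.n_passes < 1 or self.n_steps_per_pass < 2:
            raise ConfigError("need at least one pass of at least two steps")
        if abs(self.asymmetry) >= self.ds_fraction / 2:
            raise ConfigError("asymmetry too large: double support would vanish")


@dataclass
class SimGroundTruth:
    """Exact event times, turn intervals and true parameter values."""

    hs_times: np.ndarray
    hs_sides: list[str]
    to_times: np.ndarray
    to_sides: list[str]
    turn_intervals: list[tuple[float, float]]
    walk_intervals: list[tuple[float, float]]
    true_params: SpatiotemporalSummary

    def events_as_objects(self) -> list:
        """Ground-truth events as side-labeled GaitEvent objects, with
        segment ids numbering the walking passes."""
        from .events import GaitEvent, HEEL_STRIKE, TOE_OFF

        def seg_of(t: float) -> int:
            for k, (a, b) in enumerate(self.walk_intervals):
                if a <= t <= b:
                    return k
            return -1

        evs = [
            GaitEvent(time=float(t), kind=HEEL_STRIKE, side=s, segment_id=seg_of(t))
            for t, s in zip(self.hs_times, self.hs_sides)
        ] + [
            GaitEvent(time=float(t), kind=TOE_OFF, side=s, segment_id=seg_of(t))
            for t, s in zip(self.to_times, self.to_sides)
        ]
        evs.sort(key=lambda e: e.time)
        return evs


def _gauss(t: np.ndarray, centre: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - centre) / sigma) ** 2)


def simulate_recording(cfg: GaitSimConfig) -> tuple[InertialRecording, SimGroundTruth]:
    """Generate one recording plus ground truth; fixed seed, fixed output."""
    rng = np.random.default_rng(cfg.seed)
    h = cfg.gct / 2.0  # step period
    stance_s = cfg.stance_fraction * cfg.gct
    delta = cfg.asymmetry * cfg.gct  # left-side timing offset

    hs_times: list[float] = []
    hs_sides: list[str] = []
    turn_intervals: list[tuple[float, float]] = []
    walk_intervals: list[tuple[float, float]] = []

    to_times: list[float] = []
    to_sides: list[str] = []

    t_cursor = 0.0
    side_cycle = ("right", "left")
    other = {"left": "right", "right": "left"}
    step_index = 0  # global step counter keeps sides alternating across passes
    for p in range(cfg.n_passes):
        pass_start = t_cursor
        first_hs = pass_start + cfg.lead_in + h
        pass_hs: list[tuple[float, str]] = []
        for j in range(cfg.n_steps_per_pass):
            side = side_cycle[step_index % 2]
            t_hs = first_hs + j * h + (delta if side == "left" else 0.0)
            pass_hs.append((t_hs, side))
            step_index += 1
        # A foot's toe-off ends its own stance: TO = its HS + stance.  The
        # foot standing before the first step acts as a virtual heel-strike
        # one step period earlier, and the trailing foot of the final step
        # never toe-offs (the pass ends in double-stance standing).
        virtual_side = other[pass_hs[0][1]]
        virtual_hs = first_hs - h + (delta if virtual_side == "left" else 0.0)
        stance_starts = [(virtual_hs, virtual_side)] + pass_hs[:-1]
        for t_start, side in stance_starts:
            to_times.append(t_start + stance_s)
            to_sides.append(side)
        for t_hs, side in pass_hs:
            hs_times.append(t_hs)
            hs_sides.append(side)
        pass_end = max(hs_times[-1], to_times[-1]) + cfg.lead_in
        walk_intervals.append((pass_start, pass_end))
        t_cursor = pass_end
        if p < cfg.n_passes - 1:
            turn_intervals.append((t_cursor, t_cursor + cfg.turn_duration))
            t_cursor += cfg.turn_duration

    hs = np.asarray(hs_times)
    to = np.asarray(to_times)

    duration = t_cursor
    n = int(round(duration * cfg.fs)) + 1
    t = np.arange(n) / cfg.fs

    acc = np.zeros(n)
    sigma = cfg.peak_width
    for t_hs in hs_times:
        acc += cfg.peak1_amp * _gauss(t, t_hs - cfg.peak1_lead * cfg.gct, sigma * 1.25)
        acc += cfg.peak2_amp * _gauss(t, t_hs, sigma)
    for t_to in to_times:
        acc -= cfg.valley_amp * _gauss(t, t_to, sigma)
    acc += rng.normal(0.0, cfg.noise_sd, n)

    gyro = np.zeros(n)
    stride_freq = 1.0 / cfg.gct
    for a, b in walk_intervals:
        mask = (t >= a) & (t < b)
        gyro[mask] += cfg.walk_gyro_amp * np.sin(
            2.0 * np.pi * stride_freq * (t[mask] - a)
        )
    for k, (a, b) in enumerate(turn_intervals):
        mask = (t >= a) & (t < b)
        phase = (t[mask] - a) / (b - a)
        envelope = 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))  # raised cosine
        carrier = np.sin(2.0 * np.pi * cfg.turn_gyro_freq * (t[mask] - a))
        gyro[mask] += ((-1.0) ** k) * cfg.turn_gyro_amp * envelope * carrier
    gyro += rng.normal(0.0, cfg.gyro_noise_sd, n)

    ids_pct = (cfg.stance_fraction - 0.5 + cfg.asymmetry) * 100.0
    tds_pct = (cfg.stance_fraction - 0.5 - cfg.asymmetry) * 100.0
    true_params = SpatiotemporalSummary(
        gct_s=cfg.gct,
        cadence_spm=120.0 / cfg.gct,
        stance_pct=cfg.stance_fraction * 100.0,
        swing_pct=(1.0 - cfg.stance_fraction) * 100.0,
        ids_pct=ids_pct,
        tds_pct=tds_pct,
        ds_pct=cfg.ds_fraction * 100.0,
        n_cycles=cfg.n_passes * (cfg.n_steps_per_pass - 2),
    )
    rec = InertialRecording(
        fs=cfg.fs, t=t, acc_ap=acc, gyro_sag=gyro,
        subject_id=f"sim-{cfg.seed}",
    )
    truth = SimGroundTruth(
        hs_times=hs,
        hs_sides=hs_sides,
        to_times=to,
        to_sides=to_sides,
        turn_intervals=turn_intervals,
        walk_intervals=walk_intervals,
        true_params=true_params,
    )
    return rec, truth


def make_paired_table(
    truths: Mapping[str, Sequence[float]],
    bias_model: Mapping[str, Mapping[str, float]] | None = None,
    noise_sd: float | Mapping[str, float] = 0.0,
    seed: int = 0,
    noise_sd_a: float | Mapping[str, float] = 0.0,
) -> pd.DataFrame:
    """Paired per-subject parameter table for the agreement battery.

    ``truths`` maps parameter name -> per-subject true values.
    ``bias_model`` maps parameter name -> {"constant": offset,
    "proportional": slope}; then

        method_a = truth + e_a,            e_a ~ N(0, noise_sd_a)
        method_b = slope * truth + offset + e_b,  e_b ~ N(0, noise_sd)

    ``noise_sd_a`` defaults to 0 (method_a reports the truth exactly), but
    Passing-Bablok regression assumes measurement error in BOTH methods;
    power/coverage studies should give both methods comparable noise.
    Returns a tidy frame with columns parameter, method_a, method_b, used
    to verify that the agreement battery flags exactly the injected error
    types.
    """

    def _sd(spec, name: str) -> float:
        return float(spec[name]) if isinstance(spec, Mapping) else float(spec)

    rng = np.random.default_rng(seed)
    bias_model = bias_model or {}
    rows = []
    for name, values in truths.items():
        values = np.asarray(values, dtype=float)
        if len(values) < 10:
            raise ConfigError(f"need >= 10 subjects for '{name}', got {len(values)}")
        model = bias_model.get(name, {})
        slope = float(model.get("proportional", 1.0))
        offset = float(model.get("constant", 0.0))
        a_vals = values + rng.normal(0.0, _sd(noise_sd_a, name), len(values))
        b_vals = slope * values + offset + rng.normal(0.0, _sd(noise_sd, name), len(values))
        for a, b in zip(a_vals, b_vals):
            rows.append({"parameter": name, "method_a": a, "method_b": b})
    return pd.DataFrame(rows, columns=["parameter", "method_a", "method_b"])
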