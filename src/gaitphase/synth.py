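"""Synthetic planar gait generator with known phase and event times.

Emulates the structure of treadmill/overground motion-capture walking data:
per side, a periodic ankle trajectory relative to the iliac crest, sampled at
a fixed rate (nominally 150 Hz) with additive Gaussian marker noise.  The
forward-back excursion is a cosine in an underlying angle, time-warped so
that stance occupies ``duty_factor`` of the cycle; heel strike sits at phase
0 (the positive x peak) and toe-off at the stance/swing boundary (the
negative x peak), which is exactly the peak structure the kinematic event
detector relies on.  The continuous phase and both event trains are known in
closed form, so every downstream stage can be scored against ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .circular import TWO_PI, wrap_angle
from .events import EventSet
from .preprocess import MarkerTrajectory

__all__ = [
    "GaitSimConfig",
    "SimulatedWalk",
    "ConfigurationError",
    "ankle_coordinates_at_phase",
    "simulate_walk",
    "true_event_times",
    "write_walk_csv",
    "write_ground_truth_json",
]

SIDES = ("left", "right")


class ConfigurationError(ValueError):
    """A simulator configuration field is out of range."""


@dataclass(frozen=True)
class GaitSimConfig:
    """Study conditions for one simulated walk.

    Defaults emulate comfortable adult treadmill walking recorded by a
    motion-capture system: 150 Hz sampling, ~1 stride/s, ±300 mm forward-back
    ankle excursion relative to the pelvis, ~80 mm swing foot lift, 60/40
    stance/swing split, and sub-millimetre marker noise.
    """

    sampling_rate: float = 150.0
    duration: float = 30.0
    cadence: object = 1.0  # strides/s, or [(start_time_s, cadence), ...]
    amplitude_x: float = 300.0
    amplitude_y: float = 80.0
    baseline_y: float = 100.0
    duty_factor: float = 0.6
    progression_speed: float = 0.0  # mm/s; 0 = treadmill-like
    noise_sd: float = 0.5  # mm
    phase_offset_right: float = np.pi
    sway_amplitude: float = 0.0  # mm of optional sinusoidal iliac sway
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sampling_rate > 0:
            raise ConfigurationError("sampling_rate must be positive")
        if not self.duration > 0:
            raise ConfigurationError("duration must be positive")
        if not 0.0 < self.duty_factor < 1.0:
            raise ConfigurationError("duty_factor must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if self.amplitude_x <= 0 or self.amplitude_y < 0:
            raise ConfigurationError("amplitude_x must be positive, amplitude_y non-negative")
        for t, c in self._schedule():
            if c <= 0:
                raise ConfigurationError("cadence values must be positive")
            if t < 0:
                raise ConfigurationError("cadence schedule start times must be >= 0")

    def _schedule(self) -> list[tuple[float, float]]:
        if np.isscalar(self.cadence):
            return [(0.0, float(self.cadence))]
        sched = [(float(t), float(c)) for t, c in self.cadence]
        if not sched or sched[0][0] != 0.0:
            raise ConfigurationError("cadence schedule must start at time 0")
        if any(b[0] <= a[0] for a, b in zip(sched, sched[1:])):
            raise ConfigurationError("cadence schedule start times must be ascending")
        return sched

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))


@dataclass
class SimulatedWalk:
    """A simulated two-sided walk with ground-truth phase and events."""

    trajectory: dict[str, MarkerTrajectory]
    true_phase: dict[str, np.ndarray]  # wrapped to (-pi, pi] per sample
    true_events: dict[str, EventSet]
    config: GaitSimConfig

    def noiseless_relative_x(self, side: str) -> np.ndarray:
        """Closed-form R_x (no noise) for this walk's config, for oracles."""
        phi = _unwrapped_phase(self.config, side)
        x, _ = ankle_coordinates_at_phase(phi, self.config)
        return x


def ankle_coordinates_at_phase(phi, config: GaitSimConfig):
    """Noiseless ankle position relative to the iliac crest at gait phase ``phi``.

    A monotone piecewise-linear warp maps stance (phase in [0, 2*pi*duty))
    onto u in [0, pi) and swing onto u in [pi, 2*pi); the forward-back
    excursion is ``amplitude_x * cos(u)``, so the global maximum (heel
    strike) sits at phase 0 and the minimum (toe-off) at the stance/swing
    boundary.  Vertically the ankle stays at ``baseline_y`` through stance
    and lifts by ``amplitude_y * sin^2(pi * swing_progress)`` during swing.
    """
    p = np.asarray(phi, dtype=float) % TWO_PI
    d = config.duty_factor
    stance = p < TWO_PI * d
    u = np.where(stance, p / (2.0 * d), np.pi + (p - TWO_PI * d) / (2.0 * (1.0 - d)))
    x = config.amplitude_x * np.cos(u)
    swing_progress = (p - TWO_PI * d) / (TWO_PI * (1.0 - d))
    y = config.baseline_y + np.where(
        stance, 0.0, config.amplitude_y * np.sin(np.pi * swing_progress) ** 2
    )
    if np.ndim(phi) == 0:
        return float(x), float(y)
    return x, y


def _unwrapped_phase(config: GaitSimConfig, side: str) -> np.ndarray:
    """Unwrapped phase 2*pi*integral(cadence dt) (+ right-side offset) per sample."""
    t = np.arange(config.n_samples) / config.sampling_rate
    sched = config._schedule()
    starts = np.array([s[0] for s in sched])
    rates = np.array([s[1] for s in sched])
    # phase accumulated at each schedule breakpoint
    acc = np.concatenate([[0.0], np.cumsum(rates[:-1] * (starts[1:] - starts[:-1]))])
    seg = np.searchsorted(starts, t, side="right") - 1
    phase = TWO_PI * (acc[seg] + rates[seg] * (t - starts[seg]))
    if side == "right":
        phase = phase + config.phase_offset_right
    return phase


def _level_crossing_times(config: GaitSimConfig, side: str, level: float):
    """Times (s) at which the unwrapped phase hits ``level`` modulo 2*pi."""
    phi = _unwrapped_phase(config, side)
    t = np.arange(config.n_samples) / config.sampling_rate
    tol = 1e-9
    m_lo = int(np.ceil((phi[0] - level) / TWO_PI - tol))
    m_hi = int(np.floor((phi[-1] - level) / TWO_PI + tol))
    if m_hi < m_lo:
        return np.empty(0), np.empty(0, dtype=int)
    targets = level + TWO_PI * np.arange(m_lo, m_hi + 1)
    # phase is strictly increasing (cadence > 0): invert by interpolation
    times = np.interp(targets, phi, t)
    idx = np.clip(np.round(times * config.sampling_rate).astype(int), 0, config.n_samples - 1)
    return times, idx


def _events_for_side(config: GaitSimConfig, side: str) -> EventSet:
    hs_t, hs_i = _level_crossing_times(config, side, 0.0)
    to_t, to_i = _level_crossing_times(config, side, TWO_PI * config.duty_factor)
    return EventSet(
        heel_strike_idx=hs_i,
        heel_strike_times=hs_t,
        toe_off_idx=to_i,
        toe_off_times=to_t,
        side=side,
        source="ground_truth",
    )


def simulate_walk(config: GaitSimConfig) -> SimulatedWalk:
    """Simulate a two-sided walk under ``config``; bit-identical for equal seeds.

    The right side runs ``phase_offset_right`` ahead of the left (anti-phase
    by default).  The iliac crest moves at ``progression_speed`` (plus an
    optional stride-frequency sinusoidal sway); i.i.d. Gaussian noise of sd
    ``noise_sd`` is added to every marker coordinate.  Ground-truth phase and
    events come from the noiseless model.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    t = np.arange(n) / config.sampling_rate
    trajectory: dict[str, MarkerTrajectory] = {}
    true_phase: dict[str, np.ndarray] = {}
    true_events: dict[str, EventSet] = {}
    base_phase = _unwrapped_phase(config, "left")
    x_iliac_clean = config.progression_speed * t
    if config.sway_amplitude > 0:
        x_iliac_clean = x_iliac_clean + config.sway_amplitude * np.sin(base_phase)
    for side in SIDES:
        phi = _unwrapped_phase(config, side)
        x_rel, y = ankle_coordinates_at_phase(phi, config)
        x_ankle = x_iliac_clean + x_rel
        noise = rng.normal(0.0, config.noise_sd, size=(3, n)) if config.noise_sd > 0 else np.zeros((3, n))
        trajectory[side] = MarkerTrajectory(
            time=t,
            x_ankle=x_ankle + noise[0],
            y_ankle=y + noise[1],
            x_iliac=x_iliac_clean + noise[2],
            side=side,
            sampling_rate=config.sampling_rate,
        )
        true_phase[side] = wrap_angle(phi)
        true_events[side] = _events_for_side(config, side)
    return SimulatedWalk(
        trajectory=trajectory, true_phase=true_phase, true_events=true_events, config=config
    )


def true_event_times(walk: SimulatedWalk) -> dict[str, EventSet]:
    """Recompute ground-truth events from the walk's noiseless phase schedule.

    Heel strikes solve true_phase = 0 (mod 2*pi), toe-offs solve
    true_phase = 2*pi*duty_factor (mod 2*pi).
    """
    return {side: _events_for_side(walk.config, side) for side in SIDES}


def write_walk_csv(walk: SimulatedWalk, path: str | Path) -> None:
    """Write both sides as CSV: time_s, side, x_ankle_mm, y_ankle_mm, x_iliac_mm."""
    frames = []
    for side, traj in walk.trajectory.items():
        frames.append(
            pd.DataFrame(
                {
                    "time_s": traj.time,
                    "side": side,
                    "x_ankle_mm": traj.x_ankle,
                    "y_ankle_mm": traj.y_ankle,
                    "x_iliac_mm": traj.x_iliac,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_ground_truth_json(walk: SimulatedWalk, path: str | Path) -> None:
    """Ground-truth phase and event lists as JSON."""
    payload = {
        side: {
            "true_phase_rad": walk.true_phase[side].tolist(),
            "heel_strike_times_s": walk.true_events[side].heel_strike_times.tolist(),
            "toe_off_times_s": walk.true_events[side].toe_off_times.tolist(),
        }
        for side in SIDES
    }
    Path(path).write_text(json.dumps(payload))
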