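"""Gait-event detection, phase calibration, time-error scoring, CV splits.

Ground-truth heel strikes and toe-offs come from the kinematics themselves:
with the ankle expressed relative to the pelvis, heel strike is the positive
peak of the forward position (foot horizontal velocity + -> -) and toe-off the
negative peak (- -> +).  The trained detector is then calibrated by reading
off the model phase at ground-truth events on training data (circular mean),
and events on unseen data are declared whenever the unwrapped model phase
crosses those constant reference phases.  Performance is the absolute time
difference, in milliseconds, between phase-crossing detections and the
kinematic ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .circular import circular_mean, resultant, wrap_angle

__all__ = [
    "EventSet",
    "PhaseCalibration",
    "TimeErrorReport",
    "CVPlan",
    "CalibrationError",
    "detect_events_ground_truth",
    "dominant_period",
    "calibrate_event_phases",
    "detect_events_from_phase",
    "compute_time_errors",
    "crossval_split",
]


class CalibrationError(ValueError):
    """Reference phases cannot be established (no events, or antipodal phases)."""


@dataclass
class EventSet:
    """Heel-strike and toe-off events of one side, as sample indices and seconds."""

    heel_strike_idx: np.ndarray
    heel_strike_times: np.ndarray
    toe_off_idx: np.ndarray
    toe_off_times: np.ndarray
    side: str = "left"
    source: str = "ground_truth"  # ground_truth | phase_detected

    def __post_init__(self) -> None:
        self.heel_strike_idx = np.asarray(self.heel_strike_idx, dtype=int)
        self.heel_strike_times = np.asarray(self.heel_strike_times, dtype=float)
        self.toe_off_idx = np.asarray(self.toe_off_idx, dtype=int)
        self.toe_off_times = np.asarray(self.toe_off_times, dtype=float)
        for name in ("heel_strike_times", "toe_off_times"):
            t = getattr(self, name)
            if t.size > 1 and not np.all(np.diff(t) > 0):
                raise ValueError(f"{name} must be strictly increasing")

    def events(self, kind: str) -> np.ndarray:
        return self.heel_strike_times if kind == "heel_strike" else self.toe_off_times


@dataclass
class PhaseCalibration:
    """Constant reference phases at heel strike / toe-off, plus progression sign."""

    ref_phase_hs: float
    ref_phase_to: float
    direction: int  # +1 anticlockwise, -1 clockwise

    def __post_init__(self) -> None:
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")
        self.ref_phase_hs = float(wrap_angle(self.ref_phase_hs))
        self.ref_phase_to = float(wrap_angle(self.ref_phase_to))


@dataclass
class TimeErrorReport:
    """Absolute detection time errors (ms) of matched events, with bookkeeping."""

    errors_ms: np.ndarray
    n_matched: int
    n_unmatched_truth: int
    n_unmatched_detected: int
    labels: dict = field(default_factory=dict)

    @property
    def mean(self) -> float:
        return float(np.mean(self.errors_ms)) if self.n_matched else float("nan")

    @property
    def sd(self) -> float:
        return float(np.std(self.errors_ms)) if self.n_matched else float("nan")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"error_ms": self.errors_ms})
        for k, v in self.labels.items():
            df[k] = v
        return df


@dataclass
class CVPlan:
    """Subject-wise train/validation/test assignments for k folds (ratio 3:1:1)."""

    folds: list[dict[str, list]]
    seed: int

    def __post_init__(self) -> None:
        for f, fold in enumerate(self.folds):
            groups = [set(fold["train"]), set(fold["validation"]), set(fold["test"])]
            total = sum(len(g) for g in groups)
            if len(set().union(*groups)) != total:
                raise ValueError(f"fold {f}: train/validation/test groups overlap")


def dominant_period(series: np.ndarray, min_lag: int = 3) -> float | None:
    """Dominant period of a roughly periodic series, in samples, via autocorrelation.

    Returns None when no autocorrelation peak exists (aperiodic or flat input).
    """
    x = np.asarray(series, dtype=float)
    x = x - x.mean()
    if x.size < 2 * min_lag or np.allclose(x, 0.0):
        return None
    acf = np.correlate(x, x, mode="full")[x.size - 1 :]
    acf /= acf[0]
    peaks, _ = find_peaks(acf[min_lag:], height=0.1)
    if peaks.size == 0:
        return None
    return float(peaks[0] + min_lag)


def detect_events_ground_truth(
    r_x: np.ndarray,
    sampling_rate: float,
    side: str = "left",
    prominence_frac: float = 0.25,
) -> EventSet:
    """Kinematic ground-truth events from the relative forward position.

    Heel strikes are positive peaks of ``r_x`` (the foot's horizontal velocity
    changes + -> -), toe-offs are negative peaks.  Candidate extrema closer
    than half the dominant period are suppressed, and peaks must rise at least
    ``prominence_frac`` of the series' peak-to-peak range.
    """
    x = np.asarray(r_x, dtype=float)
    period = dominant_period(x)
    if period is None:
        return EventSet(
            heel_strike_idx=[], heel_strike_times=[], toe_off_idx=[], toe_off_times=[],
            side=side, source="ground_truth",
        )
    distance = max(1, int(round(0.5 * period)))
    prominence = prominence_frac * float(np.ptp(x))
    hs_idx, _ = find_peaks(x, distance=distance, prominence=prominence)
    to_idx, _ = find_peaks(-x, distance=distance, prominence=prominence)
    return EventSet(
        heel_strike_idx=hs_idx,
        heel_strike_times=hs_idx / sampling_rate,
        toe_off_idx=to_idx,
        toe_off_times=to_idx / sampling_rate,
        side=side,
        source="ground_truth",
    )


def _phase_at_samples(
    angles: np.ndarray, end_indices: np.ndarray, sample_idx: np.ndarray
) -> np.ndarray:
    """Model phase aligned to given sample indices; events before the first
    emitted phase are dropped."""
    pos = np.searchsorted(end_indices, sample_idx)
    pos_c = np.minimum(pos, end_indices.size - 1)
    keep = end_indices[pos_c] == sample_idx
    return angles[pos_c[keep]], keep


def _calibration_from_phases(
    hs_phases: np.ndarray,
    to_phases: np.ndarray,
    nu: np.ndarray,
    min_resultant: float = 0.1,
) -> PhaseCalibration:
    """Build a calibration from pooled event phases and phase steps."""
    refs = {}
    for kind, phases in (("hs", hs_phases), ("to", to_phases)):
        if phases.size < 2:
            raise CalibrationError(f"need >= 2 {kind} events with aligned phase samples")
        length, _ = resultant(phases)
        if length < min_resultant:
            raise CalibrationError(
                f"{kind} event phases are too dispersed (resultant {length:.3f})"
            )
        refs[kind] = circular_mean(phases)
    direction = 1 if np.median(nu) >= 0 else -1
    return PhaseCalibration(ref_phase_hs=refs["hs"], ref_phase_to=refs["to"], direction=direction)


def calibrate_event_phases(
    angles: np.ndarray,
    end_indices: np.ndarray,
    truth: EventSet,
    min_resultant: float = 0.1,
) -> PhaseCalibration:
    """Reference phases = circular means of model phase at ground-truth events.

    The progression direction is the sign of the median step between
    consecutive emitted phases.  Event phases whose mean resultant length
    falls below ``min_resultant`` (e.g. antipodal phases) are rejected: a
    circular mean is then meaningless.
    """
    angles = np.asarray(angles, dtype=float)
    end_indices = np.asarray(end_indices, dtype=int)
    hs, _ = _phase_at_samples(angles, end_indices, np.asarray(truth.heel_strike_idx, dtype=int))
    to, _ = _phase_at_samples(angles, end_indices, np.asarray(truth.toe_off_idx, dtype=int))
    nu = wrap_angle(np.diff(angles))
    return _calibration_from_phases(hs, to, nu, min_resultant=min_resultant)


def _crossings(
    angles: np.ndarray, ref: float, direction: int, refractory: int
) -> np.ndarray:
    """Causal reference-phase crossings with a refractory interval, as indices
    into ``angles``."""
    d = wrap_angle(direction * (angles - ref))
    out = []
    last = -np.inf
    for i in range(1, d.size):
        step = wrap_angle(d[i] - d[i - 1])
        if d[i - 1] < 0.0 <= d[i] and 0 < step < np.pi / 2 and i - last >= refractory:
            out.append(i)
            last = i
    return np.asarray(out, dtype=int)


def detect_events_from_phase(
    angles: np.ndarray,
    end_indices: np.ndarray,
    calibration: PhaseCalibration,
    sampling_rate: float,
    side: str = "left",
) -> EventSet:
    """Declare an event whenever the model phase crosses a reference phase.

    Detection is causal (each decision uses samples up to the current one) and
    at most one detection per reference per cycle is allowed, enforced by a
    refractory interval of half the dominant period of the phase progression.
    """
    angles = np.asarray(angles, dtype=float)
    end_indices = np.asarray(end_indices, dtype=int)
    nu = np.abs(wrap_angle(np.diff(angles)))
    med = float(np.median(nu)) if nu.size else 0.0
    period = (2.0 * np.pi / med) if med > 0 else angles.size
    refractory = max(1, int(round(0.5 * period)))
    sets = {}
    for kind, ref in (("hs", calibration.ref_phase_hs), ("to", calibration.ref_phase_to)):
        pos = _crossings(angles, ref, calibration.direction, refractory)
        sets[kind] = end_indices[pos] if pos.size else np.empty(0, dtype=int)
    return EventSet(
        heel_strike_idx=sets["hs"],
        heel_strike_times=sets["hs"] / sampling_rate,
        toe_off_idx=sets["to"],
        toe_off_times=sets["to"] / sampling_rate,
        side=side,
        source="phase_detected",
    )


def _match_errors(
    truth_t: np.ndarray, det_t: np.ndarray, max_gap_s: float
) -> tuple[np.ndarray, int, int]:
    """Nearest-neighbour matching of truth to detections within ``max_gap_s``."""
    if truth_t.size == 0 or det_t.size == 0:
        return np.empty(0), truth_t.size, det_t.size
    errors = []
    used = np.zeros(det_t.size, dtype=bool)
    for t in truth_t:
        j = int(np.argmin(np.abs(det_t - t)))
        if not used[j] and abs(det_t[j] - t) <= max_gap_s:
            used[j] = True
            errors.append(abs(det_t[j] - t))
    errors = np.asarray(errors)
    return errors, truth_t.size - errors.size, int((~used).sum())


def compute_time_errors(
    detected: EventSet,
    truth: EventSet,
    sampling_rate: float,
    labels: dict | None = None,
) -> dict[str, TimeErrorReport]:
    """Absolute time errors (ms) per event type, matched within half a period.

    The matching window is half the dominant event period, estimated from the
    median inter-event interval of the ground truth.  Unmatched events are
    counted but excluded from the mean/sd.
    """
    out = {}
    for kind in ("heel_strike", "toe_off"):
        truth_t = truth.events(kind)
        det_t = detected.events(kind)
        gaps = np.diff(truth_t)
        max_gap = 0.5 * float(np.median(gaps)) if gaps.size else np.inf
        err_s, n_unm_truth, n_unm_det = _match_errors(truth_t, det_t, max_gap)
        out[kind] = TimeErrorReport(
            errors_ms=err_s * 1000.0,
            n_matched=err_s.size,
            n_unmatched_truth=n_unm_truth,
            n_unmatched_detected=n_unm_det,
            labels={"event_type": kind, "side": truth.side, **(labels or {})},
        )
    return out


def crossval_split(
    subject_ids: Sequence,
    k: int = 4,
    ratio: tuple[int, int, int] = (3, 1, 1),
    seed: int = 0,
) -> CVPlan:
    """Seeded subject-wise k-fold split with a train:validation:test ratio.

    Subjects are shuffled once and cut into ``sum(ratio)/min(ratio)`` blocks
    (5 for 3:1:1, nearest-integer sizes when not divisible); fold f uses block
    f as test, the next block as validation, and the rest for training, so
    test groups rotate across folds.
    """
    ids = list(subject_ids)
    n_blocks = sum(ratio) // min(ratio)
    if k > n_blocks:
        raise ValueError(f"at most {n_blocks} folds possible with ratio {ratio}")
    if len(ids) < n_blocks:
        raise ValueError(f"need at least {n_blocks} subjects")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    bounds = np.linspace(0, len(ids), n_blocks + 1).round().astype(int)
    blocks = [order[bounds[i] : bounds[i + 1]] for i in range(n_blocks)]
    folds = []
    for f in range(k):
        test = blocks[f % n_blocks]
        val = blocks[(f + 1) % n_blocks]
        train = [s for b in range(n_blocks) if b not in (f % n_blocks, (f + 1) % n_blocks) for s in blocks[b]]
        folds.append({"train": train, "validation": val, "test": test})
    return CVPlan(folds=folds, seed=seed)
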