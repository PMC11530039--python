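"""End-to-end experiment harness: cohorts, training, calibration, scoring.

Mirrors the study design the detector is meant for: train per-side phase
networks on a treadmill-like cohort, calibrate constant reference phases at
heel strike and toe-off on the training subjects, then detect events on
held-out subjects (same condition or overground-like transfer) and report
absolute time errors in milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circular import circular_correlation, wrap_angle
from .events import (
    PhaseCalibration,
    TimeErrorReport,
    _calibration_from_phases,
    compute_time_errors,
    detect_events_from_phase,
)
from .model import NetworkParams, PhaseStream, infer_stream
from .objective import LossWeights, TrainConfig, train
from .preprocess import (
    StandardizationParams,
    WindowPairBatch,
    build_window_pairs,
    fit_standardization,
    relative_positions,
    standardize,
)
from .synth import SIDES, GaitSimConfig, SimulatedWalk, simulate_walk

__all__ = [
    "SideModel",
    "ExperimentResult",
    "simulate_cohort",
    "train_side",
    "calibrate_side",
    "infer_walk",
    "evaluate_walk",
    "run_experiment",
    "transfer_evaluation",
    "speed_condition_comparison",
]


@dataclass
class SideModel:
    """A trained phase detector for one side: feature statistics + network."""

    side: str
    std_params: StandardizationParams
    net: NetworkParams
    calibration: PhaseCalibration | None = None


@dataclass
class ExperimentResult:
    """Trained side models plus per-subject evaluation rows."""

    models: dict[str, SideModel]
    rows: pd.DataFrame  # one row per matched event: subject, side, event_type, condition, error_ms
    metrics: pd.DataFrame  # one row per (subject, side): circcorr, band fraction, counts
    train_subjects: list
    test_subjects: list
    cadences: dict[int, float] = field(default_factory=dict)


def simulate_cohort(
    n_subjects: int,
    seed: int,
    cadence_range: tuple[float, float] = (0.7, 1.3),
    duration: float = 30.0,
    noise_sd: float = 0.5,
    progression_speed: float = 0.0,
    sampling_rate: float = 150.0,
    cadences: np.ndarray | None = None,
) -> dict[int, SimulatedWalk]:
    """Simulate ``n_subjects`` walks with per-subject cadence drawn uniformly.

    Passing ``cadences`` explicitly (e.g. to match a treadmill cohort's
    cadences in an overground transfer run) overrides the random draw; walk
    seeds still derive from ``seed``.
    """
    rng = np.random.default_rng(seed)
    drawn = rng.uniform(*cadence_range, size=n_subjects)
    if cadences is not None:
        drawn = np.asarray(cadences, dtype=float)
    walks = {}
    for s in range(n_subjects):
        walks[s] = simulate_walk(
            GaitSimConfig(
                sampling_rate=sampling_rate,
                duration=duration,
                cadence=float(drawn[s]),
                noise_sd=noise_sd,
                progression_speed=progression_speed,
                seed=int(rng.integers(2**31)),
            )
        )
    return walks


def _side_pairs(
    walks: list[SimulatedWalk], side: str
) -> tuple[StandardizationParams, WindowPairBatch]:
    rels = [relative_positions(w.trajectory[side]) for w in walks]
    std_params = fit_standardization(rels)
    pooled = WindowPairBatch.concatenate(
        [build_window_pairs(standardize(r, std_params), std_params) for r in rels]
    )
    return std_params, pooled


def train_side(
    walks: list[SimulatedWalk],
    side: str,
    config: TrainConfig,
    weights: LossWeights = LossWeights(),
) -> SideModel:
    """Fit standardization on the training walks of one side and train its network."""
    std_params, pooled = _side_pairs(walks, side)
    net, _ = train(pooled, config, weights)
    return SideModel(side=side, std_params=std_params, net=net)


def infer_walk(model: SideModel, walk: SimulatedWalk) -> PhaseStream:
    """Causal phase stream of one walk's trajectory for this model's side."""
    rel = relative_positions(walk.trajectory[model.side])
    return infer_stream(model.net, standardize(rel, model.std_params), model.std_params)


def calibrate_side(model: SideModel, walks: list[SimulatedWalk]) -> PhaseCalibration:
    """Pool model phases at ground-truth events across training walks.

    Reference phases are circular means over all training subjects' events;
    the progression direction is the sign of the median phase step pooled
    over all training streams.
    """
    hs_phases, to_phases, nus = [], [], []
    for walk in walks:
        stream = infer_walk(model, walk)
        truth = walk.true_events[model.side]
        offset = stream.end_indices[0]
        for collect, idx in ((hs_phases, truth.heel_strike_idx), (to_phases, truth.toe_off_idx)):
            valid = idx[idx >= offset]
            collect.append(stream.angles[valid - offset])
        nus.append(wrap_angle(np.diff(stream.angles)))
    calibration = _calibration_from_phases(
        np.concatenate(hs_phases), np.concatenate(to_phases), np.concatenate(nus)
    )
    model.calibration = calibration
    return calibration


def phase_agreement(
    stream: PhaseStream, true_phase: np.ndarray, weights: LossWeights, direction: int
) -> dict[str, float]:
    """Direction-aligned agreement between a model stream and the true phase.

    Returns the Fisher-Lee circular correlation after reflecting clockwise
    models (rotation alignment is implicit in the statistic) and the
    fraction of consecutive phase steps inside the permitted progression
    band (a, b + 2 deg].
    """
    truth = true_phase[stream.end_indices]
    angles = direction * stream.angles
    nu = wrap_angle(np.diff(angles))
    band = float(np.mean((nu > weights.a) & (nu <= weights.b + 2.0 * np.pi / 180.0)))
    return {
        "circcorr": circular_correlation(angles, truth),
        "band_frac": band,
        "n_steps": int(nu.size),
    }


def evaluate_walk(
    model: SideModel,
    walk: SimulatedWalk,
    labels: dict | None = None,
) -> dict[str, TimeErrorReport]:
    """Detect events via calibrated phase crossings and score them in ms."""
    if model.calibration is None:
        raise ValueError("model must be calibrated before evaluation")
    stream = infer_walk(model, walk)
    fs = walk.config.sampling_rate
    detected = detect_events_from_phase(
        stream.angles, stream.end_indices, model.calibration, fs, side=model.side
    )
    truth = walk.true_events[model.side]
    return compute_time_errors(detected, truth, fs, labels=labels)


def _collect_rows(
    reports: dict[str, TimeErrorReport], rows: list[dict]
) -> None:
    for report in reports.values():
        frame = report.to_frame()
        rows.extend(frame.to_dict("records"))


def run_experiment(
    n_subjects: int = 20,
    n_train: int = 12,
    n_test: int = 4,
    seed: int = 0,
    train_config: TrainConfig | None = None,
    weights: LossWeights = LossWeights(),
    cohort_kwargs: dict | None = None,
    condition: str = "treadmill",
) -> ExperimentResult:
    """Train per-side models on a synthetic cohort and score held-out subjects.

    Subjects are shuffled by ``seed``; the first ``n_train`` train the
    networks and calibration, the last ``n_test`` are held out (any
    remainder plays the role of a validation group and is left unused
    here).  Returns matched-event rows and per-subject phase-agreement
    metrics.
    """
    if train_config is None:
        train_config = TrainConfig(iterations=2000, batch_size=1024, seed=seed)
    walks = simulate_cohort(n_subjects, seed=seed, **(cohort_kwargs or {}))
    rng = np.random.default_rng(seed + 1)
    order = rng.permutation(n_subjects)
    train_ids = [int(s) for s in order[:n_train]]
    test_ids = [int(s) for s in order[n_subjects - n_test :]]
    train_walks = [walks[s] for s in train_ids]

    models: dict[str, SideModel] = {}
    for side in SIDES:
        model = train_side(train_walks, side, train_config, weights)
        calibrate_side(model, train_walks)
        models[side] = model

    rows: list[dict] = []
    metric_rows: list[dict] = []
    for s in test_ids:
        walk = walks[s]
        for side in SIDES:
            model = models[side]
            stream = infer_walk(model, walk)
            agree = phase_agreement(
                stream, walk.true_phase[side], weights, model.calibration.direction
            )
            metric_rows.append({"subject": s, "side": side, "condition": condition, **agree})
            reports = evaluate_walk(
                model, walk, labels={"subject": s, "condition": condition}
            )
            _collect_rows(reports, rows)
    return ExperimentResult(
        models=models,
        rows=pd.DataFrame(rows),
        metrics=pd.DataFrame(metric_rows),
        train_subjects=train_ids,
        test_subjects=test_ids,
        cadences={s: float(w.config.cadence) for s, w in walks.items()},
    )


def transfer_evaluation(
    result: ExperimentResult,
    seed: int,
    progression_speed: float = 1300.0,
    cadences: np.ndarray | None = None,
    n_subjects: int | None = None,
    cohort_kwargs: dict | None = None,
    condition: str = "overground",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Evaluate already-trained models on overground-like walks.

    The iliac crest now progresses at ``progression_speed`` mm/s; relative
    coordinates remove progression, so a model trained on treadmill-like
    data should transfer.  Returns (rows, metrics) like ``run_experiment``.
    """
    n = n_subjects if n_subjects is not None else len(result.test_subjects)
    walks = simulate_cohort(
        n,
        seed=seed,
        progression_speed=progression_speed,
        cadences=cadences,
        **(cohort_kwargs or {}),
    )
    rows: list[dict] = []
    metric_rows: list[dict] = []
    for s, walk in walks.items():
        for side in SIDES:
            model = result.models[side]
            stream = infer_walk(model, walk)
            agree = phase_agreement(
                stream, walk.true_phase[side], LossWeights(), model.calibration.direction
            )
            metric_rows.append({"subject": s, "side": side, "condition": condition, **agree})
            reports = evaluate_walk(model, walk, labels={"subject": s, "condition": condition})
            _collect_rows(reports, rows)
    return pd.DataFrame(rows), pd.DataFrame(metric_rows)


def speed_condition_comparison(
    seed: int,
    conditions: dict[str, tuple[float, float]] | None = None,
    n_train_per_condition: int = 4,
    n_test_per_condition: int = 2,
    train_config: TrainConfig | None = None,
    weights: LossWeights = LossWeights(),
    cohort_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Speed-specific versus combined-speed training, as mean error per cell.

    Trains one model per speed condition (cadence band) and one on the
    pooled conditions, then evaluates every model on each condition's
    held-out subjects.  Returns a tidy frame with columns (model, condition,
    mean_error_ms, n_events).
    """
    if conditions is None:
        conditions = {"slow": (0.7, 0.9), "comfortable": (0.95, 1.05), "fast": (1.1, 1.3)}
    if train_config is None:
        train_config = TrainConfig(iterations=1000, batch_size=1024, seed=seed)
    rng = np.random.default_rng(seed)
    cohorts = {
        name: simulate_cohort(
            n_train_per_condition + n_test_per_condition,
            seed=int(rng.integers(2**31)),
            cadence_range=band,
            **(cohort_kwargs or {}),
        )
        for name, band in conditions.items()
    }
    split = {
        name: (
            [w for s, w in walks.items() if s < n_train_per_condition],
            [w for s, w in walks.items() if s >= n_train_per_condition],
        )
        for name, walks in cohorts.items()
    }
    model_sets: dict[str, dict[str, SideModel]] = {}
    for name, (train_walks, _) in split.items():
        models = {}
        for side in SIDES:
            m = train_side(train_walks, side, train_config, weights)
            calibrate_side(m, train_walks)
            models[side] = m
        model_sets[name] = models
    combined_walks = [w for name in conditions for w in split[name][0]]
    combined = {}
    for side in SIDES:
        m = train_side(combined_walks, side, train_config, weights)
        calibrate_side(m, combined_walks)
        combined[side] = m
    model_sets["combined"] = combined

    cells = []
    for model_name, models in model_sets.items():
        for cond_name in conditions:
            errors = []
            for walk in split[cond_name][1]:
                for side in SIDES:
                    reports = evaluate_walk(models[side], walk)
                    for rep in reports.values():
                        errors.append(rep.errors_ms)
            errors = np.concatenate(errors) if errors else np.empty(0)
            cells.append(
                {
                    "model": model_name,
                    "condition": cond_name,
                    "mean_error_ms": float(errors.mean()) if errors.size else float("nan"),
                    "sd_error_ms": float(errors.std()) if errors.size else float("nan"),
                    "n_events": int(errors.size),
                }
            )
    return pd.DataFrame(cells)
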