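"""Feature pipeline: relative ankle positions, standardization, heading slopes,
and paired 7-sample feature windows.

The detector never sees raw marker coordinates.  Each side's ankle trajectory
is first expressed relative to the iliac crest (x) and to the lab floor (y),
standardized with statistics fitted on the *training* pool only, and then cut
into overlapping 7-sample windows.  A window contributes four features per
sample — standardized x, standardized y, and a heading direction per axis,
the OLS slope of the 7 samples ending at that sample — for 28 network
inputs.  Because each sample's heading looks back 6 further samples, the
window ending at sample ``i`` needs samples ``i-12 .. i``: the first feature
window of a stream requires 13 samples, and each subsequent one arrives with
every new sample (stride 1).  Training uses *pairs* of consecutive windows
(ending at samples ``i-1`` and ``i``), whose phase outputs should advance by
roughly one sample's worth of gait cycle.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

WINDOW = 7  # samples per window (m = 6)
WINDOW_SPAN = 2 * WINDOW - 1  # 13: samples needed for one window incl. headings
N_FEATURES = 4 * WINDOW  # 28 network inputs

# OLS slope of 7 equally spaced points: dot with (k - 3)/28, k = 0..6
_SLOPE_KERNEL = (np.arange(WINDOW) - 3.0) / 28.0


class MalformedInputError(ValueError):
    """Input series are inconsistent (length mismatch, non-uniform time base)."""


class DegenerateDataError(ValueError):
    """Training pool has zero variance in some feature dimension."""


@dataclass
class MarkerTrajectory:
    """Planar marker time series for one side: ankle (x, y) and iliac crest x.

    Units are millimetres and seconds; sampling must be uniform.
    """

    time: np.ndarray
    x_ankle: np.ndarray
    y_ankle: np.ndarray
    x_iliac: np.ndarray
    side: str
    sampling_rate: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.x_ankle = np.asarray(self.x_ankle, dtype=float)
        self.y_ankle = np.asarray(self.y_ankle, dtype=float)
        self.x_iliac = np.asarray(self.x_iliac, dtype=float)
        n = self.time.size
        for name in ("x_ankle", "y_ankle", "x_iliac"):
            if getattr(self, name).size != n:
                raise MalformedInputError(
                    f"{name} has {getattr(self, name).size} samples, time has {n}"
                )
        if n >= 2:
            dt = np.diff(self.time)
            if np.max(np.abs(dt - 1.0 / self.sampling_rate)) >= 1e-6:
                raise MalformedInputError(
                    "time stamps are not uniform at the declared sampling rate"
                )

    def __len__(self) -> int:
        return self.time.size


@dataclass
class RelativeSeries:
    """Ankle position relative to the iliac crest (x) and floor (y), in mm."""

    r_x: np.ndarray
    r_y: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.r_x = np.asarray(self.r_x, dtype=float)
        self.r_y = np.asarray(self.r_y, dtype=float)
        if self.r_x.size != self.r_y.size:
            raise MalformedInputError("r_x and r_y differ in length")

    def __len__(self) -> int:
        return self.r_x.size


@dataclass
class StandardizationParams:
    """Training-pool statistics applied unchanged to validation/test data.

    Position statistics are the pooled mean and population (1/n) standard
    deviation of the relative positions; heading statistics are the same for
    the per-window OLS slopes of the *standardized* positions.
    """

    mean_x: float
    mean_y: float
    sd_x: float
    sd_y: float
    heading_mean_x: float
    heading_mean_y: float
    heading_sd_x: float
    heading_sd_y: float

    def __post_init__(self) -> None:
        for name in ("sd_x", "sd_y", "heading_sd_x", "heading_sd_y"):
            if not getattr(self, name) > 0:
                raise DegenerateDataError(f"{name} must be positive")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "StandardizationParams":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class StandardizedSeries:
    """Standardized relative positions of one trajectory."""

    x: np.ndarray
    y: np.ndarray
    sampling_rate: float

    def __len__(self) -> int:
        return self.x.size


@dataclass
class FeatureWindow:
    """One 7-sample window: 4 features per sample, flattened to 28 inputs."""

    x: np.ndarray
    y: np.ndarray
    h_x: np.ndarray
    h_y: np.ndarray

    def __post_init__(self) -> None:
        for name in ("x", "y", "h_x", "h_y"):
            if np.asarray(getattr(self, name)).size != WINDOW:
                raise MalformedInputError(f"{name} must have exactly {WINDOW} samples")

    def flatten(self) -> np.ndarray:
        return np.concatenate([self.x, self.y, self.h_x, self.h_y])


@dataclass
class FeatureWindowPair:
    """Two consecutive windows sharing one sample, ending at ``end_sample_index``."""

    previous: FeatureWindow
    current: FeatureWindow
    end_sample_index: int


@dataclass
class WindowPairBatch:
    """Vectorized window pairs: rows of ``prev``/``curr`` are flattened windows.

    ``end_indices[k]`` is the 0-based index of the last sample of the k-th
    current window in the source series it came from; batches pooled across
    several series keep per-row indices but drop the series identity.
    """

    prev: np.ndarray  # (N, 28)
    curr: np.ndarray  # (N, 28)
    end_indices: np.ndarray  # (N,)

    def __len__(self) -> int:
        return self.prev.shape[0]

    def __getitem__(self, k: int) -> FeatureWindowPair:
        return FeatureWindowPair(
            previous=_unflatten_window(self.prev[k]),
            current=_unflatten_window(self.curr[k]),
            end_sample_index=int(self.end_indices[k]),
        )

    @classmethod
    def concatenate(cls, batches: Sequence["WindowPairBatch"]) -> "WindowPairBatch":
        return cls(
            prev=np.concatenate([b.prev for b in batches], axis=0),
            curr=np.concatenate([b.curr for b in batches], axis=0),
            end_indices=np.concatenate([b.end_indices for b in batches]),
        )


def _unflatten_window(row: np.ndarray) -> FeatureWindow:
    return FeatureWindow(
        x=row[0:7].copy(), y=row[7:14].copy(), h_x=row[14:21].copy(), h_y=row[21:28].copy()
    )


def relative_positions(traj: MarkerTrajectory) -> RelativeSeries:
    """Ankle position relative to the body: R_x = x_ankle − x_iliac, R_y = y_ankle.

    Subtracting the iliac-crest x removes whole-body progression, so treadmill
    and overground walks with the same cadence produce the same R_x.
    """
    return RelativeSeries(
        r_x=traj.x_ankle - traj.x_iliac,
        r_y=traj.y_ankle.copy(),
        sampling_rate=traj.sampling_rate,
    )


def heading_direction(window_values: np.ndarray, sampling_rate: float | None = None) -> float:
    """OLS slope of 7 consecutive values against their sample index.

    The abscissa is the sample index, not seconds: any fixed time scale is a
    pure scale factor that the subsequent heading normalization absorbs.  The
    ``sampling_rate`` argument is accepted for signature symmetry with the
    rest of the pipeline and is not used.
    """
    v = np.asarray(window_values, dtype=float)
    if v.size != WINDOW:
        raise MalformedInputError(f"heading window must have exactly {WINDOW} values, got {v.size}")
    return float(_SLOPE_KERNEL @ v)


def _sliding_slopes(values: np.ndarray) -> np.ndarray:
    """Slope of every 7-sample window; entry j is the window ending at sample j+6."""
    if values.size < WINDOW:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(values, WINDOW)
    return windows @ _SLOPE_KERNEL


def fit_standardization(train: Iterable[RelativeSeries]) -> StandardizationParams:
    """Fit pooled training statistics for positions, then for heading slopes.

    Heading slopes are computed on the *standardized* positions (so heading
    statistics depend on the position statistics fitted first).  Standard
    deviations use the population (1/n) form: re-standardizing the pool with
    its own parameters then gives mean 0 and sd exactly 1.
    """
    series = list(train)
    if not series:
        raise DegenerateDataError("empty training collection")
    pooled_x = np.concatenate([s.r_x for s in series])
    pooled_y = np.concatenate([s.r_y for s in series])
    if pooled_x.size < 2:
        raise DegenerateDataError("need at least 2 pooled training samples")
    mean_x, mean_y = float(pooled_x.mean()), float(pooled_y.mean())
    sd_x, sd_y = float(pooled_x.std()), float(pooled_y.std())
    if sd_x == 0.0 or sd_y == 0.0:
        raise DegenerateDataError("constant training series: zero standard deviation")

    slopes_x = np.concatenate([_sliding_slopes((s.r_x - mean_x) / sd_x) for s in series])
    slopes_y = np.concatenate([_sliding_slopes((s.r_y - mean_y) / sd_y) for s in series])
    if slopes_x.size == 0:
        raise DegenerateDataError(f"no series long enough ({WINDOW} samples) for heading slopes")
    h_sd_x, h_sd_y = float(slopes_x.std()), float(slopes_y.std())
    if h_sd_x == 0.0 or h_sd_y == 0.0:
        raise DegenerateDataError("constant heading slopes: zero standard deviation")
    return StandardizationParams(
        mean_x=mean_x,
        mean_y=mean_y,
        sd_x=sd_x,
        sd_y=sd_y,
        heading_mean_x=float(slopes_x.mean()),
        heading_mean_y=float(slopes_y.mean()),
        heading_sd_x=h_sd_x,
        heading_sd_y=h_sd_y,
    )


def standardize(series: RelativeSeries, params: StandardizationParams) -> StandardizedSeries:
    """Apply training-set centering/scaling to one relative series."""
    return StandardizedSeries(
        x=(series.r_x - params.mean_x) / params.sd_x,
        y=(series.r_y - params.mean_y) / params.sd_y,
        sampling_rate=series.sampling_rate,
    )


def window_features(std: StandardizedSeries, params: StandardizationParams) -> tuple[np.ndarray, np.ndarray]:
    """Flattened 28-feature rows for every feature window of a series.

    Returns ``(features, end_indices)`` where row k is the window ending at
    sample ``end_indices[k]`` (= k + 12).  A row holds the standardized x and
    y at samples ``i-6 .. i`` and, per axis, the normalized causal heading
    slope at each of those samples (the OLS slope of the 7 samples ending
    there), so the row depends on samples ``i-12 .. i`` only.
    """
    n = len(std)
    if n < WINDOW_SPAN:
        return np.empty((0, N_FEATURES)), np.empty(0, dtype=int)
    hx = np.lib.stride_tricks.sliding_window_view(std.x, WINDOW) @ _SLOPE_KERNEL
    hy = np.lib.stride_tricks.sliding_window_view(std.y, WINDOW) @ _SLOPE_KERNEL
    hx = (hx - params.heading_mean_x) / params.heading_sd_x
    hy = (hy - params.heading_mean_y) / params.heading_sd_y
    first = WINDOW_SPAN - WINDOW  # position windows start once headings exist
    wx = np.lib.stride_tricks.sliding_window_view(std.x[first:], WINDOW)
    wy = np.lib.stride_tricks.sliding_window_view(std.y[first:], WINDOW)
    whx = np.lib.stride_tricks.sliding_window_view(hx, WINDOW)
    why = np.lib.stride_tricks.sliding_window_view(hy, WINDOW)
    feats = np.concatenate([wx, wy, whx, why], axis=1)
    return feats, np.arange(WINDOW_SPAN - 1, n)


def build_window_pairs(std: StandardizedSeries, params: StandardizationParams) -> WindowPairBatch:
    """All pairs of consecutive feature windows of a series, stride 1.

    Pair k joins the windows ending at samples ``k+12`` (previous) and
    ``k+13`` (current); the phase-progression penalty compares their two
    phase outputs.  A series shorter than 14 samples yields an empty batch
    (no error), since no two consecutive windows exist.
    """
    feats, ends = window_features(std, params)
    if feats.shape[0] < 2:
        logger.warning(
            "series of %d samples yields %d feature windows: no window pairs",
            len(std), feats.shape[0],
        )
        return WindowPairBatch(
            prev=np.empty((0, N_FEATURES)), curr=np.empty((0, N_FEATURES)), end_indices=np.empty(0, dtype=int)
        )
    return WindowPairBatch(prev=feats[:-1], curr=feats[1:], end_indices=ends[1:])


def read_trajectory_csv(path: str | Path) -> dict[str, MarkerTrajectory]:
    """Read the simulator's CSV dialect into one trajectory per side.

    Columns: time_s, side, x_ankle_mm, y_ankle_mm, x_iliac_mm.  The time
    column is authoritative for the sampling rate.
    """
    df = pd.read_csv(path)
    out: dict[str, MarkerTrajectory] = {}
    for side, grp in df.groupby("side"):
        grp = grp.sort_values("time_s")
        t = grp["time_s"].to_numpy()
        if t.size < 2:
            raise MalformedInputError(f"side {side!r} has fewer than 2 samples")
        fs = 1.0 / float(np.median(np.diff(t)))
        out[str(side)] = MarkerTrajectory(
            time=t,
            x_ankle=grp["x_ankle_mm"].to_numpy(),
            y_ankle=grp["y_ankle_mm"].to_numpy(),
            x_iliac=grp["x_iliac_mm"].to_numpy(),
            side=str(side),
            sampling_rate=fs,
        )
    return out
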