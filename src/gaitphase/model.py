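"""The phase network: 28 window features -> 2-D pre-phase -> unit-circle phase.

Architecture: six affine layers 28->25->25->25->25->25->2 with a hyperbolic
tangent after the first four hidden layers and identity activations from the
fifth hidden layer into the 2-node pre-phase output (3377 scalar parameters).
The pre-phase vector V is Euclidean-normalized onto the unit circle; its
angle is the continuous gait phase and its magnitude is the distance from
the singular configuration V = 0 that the training loss penalizes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .preprocess import N_FEATURES, FeatureWindow, StandardizationParams, StandardizedSeries, window_features

__all__ = [
    "LAYER_SIZES",
    "N_PARAMS",
    "NetworkParams",
    "PhaseOutput",
    "PhaseStream",
    "SingularityError",
    "init_params",
    "prephase",
    "forward",
    "to_phase",
    "infer_stream",
]

LAYER_SIZES = (N_FEATURES, 25, 25, 25, 25, 25, 2)
N_TANH_LAYERS = 4  # tanh after layers 1-4; layers 5 and 6 are affine
N_PARAMS = sum((LAYER_SIZES[i] + 1) * LAYER_SIZES[i + 1] for i in range(len(LAYER_SIZES) - 1))

SINGULARITY_GUARD = 1e-12


class SingularityError(ValueError):
    """Pre-phase output is (numerically) at the origin: phase is undefined."""


@dataclass
class NetworkParams:
    """Ordered affine layers (weight matrix of shape (fan_in, fan_out), bias)."""

    layers: list[tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        expected = list(zip(LAYER_SIZES[:-1], LAYER_SIZES[1:]))
        if len(self.layers) != len(expected):
            raise ValueError(f"expected {len(expected)} layers, got {len(self.layers)}")
        for k, ((w, b), (fan_in, fan_out)) in enumerate(zip(self.layers, expected)):
            if w.shape != (fan_in, fan_out) or b.shape != (fan_out,):
                raise ValueError(
                    f"layer {k}: expected shapes {(fan_in, fan_out)}/{(fan_out,)}, "
                    f"got {w.shape}/{b.shape}"
                )
            if not (np.isfinite(w).all() and np.isfinite(b).all()):
                raise ValueError(f"layer {k} contains non-finite values")

    @property
    def n_params(self) -> int:
        return sum(w.size + b.size for w, b in self.layers)

    def flatten(self) -> np.ndarray:
        return np.concatenate([np.concatenate([w.ravel(), b]) for w, b in self.layers])

    @classmethod
    def from_flat(cls, theta: np.ndarray) -> "NetworkParams":
        layers = []
        k = 0
        for fan_in, fan_out in zip(LAYER_SIZES[:-1], LAYER_SIZES[1:]):
            w = theta[k : k + fan_in * fan_out].reshape(fan_in, fan_out).copy()
            k += fan_in * fan_out
            b = theta[k : k + fan_out].copy()
            k += fan_out
            layers.append((w, b))
        return cls(layers=layers)

    def save(self, path: str | Path, meta: dict | None = None) -> None:
        """Write weights to an .npz container with a JSON sidecar of shapes."""
        path = Path(path)
        arrays = {}
        for k, (w, b) in enumerate(self.layers):
            arrays[f"w{k}"] = w
            arrays[f"b{k}"] = b
        np.savez(path, **arrays)
        sidecar = {
            "layer_sizes": list(LAYER_SIZES),
            "n_params": self.n_params,
            **(meta or {}),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "NetworkParams":
        with np.load(Path(path)) as data:
            n_layers = len(LAYER_SIZES) - 1
            layers = [(data[f"w{k}"], data[f"b{k}"]) for k in range(n_layers)]
        return cls(layers=layers)


@dataclass
class PhaseOutput:
    """A single phase estimate: point on the unit circle plus raw magnitude."""

    unit_vector: tuple[float, float]
    angle: float
    prephase_magnitude: float


@dataclass
class PhaseStream:
    """Causal phase estimates aligned to the end sample of each input window."""

    angles: np.ndarray
    unit_vectors: np.ndarray  # (n, 2)
    magnitudes: np.ndarray
    end_indices: np.ndarray
    sampling_rate: float

    def __len__(self) -> int:
        return self.angles.size


def init_params(seed: int) -> NetworkParams:
    """Seeded initialization: scaled-uniform weights, zero biases.

    Weights are drawn U(-1/sqrt(fan_in), 1/sqrt(fan_in)) per layer; biases
    start at zero so the initial network is an odd map (tanh is odd) and
    sends the centre of the standardized input distribution to the origin of
    the pre-phase plane.  The image of one gait cycle then starts as a loop
    around the origin, i.e. with the winding the trained phase needs; a
    biased start frequently leaves the origin outside the loop, and the
    singularity terms make such a topology expensive to correct later.
    """
    rng = np.random.default_rng(seed)
    layers = []
    for fan_in, fan_out in zip(LAYER_SIZES[:-1], LAYER_SIZES[1:]):
        bound = 1.0 / np.sqrt(fan_in)
        w = rng.uniform(-bound, bound, size=(fan_in, fan_out))
        layers.append((w, np.zeros(fan_out)))
    return NetworkParams(layers=layers)


def forward(params: NetworkParams, x: np.ndarray, return_caches: bool = False):
    """Batched forward pass: (B, 28) inputs -> (B, 2) pre-phase vectors.

    With ``return_caches`` the post-activation of every layer is returned as
    well, for use by the training backward pass.
    """
    h = np.asarray(x, dtype=float)
    if h.ndim == 1:
        h = h[None, :]
    if not np.isfinite(h).all():
        raise ValueError("network input contains non-finite values")
    caches = [h]
    for k, (w, b) in enumerate(params.layers):
        h = h @ w + b
        if k < N_TANH_LAYERS:
            h = np.tanh(h)
        caches.append(h)
    return (h, caches) if return_caches else h


def prephase(params: NetworkParams, window) -> np.ndarray:
    """Pre-phase 2-vector V for one feature window (28 values)."""
    x = window.flatten() if isinstance(window, FeatureWindow) else np.asarray(window, dtype=float)
    if x.shape != (N_FEATURES,):
        raise ValueError(f"window must flatten to {N_FEATURES} values, got {x.shape}")
    return forward(params, x)[0]


def to_phase(v: np.ndarray) -> PhaseOutput:
    """Euclidean-normalize a pre-phase vector onto the unit circle."""
    v = np.asarray(v, dtype=float)
    r = float(np.hypot(v[0], v[1]))
    if r < SINGULARITY_GUARD:
        raise SingularityError(f"pre-phase magnitude {r:.3e} below {SINGULARITY_GUARD}")
    unit = (float(v[0] / r), float(v[1] / r))
    return PhaseOutput(unit_vector=unit, angle=float(np.arctan2(unit[1], unit[0])), prephase_magnitude=r)


def infer_stream(
    params: NetworkParams,
    std: StandardizedSeries,
    norm: StandardizationParams,
) -> PhaseStream:
    """Sliding-window phase inference over a standardized series.

    One phase per window-pair end index i >= 12, so the first estimate uses
    the initial 13-sample batch and every later one arrives with each new
    sample; the estimate at sample i depends on samples <= i only.
    """
    feats, ends = window_features(std, norm)
    if feats.shape[0] == 0:
        return PhaseStream(
            angles=np.empty(0), unit_vectors=np.empty((0, 2)), magnitudes=np.empty(0),
            end_indices=np.empty(0, dtype=int), sampling_rate=std.sampling_rate,
        )
    v = forward(params, feats)
    r = np.hypot(v[:, 0], v[:, 1])
    if np.any(r < SINGULARITY_GUARD):
        bad = int(np.argmin(r))
        raise SingularityError(
            f"pre-phase magnitude {r[bad]:.3e} at end sample {int(ends[bad])}"
        )
    units = v / r[:, None]
    return PhaseStream(
        angles=np.arctan2(units[:, 1], units[:, 0]),
        unit_vectors=units,
        magnitudes=r,
        end_indices=ends,
        sampling_rate=std.sampling_rate,
    )
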