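"""Small circular-statistics helpers shared across the package."""

from __future__ import annotations

import numpy as np

TWO_PI = 2.0 * np.pi


def wrap_angle(angle):
    """Wrap angles to the half-open interval (-pi, pi]."""
    a = np.asarray(angle, dtype=float)
    wrapped = np.pi - (np.pi - a) % TWO_PI
    return wrapped if wrapped.ndim else float(wrapped)


def resultant(angles: np.ndarray) -> tuple[float, float]:
    """Mean resultant vector of a set of angles: (length, direction)."""
    a = np.asarray(angles, dtype=float)
    c, s = np.cos(a).mean(), np.sin(a).mean()
    return float(np.hypot(c, s)), float(np.arctan2(s, c))


def circular_mean(angles: np.ndarray) -> float:
    """Direction of the mean resultant vector, in (-pi, pi]."""
    _, direction = resultant(angles)
    return wrap_angle(direction)


def circular_correlation(alpha: np.ndarray, beta: np.ndarray) -> float:
    """Fisher-Lee circular-circular correlation coefficient.

    Defined over all sample pairs, T = sum_{i<j} sin(a_i - a_j) sin(b_i - b_j)
    normalized by the two marginal pair sums; computed in O(n) via
    product-to-sum identities.  Invariant under independent rotations of
    either variable; reflecting one variable flips the sign; equals 1 when
    beta = alpha + constant.  Unlike deviation-from-mean variants it stays
    well defined when the phases are spread uniformly around the circle.
    """
    a = np.asarray(alpha, dtype=float)
    b = np.asarray(beta, dtype=float)
    if a.size != b.size:
        raise ValueError("alpha and beta must have equal length")
    sa, ca, sb, cb = np.sin(a), np.cos(a), np.sin(b), np.cos(b)
    # sum_{i,j} sin(ai-aj) sin(bi-bj) = 2 (A1 A4 - A2 A3)
    num = (sa * sb).sum() * (ca * cb).sum() - (sa * cb).sum() * (ca * sb).sum()

    def pair_spread(x: np.ndarray) -> float:
        # sum_{i,j} sin^2(xi - xj) = (n^2 - |sum exp(2i x)|^2) / 2
        return (x.size**2 - np.cos(2 * x).sum() ** 2 - np.sin(2 * x).sum() ** 2) / 2.0

    denom = np.sqrt(pair_spread(a) * pair_spread(b))
    if denom == 0.0:
        return 0.0
    return float(2.0 * num / denom)
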