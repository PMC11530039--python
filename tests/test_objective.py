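import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitphase import LossWeights, TrainConfig, loss_breakdown, penalty_profile, phase_progression, train
from gaitphase.circular import wrap_angle
from gaitphase.model import LAYER_SIZES, NetworkParams, init_params
from gaitphase.objective import SingularityBreach, _gauss, loss_and_grad, penalty_profile_deriv
from gaitphase.preprocess import WindowPairBatch

W = LossWeights()
DEG = np.pi / 180.0


class TestPenaltyProfile:
    def test_maximum_at_c(self):
        assert penalty_profile(W.c) == pytest.approx(1.0)

    def test_zero_at_band_edges_and_inside(self):
        assert penalty_profile(W.a) == pytest.approx(0.0, abs=1e-12)
        assert penalty_profile(W.b) == pytest.approx(0.0, abs=1e-12)
        assert penalty_profile(0.0) == 0.0
        band = np.linspace(W.a + 1e-9, W.b, 100)
        assert np.all(penalty_profile(band) == 0.0)

    def test_known_value_on_rising_branch(self):
        # nu = -pi/2 lies in (c, a]: cos(0.5*pi * 45/132.7) = cos(30.5197 deg)
        assert penalty_profile(-np.pi / 2) == pytest.approx(0.86145, abs=1e-4)

    def test_continuous_including_wrap(self):
        eps = 1e-9
        for edge in (W.c, W.a, W.b):
            assert penalty_profile(edge + eps) == pytest.approx(penalty_profile(edge), abs=1e-6)
        assert penalty_profile(-np.pi + eps) == pytest.approx(penalty_profile(np.pi), abs=1e-6)

    def test_range_error_outside_domain(self):
        with pytest.raises(ValueError, match="nu"):
            penalty_profile(3.5)
        with pytest.raises(ValueError, match="nu"):
            penalty_profile(-np.pi)

    def test_derivative_matches_finite_differences(self, rng):
        nus = rng.uniform(-np.pi + 0.01, np.pi - 0.01, size=200)
        # keep clear of the piecewise kinks
        for kink in (W.a, W.b, W.c):
            nus = nus[np.abs(nus - kink) > 1e-3]
        eps = 1e-7
        fd = (penalty_profile(nus + eps) - penalty_profile(nus - eps)) / (2 * eps)
        assert np.allclose(penalty_profile_deriv(nus), fd, atol=1e-5)


class TestPhaseProgression:
    def test_quarter_turns_and_identity(self):
        assert phase_progression([1.0, 0.0], [0.0, 1.0]) == pytest.approx(np.pi / 2)
        assert phase_progression([0.0, 1.0], [1.0, 0.0]) == pytest.approx(-np.pi / 2)
        assert phase_progression([0.6, 0.8], [0.6, 0.8]) == pytest.approx(0.0)

    def test_non_unit_inputs_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            phase_progression([1.1, 0.0], [0.0, 1.0])

    @given(
        st.floats(min_value=-np.pi, max_value=np.pi, exclude_min=True),
        st.floats(min_value=-np.pi, max_value=np.pi, exclude_min=True),
    )
    @settings(deadline=None, max_examples=300)
    def test_recovers_rotation_angle(self, base, theta):
        u = np.array([np.cos(base), np.sin(base)])
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        nu = phase_progression(u, rot @ u)
        assert np.isclose(np.cos(nu - theta), 1.0, atol=1e-9)


def _odd_batch(rng, n_pairs=8):
    """Batch whose current windows come in +/- pairs (odd-symmetric inputs)."""
    half = rng.normal(size=(n_pairs // 2, 28))
    curr = np.concatenate([half, -half])
    prev = np.roll(curr, 1, axis=0)
    return WindowPairBatch(prev=prev, curr=curr, end_indices=np.arange(13, 13 + n_pairs))


def _bias_only(v=(1.0, 2.0)):
    layers = [
        (np.zeros((fi, fo)), np.zeros(fo)) for fi, fo in zip(LAYER_SIZES[:-1], LAYER_SIZES[1:])
    ]
    w, _ = layers[-1]
    layers[-1] = (w, np.asarray(v, dtype=float))
    return NetworkParams(layers=layers)


class TestLossComponents:
    def test_collapsed_outputs_give_distribution_alpha(self, rng):
        batch = _odd_batch(rng)
        bd = loss_breakdown(_bias_only(), batch, W, noise_seed=0)
        assert bd.d == pytest.approx(W.alpha)  # all unit vectors identical
        assert bd.pp == pytest.approx(0.0)  # no progression between identical outputs

    def test_antipodal_outputs_give_zero_distribution(self, rng):
        net = init_params(5)  # zero biases: odd network
        batch = _odd_batch(rng, n_pairs=16)
        bd = loss_breakdown(net, batch, W, noise_seed=0)
        assert bd.d == pytest.approx(0.0, abs=1e-12)

    def test_singularity_term_is_gaussian_of_magnitude(self, rng):
        batch = _odd_batch(rng)
        v = (1.0, 2.0)
        bd = loss_breakdown(_bias_only(v), batch, W, noise_seed=0)
        r = np.hypot(*v)
        expected = W.gamma * np.exp(-r**2 / (2 * W.sigma**2)) / (W.sigma * np.sqrt(2 * np.pi))
        assert bd.s == pytest.approx(expected, rel=1e-12)

    def test_singularity_value_at_origin(self):
        # with the magnitude at zero the S term equals gamma / (sigma sqrt(2 pi))
        assert W.gamma * _gauss(np.zeros(1), W)[0] == pytest.approx(
            W.gamma / (W.sigma * np.sqrt(2 * np.pi))
        )

    def test_singularity_terms_strictly_decreasing_in_magnitude(self):
        grid = np.linspace(0.0, 5.0, 200)
        g = _gauss(grid, W)
        assert np.all(np.diff(g) < 0)

    def test_progression_term_uses_penalty_profile(self, rng):
        net = init_params(5)
        half = rng.normal(size=(1, 28))
        batch = WindowPairBatch(prev=half, curr=-half, end_indices=np.array([13]))
        bd = loss_breakdown(net, batch, W, noise_seed=0)
        # antipodal outputs: nu = pi exactly
        assert bd.pp == pytest.approx(penalty_profile(np.pi), rel=1e-9)

    def test_total_is_weighted_sum(self, rng):
        bd = loss_breakdown(init_params(1), _odd_batch(rng), W, noise_seed=3)
        assert bd.total == pytest.approx(W.pp_weight * bd.pp + bd.d + bd.s + bd.m)

    def test_distribution_bounded_by_alpha(self, rng):
        for seed in range(5):
            bd = loss_breakdown(init_params(seed), _odd_batch(rng, 32), W, noise_seed=seed)
            assert bd.d <= W.alpha + 1e-12

    def test_marginal_noise_is_seeded(self, rng):
        net, batch = init_params(1), _odd_batch(rng)
        a = loss_breakdown(net, batch, W, noise_seed=11)
        b = loss_breakdown(net, batch, W, noise_seed=11)
        c = loss_breakdown(net, batch, W, noise_seed=12)
        assert a.m == b.m
        assert a.m != c.m

    def test_empty_batch_rejected(self):
        empty = WindowPairBatch(
            prev=np.empty((0, 28)), curr=np.empty((0, 28)), end_indices=np.empty(0, dtype=int)
        )
        with pytest.raises(ValueError, match="empty"):
            loss_breakdown(init_params(0), empty, W, noise_seed=0)

    def test_singularity_guard_reports_pair(self, rng):
        zero_net = _bias_only((0.0, 0.0))
        with pytest.raises(SingularityBreach, match="pair"):
            loss_breakdown(zero_net, _odd_batch(rng), W, noise_seed=0)

    def test_weight_ordering_invariant_enforced(self):
        with pytest.raises(ValueError):
            LossWeights(a=0.1)  # a must be negative
        with pytest.raises(ValueError):
            LossWeights(alpha=-0.1)


class TestGradients:
    def test_autograd_matches_finite_differences(self, rng, pipeline_small):
        batch = pipeline_small["batch"]
        sub = WindowPairBatch(
            prev=batch.prev[:40], curr=batch.curr[:40], end_indices=batch.end_indices[:40]
        )
        params = init_params(3)
        theta = params.flatten()
        _, grad = loss_and_grad(params, sub, W, noise_seed=5)
        eps = 1e-6
        picks = rng.choice(theta.size, size=20, replace=False)
        for k in picks:
            tp, tm = theta.copy(), theta.copy()
            tp[k] += eps
            tm[k] -= eps
            lp = loss_breakdown(NetworkParams.from_flat(tp), sub, W, noise_seed=5).total
            lm = loss_breakdown(NetworkParams.from_flat(tm), sub, W, noise_seed=5).total
            fd = (lp - lm) / (2 * eps)
            denom = max(abs(fd), abs(grad[k]), 1e-8)
            assert abs(grad[k] - fd) / denom < 1e-4


class TestTraining:
    def test_history_length_and_determinism(self, pipeline_small):
        batch = pipeline_small["batch"]
        cfg = TrainConfig(iterations=30, batch_size=128, seed=4)
        p1, h1 = train(batch, cfg)
        p2, h2 = train(batch, cfg)
        assert len(h1) == 30
        assert np.array_equal(p1.flatten(), p2.flatten())
        assert [h.total for h in h1] == [h.total for h in h2]

    def test_loss_decreases_on_synthetic_walk(self, pipeline_small):
        batch = pipeline_small["batch"]
        cfg = TrainConfig(iterations=500, batch_size=256, seed=1)
        _, history = train(batch, cfg)
        assert history[-1].total < history[0].total

    def test_empty_data_rejected(self):
        empty = WindowPairBatch(
            prev=np.empty((0, 28)), curr=np.empty((0, 28)), end_indices=np.empty(0, dtype=int)
        )
        with pytest.raises(ValueError):
            train(empty, TrainConfig(iterations=1))
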