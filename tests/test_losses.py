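import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nabind.losses import (
    CenterBank,
    ClassCounts,
    LossConfig,
    LossError,
    cb_focal_loss,
    class_weights,
    effective_number,
    joint_loss,
    triplet_center_loss,
)


def focal_loop_oracle(p_true, labels, counts, cfg):
    """Scalar per-residue reimplementation of the class-balanced focal loss."""
    w = class_weights(counts, cfg.beta)
    total = 0.0
    for p, y in zip(p_true, labels):
        total += w[y] * (1.0 - p) ** cfg.gamma * (-np.log(p))
    return total / len(p_true)


def tcl_loop_oracle(features, labels, centers, margin):
    total = 0.0
    for f, y in zip(features, labels):
        d_own = 0.5 * np.sum((f - centers[y]) ** 2)
        d_other = 0.5 * np.sum((f - centers[1 - y]) ** 2)
        total += max(d_own + margin - d_other, 0.0)
    return total / len(labels)


class TestEffectiveNumber:
    def test_single_sample(self):
        assert effective_number(1, 0.999) == pytest.approx(1.0)

    def test_two_samples_geometric(self):
        assert effective_number(2, 0.5) == pytest.approx(1.5)

    def test_matches_brute_force_geometric_sum(self):
        for n, beta in [(10, 0.9), (500, 0.99), (10**6, 0.999)]:
            brute = float(np.sum(beta ** np.arange(n, dtype=np.float64)))
            assert effective_number(n, beta) == pytest.approx(brute, abs=1e-6)

    def test_monotone_and_bounded(self):
        vals = [effective_number(n, 0.99) for n in (1, 2, 10, 100, 10_000)]
        assert all(a < b for a, b in zip(vals, vals[1:]))
        assert vals[-1] <= 1.0 / (1.0 - 0.99)

    def test_beta_one_rejected(self):
        with pytest.raises(LossError):
            effective_number(5, 1.0)


class TestClassWeights:
    def test_minority_gets_larger_weight(self):
        w = class_weights(ClassCounts(n_neg=1000, n_pos=50), beta=0.99)
        assert w[1] > w[0]

    def test_beta_zero_gives_unit_weights(self):
        np.testing.assert_allclose(class_weights(ClassCounts(7, 3), 0.0), [1.0, 1.0])


class TestCbFocalLoss:
    CFG = LossConfig(beta=0.9, gamma=2.0)
    COUNTS = ClassCounts(n_neg=2, n_pos=1)

    def test_perfect_predictions_give_zero(self):
        assert cb_focal_loss(
            np.ones(4), np.array([1, 0, 0, 1]), self.COUNTS, self.CFG
        ) == pytest.approx(0.0)

    def test_ce_limit_gamma_zero_beta_zero(self, rng):
        p = rng.uniform(0.05, 0.95, size=50)
        labels = rng.integers(0, 2, size=50)
        cfg = LossConfig(beta=0.0, gamma=0.0)
        loss = cb_focal_loss(p, labels, ClassCounts(30, 20), cfg)
        assert loss == pytest.approx(-np.mean(np.log(p)), abs=1e-12)

    def test_three_residue_example_matches_loop_oracle(self):
        p = np.array([0.6, 0.9, 0.4])
        labels = np.array([1, 0, 0])
        loss = cb_focal_loss(p, labels, self.COUNTS, self.CFG)
        assert loss == pytest.approx(
            focal_loop_oracle(p, labels, self.COUNTS, self.CFG), abs=1e-10
        )

    def test_vectorized_matches_oracle_on_random_batches(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 40))
            p = rng.uniform(1e-3, 1.0, size=n)
            labels = rng.integers(0, 2, size=n)
            counts = ClassCounts(int(rng.integers(1, 1000)), int(rng.integers(1, 1000)))
            cfg = LossConfig(beta=float(rng.uniform(0, 0.9999)),
                             gamma=float(rng.uniform(0, 6)))
            assert cb_focal_loss(p, labels, counts, cfg) == pytest.approx(
                focal_loop_oracle(p, labels, counts, cfg), abs=1e-10
            )

    def test_zero_probability_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            loss = cb_focal_loss(
                np.array([0.0, 0.5]), np.array([1, 0]), self.COUNTS, self.CFG
            )
        assert np.isfinite(loss)

    def test_mask_excludes_padding(self):
        p = np.array([0.6, 0.9, 0.123])
        labels = np.array([1, 0, 0])
        mask = np.array([True, True, False])
        full = cb_focal_loss(p[:2], labels[:2], self.COUNTS, self.CFG)
        masked = cb_focal_loss(p, labels, self.COUNTS, self.CFG, mask)
        assert masked == pytest.approx(full, abs=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(
        st.integers(0, 19),
        st.floats(0.01, 0.98),
        st.floats(0.01, 0.98),
    )
    def test_monotone_nonincreasing_in_each_p_true(self, idx, p_low, p_high):
        rng = np.random.default_rng(99)
        p = rng.uniform(0.2, 0.8, size=20)
        labels = rng.integers(0, 2, size=20)
        lo, hi = min(p_low, p_high), max(p_low, p_high)
        p_lo, p_hi = p.copy(), p.copy()
        p_lo[idx], p_hi[idx] = lo, hi
        cfg = LossConfig(beta=0.99, gamma=3.0)
        counts = ClassCounts(15, 5)
        assert cb_focal_loss(p_hi, labels, counts, cfg) <= cb_focal_loss(
            p_lo, labels, counts, cfg
        ) + 1e-12


class TestTripletCenterLoss:
    def test_zero_when_samples_sit_on_their_centers(self):
        centers = np.array([[0.0, 0.0], [4.0, 0.0]])  # half-sq distance 8 > margin
        bank = CenterBank(2, np.random.default_rng(0))
        bank.centers[...] = centers
        features = np.array([[0.0, 0.0], [4.0, 0.0], [0.0, 0.0]])
        labels = np.array([0, 1, 0])
        assert triplet_center_loss(features, labels, bank, margin=3.0) == 0.0

    def test_single_sample_hinge_arithmetic(self):
        # D(own)=2, D(other)=4, m=3 -> max(2+3-4, 0) = 1
        bank = CenterBank(1, np.random.default_rng(0))
        features = np.array([[2.0]])
        # own center 0 -> D_own = 0.5*2^2 = 2; other center 2+sqrt(8) -> D_other = 4
        bank.centers[...] = np.array([[0.0], [2.0 + np.sqrt(8.0)]])
        labels = np.array([0])
        val = triplet_center_loss(features, labels, bank, margin=3.0)
        assert val == pytest.approx(1.0, abs=1e-12)

    def test_matches_loop_oracle_on_random_batches(self, rng):
        for _ in range(100):
            m = int(rng.integers(1, 25))
            feats = rng.standard_normal((m, 4))
            labels = rng.integers(0, 2, size=m)
            centers = rng.standard_normal((2, 4))
            bank = CenterBank(4, np.random.default_rng(0))
            bank.centers[...] = centers
            margin = float(rng.uniform(0, 5))
            assert triplet_center_loss(feats, labels, bank, margin) == pytest.approx(
                tcl_loop_oracle(feats, labels, centers, margin), abs=1e-10
            )

    def test_sum_reduction_matches_oracle_scale(self, rng):
        feats = rng.standard_normal((10, 3))
        labels = rng.integers(0, 2, size=10)
        bank = CenterBank(3, np.random.default_rng(1))
        mean = triplet_center_loss(feats, labels, bank, 2.0, reduction="mean")
        total = triplet_center_loss(feats, labels, bank, 2.0, reduction="sum")
        assert total == pytest.approx(10 * mean, rel=1e-12)

    def test_moving_toward_own_center_decreases_active_hinge(self, rng):
        bank = CenterBank(3, np.random.default_rng(5))
        f = bank.centers[0] + 3.0 * rng.standard_normal(3)
        labels = np.array([0])
        margin = 50.0  # large margin keeps the hinge active along the path
        vals = []
        for t in np.linspace(0.0, 0.9, 5):
            feats = ((1 - t) * f + t * bank.centers[0])[None, :]
            vals.append(triplet_center_loss(feats, labels, bank, margin))
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_empty_mask_is_error(self, rng):
        bank = CenterBank(2, rng)
        with pytest.raises(LossError):
            triplet_center_loss(
                np.zeros((2, 2)), np.array([0, 1]), bank, 1.0, mask=np.array([False, False])
            )


class TestJointLoss:
    def test_weighted_sum(self):
        assert joint_loss(0.7, 2.0, 0.1) == pytest.approx(0.9)

    def test_lambda_zero_recovers_focal(self):
        assert joint_loss(1.234, 99.0, 0.0) == 1.234

    def test_nonfinite_rejected(self):
        with pytest.raises(LossError):
            joint_loss(np.inf, 1.0, 0.1)


class TestLossConfig:
    def test_reference_defaults(self):
        cfg = LossConfig()
        assert (cfg.beta, cfg.gamma, cfg.lambda_, cfg.margin, cfg.center_lr) == (
            0.999, 5.0, 0.1, 9.0, 0.01,
        )

    @pytest.mark.parametrize("bad", [{"beta": 1.0}, {"gamma": -1}, {"center_lr": 0.0}])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(LossError):
            LossConfig(**bad)
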