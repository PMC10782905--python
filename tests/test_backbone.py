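import numpy as np
import pytest

from nabind.backbone import (
    Backbone,
    BackboneConfig,
    BackboneError,
    PredictionTrack,
    batchify,
)
from nabind.embedding import EmbeddingMatrix
from nabind.losses import (
    CenterBank,
    ClassCounts,
    LossConfig,
    cb_focal_loss,
    cb_focal_loss_grad,
    joint_loss,
    triplet_center_loss,
    triplet_center_loss_grad,
)


def make_backbone(cfg, seed=0):
    return Backbone(cfg, np.random.default_rng(seed))


class TestConfig:
    def test_even_kernel_rejected(self):
        with pytest.raises(BackboneError):
            BackboneConfig(in_dim=4, layer_dims=(4, 4, 4, 2), kernel_sizes=(4, 3, 3, 3))

    def test_last_layer_must_be_binary(self):
        with pytest.raises(BackboneError):
            BackboneConfig(in_dim=4, layer_dims=(4, 4, 4, 3))

    def test_round_trips_through_dict(self, small_backbone_cfg):
        assert BackboneConfig.from_dict(small_backbone_cfg.to_dict()) == small_backbone_cfg


class TestForward:
    @pytest.mark.parametrize("kernels", [(3, 3, 3, 3), (7, 5, 3, 3), (9, 1, 5, 3)])
    def test_length_preserved_for_any_kernels(self, rng, kernels):
        cfg = BackboneConfig(in_dim=5, layer_dims=(6, 5, 4, 2), kernel_sizes=kernels)
        bb = make_backbone(cfg)
        x = rng.standard_normal((2, 31, 5))
        mask = np.ones((2, 31), dtype=bool)
        res = bb.forward(x, mask)
        for feat in res.features:
            assert feat.shape[:2] == (2, 31)

    def test_softmax_rows_sum_to_one(self, small_backbone_cfg, rng):
        bb = make_backbone(small_backbone_cfg)
        x = rng.standard_normal((1, 50, 6))
        mask = np.ones((1, 50), dtype=bool)
        res = bb.forward(x, mask)
        assert res.probs.shape == (1, 50, 2)
        np.testing.assert_allclose(res.probs.sum(-1), 1.0, atol=1e-6)

    def test_eval_mode_is_deterministic(self, small_backbone_cfg, rng):
        bb = make_backbone(small_backbone_cfg)
        x = rng.standard_normal((2, 20, 6))
        mask = np.ones((2, 20), dtype=bool)
        a = bb.forward(x, mask, train=False).probs
        b = bb.forward(x, mask, train=False).probs
        np.testing.assert_array_equal(a, b)

    def test_batched_equals_unbatched_on_real_positions(self, small_backbone_cfg, rng):
        bb = make_backbone(small_backbone_cfg)
        e1 = rng.standard_normal((12, 6))
        e2 = rng.standard_normal((20, 6))
        x, mask = batchify([e1, e2])
        batched = bb.forward(x, mask, train=False).probs
        single1 = bb.forward(e1[None], np.ones((1, 12), bool), train=False).probs
        single2 = bb.forward(e2[None], np.ones((1, 20), bool), train=False).probs
        np.testing.assert_allclose(batched[0, :12], single1[0], atol=1e-5)
        np.testing.assert_allclose(batched[1], single2[0], atol=1e-5)

    def test_batch_permutation_does_not_change_predictions(self, small_backbone_cfg, rng):
        bb = make_backbone(small_backbone_cfg)
        embs = [
            EmbeddingMatrix(f"s{i}", rng.standard_normal((8 + i, 6))) for i in range(4)
        ]
        fwd = {t.id: t.p_bind for t in bb.predict_batch(embs)}
        rev = {t.id: t.p_bind for t in bb.predict_batch(embs[::-1])}
        for rid in fwd:
            np.testing.assert_allclose(fwd[rid], rev[rid], atol=1e-9)

    def test_dim_mismatch_is_error(self, small_backbone_cfg, rng):
        bb = make_backbone(small_backbone_cfg)
        with pytest.raises(BackboneError):
            bb.forward(rng.standard_normal((1, 5, 9)), np.ones((1, 5), bool))


class TestBatchify:
    def test_mask_counts(self, rng):
        x, mask = batchify([rng.standard_normal((3, 4)), rng.standard_normal((5, 4))])
        assert x.shape == (2, 5, 4)
        assert mask.sum() == 8

    def test_single_sequence_mask_all_true(self, rng):
        _, mask = batchify([rng.standard_normal((6, 4))])
        assert mask.all()


class TestMaskContract:
    def _joint(self, bb, centers, x, mask, labels, counts, cfg):
        res = bb.forward(x, mask, train=True, rng=None)
        p_true = np.take_along_axis(res.probs, labels[..., None], -1)[..., 0]
        focal = cb_focal_loss(p_true.ravel(), labels.ravel(), counts, cfg, mask.ravel())
        feats = res.features[2].reshape(-1, res.features[2].shape[-1])
        tcl = triplet_center_loss(feats, labels.ravel(), centers, cfg.margin, mask.ravel())
        return joint_loss(focal, tcl, cfg.lambda_), res.probs

    def test_padding_content_cannot_change_loss_or_outputs(self, rng):
        cfg = BackboneConfig(
            in_dim=5, layer_dims=(6, 5, 4, 2), kernel_sizes=(5, 3, 3, 3), dropout_rate=0.0
        )
        bb = make_backbone(cfg)
        loss_cfg = LossConfig(tcl_feature_layer=2)
        counts = ClassCounts(20, 5)
        centers = CenterBank(4, np.random.default_rng(1))
        x = rng.standard_normal((2, 10, 5))
        mask = np.ones((2, 10), dtype=bool)
        mask[0, 7:] = False
        mask[1, 4:] = False
        labels = (rng.random((2, 10)) < 0.3).astype(int)
        labels[~mask] = 0

        loss_zeros, probs_zeros = self._joint(bb, centers, x * mask[:, :, None], mask,
                                              labels, counts, loss_cfg)
        noisy = x.copy()
        noisy[~mask] = 1e3 * rng.standard_normal((~mask).sum() * 5).reshape(-1, 5)
        loss_noise, probs_noise = self._joint(bb, centers, noisy, mask, labels,
                                              counts, loss_cfg)
        assert loss_zeros == pytest.approx(loss_noise, abs=1e-6)
        np.testing.assert_allclose(probs_zeros[mask], probs_noise[mask], atol=1e-6)


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self):
        rng = np.random.default_rng(42)
        cfg = BackboneConfig(
            in_dim=5, layer_dims=(6, 4, 3, 2), kernel_sizes=(3, 3, 3, 3),
            dropout_rate=0.0, batchnorm=True,
        )
        bb = make_backbone(cfg, seed=42)
        loss_cfg = LossConfig(beta=0.9, gamma=2.0, lambda_=0.3, margin=1.0,
                              tcl_feature_layer=2)
        counts = ClassCounts(10, 3)
        centers = CenterBank(3, rng)
        x = rng.standard_normal((2, 7, 5))
        mask = np.ones((2, 7), dtype=bool)
        mask[1, 5:] = False
        labels = (rng.random((2, 7)) < 0.3).astype(int)

        def loss_value():
            res = bb.forward(x, mask, train=True, rng=None)
            p_true = np.take_along_axis(res.probs, labels[..., None], -1)[..., 0]
            f = cb_focal_loss(p_true.ravel(), labels.ravel(), counts, loss_cfg, mask.ravel())
            feats = res.features[2].reshape(-1, 3)
            t = triplet_center_loss(feats, labels.ravel(), centers, loss_cfg.margin,
                                    mask.ravel())
            return joint_loss(f, t, loss_cfg.lambda_)

        bb.zero_grad()
        centers.zero_grad()
        res = bb.forward(x, mask, train=True, rng=None)
        _, dlogits = cb_focal_loss_grad(res.logits, labels, counts, loss_cfg, mask)
        feats = res.features[2].reshape(-1, 3)
        _, dfeat, dcent = triplet_center_loss_grad(
            feats, labels.ravel(), centers, loss_cfg.margin, mask.ravel()
        )
        centers.grad += loss_cfg.lambda_ * dcent
        bb.backward(dlogits, {2: loss_cfg.lambda_ * dfeat.reshape(2, 7, 3)})

        eps = 1e-5
        check_rng = np.random.default_rng(7)
        for name, p in bb.parameters().items():
            flat, gflat = p.value.ravel(), p.grad.ravel()
            for i in check_rng.choice(flat.size, size=min(4, flat.size), replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                lp = loss_value()
                flat[i] = orig - eps
                lm = loss_value()
                flat[i] = orig
                fd = (lp - lm) / (2 * eps)
                assert gflat[i] == pytest.approx(fd, rel=1e-3, abs=1e-7), name
        cflat, cg = centers.centers.ravel(), centers.grad.ravel()
        for i in range(cflat.size):
            orig = cflat[i]
            cflat[i] = orig + eps
            lp = loss_value()
            cflat[i] = orig - eps
            lm = loss_value()
            cflat[i] = orig
            fd = (lp - lm) / (2 * eps)
            assert cg[i] == pytest.approx(fd, rel=1e-4, abs=1e-8)


class TestPredictionTrack:
    def test_threshold_extremes(self):
        t = PredictionTrack("p", np.array([0.1, 0.6, 1.0]))
        assert t.calls(0.0).tolist() == [1, 1, 1]
        assert t.calls(1.0).tolist() == [0, 0, 0]

    def test_probability_bounds_enforced(self):
        with pytest.raises(BackboneError):
            PredictionTrack("p", np.array([0.2, 1.4]))
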