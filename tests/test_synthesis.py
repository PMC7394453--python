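import numpy as np
import pytest

from b0synth.phantom import PhantomParams, simulate_cohort
from b0synth.synthesis import (
    TrainConfig,
    compute_loss,
    ensemble_predict,
    loss_and_grads,
    prepare_sample,
    split_folds,
    synthesize_b0,
    train_fold,
    train_ensemble,
)
from b0synth.synthesis import FoldCurves, FoldEnsemble
from b0synth.unet import UNet3D, UNetConfig

TINY_NET = UNetConfig(levels=2, base_channels=4)


class TestLossAlgebra:
    def test_perfect_prediction_is_zero(self, rng):
        truth = rng.random((8, 8, 8)).astype(np.float32)
        mask = np.ones_like(truth)
        rep = compute_loss([truth, truth], truth, mask)
        assert rep.total == 0.0
        assert rep.diff_loss == 0.0

    def test_two_voxel_hand_example(self):
        # outputs (1,3) and (1,1) vs truth (1,1): MSE1=2, MSE2=0, diff=2 -> 3
        mask = np.zeros((8, 8, 8))
        mask[0, 0, 0] = mask[0, 0, 1] = 1
        o1 = np.zeros((8, 8, 8))
        o1[0, 0, 0], o1[0, 0, 1] = 1, 3
        o2 = np.zeros((8, 8, 8))
        o2[0, 0, 0], o2[0, 0, 1] = 1, 1
        truth = o2.copy()
        rep = compute_loss([o1, o2], truth, mask)
        assert rep.truth_losses == pytest.approx((2.0, 0.0))
        assert rep.diff_loss == pytest.approx(2.0)
        assert rep.total == pytest.approx(3.0)

    def test_dual_total_equals_decomposition(self, rng):
        # independent arithmetic oracle on random masked tensors
        for _ in range(100):
            o1, o2, t = (rng.normal(size=(6, 6, 6)) for _ in range(3))
            mask = (rng.random((6, 6, 6)) > 0.4).astype(float)
            if not mask.any():
                continue
            m = mask > 0
            mse1 = np.mean((o1[m] - t[m]) ** 2)
            mse2 = np.mean((o2[m] - t[m]) ** 2)
            diff = np.mean((o1[m] - o2[m]) ** 2)
            rep = compute_loss([o1, o2], t, mask)
            assert rep.total == pytest.approx((mse1 + mse2) / 2 + diff, rel=1e-10)

    def test_single_blip_is_plain_masked_mse(self, rng):
        o, t = rng.normal(size=(6, 6, 6)), rng.normal(size=(6, 6, 6))
        mask = (rng.random((6, 6, 6)) > 0.5).astype(float)
        rep = compute_loss([o], t, mask)
        m = mask > 0
        assert rep.total == pytest.approx(np.mean((o[m] - t[m]) ** 2), rel=1e-10)
        assert rep.diff_loss is None

    def test_identical_blips_degenerate_to_truth_loss(self, rng):
        o, t = rng.normal(size=(6, 6, 6)), rng.normal(size=(6, 6, 6))
        mask = np.ones((6, 6, 6))
        rep = compute_loss([o, o.copy()], t, mask)
        assert rep.diff_loss == 0.0
        assert rep.total == pytest.approx(rep.truth_losses[0], rel=1e-10)

    def test_dual_total_bounded_below_by_truth_mean(self, rng):
        for _ in range(20):
            o1, o2, t = (rng.normal(size=(5, 5, 5)) for _ in range(3))
            mask = np.ones((5, 5, 5))
            rep = compute_loss([o1, o2], t, mask)
            assert rep.total >= np.mean(rep.truth_losses) - 1e-12

    def test_empty_mask_rejected(self, rng):
        o = rng.normal(size=(5, 5, 5))
        with pytest.raises(ValueError, match="mask"):
            compute_loss([o], o, np.zeros((5, 5, 5)))

    def test_gradients_match_numeric(self, rng):
        o1 = rng.normal(size=(4, 4, 4))
        o2 = rng.normal(size=(4, 4, 4))
        t = rng.normal(size=(4, 4, 4))
        mask = (rng.random((4, 4, 4)) > 0.3).astype(float)
        _, grads = loss_and_grads([o1, o2], t, mask)
        eps = 1e-5
        for _ in range(5):
            idx = tuple(rng.integers(0, 4, size=3))
            for o, g in ((o1, grads[0]), (o2, grads[1])):
                old = o[idx]
                o[idx] = old + eps
                fp = compute_loss([o1, o2], t, mask).total
                o[idx] = old - eps
                fm = compute_loss([o1, o2], t, mask).total
                o[idx] = old
                assert g[idx] == pytest.approx((fp - fm) / (2 * eps), abs=1e-6)


class TestSplitFolds:
    def test_disjoint_covering_balanced(self):
        ids = [f"s{i}" for i in range(10)]
        test, folds = split_folds(ids, k=5, seed=0)
        assert test == []
        assert sorted(x for f in folds for x in f) == sorted(ids)
        assert all(len(f) == 2 for f in folds)

    def test_test_set_carved_before_folding(self):
        ids = [f"s{i}" for i in range(12)]
        test, folds = split_folds(ids, k=5, seed=1, n_test=2)
        learn = [x for f in folds for x in f]
        assert len(test) == 2 and not set(test) & set(learn)
        assert sorted(test + learn) == sorted(ids)

    def test_deterministic_under_seed(self):
        ids = [f"s{i}" for i in range(9)]
        assert split_folds(ids, 3, seed=5) == split_folds(ids, 3, seed=5)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            split_folds(["a", "b", "c"], k=5)


@pytest.fixture(scope="module")
def tiny_cohort():
    cohort = simulate_cohort(
        6, PhantomParams(grid=(16, 16, 16)), blips="mixed", master_seed=1
    )
    return {s.subject_id: prepare_sample(s) for s in cohort}


class TestTrainFold:
    def test_selected_epoch_is_argmin_and_reproducible(self, tiny_cohort):
        ids = sorted(tiny_cohort)
        cfg = TrainConfig(epochs=4, folds=2, seed=0)
        net1, c1 = train_fold(tiny_cohort, ids[:4], ids[4:], TINY_NET, cfg)
        net2, c2 = train_fold(tiny_cohort, ids[:4], ids[4:], TINY_NET, cfg)
        assert c1.val_mse == c2.val_mse  # bit-identical curves, same seed
        assert c1.train_loss == c2.train_loss
        assert min(c1.val_mse) == c1.val_mse[c1.best_epoch]
        s1, s2 = net1.state_dict(), net2.state_dict()
        for k in s1:
            np.testing.assert_array_equal(s1[k], s2[k])

    def test_training_reduces_validation_mse(self, tiny_cohort):
        ids = sorted(tiny_cohort)
        cfg = TrainConfig(epochs=6, folds=2, seed=1)
        _, curves = train_fold(tiny_cohort, ids[:4], ids[4:], TINY_NET, cfg)
        assert min(curves.val_mse) < curves.val_mse[0]

    def test_overlapping_subjects_rejected(self, tiny_cohort):
        ids = sorted(tiny_cohort)
        with pytest.raises(ValueError, match="overlap"):
            train_fold(
                tiny_cohort, ids[:4], ids[3:], TINY_NET,
                TrainConfig(epochs=1, folds=2),
            )


class TestEnsemble:
    def test_identical_members_equal_single_model(self, tiny_cohort, rng):
        net = UNet3D(TINY_NET, seed=0)
        ens = FoldEnsemble(
            [net, net, net], [FoldCurves([0.0], [0.0])] * 3, TINY_NET
        )
        x = rng.normal(size=(2, 16, 16, 16)).astype(np.float32)
        np.testing.assert_allclose(
            ensemble_predict(ens, x), net.forward(x)[0], atol=1e-6
        )

    def test_mean_of_constant_members(self, rng, tiny_cohort):
        class Const:
            def __init__(self, v):
                self.v = v

            def forward(self, x):
                return np.full((1,) + x.shape[1:], self.v, dtype=np.float32)

        ens = FoldEnsemble(
            [Const(0.0), Const(2.0)], [FoldCurves([0.0], [0.0])] * 2, TINY_NET
        )
        x = rng.normal(size=(2, 8, 8, 8)).astype(np.float32)
        np.testing.assert_allclose(ensemble_predict(ens, x), 1.0)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            FoldEnsemble([], [], TINY_NET)

    def test_trained_ensemble_beats_untrained_on_heldout(self, tiny_cohort):
        ids = sorted(tiny_cohort)
        folds = [ids[1:3], ids[3:5]]
        cfg = TrainConfig(epochs=5, folds=2, seed=2)
        ens = train_ensemble(tiny_cohort, folds, TINY_NET, cfg)
        held = tiny_cohort[ids[0]]
        x, truth, m = held.inputs[0], held.truth, held.mask > 0
        trained = np.mean((ensemble_predict(ens, x)[m] - truth[m]) ** 2)
        un = UNet3D(TINY_NET, seed=123)
        untrained = np.mean((un.forward(x)[0][m] - truth[m]) ** 2)
        assert trained < untrained

    def test_synthesize_returns_image_units(self, tiny_cohort):
        sid = sorted(tiny_cohort)[0]
        p = tiny_cohort[sid]
        net = UNet3D(TINY_NET, seed=0)
        ens = FoldEnsemble([net], [FoldCurves([0.0], [0.0])], TINY_NET)
        from b0synth.core_io import Volume3D

        aff = np.diag([2.5, 2.5, 2.5, 1.0])
        t1n = Volume3D(p.inputs[0][0], (2.5,) * 3, aff)
        b0dn = Volume3D(p.inputs[0][1], (2.5,) * 3, aff)
        out = synthesize_b0(ens, t1n, b0dn, p.norm)
        # de-normalized output lives on the b0 intensity scale, not [-1, 1]
        assert out.data.max() > 10.0 or out.data.min() < -10.0
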