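"""Fold construction, augmentation, the training loop, and leakage guards."""

import numpy as np
import pytest

from jeps import architectures as arch
from jeps.nn.optim import weighted_bce
from jeps.stats import roc_auc
from jeps.training import (FoldPlan, TrainConfig, _fold_inputs, augment_volume,
                           make_folds, prepare_cohort, run_cross_validation,
                           train_network)


class TestMakeFolds:
    def test_cohort_sized_stratification(self):
        labels = np.array([1] * 63 + [0] * 159)
        plan = make_folds(labels, 10, seed=0)
        sizes = [len(t) for t in plan.test_ids]
        assert sorted(sizes)[0] >= 22 and sorted(sizes)[-1] <= 23
        lab = dict(zip((str(i) for i in range(222)), labels))
        pos = [sum(lab[i] for i in t) for t in plan.test_ids]
        assert set(pos) <= {6, 7}

    def test_partition_and_determinism(self):
        labels = np.array([0, 1] * 20)
        p1 = make_folds(labels, 5, seed=3)
        p2 = make_folds(labels, 5, seed=3)
        assert p1.test_ids == p2.test_ids and p1.val_ids == p2.val_ids
        all_ids = sorted(i for t in p1.test_ids for i in t)
        assert all_ids == sorted(str(i) for i in range(40))

    def test_row_order_irrelevant_when_id_keyed(self):
        labels = np.array([0, 1] * 10)
        ids = [f"P{i:02d}" for i in range(20)]
        perm = np.random.default_rng(0).permutation(20)
        p1 = make_folds(labels, 4, seed=1, ids=ids)
        p2 = make_folds(labels[perm], 4, seed=1, ids=[ids[i] for i in perm])
        assert p1.test_ids == p2.test_ids

    def test_leave_one_out_degenerate(self):
        labels = np.array([0, 1, 0, 1])
        with pytest.warns(UserWarning):
            plan = make_folds(labels, 4, seed=0)
        assert all(len(t) == 1 for t in plan.test_ids)

    def test_validation_subset_of_train(self):
        labels = np.array([0, 1] * 30)
        plan = make_folds(labels, 5, seed=2)
        ids = [str(i) for i in range(60)]
        for f in range(5):
            train = set(plan.train_ids(f, ids))
            assert set(plan.val_ids[f]) <= train
            assert not set(plan.test_ids[f]) & train


class _ForcedRng:
    """Stub generator driving augment_volume down a chosen branch."""

    def __init__(self, op, amount=0.0):
        self.op, self.amount = op, amount

    def random(self):
        return 0.0                                    # always augment

    def integers(self, n):
        return self.op

    def uniform(self, lo, hi):
        mid = (lo + hi) / 2
        return mid + self.amount * (hi - mid)


class TestAugmentation:
    def test_probability_band_over_3000_draws(self, rng):
        vol = rng.random((4, 6, 6, 3)).astype(np.float32)
        vol[..., 2] = (vol[..., 2] > 0.5)
        changed = sum(not np.array_equal(augment_volume(vol, rng), vol)
                      for _ in range(3000))
        assert 0.63 <= changed / 3000 <= 0.70

    def test_mask_channel_stays_binary(self, rng):
        vol = rng.random((6, 8, 8, 3)).astype(np.float32)
        vol[..., 2] = (vol[..., 2] > 0.5)
        for _ in range(50):
            out = augment_volume(vol, rng)
            assert set(np.unique(out[..., 2])) <= {0.0, 1.0}
            assert out.shape == vol.shape

    @pytest.mark.parametrize("op", [0, 1, 2])
    def test_neutral_parameters_are_identity(self, rng, op):
        # zoom factor 1.0, rotation 0 deg, shift 0 all leave the volume intact
        vol = rng.random((5, 7, 7, 3)).astype(np.float32)
        out = augment_volume(vol, _ForcedRng(op, amount=0.0))
        assert np.allclose(out, vol, atol=1e-5)

    def test_shift_moves_centroid(self):
        vol = np.zeros((3, 11, 11, 3), dtype=np.float32)
        vol[1, 5, 5, :] = 1.0
        out = augment_volume(vol, _ForcedRng(2, amount=1.0))   # max +20% shift
        assert out[1, 5, 5, 0] == 0.0 and out.sum() > 0


def _toy_batches(rng, n=60, d=6):
    x = rng.normal(size=(n, d))
    w = np.array([2.0, -1.5, 1.0, 0.0, 0.5, -0.5])
    y = (x @ w + 0.3 * rng.normal(size=n) > 0).astype(int)
    return {"clinical": x.astype(np.float32)}, y


class TestTrainNetwork:
    def cfg(self, **kw):
        base = dict(batch_size=16, learning_rate=3e-3, max_epochs=30,
                    early_stop_patience=30, seed=0)
        base.update(kw)
        return TrainConfig(**base)

    def test_learns_separable_problem(self, rng):
        xb, y = _toy_batches(rng)
        spec = arch.ModelSpec("mlp_clinical", clinical_width=6, seed=1, dropout=0.1)
        m = arch.build_clinical_mlp(spec)
        train_network(m, {k: v[:48] for k, v in xb.items()}, y[:48],
                      {k: v[48:] for k, v in xb.items()}, y[48:],
                      self.cfg(), np.random.default_rng(0), augment=False)
        p = m.predict({k: v[48:] for k, v in xb.items()})
        assert roc_auc(p, y[48:]) > 0.8

    def test_two_runs_same_seed_identical_weights(self, rng):
        xb, y = _toy_batches(rng)
        weights = []
        for _ in range(2):
            spec = arch.ModelSpec("mlp_clinical", clinical_width=6, seed=4)
            m = arch.build_clinical_mlp(spec)
            train_network(m, {k: v[:48] for k, v in xb.items()}, y[:48],
                          {k: v[48:] for k, v in xb.items()}, y[48:],
                          self.cfg(max_epochs=8), np.random.default_rng(11),
                          augment=False)
            weights.append(m.get_weights())
        assert all(np.array_equal(a, b) for a, b in zip(*weights))

    def test_best_epoch_has_minimal_validation_loss(self, rng):
        xb, y = _toy_batches(rng)
        spec = arch.ModelSpec("mlp_clinical", clinical_width=6, seed=2)
        m = arch.build_clinical_mlp(spec)
        h = train_network(m, {k: v[:48] for k, v in xb.items()}, y[:48],
                          {k: v[48:] for k, v in xb.items()}, y[48:],
                          self.cfg(max_epochs=12), np.random.default_rng(1),
                          augment=False)
        assert h["best_val_loss"] == pytest.approx(min(h["val_loss"]))

    def test_empty_validation_rejected(self, rng):
        xb, y = _toy_batches(rng)
        spec = arch.ModelSpec("mlp_clinical", clinical_width=6, seed=2)
        m = arch.build_clinical_mlp(spec)
        with pytest.raises(ValueError, match="validation"):
            train_network(m, xb, y, {"clinical": xb["clinical"][:0]},
                          y[:0], self.cfg(), np.random.default_rng(0))

    def test_class_weighting_raises_sensitivity(self, rng):
        # imbalanced problem: 2:1 overweighting must push predicted
        # probabilities for true positives upward relative to 1:1
        x = rng.normal(size=(120, 4))
        y = (x[:, 0] + 0.5 * rng.normal(size=120) > 0.8).astype(int)
        preds = {}
        for w in (1.0, 2.0):
            spec = arch.ModelSpec("mlp_clinical", clinical_width=4, seed=3, dropout=0.0)
            m = arch.build_clinical_mlp(spec)
            train_network(m, {"clinical": x[:100].astype(np.float32)}, y[:100],
                          {"clinical": x[100:].astype(np.float32)}, y[100:],
                          self.cfg(pos_weight=w, max_epochs=25),
                          np.random.default_rng(2), augment=False)
            preds[w] = m.predict({"clinical": x.astype(np.float32)})
        assert preds[2.0][y == 1].mean() > preds[1.0][y == 1].mean()


@pytest.fixture(scope="module")
def tiny():
    from jeps.phantom import generate_cohort, micro_config
    cfg = micro_config(n_patients=36, seed=77)
    cohort = prepare_cohort(generate_cohort(cfg), cfg.spacing_mm, cfg.grid_shape)
    plan = make_folds(cohort.labels, 3, seed=5, ids=cohort.ids)
    return cohort, plan


class TestCrossValidationProtocol:

    def test_each_patient_tested_exactly_once(self, tiny):
        cohort, plan = tiny
        tc = TrainConfig(max_epochs=2, seed=0)
        res = run_cross_validation(cohort, ["cph_clinical", "mlp_clinical"], plan, tc)
        for design in ("cph_clinical", "mlp_clinical"):
            tested = [i for r in res if r.design == design for i in r.test_ids]
            assert sorted(tested) == sorted(cohort.ids)

    def test_designs_share_identical_test_lists(self, tiny):
        cohort, plan = tiny
        tc = TrainConfig(max_epochs=2, seed=0)
        res = run_cross_validation(cohort, ["cph_clinical", "early_cph"], plan, tc)
        by_fold = {}
        for r in res:
            by_fold.setdefault(r.fold, []).append(r.test_ids)
        for lists in by_fold.values():
            assert all(l == lists[0] for l in lists)

    def test_leakage_guard_test_rows_never_touch_fitted_parameters(self, tiny):
        cohort, plan = tiny
        io_ref = _fold_inputs(cohort, plan, 0)
        # corrupt every test row's record and radiomics, refit
        import copy
        mutated = copy.deepcopy(cohort)
        for i in io_ref["test"]:
            mutated.records[i]["age"] = 999.0
            mutated.radiomics[i].values[:] = 1e9
        io_mut = _fold_inputs(mutated, plan, 0)
        assert io_ref["encoder"].numeric_range == io_mut.get("encoder").numeric_range
        assert np.array_equal(io_ref["vfilter"].hi, io_mut["vfilter"].hi)
        assert np.array_equal(io_ref["vfilter"].keep, io_mut["vfilter"].keep)
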