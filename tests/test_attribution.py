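"""Shapley attribution: axioms, estimator convergence, modality aggregates."""

import numpy as np
import pytest

from jeps.attribution import (AttributionReport, attribute_patient,
                              baseline_expectations, exact_shapley,
                              modality_influence, modality_log_ratio,
                              shapley_attribution, voxel_heatmap)


class LinearModel:
    """f(x) = w . clinical + sum(v * volume); closed-form Shapley values."""

    def __init__(self, w, v=None):
        self.w = np.asarray(w, dtype=float)
        self.v = v

    def predict(self, batch):
        out = np.zeros(len(next(iter(batch.values()))))
        if "clinical" in batch and self.w.size:
            out = out + np.asarray(batch["clinical"]).reshape(len(out), -1) @ self.w
        if "volume" in batch and self.v is not None:
            vol = np.asarray(batch["volume"]).reshape(len(out), -1)
            out = out + vol @ self.v.ravel()
        return out


class TestBaseline:
    def test_single_sample_is_itself(self, rng):
        x = rng.random((1, 4))
        base = baseline_expectations({"clinical": x})
        assert np.array_equal(base["clinical"], x[0])

    def test_two_samples_midpoint(self, rng):
        x = rng.random((2, 3, 3, 3, 3))
        base = baseline_expectations({"volume": x})
        assert np.allclose(base["volume"], (x[0] + x[1]) / 2)

    def test_mask_channel_mean_in_unit_interval(self, rng):
        vols = (rng.random((6, 2, 2, 2, 3)) > 0.5).astype(float)
        base = baseline_expectations({"volume": vols})
        assert base["volume"][..., 2].min() >= 0 and base["volume"][..., 2].max() <= 1


class TestEstimator:
    def test_additive_model_recovers_closed_form(self, rng):
        w = rng.normal(size=5)
        m = LinearModel(w)
        sample = {"clinical": rng.normal(size=5)}
        base = {"clinical": rng.normal(size=5)}
        res = shapley_attribution(m, sample, base, n_samples=32, seed=0, granularity=1)
        expected = w * (sample["clinical"] - base["clinical"])
        assert np.allclose(res["clinical"], expected, atol=1e-10)

    def test_matches_exact_enumeration_on_toy_model(self, rng):
        # non-additive model with 8 players: sampling vs full enumeration
        class Interacting:
            def predict(self, batch):
                x = np.asarray(batch["clinical"])
                return x[:, 0] * x[:, 1] + np.tanh(x[:, 2:]).sum(axis=1)

        m = Interacting()
        sample = {"clinical": rng.normal(size=8)}
        base = {"clinical": np.zeros(8)}
        exact = exact_shapley(m, sample, base)["clinical"]
        est = shapley_attribution(m, sample, base, n_samples=400, seed=1,
                                  granularity=1)["clinical"]
        assert np.allclose(est, exact, atol=0.05)

    def test_symmetric_players_get_equal_credit(self):
        class Dup:
            def predict(self, batch):
                x = np.asarray(batch["clinical"])
                return x[:, 0] + x[:, 1] + (x[:, 0] * x[:, 1])

        sample = {"clinical": np.array([1.0, 1.0])}
        base = {"clinical": np.array([0.0, 0.0])}
        res = exact_shapley(Dup(), sample, base)["clinical"]
        assert res[0] == pytest.approx(res[1])

    def test_dummy_player_gets_zero(self, rng):
        m = LinearModel(np.array([1.0, 0.0, 2.0]))
        sample = {"clinical": rng.normal(size=3)}
        base = {"clinical": np.zeros(3)}
        res = exact_shapley(m, sample, base)["clinical"]
        assert res[1] == pytest.approx(0.0, abs=1e-12)

    def test_efficiency_sum_equals_prediction_difference(self, rng):
        class NonLin:
            def predict(self, batch):
                x = np.asarray(batch["clinical"])
                return np.sin(x).sum(axis=1) + x[:, 0] * x[:, 1]

        m = NonLin()
        sample = {"clinical": rng.normal(size=6)}
        base = {"clinical": rng.normal(size=6)}
        res = shapley_attribution(m, sample, base, n_samples=64, seed=2,
                                  granularity=1)["clinical"]
        f_s = m.predict({"clinical": sample["clinical"][None]})[0]
        f_b = m.predict({"clinical": base["clinical"][None]})[0]
        # permutation sampling satisfies efficiency exactly per permutation
        assert res.sum() == pytest.approx(f_s - f_b, abs=1e-9)

    def test_volume_blocks_toggle_together(self, rng):
        v = rng.normal(size=(4, 4, 4, 3))
        m = LinearModel(np.zeros(0), v=np.ones((4, 4, 4, 3)))
        sample = {"volume": v}
        base = {"volume": np.zeros_like(v)}
        res = shapley_attribution(m, sample, base, n_samples=8, seed=0, granularity=2)
        assert res["volume_blocks"].shape == (2, 2, 2)
        block_sum = v[:2, :2, :2].sum()
        assert res["volume_blocks"][0, 0, 0] == pytest.approx(block_sum, abs=1e-9)

    def test_convergence_rate_with_sample_size(self, rng):
        class NonLin:
            def predict(self, batch):
                x = np.asarray(batch["clinical"])
                return np.tanh(x).prod(axis=1)

        m = NonLin()
        sample = {"clinical": rng.normal(size=4)}
        base = {"clinical": np.zeros(4)}
        exact = exact_shapley(m, sample, base)["clinical"]

        def err(n, reps=12):
            errs = []
            for s in range(reps):
                est = shapley_attribution(m, sample, base, n_samples=n, seed=100 + s,
                                          granularity=1)["clinical"]
                errs.append(np.linalg.norm(est - exact))
            return np.mean(errs)

        e_small, e_large = err(8), err(128)
        # 16x more samples should shrink error about 4x; allow generous slack
        assert e_large < e_small / 2

    def test_invalid_sample_count_rejected(self):
        with pytest.raises(ValueError):
            shapley_attribution(LinearModel([1.0]), {"clinical": np.ones(1)},
                                {"clinical": np.zeros(1)}, n_samples=0)


class TestModalityAggregates:
    def test_model_ignoring_clinical_has_zero_clinical_influence(self, rng):
        v = rng.normal(size=(2, 2, 2, 3))
        m = LinearModel(np.zeros(3), v=np.ones((2, 2, 2, 3)))
        rep = attribute_patient(m, {"clinical": rng.normal(size=3), "volume": v},
                                {"clinical": np.zeros(3), "volume": np.zeros_like(v)},
                                n_samples=16, granularity=1, seed=0)
        clin, vol = modality_influence(rep)
        assert clin == pytest.approx(0.0, abs=1e-12)
        assert vol > 0

    def test_output_scaling_scales_both_aggregates(self, rng):
        w = rng.normal(size=3)
        v = rng.normal(size=(2, 2, 2, 3))
        sample = {"clinical": rng.normal(size=3), "volume": rng.normal(size=(2, 2, 2, 3))}
        base = {"clinical": np.zeros(3), "volume": np.zeros((2, 2, 2, 3))}
        r1 = attribute_patient(LinearModel(w, v), sample, base, n_samples=8,
                               granularity=2, seed=3)
        r3 = attribute_patient(LinearModel(3 * w, 3 * v), sample, base, n_samples=8,
                               granularity=2, seed=3)
        assert r3.clinical_aggregate == pytest.approx(3 * r1.clinical_aggregate)
        assert r3.volume_aggregate == pytest.approx(3 * r1.volume_aggregate)

    def test_log_ratio_zero_when_balanced(self):
        rep = AttributionReport("p", np.array([0.5, -0.5]),
                                np.array([[[0.4, -0.6]]]), 1, 8, 0)
        assert modality_log_ratio(rep) == pytest.approx(0.0)


class TestHeatmap:
    def make_report(self, blocks):
        return AttributionReport("p", np.zeros(2), np.asarray(blocks, float), 2, 8, 0)

    def test_single_report_heatmap_is_itself(self, rng):
        b = rng.normal(size=(3, 4, 5))
        heat, views = voxel_heatmap([self.make_report(b)])
        assert np.array_equal(heat, b)
        assert views["axial"].shape == (4, 5)
        assert views["coronal"].shape == (3, 5)
        assert views["sagittal"].shape == (3, 4)

    def test_zero_attributions_zero_views(self):
        heat, views = voxel_heatmap([self.make_report(np.zeros((2, 2, 2)))] * 3)
        assert not heat.any()
        assert all(not v.any() for v in views.values())

    def test_hot_block_appears_in_all_views(self):
        b = np.zeros((4, 4, 4))
        b[1, 2, 3] = 5.0
        _, views = voxel_heatmap([self.make_report(b)])
        assert np.unravel_index(views["axial"].argmax(), (4, 4)) == (2, 3)
        assert np.unravel_index(views["coronal"].argmax(), (4, 4)) == (1, 3)
        assert np.unravel_index(views["sagittal"].argmax(), (4, 4)) == (1, 2)

    def test_mixed_granularity_rejected(self):
        r1 = self.make_report(np.zeros((2, 2, 2)))
        r2 = AttributionReport("q", np.zeros(2), np.zeros((2, 2, 2)), 4, 8, 0)
        with pytest.raises(ValueError, match="granular"):
            voxel_heatmap([r1, r2])
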