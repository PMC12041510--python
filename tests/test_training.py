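"""The masked multivariate pinball loss and the training loop."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import vitalcast as vc
from vitalcast.exceptions import DataError, ParameterError, ShapeError
from vitalcast.training import (
    TrainingConfig,
    masked_multivariate_loss,
    quantile_loss,
    train,
)

from conftest import rand_loss_instance


def loss_by_nested_loops(truth, forecasts, masks, quantiles):
    """Literal transcription of the loss definition: explicit loops over
    samples, variables, quantiles and steps.  Kept deliberately naive to
    serve as an independent oracle for the vectorized implementation."""
    B, H, T = truth.shape
    total = 0.0
    for i in range(B):
        for v in range(T):
            for q in quantiles:
                num = 0.0
                den = 0.0
                for t in range(H):
                    if masks[i, t, v] == 1:
                        y = truth[i, t, v]
                        yh = forecasts[i, t, v, quantiles.index(q)]
                        num += q * max(0.0, y - yh) + (1 - q) * max(0.0, yh - y)
                        den += 1
                if den > 0:
                    total += num / den
    return total / B


class TestQuantileLoss:
    def test_spot_values(self):
        assert quantile_loss(10, 8, 0.9) == pytest.approx(1.8)
        assert quantile_loss(10, 8, 0.1) == pytest.approx(0.2)
        assert quantile_loss(3.7, 3.7, 0.5) == 0.0

    @pytest.mark.parametrize("q", [0.0, 1.0, -0.5, 1.5])
    def test_quantile_level_outside_unit_interval_rejected(self, q):
        with pytest.raises(ParameterError):
            quantile_loss(1.0, 0.0, q)

    @settings(derandomize=True, max_examples=50)
    @given(
        y=st.floats(-100, 100),
        yhat=st.floats(-100, 100),
        q=st.floats(0.01, 0.99),
    )
    def test_nonnegative_and_zero_iff_equal(self, y, yhat, q):
        val = quantile_loss(y, yhat, q)
        assert val >= 0
        if y != yhat:
            assert val > 0
        assert quantile_loss(y, y, q) == 0.0


class TestMaskedLoss:
    def test_worked_two_variable_example(self):
        """Two variables, one quantile, horizon 2: per-variable terms
        (0.5+0.5)/2 and (0.5*2)/1 total 1.5."""
        truth = np.array([[[2.0, 10.0], [4.0, -1.0]]])  # (1, 2, 2)
        forecasts = np.array([[[[3.0], [8.0]], [[3.0], [99.0]]]])  # (1, 2, 2, 1)
        masks = np.array([[[1.0, 1.0], [1.0, 0.0]]])
        val = masked_multivariate_loss(truth, forecasts, masks, [0.5])
        assert val == pytest.approx(1.5)

    def test_perturbing_masked_steps_changes_nothing(self):
        rng = np.random.default_rng(0)
        truth, forecasts, masks = rand_loss_instance(rng)
        base = masked_multivariate_loss(truth, forecasts, masks, (0.1, 0.5, 0.9))
        forecasts2 = forecasts.copy()
        forecasts2[masks == 0] = 1e9
        truth2 = truth.copy()
        truth2[masks == 0] = -1e9
        assert masked_multivariate_loss(truth2, forecasts2, masks, (0.1, 0.5, 0.9)) == base

    def test_matches_nested_loop_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            truth, forecasts, masks = rand_loss_instance(rng)
            fast = masked_multivariate_loss(truth, forecasts, masks, (0.1, 0.5, 0.9))
            slow = loss_by_nested_loops(truth, forecasts, masks, [0.1, 0.5, 0.9])
            assert fast == pytest.approx(slow, abs=1e-6)

    def test_all_ones_mask_equals_unmasked_loss(self):
        rng = np.random.default_rng(1)
        truth, forecasts, _ = rand_loss_instance(rng, Q=1)
        masks = np.ones_like(truth)
        val = masked_multivariate_loss(truth, forecasts, masks, (0.5,))
        H = truth.shape[1]
        plain = np.mean(
            np.sum(quantile_loss(truth, forecasts[..., 0], 0.5).sum(axis=1) / H, axis=1)
        )
        assert val == pytest.approx(plain)

    def test_zero_mask_variable_contributes_zero_not_nan(self):
        truth = np.zeros((1, 3, 2))
        forecasts = np.ones((1, 3, 2, 1))
        masks = np.zeros((1, 3, 2))
        masks[0, :, 0] = 1
        val = masked_multivariate_loss(truth, forecasts, masks, [0.5])
        assert np.isfinite(val) and val == pytest.approx(0.5)

    def test_zero_iff_exact_on_real_steps(self):
        rng = np.random.default_rng(2)
        truth, _, masks = rand_loss_instance(rng)
        forecasts = np.repeat(truth[..., None], 3, axis=-1)
        assert masked_multivariate_loss(truth, forecasts, masks, (0.1, 0.5, 0.9)) == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            masked_multivariate_loss(np.zeros((1, 2, 2)), np.zeros((1, 2, 2, 3)), np.zeros((1, 2, 1)), (0.5,))


def test_grid_minimizer_recovers_normal_quantiles():
    """The constant minimizing mean pinball loss over N(0,1) draws is the
    corresponding normal quantile (+-0.05 at n=10,000)."""
    rng = np.random.default_rng(0)
    y = rng.normal(size=10_000)
    grid = np.arange(-3.0, 3.0, 0.01)
    for q, target in ((0.9, 1.2816), (0.1, -1.2816)):
        means = [quantile_loss(y, c, q).mean() for c in grid]
        best = grid[int(np.argmin(means))]
        assert abs(best - target) <= 0.05


class TestTrainLoop:
    def test_zero_learning_rate_leaves_parameters_unchanged(self, small_windows):
        ws, train_ids, *_ = small_windows
        cfg = vc.ModelConfig.from_windowset(ws, state_size=16, dropout=0.1)
        model = vc.TFTMulti(cfg, seed=0)
        before = {k: v.copy() for k, v in model.state_dict().items()}
        tcfg = TrainingConfig(learning_rate=0.0, batch_size=32, max_epochs=1, seed=0)
        model, _ = train(model, ws.for_subjects(train_ids), tcfg)
        after = model.state_dict()
        for k in before:
            np.testing.assert_array_equal(before[k], after[k])

    def test_loss_decreases_on_small_fixture(self, small_windows):
        ws, train_ids, *_ = small_windows
        cfg = vc.ModelConfig.from_windowset(ws, state_size=16, dropout=0.1)
        model = vc.TFTMulti(cfg, seed=1)
        tcfg = TrainingConfig(batch_size=32, max_epochs=5, learning_rate=5e-3, seed=1)
        model, hist = train(model, ws.for_subjects(train_ids), tcfg)
        assert hist.val_loss[-1] < hist.val_loss[0]
        assert len(hist.train_loss) <= 5

    def test_early_stop_contract(self, small_windows):
        """If training stopped early, the last `patience` validation losses
        each exceed their predecessor."""
        ws, train_ids, *_ = small_windows
        cfg = vc.ModelConfig.from_windowset(ws, state_size=8, n_heads=2, dropout=0.0)
        model = vc.TFTMulti(cfg, seed=2)
        # huge lr destabilizes quickly, provoking the rising-loss rule
        tcfg = TrainingConfig(batch_size=32, max_epochs=40, learning_rate=0.5, patience=3, seed=2)
        model, hist = train(model, ws.for_subjects(train_ids), tcfg)
        assert len(hist.val_loss) <= 40
        if hist.stopped_early:
            tail = hist.val_loss[-4:]
            assert all(b > a for a, b in zip(tail, tail[1:]))

    def test_empty_training_set_rejected(self, small_windows):
        ws, *_ = small_windows
        cfg = vc.ModelConfig.from_windowset(ws, state_size=16)
        model = vc.TFTMulti(cfg, seed=0)
        with pytest.raises(DataError):
            train(model, ws.for_subjects([]), TrainingConfig())

    @pytest.mark.parametrize(
        "bad",
        [dict(patience=0), dict(validation_fraction=0.0), dict(validation_fraction=1.0)],
    )
    def test_invalid_training_config_rejected(self, bad):
        with pytest.raises(ParameterError):
            TrainingConfig(**bad)
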