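"""Architecture contracts: shapes, determinism, symmetry, gradient flow."""

import numpy as np
import pytest

from vitalcast import nn
from vitalcast.exceptions import ConfigurationError, ShapeError
from vitalcast.model import ModelConfig, TFTMulti

FIVE = ("meanbp", "pulse", "spo2", "resp", "temp")
NORM = {t: (0.0, 1.0) for t in FIVE}


def make_config(**overrides):
    base = dict(
        targets=FIVE,
        state_size=16,
        n_heads=2,
        dropout=0.1,
        static_dim=4,
        past_dim=7,
        future_dim=1,
        binary_past=(False,) * 5 + (True, False),
        binary_future=(False,),
        binary_static=(True,) * 4,
        normalization=dict(NORM),
    )
    base.update(overrides)
    return ModelConfig(**base)


def make_batch(rng, B, cfg):
    past = rng.normal(size=(B, cfg.past_len, cfg.past_dim))
    for j, b in enumerate(cfg.binary_past):
        if b:
            past[:, :, j] = (past[:, :, j] > 0).astype(float)
    fut = rng.normal(size=(B, cfg.horizon, cfg.future_dim))
    stat = (rng.normal(size=(B, cfg.static_dim)) > 0).astype(float)
    return past, fut, stat


class TestConfig:
    def test_output_head_width_is_targets_times_quantiles(self):
        model = TFTMulti(make_config(), seed=0)
        assert model.params["head.W"].data.shape[1] == 15

    def test_heads_must_divide_state_size(self):
        make_config(n_heads=3, state_size=240)  # valid
        with pytest.raises(ConfigurationError):
            make_config(n_heads=7, state_size=240)

    def test_quantiles_must_increase_within_unit_interval(self):
        with pytest.raises(ConfigurationError):
            make_config(quantiles=(0.5, 0.1, 0.9))
        with pytest.raises(ConfigurationError):
            make_config(quantiles=(0.0, 0.5, 0.9))

    def test_reference_defaults(self):
        cfg = ModelConfig()
        assert cfg.quantiles == (0.1, 0.5, 0.9)
        assert (cfg.past_len, cfg.horizon) == (75, 25)
        assert (cfg.state_size, cfg.n_heads, cfg.dropout) == (240, 2, 0.3)


class TestForward:
    def test_batch_output_shape(self):
        cfg = make_config()
        model = TFTMulti(cfg, seed=0)
        past, fut, stat = make_batch(np.random.default_rng(0), 2, cfg)
        res = model.forward(past, fut, stat)
        assert res.raw.shape == (2, 25, 5, 3)

    def test_same_seed_identical_parameters(self):
        a = TFTMulti(make_config(), seed=3)
        b = TFTMulti(make_config(), seed=3)
        for k in a.params:
            np.testing.assert_array_equal(a.params[k].data, b.params[k].data)

    def test_eval_mode_is_deterministic(self):
        cfg = make_config()
        model = TFTMulti(cfg, seed=0)
        past, fut, stat = make_batch(np.random.default_rng(1), 3, cfg)
        r1 = model.forward(past, fut, stat, training=False)
        r2 = model.forward(past, fut, stat, training=False)
        np.testing.assert_array_equal(r1.raw.data, r2.raw.data)

    def test_dimension_mismatch_names_role(self):
        cfg = make_config()
        model = TFTMulti(cfg, seed=0)
        past, fut, stat = make_batch(np.random.default_rng(1), 2, cfg)
        with pytest.raises(ShapeError, match="past"):
            model.forward(past[:, :50, :], fut, stat)
        with pytest.raises(ShapeError, match="future"):
            model.forward(past, fut[:, :10, :], stat)
        with pytest.raises(ShapeError, match="static"):
            model.forward(past, fut, stat[:, :2])

    def test_selection_weights_are_probability_vectors(self):
        cfg = make_config()
        model = TFTMulti(cfg, seed=0)
        past, fut, stat = make_batch(np.random.default_rng(2), 4, cfg)
        res = model.forward(past, fut, stat)
        for w in (res.sel_past, res.sel_future, res.sel_static):
            assert np.all(w >= 0)
            assert np.allclose(w.sum(axis=-1), 1.0, atol=1e-5)

    def test_predict_sorts_quantile_axis(self, small_windows, tiny_model):
        ws, *_ = small_windows
        fs = tiny_model.predict(ws.subset(range(4)))
        assert np.all(np.diff(fs.values, axis=-1) >= 0)

    def test_gradient_reaches_every_parameter(self):
        """No dead branch: a random batch with a full loss touches all
        parameters."""
        cfg = make_config()
        model = TFTMulti(cfg, seed=0)
        past, fut, stat = make_batch(np.random.default_rng(3), 4, cfg)
        res = model.forward(past, fut, stat, training=False)
        loss = nn.mean_(nn.mul(res.raw, res.raw))
        loss.backward()
        dead = [k for k, p in model.params.items() if p.grad is None or not np.any(p.grad)]
        assert dead == []


def _swap_past_params(model, j1, j2, k, d):
    """Swap every parameter tied to past covariates j1 and j2."""
    P = model.params

    def swap(a, b):
        P[a].data, P[b].data = P[b].data.copy(), P[a].data.copy()

    swap(f"proj.past{j1}.W", f"proj.past{j2}.W")
    swap(f"proj.past{j1}.b", f"proj.past{j2}.b")
    for suffix in ("W2", "b2", "W1", "b1", "W4", "b4", "W5", "b5", "ln_g", "ln_b"):
        swap(f"vsn_past.var{j1}.{suffix}", f"vsn_past.var{j2}.{suffix}")
    # selection GRN: swap input row-blocks and output coordinates
    sel = "vsn_past.sel"
    perm_in = np.arange(k * d)
    block1, block2 = slice(j1 * d, (j1 + 1) * d), slice(j2 * d, (j2 + 1) * d)
    perm_in[block1], perm_in[block2] = np.arange(j2 * d, (j2 + 1) * d), np.arange(j1 * d, (j1 + 1) * d)
    perm_out = np.arange(k)
    perm_out[[j1, j2]] = [j2, j1]
    P[f"{sel}.W2"].data = P[f"{sel}.W2"].data[perm_in]
    P[f"{sel}.W1"].data = P[f"{sel}.W1"].data[:, perm_out]
    P[f"{sel}.b1"].data = P[f"{sel}.b1"].data[perm_out]
    for w in ("W4", "W5"):
        P[f"{sel}.{w}"].data = P[f"{sel}.{w}"].data[perm_out][:, perm_out]
    for b in ("b4", "b5", "ln_g", "ln_b"):
        P[f"{sel}.{b}"].data = P[f"{sel}.{b}"].data[perm_out]
    P[f"{sel}.Ws"].data = P[f"{sel}.Ws"].data[perm_in][:, perm_out]


def test_past_covariate_permutation_symmetry():
    """Swapping two continuous non-target past covariates together with
    their per-variable parameters leaves the forecast unchanged: the
    architecture is symmetric up to per-variable parameters."""
    cfg = make_config(
        past_dim=8,
        binary_past=(False,) * 8,  # all continuous so the swap maps cleanly
    )
    model = TFTMulti(cfg, seed=5)
    rng = np.random.default_rng(5)
    past, fut, stat = make_batch(rng, 3, cfg)
    base = model.forward(past, fut, stat).raw.data.copy()

    j1, j2 = 5, 7  # two non-target covariates
    _swap_past_params(model, j1, j2, k=8, d=cfg.state_size)
    past_sw = past.copy()
    past_sw[:, :, [j1, j2]] = past[:, :, [j2, j1]]
    swapped = model.forward(past_sw, fut, stat).raw.data
    np.testing.assert_allclose(swapped, base, atol=1e-10)


def test_checkpoint_roundtrip(tmp_path, small_windows, tiny_model):
    ws, *_ = small_windows
    tiny_model.save(tmp_path)
    back = TFTMulti.load(tmp_path)
    sub = ws.subset(range(3))
    np.testing.assert_array_equal(back.predict(sub).values, tiny_model.predict(sub).values)
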