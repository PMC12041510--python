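"""The joint multi-target temporal fusion transformer.

A temporal fusion transformer (TFT) consumes three kinds of inputs --
static covariates, past time series, and known-future time series -- and
emits multi-horizon quantile forecasts.  The network here follows the
standard TFT data flow:

* per-variable projections (linear maps for continuous channels, learned
  embeddings for binary ones) to a common ``state_size`` width;
* a static covariate encoder producing four context vectors (variable
  selection, recurrent initial state x2, enrichment);
* variable-selection networks over static, past, and future inputs, whose
  softmax weights double as per-feature importance;
* an LSTM sequence-to-sequence pair over past/future positions with a gated
  residual skip;
* static enrichment, interpretable multi-head attention (per-head queries
  and keys, shared values, head-averaged output) with a causal mask, and a
  position-wise feed-forward block;
* one output head mapping each future step's representation to
  ``len(targets) * len(quantiles)`` values at once, so all target channels
  and all quantiles come out of a single forward pass.

Training leaves the quantile axis unconstrained (the pinball objective is
applied per quantile); at inference the quantile axis is sorted
non-decreasing per (step, target) so the 10-90 band is always usable as a
prediction interval.

Targets are modelled on the z-scored scale; :meth:`TFTMulti.predict`
inverts the stored normalization so forecasts are reported in clinical
units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .exceptions import ConfigurationError, ShapeError
from .prep import WindowSet

__all__ = ["ModelConfig", "ForecastSet", "TFTMulti"]

DEFAULT_QUANTILES = (0.1, 0.5, 0.9)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    Defaults mirror the reference configuration for the full-scale clinical
    cohort: state size 240, 2 attention heads, dropout 0.3, a 75-bin past
    (18.75 h at 15-minute bins) and a 25-bin horizon (6.25 h).  Fixture-
    scale runs shrink ``state_size``.
    """

    targets: tuple[str, ...] = ("meanbp", "pulse", "spo2", "resp", "temp")
    quantiles: tuple[float, ...] = DEFAULT_QUANTILES
    past_len: int = 75
    horizon: int = 25
    state_size: int = 240
    n_heads: int = 2
    dropout: float = 0.3
    static_dim: int = 1
    past_dim: int = 6
    future_dim: int = 1
    binary_past: tuple[bool, ...] = ()
    binary_future: tuple[bool, ...] = ()
    binary_static: tuple[bool, ...] = ()
    normalization: dict = field(default_factory=dict)

    def __post_init__(self):
        q = tuple(self.quantiles)
        if any(not (0.0 < x < 1.0) for x in q) or any(b <= a for a, b in zip(q, q[1:])):
            raise ConfigurationError("quantiles must be strictly increasing, each in (0, 1)")
        if self.horizon < 1:
            raise ConfigurationError("horizon must be >= 1")
        if self.past_len < 1:
            raise ConfigurationError("past_len must be >= 1")
        if self.state_size % self.n_heads != 0:
            raise ConfigurationError(
                f"state_size ({self.state_size}) must be divisible by n_heads ({self.n_heads})"
            )
        if not (0.0 <= self.dropout < 1.0):
            raise ConfigurationError("dropout must lie in [0, 1)")
        for name, dim in (("static_dim", self.static_dim), ("past_dim", self.past_dim), ("future_dim", self.future_dim)):
            if dim < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        object.__setattr__(self, "targets", tuple(self.targets))
        object.__setattr__(self, "quantiles", q)
        bp = tuple(self.binary_past) or (False,) * self.past_dim
        bf = tuple(self.binary_future) or (False,) * self.future_dim
        bs = tuple(self.binary_static) or (False,) * self.static_dim
        object.__setattr__(self, "binary_past", bp)
        object.__setattr__(self, "binary_future", bf)
        object.__setattr__(self, "binary_static", bs)

    @classmethod
    def from_windowset(cls, ws: WindowSet, **overrides) -> "ModelConfig":
        base = dict(
            targets=tuple(ws.schema.targets),
            past_len=ws.past_len,
            horizon=ws.horizon,
            static_dim=ws.static.shape[1],
            past_dim=ws.past.shape[2],
            future_dim=ws.known_future.shape[2],
            binary_past=ws.binary_past,
            binary_future=ws.binary_future,
            binary_static=ws.binary_static,
            normalization=dict(ws.normalization),
        )
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        for k in ("targets", "quantiles", "binary_past", "binary_future", "binary_static"):
            d[k] = list(d[k])
        d["normalization"] = {k: list(v) for k, v in self.normalization.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for k in ("targets", "quantiles", "binary_past", "binary_future", "binary_static"):
            d[k] = tuple(d[k])
        d["normalization"] = {k: tuple(v) for k, v in d["normalization"].items()}
        return cls(**d)


@dataclass
class ForecastSet:
    """Quantile forecasts for a batch of windows, in clinical units.

    ``values`` is (n_windows, horizon, n_targets, n_quantiles), sorted
    non-decreasing along the quantile axis.  ``attention`` is the per-head
    future->(past+future) attention map; the ``selection_*`` arrays are the
    softmax variable-selection weights that interpretability aggregates.
    """

    values: np.ndarray
    quantiles: tuple[float, ...]
    targets: tuple[str, ...]
    subject_ids: list[str]
    attention: np.ndarray  # (n_windows, n_heads, horizon, past_len + horizon)
    selection_past: np.ndarray  # (n_windows, past_len, past_dim)
    selection_future: np.ndarray  # (n_windows, horizon, future_dim)
    selection_static: np.ndarray  # (n_windows, static_dim)

    def quantile(self, q: float) -> np.ndarray:
        """The (n_windows, horizon, n_targets) trajectory at quantile q."""
        return self.values[:, :, :, self.quantiles.index(q)]

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.savez(
            out / "forecasts.npz",
            values=self.values,
            attention=self.attention,
            selection_past=self.selection_past,
            selection_future=self.selection_future,
            selection_static=self.selection_static,
        )
        meta = {
            "quantiles": list(self.quantiles),
            "targets": list(self.targets),
            "subject_ids": self.subject_ids,
        }
        (out / "forecasts_meta.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, in_dir: str | Path) -> "ForecastSet":
        path = Path(in_dir)
        arrs = np.load(path / "forecasts.npz")
        meta = json.loads((path / "forecasts_meta.json").read_text())
        return cls(
            values=arrs["values"],
            quantiles=tuple(meta["quantiles"]),
            targets=tuple(meta["targets"]),
            subject_ids=meta["subject_ids"],
            attention=arrs["attention"],
            selection_past=arrs["selection_past"],
            selection_future=arrs["selection_future"],
            selection_static=arrs["selection_static"],
        )


class _GRN:
    """Gated residual network: dense -> ELU -> dense -> GLU, residual + LN."""

    def __init__(self, model: "TFTMulti", name: str, d_in: int, d_out: int, d_hidden: int, context: bool):
        self.m = model
        self.d_in, self.d_out = d_in, d_out
        p = model._new_param
        self.W2 = p(f"{name}.W2", (d_in, d_hidden))
        self.b2 = p(f"{name}.b2", (d_hidden,), zero=True)
        self.Wc = p(f"{name}.Wc", (model.config.state_size, d_hidden)) if context else None
        self.W1 = p(f"{name}.W1", (d_hidden, d_out))
        self.b1 = p(f"{name}.b1", (d_out,), zero=True)
        self.W4 = p(f"{name}.W4", (d_out, d_out))
        self.b4 = p(f"{name}.b4", (d_out,), zero=True)
        self.W5 = p(f"{name}.W5", (d_out, d_out))
        self.b5 = p(f"{name}.b5", (d_out,), zero=True)
        self.Ws = p(f"{name}.Ws", (d_in, d_out)) if d_in != d_out else None
        self.gamma = p(f"{name}.ln_g", (d_out,), one=True)
        self.beta = p(f"{name}.ln_b", (d_out,), zero=True)

    def __call__(self, x: nn.Tensor, context: nn.Tensor | None = None) -> nn.Tensor:
        eta2 = nn.linear(x, self.W2, self.b2)
        if context is not None:
            if self.Wc is None:
                raise ConfigurationError("GRN built without context support")
            eta2 = nn.add(eta2, nn.linear(context, self.Wc))
        a = nn.elu(eta2)
        eta1 = nn.linear(a, self.W1, self.b1)
        eta1 = self.m._dropout(eta1)
        glu = nn.mul(nn.sigmoid(nn.linear(eta1, self.W4, self.b4)), nn.linear(eta1, self.W5, self.b5))
        skip = x if self.Ws is None else nn.linear(x, self.Ws)
        return nn.layer_norm(nn.add(skip, glu), self.gamma, self.beta)


class _GateAddNorm:
    """GLU gate on the sublayer output, residual add, layer norm."""

    def __init__(self, model: "TFTMulti", name: str, d: int):
        p = model._new_param
        self.m = model
        self.W4 = p(f"{name}.W4", (d, d))
        self.b4 = p(f"{name}.b4", (d,), zero=True)
        self.W5 = p(f"{name}.W5", (d, d))
        self.b5 = p(f"{name}.b5", (d,), zero=True)
        self.gamma = p(f"{name}.ln_g", (d,), one=True)
        self.beta = p(f"{name}.ln_b", (d,), zero=True)

    def __call__(self, sub: nn.Tensor, skip: nn.Tensor) -> nn.Tensor:
        sub = self.m._dropout(sub)
        glu = nn.mul(nn.sigmoid(nn.linear(sub, self.W4, self.b4)), nn.linear(sub, self.W5, self.b5))
        return nn.layer_norm(nn.add(skip, glu), self.gamma, self.beta)


class _VSN:
    """Variable selection: per-variable GRNs + a softmax selection GRN."""

    def __init__(self, model: "TFTMulti", name: str, k: int, context: bool):
        d = model.config.state_size
        self.k = k
        # with one variable the softmax weight is identically 1, so a
        # selection GRN would be a dead branch; skip building it
        self.sel = _GRN(model, f"{name}.sel", k * d, k, d, context=context) if k > 1 else None
        self.var_grns = [_GRN(model, f"{name}.var{j}", d, d, d, context=False) for j in range(k)]

    def __call__(
        self, embs: list[nn.Tensor], context: nn.Tensor | None = None
    ) -> tuple[nn.Tensor, nn.Tensor]:
        if self.sel is None:
            combined = self.var_grns[0](embs[0])
            weights = nn.const(np.ones(embs[0].shape[:-1] + (1,)))
            return combined, weights
        flat = nn.concat(embs, axis=-1)
        weights = nn.softmax(self.sel(flat, context), axis=-1)  # (..., k)
        combined = None
        for j, grn in enumerate(self.var_grns):
            wj = nn.slice_axis(weights, weights.ndim - 1, j, 1)
            term = nn.mul(wj, grn(embs[j]))
            combined = term if combined is None else nn.add(combined, term)
        return combined, weights


@dataclass
class _ForwardResult:
    raw: nn.Tensor  # (B, horizon, T, Q) on the z-scored scale
    attention: np.ndarray
    sel_past: np.ndarray
    sel_future: np.ndarray
    sel_static: np.ndarray


class TFTMulti:
    """The network.  Deterministic initialization and forward under seeds."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        self._init_rng = np.random.default_rng(seed)
        self.params: dict[str, nn.Tensor] = {}
        self._drop_rng: np.random.Generator | None = None
        self._training = False
        self._build()

    # -- parameter management -------------------------------------------------
    def _new_param(self, name: str, shape: tuple[int, ...], zero=False, one=False) -> nn.Tensor:
        if name in self.params:
            return self.params[name]
        if zero:
            data = np.zeros(shape)
        elif one:
            data = np.ones(shape)
        else:
            fan_in = shape[0] if len(shape) > 1 else shape[0]
            fan_out = shape[-1]
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            data = self._init_rng.uniform(-lim, lim, size=shape)
        t = nn.param(data)
        self.params[name] = t
        return t

    def parameters(self) -> list[nn.Tensor]:
        return [self.params[k] for k in sorted(self.params)]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self.params[k].data = np.array(v, dtype=np.float64)

    def _dropout(self, x: nn.Tensor) -> nn.Tensor:
        if self._training and self._drop_rng is not None:
            return nn.dropout(x, self.config.dropout, self._drop_rng, True)
        return x

    # -- construction ---------------------------------------------------------
    def _build(self) -> None:
        c = self.config
        d = c.state_size
        p = self._new_param
        # per-variable input transforms
        for j in range(c.past_dim):
            if c.binary_past[j]:
                p(f"emb.past{j}", (2, d))
            else:
                p(f"proj.past{j}.W", (1, d))
                p(f"proj.past{j}.b", (d,), zero=True)
        for j in range(c.future_dim):
            if c.binary_future[j]:
                p(f"emb.future{j}", (2, d))
            else:
                p(f"proj.future{j}.W", (1, d))
                p(f"proj.future{j}.b", (d,), zero=True)
        for j in range(c.static_dim):
            if c.binary_static[j]:
                p(f"emb.static{j}", (2, d))
            else:
                p(f"proj.static{j}.W", (1, d))
                p(f"proj.static{j}.b", (d,), zero=True)

        self.vsn_static = _VSN(self, "vsn_static", c.static_dim, context=False)
        self.ctx_selection = _GRN(self, "ctx_sel", d, d, d, context=False)
        self.ctx_enrich = _GRN(self, "ctx_enr", d, d, d, context=False)
        self.ctx_h = _GRN(self, "ctx_h", d, d, d, context=False)
        self.ctx_c = _GRN(self, "ctx_c", d, d, d, context=False)
        self.vsn_past = _VSN(self, "vsn_past", c.past_dim, context=True)
        self.vsn_future = _VSN(self, "vsn_future", c.future_dim, context=True)

        for tag in ("enc", "dec"):
            p(f"lstm.{tag}.Wx", (d, 4 * d))
            p(f"lstm.{tag}.Wh", (d, 4 * d))
            p(f"lstm.{tag}.b", (4 * d,), zero=True)
        self.gate_lstm = _GateAddNorm(self, "gate_lstm", d)
        self.enrich = _GRN(self, "enrich", d, d, d, context=True)

        d_att = d // c.n_heads
        for h in range(c.n_heads):
            p(f"attn.Wq{h}", (d, d_att))
            p(f"attn.Wk{h}", (d, d_att))
        p("attn.Wv", (d, d_att))
        p("attn.Wo", (d_att, d))
        self.gate_attn = _GateAddNorm(self, "gate_attn", d)
        self.ff = _GRN(self, "ff", d, d, d, context=False)
        self.gate_ff = _GateAddNorm(self, "gate_ff", d)

        n_out = len(c.targets) * len(c.quantiles)
        p("head.W", (d, n_out))
        p("head.b", (n_out,), zero=True)

    # -- forward --------------------------------------------------------------
    def _embed_group(self, x: np.ndarray, group: str, binary: Sequence[bool]) -> list[nn.Tensor]:
        """Project each channel of x (..., k) to (..., d)."""
        embs = []
        for j, isbin in enumerate(binary):
            xj = x[..., j]
            if isbin:
                idx = np.clip(np.round(xj).astype(int), 0, 1)
                embs.append(nn.embedding(self.params[f"emb.{group}{j}"], idx))
            else:
                col = nn.const(xj[..., None])
                embs.append(
                    nn.linear(col, self.params[f"proj.{group}{j}.W"], self.params[f"proj.{group}{j}.b"])
                )
        return embs

    def _lstm_run(self, tag: str, seq: nn.Tensor, h0: nn.Tensor, c0: nn.Tensor):
        Wx = self.params[f"lstm.{tag}.Wx"]
        Wh = self.params[f"lstm.{tag}.Wh"]
        b = self.params[f"lstm.{tag}.b"]
        B, L, d = seq.shape
        h, c = h0, c0
        outs = []
        for t in range(L):
            xt = nn.reshape(nn.slice_axis(seq, 1, t, 1), (B, d))
            h, c = nn.lstm_cell(xt, h, c, Wx, Wh, b)
            outs.append(nn.reshape(h, (B, 1, d)))
        return nn.concat(outs, axis=1), h, c

    def forward(
        self,
        past: np.ndarray,
        known_future: np.ndarray,
        static: np.ndarray,
        training: bool = False,
        dropout_rng: np.random.Generator | None = None,
    ) -> _ForwardResult:
        """One pass over a batch; returns z-scale quantile outputs and weights."""
        c = self.config
        B = past.shape[0]
        if past.shape[1] != c.past_len or past.shape[2] != c.past_dim:
            raise ShapeError(
                f"past inputs shaped {past.shape[1:]}, expected ({c.past_len}, {c.past_dim})"
            )
        if known_future.shape[1] != c.horizon or known_future.shape[2] != c.future_dim:
            raise ShapeError(
                f"known-future inputs shaped {known_future.shape[1:]}, expected ({c.horizon}, {c.future_dim})"
            )
        if static.shape[1] != c.static_dim:
            raise ShapeError(f"static inputs shaped {static.shape[1:]}, expected ({c.static_dim},)")
        self._training = training
        self._drop_rng = dropout_rng
        d = c.state_size
        L, H = c.past_len, c.horizon

        static_embs = self._embed_group(static, "static", c.binary_static)
        static_enc, w_static = self.vsn_static(static_embs)
        c_sel = self.ctx_selection(static_enc)
        c_enr = self.ctx_enrich(static_enc)
        c_h = self.ctx_h(static_enc)
        c_c = self.ctx_c(static_enc)

        c_sel_t = nn.reshape(c_sel, (B, 1, d))
        past_embs = self._embed_group(past, "past", c.binary_past)
        past_in, w_past = self.vsn_past(past_embs, context=c_sel_t)
        fut_embs = self._embed_group(known_future, "future", c.binary_future)
        fut_in, w_future = self.vsn_future(fut_embs, context=c_sel_t)

        enc_seq, h_n, c_n = self._lstm_run("enc", past_in, c_h, c_c)
        dec_seq, _, _ = self._lstm_run("dec", fut_in, h_n, c_n)
        lstm_seq = nn.concat([enc_seq, dec_seq], axis=1)
        temporal_in = nn.concat([past_in, fut_in], axis=1)
        phi = self.gate_lstm(lstm_seq, temporal_in)

        c_enr_t = nn.reshape(c_enr, (B, 1, d))
        theta = self.enrich(phi, context=c_enr_t)

        # interpretable multi-head attention over all positions, causal mask
        d_att = d // c.n_heads
        queries = nn.slice_axis(theta, 1, L, H)
        V = nn.linear(theta, self.params["attn.Wv"])
        mask = np.zeros((H, L + H))
        for i in range(H):
            mask[i, L + i + 1 :] = -1e9
        head_sum = None
        attn_maps = []
        for hidx in range(c.n_heads):
            Q = nn.linear(queries, self.params[f"attn.Wq{hidx}"])
            K = nn.linear(theta, self.params[f"attn.Wk{hidx}"])
            scores = nn.matmul(Q, nn.transpose(K, (0, 2, 1)))
            scores = nn.add_const(nn.scale(scores, 1.0 / np.sqrt(d_att)), mask)
            A = nn.softmax(scores, axis=-1)
            attn_maps.append(A.data.copy())
            out = nn.matmul(A, V)
            head_sum = out if head_sum is None else nn.add(head_sum, out)
        head_mean = nn.scale(head_sum, 1.0 / c.n_heads)
        attn_out = nn.linear(head_mean, self.params["attn.Wo"])

        theta_future = queries
        post_attn = self.gate_attn(attn_out, theta_future)
        ff_out = self.ff(post_attn)
        phi_future = nn.slice_axis(phi, 1, L, H)
        final = self.gate_ff(ff_out, phi_future)

        raw = nn.linear(final, self.params["head.W"], self.params["head.b"])
        raw = nn.reshape(raw, (B, H, len(c.targets), len(c.quantiles)))
        self._training = False
        self._drop_rng = None
        return _ForwardResult(
            raw=raw,
            attention=np.stack(attn_maps, axis=1),
            sel_past=w_past.data.copy(),
            sel_future=w_future.data.copy(),
            sel_static=w_static.data.copy(),
        )

    # -- inference ------------------------------------------------------------
    def predict(self, ws: WindowSet, batch_size: int = 128) -> ForecastSet:
        """Forecasts in clinical units, quantile axis sorted non-decreasing."""
        c = self.config
        values, att, sp, sf, ss = [], [], [], [], []
        for lo in range(0, len(ws), batch_size):
            sl = slice(lo, min(lo + batch_size, len(ws)))
            res = self.forward(ws.past[sl], ws.known_future[sl], ws.static[sl], training=False)
            z = np.sort(res.raw.data, axis=-1)
            clin = np.empty_like(z)
            for j, tgt in enumerate(c.targets):
                mu, sd = c.normalization[tgt]
                clin[:, :, j, :] = z[:, :, j, :] * sd + mu
            values.append(clin)
            att.append(res.attention)
            sp.append(res.sel_past)
            sf.append(res.sel_future)
            ss.append(res.sel_static)
        return ForecastSet(
            values=np.concatenate(values) if values else np.zeros((0, c.horizon, len(c.targets), len(c.quantiles))),
            quantiles=c.quantiles,
            targets=c.targets,
            subject_ids=list(ws.subject_ids),
            attention=np.concatenate(att) if att else np.zeros((0, c.n_heads, c.horizon, c.past_len + c.horizon)),
            selection_past=np.concatenate(sp) if sp else np.zeros((0, c.past_len, c.past_dim)),
            selection_future=np.concatenate(sf) if sf else np.zeros((0, c.horizon, c.future_dim)),
            selection_static=np.concatenate(ss) if ss else np.zeros((0, c.static_dim)),
        )

    # -- checkpointing --------------------------------------------------------
    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.savez(out / "checkpoint.npz", **self.state_dict())
        (out / "model_config.json").write_text(json.dumps(self.config.to_dict()))

    @classmethod
    def load(cls, in_dir: str | Path) -> "TFTMulti":
        path = Path(in_dir)
        config = ModelConfig.from_dict(json.loads((path / "model_config.json").read_text()))
        model = cls(config, seed=0)
        state = np.load(path / "checkpoint.npz")
        model.load_state_dict({k: state[k] for k in state.files})
        return model
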