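"""Masked multivariate quantile loss and the training loop.

The objective is a pinball (quantile) loss summed over target variables and
quantile levels, where each (window, variable) term averages only over
future steps whose value was actually observed -- imputed steps carry an
indicator of 0 and contribute nothing.  Writing y for truth, yhat(q) for
the q-quantile forecast and I_t for the realness indicator of step t:

    L = mean over windows of
        sum_v sum_q [ sum_t QL(y_t^v, yhat_t^v(q), q) * I_t^v ]
                    / [ sum_t I_t^v ]

    QL(y, yhat, q) = q * max(0, y - yhat) + (1 - q) * max(0, yhat - y)

A (window, variable) pair with no observed future steps would make the
denominator zero; such terms are defined as 0 (skipped), which keeps the
estimator finite and unbiased toward observed variables.

The loss operates on the z-scored target scale so the five channels'
different clinical magnitudes contribute comparably; evaluation inverts
the transform.

Training uses Adam with global gradient-norm clipping, a per-epoch
shuffled batch order, a validation split carved from training subjects,
and early stopping once the validation loss has increased for ``patience``
consecutive epochs; the best-validation checkpoint is restored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .exceptions import DataError, ParameterError, ShapeError
from .model import TFTMulti
from .prep import WindowSet, split_subjects

__all__ = [
    "TrainingConfig",
    "TrainingHistory",
    "quantile_loss",
    "masked_multivariate_loss",
    "train",
]


def quantile_loss(y, yhat, q: float):
    """Pinball loss; scalar or elementwise on arrays.

    Zero iff ``y == yhat``; the expectation over y is minimised by the
    q-th conditional quantile.
    """
    if not (0.0 < q < 1.0):
        raise ParameterError(f"quantile level q must lie in (0, 1), got {q}")
    diff = np.asarray(y, dtype=float) - np.asarray(yhat, dtype=float)
    out = q * np.maximum(0.0, diff) + (1.0 - q) * np.maximum(0.0, -diff)
    return float(out) if out.ndim == 0 else out


def _mask_weights(masks: np.ndarray) -> np.ndarray:
    """Per-step weights mask / per-(window, variable) mask count, 0-guarded."""
    counts = masks.sum(axis=1, keepdims=True)  # (B, 1, T)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(counts > 0, masks / np.where(counts > 0, counts, 1.0), 0.0)
    return w


def masked_multivariate_loss(
    truth: np.ndarray,
    forecasts: np.ndarray,
    masks: np.ndarray,
    quantiles,
) -> float:
    """The masked multivariate quantile loss on plain arrays.

    truth, masks: (batch, horizon, n_targets); forecasts: (batch, horizon,
    n_targets, n_quantiles).  Returns the batch-averaged loss.
    """
    truth = np.asarray(truth, dtype=float)
    forecasts = np.asarray(forecasts, dtype=float)
    masks = np.asarray(masks, dtype=float)
    if truth.shape != masks.shape:
        raise ShapeError(f"truth {truth.shape} and masks {masks.shape} differ")
    if forecasts.shape != truth.shape + (len(quantiles),):
        raise ShapeError(
            f"forecasts {forecasts.shape} incompatible with truth {truth.shape} "
            f"and {len(quantiles)} quantiles"
        )
    w = _mask_weights(masks)  # (B, H, T)
    total = 0.0
    for k, q in enumerate(quantiles):
        ql = quantile_loss(truth, forecasts[..., k], q)  # (B, H, T)
        total += float((ql * w).sum())
    return total / truth.shape[0]


def _loss_tensor(raw: nn.Tensor, z_truth: np.ndarray, masks: np.ndarray, quantiles) -> nn.Tensor:
    """Differentiable version of the masked loss on the model's raw output."""
    B = z_truth.shape[0]
    w = _mask_weights(masks)
    terms = None
    for k, q in enumerate(quantiles):
        pred = nn.reshape(
            nn.slice_axis(raw, 3, k, 1), z_truth.shape
        )  # (B, H, T)
        diff = nn.add_const(nn.scale(pred, -1.0), z_truth)  # y - yhat
        ql = nn.add(
            nn.scale(nn.relu(diff), q),
            nn.scale(nn.relu(nn.scale(diff, -1.0)), 1.0 - q),
        )
        term = nn.sum_(nn.mul_const(ql, w))
        terms = term if terms is None else nn.add(terms, term)
    return nn.scale(terms, 1.0 / B)


@dataclass(frozen=True)
class TrainingConfig:
    """Optimisation hyperparameters.

    Reference defaults: Adam at learning rate 1e-3, batch size 800, up to
    2000 epochs, early stop after 20 consecutive epochs of rising
    validation loss.  Fixture-scale runs use batch 32 and far fewer epochs.
    """

    learning_rate: float = 1e-3
    batch_size: int = 800
    max_epochs: int = 2000
    patience: int = 20
    seed: int = 0
    validation_fraction: float = 0.1
    gradient_clip_norm: float = 1.0

    def __post_init__(self):
        if self.patience < 1:
            raise ParameterError("patience must be >= 1")
        if not (0.0 < self.validation_fraction < 1.0):
            raise ParameterError("validation_fraction must lie strictly in (0, 1)")
        if self.batch_size < 1:
            raise ParameterError("batch_size must be >= 1")
        if self.max_epochs < 1:
            raise ParameterError("max_epochs must be >= 1")
        if self.learning_rate < 0:
            raise ParameterError("learning_rate must be >= 0")


@dataclass
class TrainingHistory:
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    best_epoch: int = -1
    stopped_early: bool = False

    def to_csv(self) -> str:
        lines = ["epoch,train_loss,val_loss"]
        for i, (tr, va) in enumerate(zip(self.train_loss, self.val_loss)):
            lines.append(f"{i},{tr:.6f},{va:.6f}")
        return "\n".join(lines) + "\n"


def _z_truth(ws: WindowSet) -> np.ndarray:
    out = np.empty_like(ws.future_truth)
    for j, tgt in enumerate(ws.schema.targets):
        mu, sd = ws.normalization[tgt]
        out[:, :, j] = (ws.future_truth[:, :, j] - mu) / sd
    return out


def _eval_loss(model: TFTMulti, ws: WindowSet, z_truth: np.ndarray, batch_size: int = 256) -> float:
    total = 0.0
    for lo in range(0, len(ws), batch_size):
        sl = slice(lo, min(lo + batch_size, len(ws)))
        res = model.forward(ws.past[sl], ws.known_future[sl], ws.static[sl], training=False)
        n = res.raw.shape[0]
        total += n * masked_multivariate_loss(
            z_truth[sl], res.raw.data, ws.future_masks[sl], model.config.quantiles
        )
    return total / max(len(ws), 1)


def train(
    model: TFTMulti, train_windows: WindowSet, config: TrainingConfig
) -> tuple[TFTMulti, TrainingHistory]:
    """Fit the model in place; returns it with the best-validation weights.

    The validation split is carved from the training subjects (by subject,
    never by window) so the early-stopping rule never sees test data.
    """
    if len(train_windows) == 0:
        raise DataError("training window set is empty")
    subjects = sorted(set(train_windows.subject_ids))
    if len(subjects) < 2:
        raise DataError("need at least 2 training subjects for a validation split")
    fit_ids, val_ids = split_subjects(
        subjects, train_frac=1.0 - config.validation_fraction, seed=config.seed
    )
    if not val_ids:  # tiny cohorts: keep at least one validation subject
        fit_ids, val_ids = fit_ids[:-1], fit_ids[-1:]
    fit_ws = train_windows.for_subjects(fit_ids)
    val_ws = train_windows.for_subjects(val_ids)

    z_fit = _z_truth(fit_ws)
    z_val = _z_truth(val_ws)
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(
        model.parameters(), lr=config.learning_rate, clip_norm=config.gradient_clip_norm
    )
    history = TrainingHistory()
    best_val = np.inf
    best_state = model.state_dict()
    rising = 0
    prev_val = np.inf

    n = len(fit_ws)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        drop_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        epoch_loss = 0.0
        n_seen = 0
        for lo in range(0, n, config.batch_size):
            ix = order[lo : lo + config.batch_size]
            res = model.forward(
                fit_ws.past[ix],
                fit_ws.known_future[ix],
                fit_ws.static[ix],
                training=True,
                dropout_rng=drop_rng,
            )
            loss = _loss_tensor(res.raw, z_fit[ix], fit_ws.future_masks[ix], model.config.quantiles)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.item() * len(ix)
            n_seen += len(ix)
        val_loss = _eval_loss(model, val_ws, z_val)
        history.train_loss.append(epoch_loss / max(n_seen, 1))
        history.val_loss.append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state_dict()
            history.best_epoch = epoch
        if val_loss > prev_val:
            rising += 1
        else:
            rising = 0
        prev_val = val_loss
        if rising >= config.patience:
            history.stopped_early = True
            break
    model.load_state_dict(best_state)
    return model, history
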