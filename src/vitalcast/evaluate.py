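"""Masked accuracy metrics, interval coverage, and agreement analysis.

All metrics here share one rule with the training loss: only future steps
whose value was genuinely observed (mask 1) count; forward-filled steps are
invisible.  The point forecast throughout is the 50th-quantile trajectory.

* masked MAE -- pooled |y - yhat| over real points, per target, in
  clinical units;
* masked MAPE -- mean of per-point |y - yhat|/|y| * 100 over real points,
  zero-truth points excluded (and counted);
* per-subject coverage -- percentage of real future points falling inside
  the closed 10th-90th quantile band, summarised by quartiles;
* Bland-Altman agreement -- mean of (prediction - truth) differences with
  limits mean +/- 1.96 * sample standard deviation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .exceptions import InsufficientDataError, ParameterError
from .model import ForecastSet, ModelConfig, TFTMulti
from .prep import WindowSet

__all__ = [
    "EvaluationReport",
    "BlandAltman",
    "masked_mae",
    "masked_mape",
    "coverage_per_subject",
    "bland_altman",
    "evaluate_forecasts",
    "run_lookback_ablation",
]


def _check_shapes(truth: np.ndarray, pred: np.ndarray, masks: np.ndarray) -> None:
    if truth.shape != pred.shape or truth.shape != masks.shape:
        raise ParameterError(
            f"truth {truth.shape}, predictions {pred.shape} and masks {masks.shape} must match"
        )


def masked_mae(truth: np.ndarray, pred50: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """Pooled masked MAE per target.

    Arrays are (..., n_targets); all leading axes are pooled.  A target with
    zero real points is reported as NaN (undefined), never as 0.
    """
    truth, pred50, masks = (np.asarray(a, dtype=float) for a in (truth, pred50, masks))
    _check_shapes(truth, pred50, masks)
    T = truth.shape[-1]
    err = np.abs(truth - pred50) * masks
    num = err.reshape(-1, T).sum(axis=0)
    den = masks.reshape(-1, T).sum(axis=0)
    return np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)


def masked_mape(
    truth: np.ndarray, pred50: np.ndarray, masks: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Masked MAPE (%) per target: mean of per-point ratios over real points.

    Points with zero truth are excluded from the mean; the second return
    value counts them per target.
    """
    truth, pred50, masks = (np.asarray(a, dtype=float) for a in (truth, pred50, masks))
    _check_shapes(truth, pred50, masks)
    T = truth.shape[-1]
    usable = (masks > 0) & (truth != 0)
    excluded = ((masks > 0) & (truth == 0)).reshape(-1, T).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(usable, np.abs(truth - pred50) / np.abs(np.where(usable, truth, 1.0)), 0.0)
    num = ratio.reshape(-1, T).sum(axis=0)
    den = usable.reshape(-1, T).sum(axis=0)
    mape = np.where(den > 0, 100.0 * num / np.where(den > 0, den, 1.0), np.nan)
    return mape, excluded.astype(int)


def coverage_per_subject(
    truth: np.ndarray, pred10: np.ndarray, pred90: np.ndarray, masks: np.ndarray
) -> np.ndarray:
    """Per-(window, target) percentage of real points inside [pred10, pred90].

    The interval is closed: a truth exactly on a bound counts as covered.
    Windows with no real points for a target are NaN (excluded from that
    target's distribution).  Input arrays are (n_windows, horizon,
    n_targets).
    """
    truth, pred10, pred90, masks = (
        np.asarray(a, dtype=float) for a in (truth, pred10, pred90, masks)
    )
    _check_shapes(truth, pred10, masks)
    _check_shapes(truth, pred90, masks)
    inside = ((truth >= pred10) & (truth <= pred90)) * masks
    num = inside.sum(axis=1)  # (N, T)
    den = masks.sum(axis=1)
    return np.where(den > 0, 100.0 * num / np.where(den > 0, den, 1.0), np.nan)


@dataclass(frozen=True)
class BlandAltman:
    mean_diff: float
    lower: float
    upper: float
    n: int


def bland_altman(truth: np.ndarray, pred50: np.ndarray, masks: np.ndarray) -> BlandAltman:
    """Agreement of predictions with truth over real points (pooled).

    Differences are prediction - truth; limits are mean +/- 1.96 times the
    sample standard deviation (ddof=1).
    """
    truth, pred50, masks = (np.asarray(a, dtype=float) for a in (truth, pred50, masks))
    _check_shapes(truth, pred50, masks)
    d = (pred50 - truth)[masks > 0]
    if d.size < 2:
        raise InsufficientDataError("Bland-Altman needs at least 2 real points")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(mean_diff=mean, lower=mean - 1.96 * sd, upper=mean + 1.96 * sd, n=int(d.size))


@dataclass
class EvaluationReport:
    """Per-target accuracy, coverage and agreement on a window set."""

    targets: tuple[str, ...]
    mae: dict = field(default_factory=dict)
    mape: dict = field(default_factory=dict)
    mape_excluded: dict = field(default_factory=dict)
    coverage_quartiles: dict = field(default_factory=dict)  # target -> (q1, q2, q3)
    coverage_pooled: dict = field(default_factory=dict)  # target -> % over pooled points
    bland_altman: dict = field(default_factory=dict)  # target -> BlandAltman
    n_real_points: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def enc(v):
            if isinstance(v, BlandAltman):
                return {"mean_diff": v.mean_diff, "lower": v.lower, "upper": v.upper, "n": v.n}
            if isinstance(v, float) and np.isnan(v):
                return None
            return v

        payload = {
            "targets": list(self.targets),
            "mae": {k: enc(v) for k, v in self.mae.items()},
            "mape": {k: enc(v) for k, v in self.mape.items()},
            "mape_excluded": self.mape_excluded,
            "coverage_quartiles": {k: list(v) for k, v in self.coverage_quartiles.items()},
            "coverage_pooled": {k: enc(v) for k, v in self.coverage_pooled.items()},
            "bland_altman": {k: enc(v) for k, v in self.bland_altman.items()},
            "n_real_points": self.n_real_points,
        }
        return json.dumps(payload, indent=2)


def evaluate_forecasts(ws: WindowSet, fs: ForecastSet) -> EvaluationReport:
    """Full masked evaluation of a forecast set against its windows."""
    targets = tuple(ws.schema.targets)
    truth, masks = ws.future_truth, ws.future_masks
    p50 = fs.quantile(0.5)
    p10 = fs.quantile(fs.quantiles[0])
    p90 = fs.quantile(fs.quantiles[-1])
    report = EvaluationReport(targets=targets)
    mae = masked_mae(truth, p50, masks)
    mape, excl = masked_mape(truth, p50, masks)
    cov = coverage_per_subject(truth, p10, p90, masks)
    inside = ((truth >= p10) & (truth <= p90)) * masks
    for j, tgt in enumerate(targets):
        report.mae[tgt] = float(mae[j])
        report.mape[tgt] = float(mape[j])
        report.mape_excluded[tgt] = int(excl[j])
        col = cov[:, j]
        col = col[~np.isnan(col)]
        if col.size:
            q1, q2, q3 = np.percentile(col, [25, 50, 75])  # linear interpolation
            report.coverage_quartiles[tgt] = (float(q1), float(q2), float(q3))
        n_real = float(masks[:, :, j].sum())
        report.coverage_pooled[tgt] = (
            float(100.0 * inside[:, :, j].sum() / n_real) if n_real > 0 else float("nan")
        )
        report.n_real_points[tgt] = int(n_real)
        try:
            report.bland_altman[tgt] = bland_altman(
                truth[:, :, j : j + 1], p50[:, :, j : j + 1], masks[:, :, j : j + 1]
            )
        except InsufficientDataError:
            report.bland_altman[tgt] = None
    return report


def run_lookback_ablation(
    train_ws: WindowSet,
    test_ws: WindowSet,
    lookbacks: Sequence[int],
    model_overrides: Mapping | None = None,
    train_config=None,
    seed: int = 0,
) -> dict[int, EvaluationReport]:
    """Retrain from scratch per lookback length and evaluate each model.

    Windows are built once at the full past length; each run truncates the
    past to its last ``lookback`` bins (3 h / 9 h / 18.75 h at 15-minute
    bins correspond to 12 / 36 / 75 bins), keeping everything else --
    including the seed -- identical.
    """
    from .training import TrainingConfig, train  # local import avoids a cycle

    if train_config is None:
        train_config = TrainingConfig()
    reports: dict[int, EvaluationReport] = {}
    for lb in lookbacks:
        if lb > train_ws.past_len:
            raise ParameterError(
                f"lookback {lb} exceeds available past length {train_ws.past_len}"
            )
        tr = train_ws.truncate_past(lb)
        te = test_ws.truncate_past(lb)
        cfg = ModelConfig.from_windowset(tr, **dict(model_overrides or {}))
        model = TFTMulti(cfg, seed=seed)
        model, _ = train(model, tr, train_config)
        reports[lb] = evaluate_forecasts(te, model.predict(te))
    return reports
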