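"""Counterfactual medication-scenario forecasting.

When the model is trained with the binary medication channel as a
known-future input, the same window can be re-forecast under hypothetical
administration schedules.  Three scenarios are compared on the mean-BP
channel for subjects who actually received pressors:

* ``observed`` -- the schedule that really happened;
* ``all_ones`` -- constant administration throughout the horizon;
* ``all_zeros`` -- no administration.

The inputs are identical except the medication block, so any difference in
the forecasts is the model's learned medication response.  Hypothesis
tests compare pooled per-step 50th-quantile predictions between the two
counterfactual schedules: over all steps, over steps where medication was
truly given, and over steps where it was not.  Because the pairing and
pooling behind such comparisons is a genuine modelling choice, both an
unequal-variance two-sample test and a paired-by-step test are reported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .evaluate import masked_mae
from .exceptions import SchemaError
from .model import ModelConfig, TFTMulti
from .prep import MEDICATION_CHANNEL, WindowSet

__all__ = [
    "ScenarioForecasts",
    "TestResult",
    "ScenarioComparison",
    "train_scenario_model",
    "forecast_scenarios",
    "compare_scenarios",
    "run_scenario_analysis",
]

SCENARIOS = ("observed", "all_ones", "all_zeros")


def _med_future_index(ws: WindowSet) -> int:
    names = list(ws.schema.known_future)
    if MEDICATION_CHANNEL not in names:
        raise SchemaError(
            "scenario analysis needs the medication channel as a known-future input"
        )
    return names.index(MEDICATION_CHANNEL)


def train_scenario_model(train_ws: WindowSet, model_config: ModelConfig, train_config, seed: int = 0):
    """Train the usual architecture with medication as a known-future input."""
    from .training import train

    _med_future_index(train_ws)  # validates the schema
    if model_config.future_dim != train_ws.known_future.shape[2]:
        raise SchemaError(
            f"model future_dim {model_config.future_dim} does not match the "
            f"{train_ws.known_future.shape[2]} known-future channels of the windows"
        )
    model = TFTMulti(model_config, seed=seed)
    return train(model, train_ws, train_config)


@dataclass
class ScenarioForecasts:
    """50th-quantile mean-BP trajectories under the three schedules."""

    target: str
    subject_ids: list
    med_truth: np.ndarray  # (N, horizon) binary observed schedule
    trajectories: dict  # scenario -> (N, horizon)
    masked_mae: dict  # scenario -> float, vs the observed truth


def forecast_scenarios(
    model: TFTMulti, ws: WindowSet, target: str = "meanbp"
) -> ScenarioForecasts:
    """Re-forecast every window under observed / all-ones / all-zeros meds.

    Only the known-future medication block differs between variants; if a
    window's observed schedule already equals a constant schedule, the two
    forecasts are identical by construction.
    """
    j_med = _med_future_index(ws)
    j_tgt = list(ws.schema.targets).index(target)
    med_truth = np.round(ws.known_future[:, :, j_med]).astype(int)

    trajectories = {}
    maes = {}
    for scenario in SCENARIOS:
        variant = ws.subset(range(len(ws)))
        kf = variant.known_future.copy()
        if scenario == "all_ones":
            kf[:, :, j_med] = 1.0
        elif scenario == "all_zeros":
            kf[:, :, j_med] = 0.0
        variant.known_future = kf
        fs = model.predict(variant)
        traj = fs.quantile(0.5)[:, :, j_tgt]
        trajectories[scenario] = traj
        maes[scenario] = float(
            masked_mae(
                ws.future_truth[:, :, j_tgt : j_tgt + 1],
                traj[:, :, None],
                ws.future_masks[:, :, j_tgt : j_tgt + 1],
            )[0]
        )
    return ScenarioForecasts(
        target=target,
        subject_ids=list(ws.subject_ids),
        med_truth=med_truth,
        trajectories=trajectories,
        masked_mae=maes,
    )


@dataclass(frozen=True)
class TestResult:
    mean_diff: float
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    computable: bool = True

    def as_dict(self) -> dict:
        return {
            "mean_diff": self.mean_diff,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "computable": self.computable,
        }


_NOT_COMPUTABLE = TestResult(float("nan"), float("nan"), float("nan"), 0, 0, computable=False)


def _welch(a: np.ndarray, b: np.ndarray) -> TestResult:
    if a.size < 2 or b.size < 2:
        return _NOT_COMPUTABLE
    if np.array_equal(a, b):
        # identical samples: zero effect by definition
        return TestResult(0.0, 0.0, 1.0, int(a.size), int(b.size))
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return TestResult(float(a.mean() - b.mean()), float(t), float(p), int(a.size), int(b.size))


def _paired(a: np.ndarray, b: np.ndarray) -> TestResult:
    if a.size < 2 or a.size != b.size:
        return _NOT_COMPUTABLE
    if np.array_equal(a, b):
        return TestResult(0.0, 0.0, 1.0, int(a.size), int(b.size))
    t, p = stats.ttest_rel(a, b)
    return TestResult(float((a - b).mean()), float(t), float(p), int(a.size), int(b.size))


@dataclass
class ScenarioComparison:
    """Three location tests between the all-ones and all-zeros forecasts.

    ``pooled`` treats every (window, step) prediction as an observation in
    an unequal-variance two-sample test; ``paired`` pairs the two scenarios
    step by step.  Rows: all steps; steps with observed medication = 1;
    steps with observed medication = 0 (the latter two partition the
    steps).
    """

    pooled: dict  # row -> TestResult
    paired: dict
    effect_direction: str

    def to_json(self) -> str:
        return json.dumps(
            {
                "pooled": {k: v.as_dict() for k, v in self.pooled.items()},
                "paired": {k: v.as_dict() for k, v in self.paired.items()},
                "effect_direction": self.effect_direction,
            },
            indent=2,
        )


def compare_scenarios(sf: ScenarioForecasts) -> ScenarioComparison:
    """Test predicted mean-BP differences between constant-on and constant-off."""
    ones = sf.trajectories["all_ones"]
    zeros = sf.trajectories["all_zeros"]
    med = sf.med_truth.astype(bool)

    rows = {
        "all_steps": (ones.ravel(), zeros.ravel()),
        "obs_med_1": (ones[med], zeros[med]),
        "obs_med_0": (ones[~med], zeros[~med]),
    }
    pooled = {k: _welch(a, b) for k, (a, b) in rows.items()}
    paired = {k: _paired(a, b) for k, (a, b) in rows.items()}
    diff = pooled["all_steps"].mean_diff
    direction = "increase" if diff > 0 else ("decrease" if diff < 0 else "none")
    return ScenarioComparison(pooled=pooled, paired=paired, effect_direction=direction)


def run_scenario_analysis(
    model: TFTMulti, test_ws: WindowSet, target: str = "meanbp", treated_only: bool = True
) -> tuple[ScenarioForecasts, ScenarioComparison]:
    """Scenario forecasts + comparison, restricted to treated subjects.

    Treated means the observed future schedule contains at least one active
    medication step, mirroring a cohort of subjects who actually received
    pressors during the forecast interval.
    """
    ws = test_ws
    if treated_only:
        j_med = _med_future_index(test_ws)
        active = np.round(test_ws.known_future[:, :, j_med]).sum(axis=1) > 0
        ws = test_ws.subset(np.nonzero(active)[0])
    sf = forecast_scenarios(model, ws, target=target)
    return sf, compare_scenarios(sf)
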