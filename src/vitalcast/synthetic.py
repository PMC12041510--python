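"""Synthetic ICU-like cohort generator.

Emulates the structure of an ICU vitals extract -- five correlated vital
channels on an irregular timestamp grid, channel-specific missingness,
binary static covariates, and a binary pressor channel with a known additive
effect on mean blood pressure -- so the whole forecasting pipeline can be
exercised and validated without any protected health data.

The latent process is intentionally simple and fully known:

* each channel's standardized deviation follows a stationary AR(1) with
  coefficient ``ar_coeff`` (unit marginal variance);
* spo2's deviation is driven by the previous bin's pulse deviation with
  coupling ``cross_coeff`` (plus independent innovation keeping unit
  variance), mirroring the premise that vitals carry information about one
  another;
* mean blood pressure gains ``med_effect_delta`` (clinical units) while a
  pressor is active, and ``informative_static_effect`` when the designated
  static flag is set.

Observations are the latent values plus measurement noise, each (bin,
channel) pair dropped independently at the channel's missingness rate --
missing completely at random, the simplest mechanism that exercises a
masked loss.  Timestamps sit on a regular grid with uniform jitter so the
downstream resampler has real work to do.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import json
import numpy as np
import pandas as pd

from .exceptions import ParameterError

__all__ = ["CHANNELS", "SimulationParams", "SyntheticCohort", "simulate_cohort", "truth_forecast"]

CHANNELS: tuple[str, ...] = ("meanbp", "pulse", "spo2", "resp", "temp")

#: Pressor names used for emitted medication rows (a subset of the drug class).
PRESSOR_NAMES: tuple[str, ...] = ("norepinephrine", "vasopressin", "epinephrine")

_DEFAULT_MEANS = {"meanbp": 75.0, "pulse": 85.0, "spo2": 97.0, "resp": 18.0, "temp": 37.0}
_DEFAULT_SDS = {"meanbp": 8.0, "pulse": 10.0, "spo2": 2.0, "resp": 4.0, "temp": 0.4}
_DEFAULT_MISSING = {"meanbp": 0.15, "pulse": 0.05, "spo2": 0.70, "resp": 0.30, "temp": 0.60}

_EPOCH = pd.Timestamp("2024-01-01 00:00:00")


@dataclass(frozen=True)
class SimulationParams:
    """Generating parameters for a synthetic cohort.

    Defaults define the package's reference study conditions: five vital
    channels in clinical units, strong persistence (AR coefficient 0.9),
    pulse->spo2 coupling 0.8, spo2 70% missing, and a +5 mmHg pressor effect
    on mean blood pressure.
    """

    n_subjects: int = 375
    n_bins: int = 110
    channel_names: tuple[str, ...] = CHANNELS
    baseline_means: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_MEANS))
    baseline_sds: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_SDS))
    ar_coeff: float = 0.9
    cross_coeff: float = 0.8
    missing_rates: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_MISSING))
    obs_noise_frac: float = 0.25
    med_effect_delta: float = 5.0
    med_prob: float = 0.5
    n_static: int = 4
    informative_static_effect: float = 3.0
    bin_minutes: float = 15.0
    jitter_minutes: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ParameterError("n_subjects must be >= 1")
        if self.n_bins < 100:
            raise ParameterError("n_bins must be >= 100")
        if len(self.channel_names) != 5:
            raise ParameterError("channel_names must list exactly 5 channels")
        if not (0.0 < self.ar_coeff < 1.0):
            raise ParameterError("ar_coeff must lie in the open interval (0, 1)")
        if not (-1.0 < self.cross_coeff < 1.0):
            raise ParameterError("cross_coeff must lie in (-1, 1)")
        for name in self.channel_names:
            for table, label in (
                (self.baseline_means, "baseline_means"),
                (self.baseline_sds, "baseline_sds"),
                (self.missing_rates, "missing_rates"),
            ):
                if name not in table:
                    raise ParameterError(f"{label} is missing channel '{name}'")
            if not (0.0 <= self.missing_rates[name] <= 1.0):
                raise ParameterError(f"missing_rates['{name}'] must lie in [0, 1]")
            if self.baseline_sds[name] <= 0:
                raise ParameterError(f"baseline_sds['{name}'] must be positive")
        if not (0.0 <= self.med_prob <= 1.0):
            raise ParameterError("med_prob must lie in [0, 1]")
        if self.n_static < 1:
            raise ParameterError("n_static must be >= 1")
        if self.obs_noise_frac < 0:
            raise ParameterError("obs_noise_frac must be >= 0")
        if self.jitter_minutes < 0 or self.jitter_minutes >= self.bin_minutes / 2:
            raise ParameterError("jitter_minutes must lie in [0, bin_minutes/2)")


@dataclass
class SyntheticCohort:
    """A generated cohort: observed rows, static covariates and ground truth.

    ``truth_record`` holds, per subject, the noiseless latent clinical
    trajectories (n_bins x 5), the standardized AR deviations the channels
    were generated from, the medication schedule, and the generating
    parameters -- enough to compute exact conditional-mean forecasts.
    """

    long_table: pd.DataFrame
    static_table: pd.DataFrame
    truth_record: dict

    @property
    def params(self) -> SimulationParams:
        return self.truth_record["params"]

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.long_table.to_csv(out / "long_table.csv", index=False)
        self.static_table.to_csv(out / "static_table.csv", index=False)
        tr = self.truth_record
        payload = {
            "params": _params_to_dict(tr["params"]),
            "subjects": {
                str(sid): {
                    "latent": tr["latent"][sid].tolist(),
                    "devs": tr["devs"][sid].tolist(),
                    "med_schedule": tr["med_schedule"][sid].tolist(),
                }
                for sid in tr["latent"]
            },
        }
        (out / "truth.json").write_text(json.dumps(payload))


def _params_to_dict(p: SimulationParams) -> dict:
    d = {k: getattr(p, k) for k in p.__dataclass_fields__}
    d["channel_names"] = list(p.channel_names)
    for key in ("baseline_means", "baseline_sds", "missing_rates"):
        d[key] = dict(d[key])
    return d


def simulate_cohort(params: SimulationParams) -> SyntheticCohort:
    """Generate a cohort; bit-identical output under the same params + seed."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    phi = params.ar_coeff
    cc = params.cross_coeff
    chans = params.channel_names
    n_bins = params.n_bins

    ar_innov = np.sqrt(1.0 - phi * phi)
    cross_innov = np.sqrt(max(1.0 - cc * cc, 1e-12))

    rows: list[tuple] = []
    static_rows: list[dict] = []
    latent_rec: dict[str, np.ndarray] = {}
    devs_rec: dict[str, np.ndarray] = {}
    med_rec: dict[str, np.ndarray] = {}

    for i in range(params.n_subjects):
        sid = f"s{i:04d}"
        static = (rng.random(params.n_static) < 0.3).astype(int)
        # standardized deviations, unit marginal variance
        devs = np.zeros((n_bins, 5))
        idx = {c: j for j, c in enumerate(chans)}
        for c in ("pulse", "meanbp", "resp", "temp"):
            j = idx[c]
            devs[0, j] = rng.normal()
            eps = rng.normal(size=n_bins - 1) * ar_innov
            for t in range(1, n_bins):
                devs[t, j] = phi * devs[t - 1, j] + eps[t - 1]
        js, jp = idx["spo2"], idx["pulse"]
        devs[0, js] = rng.normal()
        eps = rng.normal(size=n_bins - 1) * cross_innov
        devs[1:, js] = cc * devs[:-1, jp] + eps

        # medication schedule: treated subjects get one contiguous interval
        med = np.zeros(n_bins, dtype=int)
        treated = rng.random() < params.med_prob
        if treated:
            onset = int(rng.integers(5, n_bins - 10))
            length = int(rng.integers(10, 41))
            med[onset : min(onset + length, n_bins)] = 1

        latent = np.empty((n_bins, 5))
        for c in chans:
            j = idx[c]
            latent[:, j] = params.baseline_means[c] + params.baseline_sds[c] * devs[:, j]
        jb = idx["meanbp"]
        latent[:, jb] += params.med_effect_delta * med
        latent[:, jb] += params.informative_static_effect * static[0]

        # observations: latent + measurement noise, MCAR dropout, jittered stamps
        for c in chans:
            j = idx[c]
            noise = rng.normal(size=n_bins) * (params.obs_noise_frac * params.baseline_sds[c])
            keep = rng.random(n_bins) >= params.missing_rates[c]
            jitter = rng.uniform(-params.jitter_minutes, params.jitter_minutes, size=n_bins)
            for t in np.nonzero(keep)[0]:
                ts = _EPOCH + pd.Timedelta(minutes=t * params.bin_minutes + jitter[t])
                rows.append((sid, ts, c, latent[t, j] + noise[t]))
        if treated:
            drug = PRESSOR_NAMES[int(rng.integers(0, len(PRESSOR_NAMES)))]
            jitter = rng.uniform(-params.jitter_minutes, params.jitter_minutes, size=n_bins)
            for t in np.nonzero(med)[0]:
                ts = _EPOCH + pd.Timedelta(minutes=t * params.bin_minutes + jitter[t])
                rows.append((sid, ts, drug, 1.0))

        static_rows.append(
            {"subject_id": sid, **{f"static_{k}": int(static[k]) for k in range(params.n_static)}}
        )
        latent_rec[sid] = latent
        devs_rec[sid] = devs
        med_rec[sid] = med

    long_table = pd.DataFrame(rows, columns=["subject_id", "timestamp", "variable", "value"])
    long_table = long_table.sort_values(["subject_id", "timestamp"], kind="stable").reset_index(
        drop=True
    )
    static_table = pd.DataFrame(static_rows)
    truth = {
        "params": params,
        "latent": latent_rec,
        "devs": devs_rec,
        "med_schedule": med_rec,
        "static": {r["subject_id"]: [r[f"static_{k}"] for k in range(params.n_static)] for r in static_rows},
    }
    return SyntheticCohort(long_table=long_table, static_table=static_table, truth_record=truth)


def truth_forecast(
    cohort: SyntheticCohort,
    subject_id: str,
    horizon: int,
    origin: int = 75,
) -> pd.DataFrame:
    """Exact conditional-mean trajectories given the latent state at ``origin``.

    Returns a DataFrame with one column per channel and ``horizon`` rows,
    row ``s`` being the conditional mean of bin ``origin + s``.  For an AR(1)
    deviation with coefficient phi and state z at bin origin-1, the mean at
    bin origin+s is phi**(s+1) * z; the coupled spo2 channel propagates
    through the lagged pulse forecast.  The known medication schedule and
    static effect are added back on the clinical scale for mean BP.

    This is the unbeatable reference predictor for recovery tests: no model
    seeing only data up to ``origin`` can systematically beat it.
    """
    params = cohort.params
    if subject_id not in cohort.truth_record["latent"]:
        raise KeyError(f"unknown subject '{subject_id}'")
    if horizon < 0 or origin + horizon > params.n_bins:
        raise ParameterError("horizon must satisfy 0 <= horizon <= n_bins - origin")
    chans = params.channel_names
    idx = {c: j for j, c in enumerate(chans)}
    devs = cohort.truth_record["devs"][subject_id]
    med = cohort.truth_record["med_schedule"][subject_id]
    static = cohort.truth_record["static"][subject_id]
    phi = params.ar_coeff
    cc = params.cross_coeff

    out = np.empty((horizon, 5))
    z0 = devs[origin - 1]  # state at the forecast origin
    for c in ("pulse", "meanbp", "resp", "temp"):
        j = idx[c]
        for s in range(horizon):
            out[s, j] = phi ** (s + 1) * z0[j]
    js, jp = idx["spo2"], idx["pulse"]
    for s in range(horizon):
        # spo2 at bin origin+s is driven by pulse at bin origin+s-1
        out[s, js] = cc * (z0[jp] if s == 0 else out[s - 1, jp])

    for c in chans:
        j = idx[c]
        out[:, j] = params.baseline_means[c] + params.baseline_sds[c] * out[:, j]
    jb = idx["meanbp"]
    out[:, jb] += params.med_effect_delta * med[origin : origin + horizon]
    out[:, jb] += params.informative_static_effect * static[0]
    return pd.DataFrame(out, columns=list(chans))
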