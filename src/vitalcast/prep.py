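"""Clinical time-series preparation.

Turns irregular long-format observations (subject, timestamp, variable,
value) into aligned, masked, role-annotated forecast windows:

1. resample every series to 15-minute bins anchored at the subject's first
   observation, aggregating with the mean (numeric) or median (categorical);
2. forward-fill empty bins, keeping a per-bin mask that records which bins
   held at least one raw observation (1) and which were imputed (0);
3. unify all pressor administrations into one binary medication channel
   where absence means "no medication given";
4. cut each encounter's first 100 bins into a window of 75 past and 25
   future steps, z-scoring continuous inputs with statistics computed from
   training subjects' real (non-imputed) values only.

The mask is the load-bearing artifact: the training loss and every
evaluation metric downstream consume only mask-1 entries.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ParameterError, SchemaError

__all__ = [
    "RoleSchema",
    "BinnedSeries",
    "ForecastWindow",
    "WindowSet",
    "PrepReport",
    "resample_to_bins",
    "forward_fill",
    "prepare_static",
    "unify_medications",
    "build_windows",
    "split_subjects",
    "prepare_windows",
    "default_schema",
]

#: Name of the derived elapsed-time channel (hours since first observation).
#: It is deterministic, hence usable both as a past input and a known-future
#: input -- the synthetic cohort's analogue of age in the clinical setting.
TIME_CHANNEL = "hours_in"

MEDICATION_CHANNEL = "medication"


@dataclass(frozen=True)
class RoleSchema:
    """Variable roles: targets, static, past time-series, known-future."""

    targets: tuple[str, ...]
    past_static: tuple[str, ...]
    past_timeseries: tuple[str, ...]
    known_future: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "targets", tuple(self.targets))
        object.__setattr__(self, "past_static", tuple(self.past_static))
        object.__setattr__(self, "past_timeseries", tuple(self.past_timeseries))
        object.__setattr__(self, "known_future", tuple(self.known_future))
        if not set(self.targets) <= set(self.past_timeseries):
            raise SchemaError("targets must be a subset of past_timeseries")
        if set(self.past_static) & set(self.past_timeseries):
            raise SchemaError("past_static and past_timeseries overlap")
        if set(self.past_static) & set(self.known_future):
            raise SchemaError("past_static and known_future overlap")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RoleSchema":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        keys = {"targets", "past_static", "past_timeseries", "known_future"}
        unknown = set(raw) - keys
        if unknown:
            raise ConfigurationError(f"unknown schema keys: {sorted(unknown)}")
        missing = keys - set(raw)
        if missing:
            raise ConfigurationError(f"schema missing keys: {sorted(missing)}")
        return cls(**{k: tuple(raw[k]) for k in keys})


def default_schema(
    targets: Sequence[str],
    static: Sequence[str],
    medication_known_future: bool = False,
) -> RoleSchema:
    """The package's standard role assignment for a vitals cohort."""
    known_future = [TIME_CHANNEL] + ([MEDICATION_CHANNEL] if medication_known_future else [])
    return RoleSchema(
        targets=tuple(targets),
        past_static=tuple(static),
        past_timeseries=tuple(targets) + (MEDICATION_CHANNEL, TIME_CHANNEL),
        known_future=tuple(known_future),
    )


@dataclass
class BinnedSeries:
    """One subject/variable series on the bin grid, with its realness mask."""

    subject_id: str
    variable: str
    values: np.ndarray  # float; NaN at missing bins before fill
    mask: np.ndarray  # 1 = bin held >=1 raw observation, 0 = imputed


@dataclass
class ForecastWindow:
    """One encounter's aligned 100-step window, split 75 past / 25 future."""

    subject_id: str
    past_inputs: np.ndarray  # (past_len, n_past_channels), normalized
    past_masks: np.ndarray  # (past_len, n_targets)
    known_future_inputs: np.ndarray  # (horizon, n_future_channels), normalized
    static_inputs: np.ndarray  # (n_static,)
    future_truth: np.ndarray  # (horizon, n_targets), clinical units
    future_masks: np.ndarray  # (horizon, n_targets)
    normalization_record: dict


@dataclass
class PrepReport:
    n_subjects_in: int = 0
    n_windows: int = 0
    excluded_short: int = 0
    dropped_missing_numeric_static: list = field(default_factory=list)
    normalization_record: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_subjects_in": self.n_subjects_in,
                "n_windows": self.n_windows,
                "excluded_short": self.excluded_short,
                "dropped_missing_numeric_static": self.dropped_missing_numeric_static,
                "normalization_record": {
                    k: list(v) for k, v in self.normalization_record.items()
                },
            },
            indent=2,
        )


def resample_to_bins(
    obs: pd.DataFrame,
    bin_minutes: float = 15.0,
    kind: str = "numeric",
    anchor: pd.Timestamp | None = None,
    n_bins: int | None = None,
    subject_id: str = "",
    variable: str = "",
) -> BinnedSeries:
    """Aggregate one irregular series onto left-closed [t, t+bin) bins.

    Numeric series take the within-bin mean, categorical the within-bin
    median (ties at .5 rounded half up).  Empty bins are NaN with mask 0.
    ``anchor`` defaults to the series' first timestamp; pass the subject's
    first observation across all variables to align channels.
    """
    if bin_minutes <= 0:
        raise ParameterError("bin_minutes must be > 0")
    if kind not in ("numeric", "categorical"):
        raise ParameterError(f"kind must be 'numeric' or 'categorical', got '{kind}'")
    if len(obs) == 0:
        n = n_bins or 0
        return BinnedSeries(subject_id, variable, np.full(n, np.nan), np.zeros(n, dtype=int))
    ts = pd.to_datetime(obs["timestamp"])
    vals = np.asarray(obs["value"], dtype=float)
    if anchor is None:
        anchor = ts.min()
    idx = np.floor((ts - anchor).dt.total_seconds().to_numpy() / (bin_minutes * 60.0)).astype(int)
    keep = idx >= 0
    idx, vals = idx[keep], vals[keep]
    n = n_bins if n_bins is not None else (int(idx.max()) + 1 if len(idx) else 0)
    values = np.full(n, np.nan)
    mask = np.zeros(n, dtype=int)
    inside = idx < n
    for b in np.unique(idx[inside]):
        v = vals[idx == b]
        if kind == "numeric":
            values[b] = float(np.mean(v))
        else:
            med = float(np.median(v))
            values[b] = float(math.floor(med + 0.5))
        mask[b] = 1
    return BinnedSeries(subject_id, variable, values, mask)


def forward_fill(series: BinnedSeries, fallback: float | None = None) -> BinnedSeries:
    """Carry the last observed value forward; leading gaps take ``fallback``.

    The mask is unchanged: filled bins stay 0 so downstream losses and
    metrics can ignore them.
    """
    values = series.values.copy()
    missing = np.isnan(values)
    if missing.any():
        last = np.nan
        for t in range(len(values)):
            if not missing[t]:
                last = values[t]
            elif not np.isnan(last):
                values[t] = last
            else:
                if fallback is None:
                    raise ConfigurationError(
                        f"series '{series.variable}' has leading missing bins and no fallback"
                    )
                values[t] = fallback
    return BinnedSeries(series.subject_id, series.variable, values, series.mask.copy())


def prepare_static(
    static_table: pd.DataFrame, schema: RoleSchema
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Impute binary statics with 0; drop subjects missing a numeric static.

    A column is treated as binary when its observed values all lie in {0, 1}.
    Returns (cleaned table indexed by subject, retained ids, dropped ids).
    """
    df = static_table.set_index("subject_id") if "subject_id" in static_table else static_table
    cols = [c for c in schema.past_static]
    missing_cols = [c for c in cols if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"static variables absent from static_table: {missing_cols}")
    df = df[cols].copy()
    dropped: list[str] = []
    for c in cols:
        observed = df[c].dropna()
        is_binary = bool(observed.isin([0, 1, 0.0, 1.0]).all())
        if is_binary:
            df[c] = df[c].fillna(0).astype(float)
        else:
            bad = df.index[df[c].isna()].tolist()
            dropped.extend(str(s) for s in bad)
    dropped = sorted(set(dropped))
    retained = [str(s) for s in df.index if str(s) not in set(dropped)]
    return df.loc[retained], retained, dropped


def unify_medications(
    long_table: pd.DataFrame, pressor_names: Sequence[str]
) -> pd.DataFrame:
    """Collapse all pressor rows into one binary ``medication`` variable.

    Any pressor record maps to medication=1 at its timestamp; the absence of
    records means no medication (handled as fill-with-zero downstream, never
    forward-filled).
    """
    if not pressor_names:
        raise ParameterError("pressor_names must be non-empty")
    out = long_table.copy()
    is_pressor = out["variable"].isin(list(pressor_names))
    out.loc[is_pressor, "variable"] = MEDICATION_CHANNEL
    out.loc[is_pressor, "value"] = 1.0
    return out


def split_subjects(
    subject_ids: Sequence[str], train_frac: float = 0.8, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Deterministic disjoint, exhaustive split by subject."""
    if not (0.0 < train_frac < 1.0):
        raise ParameterError("train_frac must lie strictly between 0 and 1")
    ids = list(subject_ids)
    if len(ids) != len(set(ids)):
        raise ParameterError("subject_ids must be unique")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_train = int(round(train_frac * len(ids)))
    train = sorted(ids[i] for i in order[:n_train])
    test = sorted(ids[i] for i in order[n_train:])
    return train, test


@dataclass
class WindowSet:
    """Stacked forecast windows plus the metadata needed to use them.

    ``past`` is (N, past_len, P) normalized; ``future_truth`` stays in
    clinical units.  ``binary_past`` / ``binary_static`` flag channels that
    the model embeds as categories rather than projecting linearly.
    """

    subject_ids: list[str]
    past: np.ndarray
    past_masks: np.ndarray
    known_future: np.ndarray
    static: np.ndarray
    future_truth: np.ndarray
    future_masks: np.ndarray
    schema: RoleSchema
    normalization: dict  # variable -> (center, scale); identity for binary
    binary_past: tuple[bool, ...]
    binary_future: tuple[bool, ...]
    binary_static: tuple[bool, ...]

    def __len__(self) -> int:
        return len(self.subject_ids)

    @property
    def past_len(self) -> int:
        return self.past.shape[1]

    @property
    def horizon(self) -> int:
        return self.future_truth.shape[1]

    def subset(self, indices: Iterable[int]) -> "WindowSet":
        ix = list(indices)
        return WindowSet(
            subject_ids=[self.subject_ids[i] for i in ix],
            past=self.past[ix],
            past_masks=self.past_masks[ix],
            known_future=self.known_future[ix],
            static=self.static[ix],
            future_truth=self.future_truth[ix],
            future_masks=self.future_masks[ix],
            schema=self.schema,
            normalization=self.normalization,
            binary_past=self.binary_past,
            binary_future=self.binary_future,
            binary_static=self.binary_static,
        )

    def for_subjects(self, ids: Iterable[str]) -> "WindowSet":
        wanted = set(ids)
        return self.subset([i for i, s in enumerate(self.subject_ids) if s in wanted])

    def truncate_past(self, lookback: int) -> "WindowSet":
        """Keep only the last ``lookback`` past bins (lookback ablation)."""
        if lookback < 1 or lookback > self.past_len:
            raise ParameterError(f"lookback must lie in [1, {self.past_len}]")
        out = self.subset(range(len(self)))
        out.past = out.past[:, -lookback:, :]
        out.past_masks = out.past_masks[:, -lookback:, :]
        return out

    def windows(self) -> list[ForecastWindow]:
        return [
            ForecastWindow(
                subject_id=self.subject_ids[i],
                past_inputs=self.past[i],
                past_masks=self.past_masks[i],
                known_future_inputs=self.known_future[i],
                static_inputs=self.static[i],
                future_truth=self.future_truth[i],
                future_masks=self.future_masks[i],
                normalization_record=self.normalization,
            )
            for i in range(len(self))
        ]

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.savez(
            out / "windows.npz",
            past=self.past,
            past_masks=self.past_masks,
            known_future=self.known_future,
            static=self.static,
            future_truth=self.future_truth,
            future_masks=self.future_masks,
        )
        meta = {
            "subject_ids": self.subject_ids,
            "schema": {
                "targets": list(self.schema.targets),
                "past_static": list(self.schema.past_static),
                "past_timeseries": list(self.schema.past_timeseries),
                "known_future": list(self.schema.known_future),
            },
            "normalization": {k: list(v) for k, v in self.normalization.items()},
            "binary_past": list(self.binary_past),
            "binary_future": list(self.binary_future),
            "binary_static": list(self.binary_static),
        }
        (out / "windows_meta.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, in_dir: str | Path) -> "WindowSet":
        path = Path(in_dir)
        arrs = np.load(path / "windows.npz")
        meta = json.loads((path / "windows_meta.json").read_text())
        return cls(
            subject_ids=meta["subject_ids"],
            past=arrs["past"],
            past_masks=arrs["past_masks"],
            known_future=arrs["known_future"],
            static=arrs["static"],
            future_truth=arrs["future_truth"],
            future_masks=arrs["future_masks"],
            schema=RoleSchema(**{k: tuple(v) for k, v in meta["schema"].items()}),
            normalization={k: tuple(v) for k, v in meta["normalization"].items()},
            binary_past=tuple(meta["binary_past"]),
            binary_future=tuple(meta["binary_future"]),
            binary_static=tuple(meta["binary_static"]),
        )


def _is_binary_variable(name: str) -> bool:
    return name == MEDICATION_CHANNEL


def build_windows(
    binned: dict[str, dict[str, BinnedSeries]],
    static_df: pd.DataFrame,
    schema: RoleSchema,
    train_ids: Sequence[str],
    total: int = 100,
    past: int = 75,
    bin_minutes: float = 15.0,
    report: PrepReport | None = None,
) -> WindowSet:
    """Assemble normalized (past, future, static) tensors from binned series.

    ``binned`` maps subject -> variable -> filled BinnedSeries of length >=
    ``total`` (shorter encounters must already have been excluded).
    Normalization statistics come from training subjects' mask-1 values
    only; binary channels pass through untouched.
    """
    if past >= total:
        raise ParameterError("past must be < total")
    horizon = total - past
    ts_vars = [v for v in schema.past_timeseries if v != TIME_CHANNEL]
    for v in ts_vars:
        for sid, per_var in binned.items():
            if v not in per_var:
                raise SchemaError(f"schema variable '{v}' absent from panel for subject {sid}")

    train_set = set(train_ids)
    norm: dict[str, tuple[float, float]] = {}
    for v in ts_vars:
        if _is_binary_variable(v):
            norm[v] = (0.0, 1.0)
            continue
        pooled = []
        for sid in binned:
            if sid in train_set:
                s = binned[sid][v]
                real = s.mask[:total].astype(bool)
                pooled.append(s.values[:total][real])
        allv = np.concatenate(pooled) if pooled else np.array([0.0])
        mu = float(np.mean(allv)) if allv.size else 0.0
        sd = float(np.std(allv)) if allv.size else 1.0
        norm[v] = (mu, sd if sd > 1e-9 else 1.0)
    # elapsed-time channel: normalized over the window span
    hours = np.arange(total) * bin_minutes / 60.0
    norm[TIME_CHANNEL] = (float(hours.mean()), float(hours.std()))

    static_cols = list(schema.past_static)
    binary_static = []
    for c in static_cols:
        vals = static_df[c].dropna()
        binary_static.append(bool(vals.isin([0, 1]).all()))
    stat_norm: dict[str, tuple[float, float]] = {}
    for c, isbin in zip(static_cols, binary_static):
        if isbin:
            stat_norm[c] = (0.0, 1.0)
        else:
            tr = static_df.loc[[s for s in static_df.index if s in train_set], c]
            sd = float(tr.std(ddof=0)) or 1.0
            stat_norm[c] = (float(tr.mean()), sd)
    norm.update({f"static:{c}": stat_norm[c] for c in static_cols})

    past_vars = list(schema.past_timeseries)
    fut_vars = list(schema.known_future)
    targets = list(schema.targets)

    sids, P, PM, F, S, FT, FM = [], [], [], [], [], [], []
    for sid in sorted(binned):
        if sid not in static_df.index:
            continue
        per_var = binned[sid]
        n_avail = min(len(per_var[v].values) for v in ts_vars)
        if n_avail < total:
            if report is not None:
                report.excluded_short += 1
            continue

        def channel(v: str) -> np.ndarray:
            if v == TIME_CHANNEL:
                vals = hours.copy()
            else:
                vals = per_var[v].values[:total].astype(float)
            mu, sd = norm[v]
            return (vals - mu) / sd

        past_mat = np.stack([channel(v)[:past] for v in past_vars], axis=1)
        fut_mat = np.stack([channel(v)[past:] for v in fut_vars], axis=1) if fut_vars else np.zeros((horizon, 0))
        pm = np.stack([per_var[v].mask[:past] for v in targets], axis=1).astype(float)
        fm = np.stack([per_var[v].mask[past:total] for v in targets], axis=1).astype(float)
        ft = np.stack([per_var[v].values[past:total] for v in targets], axis=1).astype(float)
        svec = np.array(
            [
                (static_df.loc[sid, c] - stat_norm[c][0]) / stat_norm[c][1]
                for c in static_cols
            ],
            dtype=float,
        )
        sids.append(sid)
        P.append(past_mat)
        PM.append(pm)
        F.append(fut_mat)
        S.append(svec)
        FT.append(ft)
        FM.append(fm)

    if report is not None:
        report.n_windows = len(sids)
        report.normalization_record = dict(norm)

    return WindowSet(
        subject_ids=sids,
        past=np.array(P) if P else np.zeros((0, past, len(past_vars))),
        past_masks=np.array(PM) if PM else np.zeros((0, past, len(targets))),
        known_future=np.array(F) if F else np.zeros((0, horizon, len(fut_vars))),
        static=np.array(S) if S else np.zeros((0, len(static_cols))),
        future_truth=np.array(FT) if FT else np.zeros((0, horizon, len(targets))),
        future_masks=np.array(FM) if FM else np.zeros((0, horizon, len(targets))),
        schema=schema,
        normalization=norm,
        binary_past=tuple(_is_binary_variable(v) for v in past_vars),
        binary_future=tuple(_is_binary_variable(v) for v in fut_vars),
        binary_static=tuple(binary_static),
    )


def prepare_windows(
    long_table: pd.DataFrame,
    static_table: pd.DataFrame,
    schema: RoleSchema,
    train_ids: Sequence[str],
    pressor_names: Sequence[str] | None = None,
    bin_minutes: float = 15.0,
    total: int = 100,
    past: int = 75,
) -> tuple[WindowSet, PrepReport]:
    """End-to-end preparation: unify meds, bin, fill, window, normalize.

    Fallbacks for leading-missing bins are the variable's training-subject
    mean of real values (medication falls back to 0: absence means none
    given).  Returns the window set together with a report of exclusions
    and the normalization record.
    """
    report = PrepReport(n_subjects_in=static_table["subject_id"].nunique())
    if pressor_names:
        long_table = unify_medications(long_table, pressor_names)

    static_df, retained, dropped = prepare_static(static_table, schema)
    report.dropped_missing_numeric_static = dropped

    ts_vars = [v for v in schema.past_timeseries if v != TIME_CHANNEL]
    present = set(long_table["variable"].unique())
    # medication may legitimately be absent (no record means none given)
    absent = [v for v in ts_vars if v not in present and v != MEDICATION_CHANNEL]
    if absent:
        raise SchemaError(f"schema variables absent from long_table: {absent}")
    train_set = set(train_ids)
    groups = dict(tuple(long_table.groupby("subject_id")))

    # first pass: bin everything (masks + raw aggregated values)
    binned_raw: dict[str, dict[str, BinnedSeries]] = {}
    for sid in retained:
        if sid not in groups:
            continue
        sub = groups[sid]
        anchor = pd.to_datetime(sub["timestamp"]).min()
        per_var: dict[str, BinnedSeries] = {}
        last = pd.to_datetime(sub["timestamp"]).max()
        n_sub = int(np.floor((last - anchor).total_seconds() / (bin_minutes * 60.0))) + 1
        for v in ts_vars:
            obs = sub[sub["variable"] == v]
            kind = "categorical" if _is_binary_variable(v) else "numeric"
            per_var[v] = resample_to_bins(
                obs, bin_minutes, kind, anchor=anchor, n_bins=n_sub, subject_id=sid, variable=v
            )
        binned_raw[sid] = per_var

    # training means of real values, for leading-gap fallback
    fallback: dict[str, float] = {}
    for v in ts_vars:
        if _is_binary_variable(v):
            fallback[v] = 0.0
            continue
        pooled = [
            binned_raw[sid][v].values[binned_raw[sid][v].mask.astype(bool)]
            for sid in binned_raw
            if sid in train_set and v in binned_raw[sid]
        ]
        allv = np.concatenate(pooled) if pooled else np.array([])
        fallback[v] = float(np.mean(allv)) if allv.size else 0.0

    binned: dict[str, dict[str, BinnedSeries]] = {}
    for sid, per_var in binned_raw.items():
        filled: dict[str, BinnedSeries] = {}
        for v, s in per_var.items():
            if _is_binary_variable(v):
                vals = np.nan_to_num(s.values, nan=0.0)
                filled[v] = BinnedSeries(sid, v, vals, s.mask.copy())
            else:
                filled[v] = forward_fill(s, fallback=fallback[v])
        binned[sid] = filled

    ws = build_windows(
        binned,
        static_df,
        schema,
        train_ids,
        total=total,
        past=past,
        bin_minutes=bin_minutes,
        report=report,
    )
    return ws, report
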