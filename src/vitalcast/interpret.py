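"""Feature-importance aggregation from variable-selection weights.

The variable-selection networks emit a softmax weight per input variable at
every step of every window; averaged over steps, then over windows, and
renormalised, these weights are the per-feature importance the architecture
makes available.  Temporal multi-head attention is a different quantity --
it weights *positions*, not features -- so it is reported separately as a
horizon-by-position profile rather than folded into the feature ranking.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .exceptions import DataError
from .model import ForecastSet

__all__ = ["ImportanceReport", "aggregate_importance"]


@dataclass
class ImportanceReport:
    """Mean normalised selection weight per feature, ranked within group."""

    static_importance: dict  # feature -> weight, sums to 1
    timeseries_importance: dict  # feature -> weight, sums to 1
    static_ranking: list
    timeseries_ranking: list
    attention_profile: np.ndarray  # (horizon, past_len + horizon), head-averaged
    n_windows: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "static_importance": self.static_importance,
                "timeseries_importance": self.timeseries_importance,
                "static_ranking": self.static_ranking,
                "timeseries_ranking": self.timeseries_ranking,
                "n_windows": self.n_windows,
            },
            indent=2,
        )


def _normalise(weights: np.ndarray, names: list[str]) -> tuple[dict, list]:
    total = float(weights.sum())
    if total <= 0:
        weights = np.full_like(weights, 1.0 / len(weights))
        total = 1.0
    w = weights / total
    table = {name: float(x) for name, x in zip(names, w)}
    ranking = sorted(table, key=table.get, reverse=True)
    return table, ranking


def aggregate_importance(
    fs: ForecastSet,
    timeseries_names: list[str],
    static_names: list[str],
) -> ImportanceReport:
    """Aggregate a forecast set's selection weights into ranked importances.

    Per-window, per-step weights are averaged over steps, then over
    windows, within each input group, and renormalised to sum to one.
    Relabelling features permutes the report identically (the aggregation
    is positionwise).
    """
    if len(fs.subject_ids) == 0:
        raise DataError("cannot aggregate importance over an empty window set")
    if fs.selection_past.shape[-1] != len(timeseries_names):
        raise DataError(
            f"{len(timeseries_names)} time-series names for "
            f"{fs.selection_past.shape[-1]} selection channels"
        )
    if fs.selection_static.shape[-1] != len(static_names):
        raise DataError(
            f"{len(static_names)} static names for "
            f"{fs.selection_static.shape[-1]} selection channels"
        )
    ts_w = fs.selection_past.mean(axis=1).mean(axis=0)  # steps, then windows
    st_w = fs.selection_static.mean(axis=0)
    ts_table, ts_rank = _normalise(ts_w, timeseries_names)
    st_table, st_rank = _normalise(st_w, static_names)
    return ImportanceReport(
        static_importance=st_table,
        timeseries_importance=ts_table,
        static_ranking=st_rank,
        timeseries_ranking=ts_rank,
        attention_profile=fs.attention.mean(axis=(0, 1)),
        n_windows=len(fs.subject_ids),
    )
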