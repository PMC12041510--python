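"""Preparation: binning, filling, masking, windowing, splitting."""

import numpy as np
import pandas as pd
import pytest

import vitalcast as vc
from vitalcast.exceptions import ConfigurationError, ParameterError, SchemaError
from vitalcast.prep import (
    BinnedSeries,
    RoleSchema,
    forward_fill,
    prepare_static,
    prepare_windows,
    resample_to_bins,
    split_subjects,
    unify_medications,
)
from vitalcast.synthetic import PRESSOR_NAMES

T0 = pd.Timestamp("2024-01-01")


def obs_at(minutes, values):
    return pd.DataFrame(
        {"timestamp": [T0 + pd.Timedelta(minutes=m) for m in minutes], "value": values}
    )


class TestResample:
    def test_numeric_mean_within_bins(self):
        s = resample_to_bins(obs_at([0, 5, 20], [10, 20, 30]), 15, "numeric")
        assert s.values[0] == 15.0 and s.mask[0] == 1
        assert s.values[1] == 30.0 and s.mask[1] == 1

    def test_categorical_median_rounds_half_up(self):
        s = resample_to_bins(obs_at([0, 1, 2], [1, 1, 0]), 15, "categorical")
        assert s.values[0] == 1.0
        s2 = resample_to_bins(obs_at([0, 1], [0, 1]), 15, "categorical")
        assert s2.values[0] == 1.0  # median 0.5 rounds half up

    def test_empty_bin_flagged_missing(self):
        s = resample_to_bins(obs_at([0, 40], [1.0, 2.0]), 15, "numeric")
        assert np.isnan(s.values[1]) and s.mask[1] == 0

    def test_empty_series_gives_empty_result(self):
        s = resample_to_bins(obs_at([], []), 15, "numeric")
        assert len(s.values) == 0

    def test_invalid_bin_width_rejected(self):
        with pytest.raises(ParameterError):
            resample_to_bins(obs_at([0], [1.0]), 0, "numeric")


class TestForwardFill:
    def test_fill_pattern_and_mask_preserved(self):
        s = BinnedSeries("s", "v", np.array([np.nan, 5.0, np.nan, 7.0]), np.array([0, 1, 0, 1]))
        f = forward_fill(s, fallback=99.0)
        assert list(f.values) == [99.0, 5.0, 5.0, 7.0]
        assert list(f.mask) == [0, 1, 0, 1]

    def test_fully_observed_unchanged(self):
        s = BinnedSeries("s", "v", np.array([1.0, 2.0]), np.array([1, 1]))
        f = forward_fill(s)
        assert list(f.values) == [1.0, 2.0]

    def test_all_missing_takes_fallback_everywhere(self):
        s = BinnedSeries("s", "v", np.array([np.nan] * 3), np.zeros(3, dtype=int))
        f = forward_fill(s, fallback=2.5)
        assert list(f.values) == [2.5] * 3 and list(f.mask) == [0, 0, 0]

    def test_missing_fallback_is_configuration_error(self):
        s = BinnedSeries("s", "v", np.array([np.nan, 1.0]), np.array([0, 1]))
        with pytest.raises(ConfigurationError):
            forward_fill(s, fallback=None)


class TestPrepareStatic:
    def schema(self):
        return RoleSchema(
            targets=("meanbp",),
            past_static=("comorb", "age"),
            past_timeseries=("meanbp",),
            known_future=(),
        )

    def test_binary_missing_becomes_zero(self):
        table = pd.DataFrame(
            {"subject_id": ["a", "b"], "comorb": [1.0, np.nan], "age": [60.0, 70.0]}
        )
        df, retained, dropped = prepare_static(table, self.schema())
        assert df.loc["b", "comorb"] == 0.0 and retained == ["a", "b"]

    def test_missing_numeric_drops_subject(self):
        table = pd.DataFrame(
            {"subject_id": ["a", "b"], "comorb": [1.0, 0.0], "age": [np.nan, 70.0]}
        )
        _, retained, dropped = prepare_static(table, self.schema())
        assert retained == ["b"] and dropped == ["a"]

    def test_complete_table_retains_everyone(self):
        table = pd.DataFrame({"subject_id": ["a", "b"], "comorb": [0, 1], "age": [60.0, 70.0]})
        _, retained, dropped = prepare_static(table, self.schema())
        assert retained == ["a", "b"] and dropped == []


class TestUnifyMedications:
    def test_any_pressor_becomes_medication_one(self):
        lt = pd.DataFrame(
            {
                "subject_id": ["a"] * 3,
                "timestamp": [T0, T0, T0 + pd.Timedelta(minutes=1)],
                "variable": ["norepinephrine", "vasopressin", "pulse"],
                "value": [2.0, 4.0, 80.0],
            }
        )
        out = unify_medications(lt, ["norepinephrine", "vasopressin"])
        med = out[out.variable == "medication"]
        assert len(med) == 2 and (med.value == 1.0).all()
        assert (out.variable == "pulse").sum() == 1

    def test_no_pressor_rows_changes_nothing(self):
        lt = pd.DataFrame(
            {"subject_id": ["a"], "timestamp": [T0], "variable": ["pulse"], "value": [80.0]}
        )
        out = unify_medications(lt, ["norepinephrine"])
        assert "medication" not in set(out.variable)

    def test_empty_pressor_list_rejected(self):
        with pytest.raises(ParameterError):
            unify_medications(pd.DataFrame(), [])


class TestSchema:
    def test_targets_must_be_past_timeseries(self):
        with pytest.raises(SchemaError):
            RoleSchema(targets=("x",), past_static=(), past_timeseries=("y",), known_future=())

    def test_static_timeseries_overlap_rejected(self):
        with pytest.raises(SchemaError):
            RoleSchema(targets=("x",), past_static=("x",), past_timeseries=("x",), known_future=())


class TestSplitSubjects:
    def test_sizes_disjoint_exhaustive(self):
        ids = [f"s{i}" for i in range(10)]
        tr, te = split_subjects(ids, 0.8, seed=1)
        assert len(tr) == 8 and len(te) == 2
        assert set(tr) | set(te) == set(ids) and not set(tr) & set(te)

    def test_deterministic_under_seed(self):
        ids = [f"s{i}" for i in range(20)]
        assert split_subjects(ids, 0.8, 5) == split_subjects(ids, 0.8, 5)

    @pytest.mark.parametrize("frac", [0.0, 1.0, 1.5])
    def test_degenerate_fraction_rejected(self, frac):
        with pytest.raises(ParameterError):
            split_subjects(["a", "b"], frac, 0)


class TestWindows:
    def test_window_shapes_and_split_lengths(self, small_windows):
        ws, *_ = small_windows
        assert ws.past.shape[1] == 75
        assert ws.future_truth.shape[1] == 25
        assert ws.past_masks.shape[2] == 5
        assert ws.known_future.shape[2] == 1

    def test_short_encounter_excluded_and_counted(self):
        cohort = vc.simulate_cohort(vc.SimulationParams(n_subjects=6, seed=1))
        # truncate one subject's rows to fewer than 100 bins
        lt = cohort.long_table
        cutoff = pd.Timestamp("2024-01-01") + pd.Timedelta(minutes=80 * 15)
        lt = lt[(lt.subject_id != "s0000") | (lt.timestamp < cutoff)]
        schema = vc.default_schema(vc.CHANNELS, [f"static_{k}" for k in range(4)])
        ids = sorted(cohort.static_table.subject_id)
        ws, report = prepare_windows(
            lt, cohort.static_table, schema, ids[:5], pressor_names=list(PRESSOR_NAMES)
        )
        assert report.excluded_short == 1
        assert "s0000" not in ws.subject_ids
        assert len(ws) == 5

    def test_lossless_roundtrip_without_missingness(self):
        """With no dropout and no jitter, resample+fill reproduces the
        latent-plus-noise series exactly at bin resolution (all masks 1)."""
        p = vc.SimulationParams(
            n_subjects=4,
            missing_rates={c: 0.0 for c in vc.CHANNELS},
            jitter_minutes=0.0,
            med_prob=0.0,
            seed=2,
        )
        cohort = vc.simulate_cohort(p)
        schema = vc.default_schema(vc.CHANNELS, [f"static_{k}" for k in range(4)])
        ids = sorted(cohort.static_table.subject_id)
        ws, _ = prepare_windows(
            cohort.long_table, cohort.static_table, schema, ids, pressor_names=list(PRESSOR_NAMES)
        )
        assert np.all(ws.past_masks == 1) and np.all(ws.future_masks == 1)

    def test_mask_conservation(self, small_cohort, small_windows):
        """Total mask-1 future bins equals raw observation-bearing bins in
        the future range, unchanged by filling."""
        ws, *_ = small_windows
        lt = small_cohort.long_table
        total_real = 0
        for sid, sub in lt.groupby("subject_id"):
            anchor = sub.timestamp.min()
            for j, var in enumerate(vc.CHANNELS):
                t = sub[sub.variable == var].timestamp
                bins = np.floor((t - anchor).dt.total_seconds() / 900).astype(int)
                total_real += len(set(b for b in bins if 75 <= b < 100))
        assert int(ws.future_masks.sum()) == total_real

    def test_normalization_ignores_test_subjects(self, small_cohort):
        """Injecting an extreme value into a held-out subject must not
        move the normalization statistics (no leakage)."""
        schema = vc.default_schema(vc.CHANNELS, [f"static_{k}" for k in range(4)])
        ids = sorted(small_cohort.static_table.subject_id)
        train_ids = ids[:-1]
        lt = small_cohort.long_table
        ws1, _ = prepare_windows(
            lt, small_cohort.static_table, schema, train_ids, pressor_names=list(PRESSOR_NAMES)
        )
        lt2 = lt.copy()
        test_rows = (lt2.subject_id == ids[-1]) & (lt2.variable == "pulse")
        lt2.loc[test_rows, "value"] = 1e6
        ws2, _ = prepare_windows(
            lt2, small_cohort.static_table, schema, train_ids, pressor_names=list(PRESSOR_NAMES)
        )
        assert ws1.normalization["pulse"] == ws2.normalization["pulse"]

    def test_missing_schema_variable_raises(self, small_cohort):
        schema = RoleSchema(
            targets=("meanbp",),
            past_static=("static_0",),
            past_timeseries=("meanbp", "not_a_channel"),
            known_future=(),
        )
        ids = sorted(small_cohort.static_table.subject_id)
        with pytest.raises(SchemaError, match="not_a_channel"):
            prepare_windows(small_cohort.long_table, small_cohort.static_table, schema, ids)

    def test_truncate_past_for_lookback(self, small_windows):
        ws, *_ = small_windows
        short = ws.truncate_past(12)
        assert short.past.shape[1] == 12
        np.testing.assert_array_equal(short.past, ws.past[:, -12:, :])
        with pytest.raises(ParameterError):
            ws.truncate_past(80)

    def test_save_load_roundtrip(self, small_windows, tmp_path):
        ws, *_ = small_windows
        ws.save(tmp_path)
        back = vc.WindowSet.load(tmp_path)
        np.testing.assert_array_equal(back.past, ws.past)
        assert back.schema == ws.schema
        assert back.normalization == ws.normalization
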