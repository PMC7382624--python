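"""Temporal featurization: the worked scenario, oracle equivalence, leakage
safety, time features, and the log2 + z-score transform."""

import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_features, brute_force_responses, make_scenario
from clinicrec.features import (
    WindowSpec,
    apply_transforms,
    build_feature_rows,
    build_response_rows,
    encode_time_features,
    fit_transform_stats,
)
from clinicrec.synthetic import CohortSpec, generate_cohort

VOCAB = ["acetaminophen", "aspirin", "never_ordered"]
WLAB = ["pre-1", "pre-7", "pre-30", "pre-any"]


def feature_value(fm, row, item, window):
    j = fm.column_names.index(f"{item}|{window}")
    return fm.X[row, j]


class TestWorkedScenario:
    def test_first_row_all_zero(self, scenario_events):
        fm = build_feature_rows(scenario_events, VOCAB)
        assert fm.X[0].sum() == fm.X[0, -4:].sum()  # only time features nonzero

    def test_second_acetaminophen_counts_one_in_all_windows(self, scenario_events):
        fm = build_feature_rows(scenario_events, VOCAB)
        assert [feature_value(fm, 1, "acetaminophen", w) for w in WLAB] == [1, 1, 1, 1]

    def test_third_acetaminophen_two_in_long_windows_only(self, scenario_events):
        fm = build_feature_rows(scenario_events, VOCAB)
        assert [feature_value(fm, 2, "acetaminophen", w) for w in WLAB] == [0, 0, 2, 2]

    def test_second_aspirin_counts_one_everywhere_zero_before(self, scenario_events):
        fm = build_feature_rows(scenario_events, VOCAB)
        assert [feature_value(fm, 4, "aspirin", w) for w in WLAB] == [1, 1, 1, 1]
        for r in range(4):
            assert all(feature_value(fm, r, "aspirin", w) == 0 for w in WLAB)

    def test_row_at_identical_history_state_equals_predecessor(self):
        """An aspirin co-signed at the instant of the third acetaminophen sees
        the same patient history, so its feature row equals its predecessor
        (up to the identical time features)."""
        fm = build_feature_rows(make_scenario(aspirin_same_instant=True), VOCAB)
        assert np.array_equal(
            np.asarray(fm.X[2].todense()), np.asarray(fm.X[3].todense())
        )

    def test_response_row3_acetaminophen_and_aspirin_only(self, scenario_events):
        rm = build_response_rows(scenario_events, VOCAB)
        Y = np.asarray(rm.Y.todense())
        row = dict(zip(rm.target_vocab, Y[2]))
        # the triggering acetaminophen counts toward its own label
        assert row == {"acetaminophen": 1.0, "aspirin": 1.0, "never_ordered": 0.0}

    def test_no_targets_in_next_day_gives_zero_row(self, scenario_events):
        rm = build_response_rows(scenario_events, ["never_ordered"])
        assert rm.Y.sum() == 0


@pytest.fixture(scope="module")
def small_cohort():
    return generate_cohort(CohortSpec(n_patients=25, seed=21))


class TestOracleEquivalence:
    def test_windowed_counts_equal_full_history_rescan(self, small_cohort):
        events, _, _ = small_cohort
        events = events.head(400)
        vocab = sorted(events["item_id"].unique())[:30]
        fm = build_feature_rows(events, vocab)
        n_cols = len(vocab) * 4
        got = np.asarray(fm.X[:, :n_cols].todense())
        expected = brute_force_features(events, vocab)
        assert np.array_equal(got, expected)

    def test_responses_equal_rescan(self, small_cohort):
        events, order_sets, _ = small_cohort
        events = events.head(400)
        vocab = sorted(events["item_id"].unique())[:20]
        rm = build_response_rows(events, vocab, kind="items")
        assert np.array_equal(
            np.asarray(rm.Y.todense()), brute_force_responses(events, vocab)
        )
        os_ids = sorted(order_sets)
        rs = build_response_rows(events, os_ids, kind="ordersets")
        assert np.array_equal(
            np.asarray(rs.Y.todense()),
            brute_force_responses(events, os_ids, kind="ordersets"),
        )


class TestLeakageSafety:
    def test_future_events_never_change_feature_rows(self, scenario_events):
        """Perturbing any event at t >= t_row leaves feature row t unchanged;
        perturbing events at t >= t_row + 24h leaves response row t unchanged."""
        fm = build_feature_rows(scenario_events, VOCAB)
        rm = build_response_rows(scenario_events, VOCAB)
        perturbed = scenario_events.copy()
        # change the last two events (10 days after row 2) into something else
        perturbed.loc[3:, "item_id"] = "acetaminophen"
        fm2 = build_feature_rows(perturbed, VOCAB)
        rm2 = build_response_rows(perturbed, VOCAB)
        for r in range(3):  # rows 0-2 precede every perturbed event
            assert (fm.X[r] != fm2.X[r]).nnz == 0
        # rows 0,1 are >24h before the perturbed events: responses unchanged
        for r in range(2):
            assert (rm.Y[r] != rm2.Y[r]).nnz == 0
        # row 4 now sees a different prior item: sanity of the perturbation
        # (row 3's own features exclude the current event, so they are stable)
        assert (fm.X[4] != fm2.X[4]).nnz > 0

    def test_unsorted_input_rejected_naming_patient(self, scenario_events):
        shuffled = scenario_events.iloc[[4, 0, 1, 2, 3]]
        with pytest.raises(ValueError, match="P1"):
            build_feature_rows(shuffled, VOCAB)

    def test_nonpositive_horizon_rejected(self, scenario_events):
        with pytest.raises(ValueError):
            build_response_rows(scenario_events, VOCAB, horizon=pd.Timedelta(0))


class TestTimeFeatures:
    @pytest.mark.parametrize(
        "ts,expected",
        [
            (pd.Timestamp("2010-01-15 00:30"), (0.0, 1.0, 0.0, 1.0)),
            (pd.Timestamp("2010-01-01 06:00"), (0.0, 1.0, 1.0, 0.0)),
            (pd.Timestamp("2010-07-01 00:00"), (0.0, -1.0, 0.0, 1.0)),
        ],
    )
    def test_cyclical_encoding(self, ts, expected):
        got = encode_time_features(ts)
        assert np.allclose(got, expected, atol=1e-12)

    def test_windows_must_increase(self):
        with pytest.raises(ValueError):
            WindowSpec(
                feature_windows=(
                    ("pre-7", pd.Timedelta(days=7)),
                    ("pre-1", pd.Timedelta(days=1)),
                    ("pre-any", None),
                )
            )


class TestTransforms:
    def _matrix(self, events, vocab=VOCAB):
        return build_feature_rows(events, vocab)

    def test_constant_zero_column_masked(self, scenario_events):
        fm = self._matrix(scenario_events)
        stats = fit_transform_stats(fm, sd_threshold=0.01)
        never = fm.column_names.index("never_ordered|pre-any")
        assert not stats.mask[never]

    def test_zero_threshold_drops_nothing(self, scenario_events):
        fm = self._matrix(scenario_events)
        stats = fit_transform_stats(fm, sd_threshold=0.0)
        assert stats.mask.all()

    def test_log2_of_count_three_is_two(self):
        # column with values {0,...,3}: log2(1+3) = 2 before standardization
        ev = make_scenario()
        fm = self._matrix(ev)
        stats = fit_transform_stats(fm, sd_threshold=0.0)
        j = fm.column_names.index("acetaminophen|pre-30")
        # row 4 has count 3 there; undo the z-score to recover log2(1+3)
        X = apply_transforms(fm, stats)
        jm = int(np.flatnonzero(np.array(stats.column_names)[stats.mask] == "acetaminophen|pre-30")[0])
        recovered = X[4, jm] * max(stats.sd[j], stats.sd_floor) + stats.mean[j]
        assert recovered == pytest.approx(2.0, abs=1e-12)

    def test_train_transform_is_zero_mean_unit_sd(self, small_cohort):
        events, _, _ = small_cohort
        vocab = sorted(events["item_id"].unique())[:15]
        fm = build_feature_rows(events, vocab)
        stats = fit_transform_stats(fm, sd_threshold=0.01)
        X = apply_transforms(fm, stats)
        assert np.allclose(X.mean(axis=0), 0.0, atol=1e-6)
        assert np.allclose(X.std(axis=0, ddof=1), 1.0, atol=1e-6)

    def test_column_mismatch_rejected(self, scenario_events):
        fm = self._matrix(scenario_events)
        stats = fit_transform_stats(fm, sd_threshold=0.01)
        fm2 = self._matrix(scenario_events, vocab=["acetaminophen"])
        with pytest.raises(ValueError, match="columns"):
            apply_transforms(fm2, stats)

    def test_empty_training_matrix_rejected(self, scenario_events):
        fm = self._matrix(scenario_events)
        import dataclasses

        empty = dataclasses.replace(fm, X=fm.X[:0], row_index=fm.row_index.iloc[:0])
        with pytest.raises(ValueError):
            fit_transform_stats(empty)

    def test_stats_round_trip_json(self, scenario_events):
        from clinicrec.features import TransformStats

        fm = self._matrix(scenario_events)
        stats = fit_transform_stats(fm, sd_threshold=0.01)
        back = TransformStats.from_json(stats.to_json())
        assert np.array_equal(back.mean, stats.mean)
        assert np.array_equal(back.mask, stats.mask)
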