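"""Inclusion filters, Welch t-tests, and the feature-correlation matrix."""

import math

import numpy as np
import pandas as pd
import pytest

from szspeech.cohort import (
    COMBINED_FEATURES,
    FeatureTable,
    apply_participant_filter,
    correlation_matrix,
    filter_participants,
    filter_responses,
    group_ttests,
    normality_report,
)


def welch_oracle(a, b):
    """Textbook Welch t computed from first principles."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    return (a.mean() - b.mean()) / math.sqrt(va + vb)


def make_table(rows):
    df = pd.DataFrame(rows)
    for col in COMBINED_FEATURES:
        if col not in df.columns:
            df[col] = 0.0
    return FeatureTable(df)


def toy_table(rng=None, n_per_group=12):
    rng = rng or np.random.default_rng(0)
    rows = []
    for g, pid0 in (("control", "c"), ("patient", "p")):
        for i in range(n_per_group):
            row = {
                "participant_id": f"{pid0}{i % 4}",
                "response_id": f"r{i}",
                "group": g,
            }
            for col in COMBINED_FEATURES:
                row[col] = rng.normal(0 if g == "control" else 1, 1)
            rows.append(row)
    return FeatureTable(pd.DataFrame(rows))


class TestResponseFilter:
    def test_threshold_boundary(self):
        table = make_table(
            [
                {"participant_id": "a", "response_id": "r1", "group": "control"},
                {"participant_id": "a", "response_id": "r2", "group": "control"},
            ]
        )
        seconds = {("a", "r1"): 9.99, ("a", "r2"): 10.0}
        kept = filter_responses(table, seconds)
        assert list(kept.df["response_id"]) == ["r2"]  # exactly 10 s is kept

    def test_hand_counted_toy_cohort(self):
        rows = [
            {"participant_id": "a", "response_id": f"r{i}", "group": "control"}
            for i in range(3)
        ] + [
            {"participant_id": "b", "response_id": f"r{i}", "group": "patient"}
            for i in range(2)
        ]
        table = make_table(rows)
        seconds = {
            ("a", "r0"): 30.0,
            ("a", "r1"): 5.0,
            ("a", "r2"): 12.0,
            ("b", "r0"): 8.0,
            ("b", "r1"): 25.0,
        }
        kept = filter_responses(table, seconds)
        assert len(kept) == 3
        assert kept.group_counts() == {"control": 2, "patient": 1}


class TestParticipantFilter:
    @pytest.mark.parametrize("count, included", [(499, False), (500, True), (1200, True)])
    def test_word_threshold(self, count, included):
        kept = filter_participants({"x": count})
        assert ("x" in kept) is included

    def test_cascade_drops_all_responses(self):
        table = make_table(
            [
                {"participant_id": "a", "response_id": "r1", "group": "control"},
                {"participant_id": "b", "response_id": "r1", "group": "patient"},
                {"participant_id": "b", "response_id": "r2", "group": "patient"},
            ]
        )
        kept = filter_participants({"a": 600, "b": 120})
        out = apply_participant_filter(table, kept)
        assert set(out.df["participant_id"]) == {"a"}

    def test_filter_order_independent(self):
        table = toy_table()
        seconds = {
            (r.participant_id, r.response_id): 5.0 + 10 * (i % 2)
            for i, r in enumerate(table.df.itertuples())
        }
        words = {p: 400 + 200 * (p.startswith("c")) for p in table.df["participant_id"]}
        kept = filter_participants(words)
        a = filter_responses(apply_participant_filter(table, kept), seconds)
        b = apply_participant_filter(filter_responses(table, seconds), kept)
        pd.testing.assert_frame_equal(a.df, b.df)


class TestGroupTTests:
    def test_identical_distributions_t_near_zero(self):
        rng = np.random.default_rng(4)
        values = rng.normal(size=24)
        table = toy_table()
        table.df["MUD"] = np.concatenate([values[:12], values[:12]])
        res = group_ttests(table, "acoustic").table
        assert res.loc["MUD", "t"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_welch(self):
        a, b = [1.0, 2.0, 4.0], [7.0, 9.0, 14.0]
        rows = [
            {"participant_id": f"c{i}", "response_id": "r", "group": "control", "MUD": v}
            for i, v in enumerate(a)
        ] + [
            {"participant_id": f"p{i}", "response_id": "r", "group": "patient", "MUD": v}
            for i, v in enumerate(b)
        ]
        table = make_table(rows)
        res = group_ttests(table, "acoustic").table
        assert res.loc["MUD", "t"] == pytest.approx(welch_oracle(a, b))
        assert res.loc["MUD", "control_mean"] == pytest.approx(np.mean(a))
        assert res.loc["MUD", "patient_sd"] == pytest.approx(np.std(b, ddof=1))

    def test_participant_level_aggregates_first(self):
        rows = []
        # one participant per group, several responses: participant-level
        # test must be untestable (n=1 per group)
        for g, pid in (("control", "c1"), ("patient", "p1")):
            for i in range(5):
                rows.append(
                    {
                        "participant_id": pid,
                        "response_id": f"r{i}",
                        "group": g,
                        "MUD": float(i),
                    }
                )
        table = make_table(rows)
        response_level = group_ttests(table, "acoustic", level="response").table
        assert np.isfinite(response_level.loc["MUD", "t"])
        participant_level = group_ttests(table, "acoustic", level="participant").table
        assert math.isnan(participant_level.loc["MUD", "t"])

    def test_untestable_feature_marked(self):
        table = toy_table()
        table.df.loc[table.df["group"] == "patient", "PS"] = np.nan
        res = group_ttests(table, "acoustic").table
        assert math.isnan(res.loc["PS", "t"])


class TestCorrelationMatrix:
    def test_diagonal_and_symmetry(self):
        corr = correlation_matrix(toy_table())
        np.testing.assert_allclose(np.diag(corr), 1.0)
        np.testing.assert_allclose(corr.values, corr.values.T, atol=1e-12)
        assert np.nanmax(np.abs(corr.values)) <= 1.0 + 1e-12

    def test_negated_feature(self):
        table = toy_table()
        table.df["MGD"] = -table.df["MUD"]
        corr = correlation_matrix(table)
        assert corr.loc["MUD", "MGD"] == pytest.approx(-1.0)

    def test_constant_feature_undefined(self):
        table = toy_table()
        table.df["J"] = 3.0
        corr = correlation_matrix(table)
        assert math.isnan(corr.loc["J", "MUD"])

    def test_positive_semidefinite_complete_case(self):
        corr = correlation_matrix(toy_table(np.random.default_rng(8), 30))
        eigenvalues = np.linalg.eigvalsh(corr.to_numpy())
        assert eigenvalues.min() > -1e-10


class TestNormalityReport:
    def test_advisory_report_shape(self):
        rep = normality_report(toy_table(), "acoustic")
        assert set(rep.columns) == {"feature", "group", "W", "p"}
        assert len(rep) == 18  # 9 features x 2 groups


class TestPlots:
    def test_heatmap_written(self, tmp_path):
        from szspeech.cohort import plot_correlation_heatmap

        corr = correlation_matrix(toy_table())
        out = plot_correlation_heatmap(corr, tmp_path / "corr.png")
        assert out.is_file() and out.stat().st_size > 0
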