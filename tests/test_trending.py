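"""Unit and property tests for the two-cut-off trending filter."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vulntrend.synthetic import TrendingSimSpec, simulate_expression
from vulntrend.trending import (ExpressionStudy, extreme_group_test,
                                rank_by_enrichment_ratio, run_trending,
                                trend_filter)

from _oracles import trending_by_hand, welch_by_hand
from conftest import make_study


class TestExtremeGroupTest:
    def test_identical_groups_give_zero_fc_and_p_one(self):
        study = make_study(np.full((1, 9), 7.0))
        log2fc, p = extreme_group_test(study, "T0000")
        assert log2fc == 0.0
        assert p == 1.0

    def test_clear_separation_matches_welch_closed_form(self):
        eps = 1e-6
        row = np.array([[10, 10, 10 + eps, 9, 9, 9, 8, 8, 8 + eps]],
                       dtype=float)
        study = make_study(row)
        log2fc, p = extreme_group_test(study, "T0000")
        assert log2fc == pytest.approx(2.0, abs=1e-6)
        assert p < 1e-4
        _, p_oracle = welch_by_hand([10, 10, 10 + eps], [8, 8, 8 + eps])
        assert p == pytest.approx(p_oracle, rel=1e-12)

    def test_five_fold_transcript_passes_at_realistic_noise(self):
        # a transcript ~5-fold (log2fc ~2.32) higher in the resistant pool,
        # like the Pgk1 example, clears p < 0.05 at modest within-group sd
        rng = np.random.default_rng(0)
        row = np.concatenate([10.32 + 0.1 * rng.standard_normal(3),
                              9.2 + 0.1 * rng.standard_normal(3),
                              8.0 + 0.1 * rng.standard_normal(3)])
        study = make_study(row[None, :])
        log2fc, p = extreme_group_test(study, "T0000")
        assert log2fc == pytest.approx(2.32, abs=0.3)
        assert p < 0.05


class TestTrendFilter:
    @pytest.mark.parametrize("means,direction,expected", [
        ((10, 9, 8), "protective", True),
        ((10, 10, 8), "protective", False),  # tie is not a trend
        ((8, 9, 10), "harmful", True),
        ((10, 9, 8), "harmful", False),
        ((9, 10, 8), "protective", False),  # intermediate overshoots
    ])
    def test_examples(self, means, direction, expected):
        assert trend_filter(means, direction) is expected

    def test_all_weak_orderings_match_brute_comparator(self):
        # enumerate every pattern of three means drawn from {1, 2, 3}
        # (covers all 13 weak orderings) against direct comparisons
        for means in itertools.product((1.0, 2.0, 3.0), repeat=3):
            r, i, v = means
            assert trend_filter(means, "protective") is (r > i > v)
            assert trend_filter(means, "harmful") is (r < i < v)

    def test_gap_requires_margin(self):
        assert trend_filter((10, 9, 8), "protective", gap=0.5)
        assert not trend_filter((10, 9.8, 8), "protective", gap=0.5)

    def test_nonfinite_means_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            trend_filter((np.nan, 1, 2), "protective")


class TestRunTrending:
    def test_matches_brute_force_on_random_study(self):
        rng = np.random.default_rng(42)
        mat = rng.normal(8, 1, size=(60, 9))
        study = make_study(mat)
        result = run_trending(study, alpha=0.05)
        oracle = trending_by_hand(mat, [study.groups[c]
                                        for c in study.matrix.columns],
                                  ("EDL", "GS", "TA"), 0.05)
        for row, exp in zip(result.table.itertuples(), oracle):
            assert row.call == exp["call"]
            assert row.p_value == pytest.approx(exp["p"], abs=1e-12)
            assert row.log2fc_res_vs_vul == pytest.approx(exp["log2fc"],
                                                          abs=1e-12)

    def test_noise_free_planted_study_recovered_exactly(self, noise_free_study):
        study, truth = noise_free_study
        result = run_trending(study)
        expected_prot = set(truth.loc[truth.truth_label == "protective",
                                      "transcript_id"])
        expected_harm = set(truth.loc[truth.truth_label == "harmful",
                                      "transcript_id"])
        assert set(result.protective) == expected_prot
        assert set(result.harmful) == expected_harm

    def test_alpha_zero_calls_nothing(self, noise_free_study):
        study, _ = noise_free_study
        result = run_trending(study, alpha=0.0)
        assert result.protective == [] and result.harmful == []

    @pytest.mark.parametrize("alpha", [-0.1, 1.0, 2.0])
    def test_invalid_alpha_rejected(self, alpha):
        study = make_study(np.zeros((2, 9)))
        with pytest.raises(ValueError, match="alpha"):
            run_trending(study, alpha=alpha)

    def test_calls_partition_transcripts(self, planted_spec):
        study, _ = simulate_expression(planted_spec)
        result = run_trending(study)
        calls = result.table["call"]
        assert set(calls) <= {"protective", "harmful", "none"}
        assert not (set(result.protective) & set(result.harmful))
        assert len(result.protective) + len(result.harmful) + \
            (calls == "none").sum() == len(calls)

    def test_negating_matrix_swaps_calls(self, planted_spec):
        study, _ = simulate_expression(planted_spec)
        flipped = ExpressionStudy(matrix=-study.matrix, groups=study.groups,
                                  group_order=study.group_order)
        a = run_trending(study)
        b = run_trending(flipped)
        assert set(a.protective) == set(b.harmful)
        assert set(a.harmful) == set(b.protective)

    def test_protective_call_implies_positive_fold_change(self, planted_spec):
        study, _ = simulate_expression(planted_spec)
        table = run_trending(study).table
        assert (table.loc[table.call == "protective",
                          "log2fc_res_vs_vul"] > 0).all()
        assert (table.loc[table.call == "harmful",
                          "log2fc_res_vs_vul"] < 0).all()

    def test_recall_nondecreasing_in_effect_size(self):
        recalls = []
        for effect in (0.5, 1.0, 2.0, 3.0):
            spec = TrendingSimSpec(n_transcripts=400, n_per_group=3,
                                   n_planted_protective=40,
                                   n_planted_harmful=0,
                                   effect_log2fc=effect, noise_sd=0.25,
                                   seed=7)
            study, truth = simulate_expression(spec)
            planted = set(truth.loc[truth.truth_label == "protective",
                                    "transcript_id"])
            found = set(run_trending(study).protective)
            recalls.append(len(found & planted) / len(planted))
        assert all(b >= a - 0.02 for a, b in zip(recalls, recalls[1:]))

    def test_student_test_option(self):
        rng = np.random.default_rng(1)
        study = make_study(rng.normal(8, 1, size=(30, 9)))
        welch = run_trending(study, test="welch").table["p_value"]
        student = run_trending(study, test="student").table["p_value"]
        assert not np.allclose(welch, student)


class TestRanking:
    def test_empty_call_set_gives_empty_table(self):
        study = make_study(np.full((5, 9), 3.0))
        table = run_trending(study).table
        assert rank_by_enrichment_ratio(table).empty

    def test_orders_by_absolute_fold_change(self, noise_free_study):
        study, _ = noise_free_study
        table = run_trending(study).table
        ranked = rank_by_enrichment_ratio(table)
        fcs = ranked["log2fc_res_vs_vul"].abs().to_numpy()
        assert (np.diff(fcs) <= 1e-12).all()

    def test_ties_broken_lexicographically_and_stable_under_shuffle(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame({
            "log2fc_res_vs_vul": [2.0, -2.0, 1.0, 2.0],
            "call": ["protective", "harmful", "protective", "protective"],
        }, index=["b", "a", "c", "aa"])
        ranked = rank_by_enrichment_ratio(table)
        shuffled = table.sample(frac=1, random_state=rng.integers(1 << 16))
        ranked2 = rank_by_enrichment_ratio(shuffled)
        assert list(ranked.index) == ["a", "aa", "b", "c"]
        assert list(ranked2.index) == list(ranked.index)


class TestStudyValidation:
    def test_duplicate_transcript_ids_rejected(self):
        samples = [f"{g}_{i}" for g in ("EDL", "GS", "TA") for i in (1, 2)]
        mat = pd.DataFrame(np.zeros((2, 6)), index=["x", "x"],
                           columns=samples)
        groups = pd.Series([s.split("_")[0] for s in samples], index=samples)
        with pytest.raises(ValueError, match="unique"):
            ExpressionStudy(mat, groups, ("EDL", "GS", "TA"))

    def test_single_sample_group_rejected(self):
        samples = ["EDL_1", "EDL_2", "GS_1", "GS_2", "TA_1"]
        mat = pd.DataFrame(np.zeros((2, 5)), index=["a", "b"],
                           columns=samples)
        groups = pd.Series([s.split("_")[0] for s in samples], index=samples)
        with pytest.raises(ValueError, match="TA"):
            ExpressionStudy(mat, groups, ("EDL", "GS", "TA"))

    def test_missing_values_rejected(self):
        samples = [f"{g}_{i}" for g in ("EDL", "GS", "TA") for i in (1, 2)]
        mat = pd.DataFrame(np.zeros((2, 6)), index=["a", "b"],
                           columns=samples)
        mat.iloc[0, 0] = np.nan
        groups = pd.Series([s.split("_")[0] for s in samples], index=samples)
        with pytest.raises(ValueError, match="missing"):
            ExpressionStudy(mat, groups, ("EDL", "GS", "TA"))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_welch_p_values_match_hand_formula(seed):
    """Vectorized p-values equal the explicit Welch formula, any data."""
    rng = np.random.default_rng(seed)
    mat = rng.normal(0, 1, size=(5, 9))
    study = make_study(mat)
    table = run_trending(study).table
    for i, row in enumerate(table.itertuples()):
        _, p = welch_by_hand(mat[i, :3], mat[i, 6:])
        assert row.p_value == pytest.approx(p, abs=1e-12)
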