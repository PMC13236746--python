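"""Meta-analytic combination, g-prior Bayes factors, overlap, ranking."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import retrocal as rc
from conftest import make_two_condition_study


class TestVarianceOfT:
    def test_central_t_variance(self):
        assert rc.variance_of_t(7) == pytest.approx(1.4)

    def test_asymptotic_limit(self):
        assert rc.variance_of_t(10**6) == pytest.approx(1.0, abs=1e-5)

    @pytest.mark.parametrize("df", [0, 1, 2])
    def test_undefined_below_three(self, df):
        with pytest.raises(rc.UndefinedVarianceError):
            rc.variance_of_t(df)


class TestCombineWeights:
    def test_equal_variances(self):
        w = rc.combine_weights([2.0] * 4)
        assert [sw.weight for sw in w] == pytest.approx([0.5] * 4)

    def test_single_study(self):
        assert rc.combine_weights([1.7])[0].weight == pytest.approx(1.0)

    def test_unequal_variances(self):
        w = rc.combine_weights([1.0, 3.0])
        assert w[0].weight == pytest.approx(0.8660, abs=1e-4)
        assert w[1].weight == pytest.approx(0.5000, abs=1e-4)

    @given(
        st.lists(st.floats(1e-3, 1e3, allow_nan=False), min_size=1, max_size=12)
    )
    @settings(max_examples=100, deadline=None)
    def test_squared_weights_sum_to_one(self, variances):
        w = rc.combine_weights(variances)
        assert sum(sw.weight**2 for sw in w) == pytest.approx(1.0, abs=1e-12)

    def test_empty_list_rejected(self):
        with pytest.raises(rc.ValidationError):
            rc.combine_weights([])


class TestCombineT:
    def test_single_study_identity(self):
        w = rc.combine_weights([1.3])
        assert rc.combine_t([2.5], w) == pytest.approx(2.5)

    def test_stouffer_limit(self):
        # K equal-variance studies with the same t combine to t*sqrt(K)
        for k in (2, 5, 9):
            w = rc.combine_weights([1.25] * k)
            assert rc.combine_t([1.8] * k, w) == pytest.approx(1.8 * math.sqrt(k))

    def test_length_mismatch(self):
        with pytest.raises(rc.ValidationError):
            rc.combine_t([1.0, 2.0], rc.combine_weights([1.0]))

    def test_table1_scr_column_brute_force(self, table1):
        # combine the SCR column by a plain-python transcription of the
        # weighting formulae, independent of the implementation
        ts, vs, ns = [], [], []
        for e in table1:
            if "SCR" in e.methods_available:
                n = e.n_subjects("SCR")
                ts.append(e.cohen_d("SCR") * math.sqrt(n))
                vs.append((n - 1) / (n - 3))
                ns.append(n)
        inv_sum = sum(1.0 / v for v in vs)
        expected = sum(
            math.sqrt((1.0 / v) / inv_sum) * t for v, t in zip(vs, ts)
        )
        assert expected == pytest.approx(8.08, abs=0.01)
        got = rc.method_evidence(table1, "SCR")
        assert got.combined_t == pytest.approx(expected, rel=1e-12)


class TestLogBF:
    def test_null_closed_form(self):
        assert rc.log_bf10(0.0, 10, 10.0) == pytest.approx(-0.5 * math.log(11.0), rel=1e-12)

    def test_worked_value(self):
        assert rc.log_bf10(3.0, 20, 20.0) == pytest.approx(2.106, abs=1e-3)

    def test_even_in_t(self):
        assert rc.log_bf10(-4.2, 30, 30.0) == rc.log_bf10(4.2, 30, 30.0)

    def test_strictly_increasing_in_t_squared(self):
        ts = np.linspace(0, 20, 60)
        vals = [rc.log_bf10(t, 50, 50.0) for t in ts]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_matches_direct_formula_on_random_triples(self):
        # an independent numpy transcription of the g-prior identity
        rng = np.random.default_rng(42)
        t = rng.normal(0, 5, size=1000)
        n = rng.integers(3, 500, size=1000)
        g = rng.uniform(0.1, 1000, size=1000)
        direct = 0.5 * (
            (n - 2) * np.log(1 + g)
            - (n - 1) * np.log(1 + g / (t**2 / (n - 2) + 1))
        )
        got = np.array([rc.log_bf10(ti, ni, gi) for ti, ni, gi in zip(t, n, g)])
        np.testing.assert_allclose(got, direct, rtol=1e-10)

    def test_small_n_rejected(self):
        with pytest.raises(rc.ValidationError):
            rc.log_bf10(1.0, 2, 2.0)


class TestMethodEvidence:
    def test_table1_scr_total_n(self, table1):
        e = rc.method_evidence(table1, "SCR")
        assert e.total_n == 209
        assert e.g_param == 209.0
        assert len(e.studies_used) == 9

    def test_single_study_reduction(self):
        corpus = rc.CalibrationCorpus(
            [rc.StudySummary("only", "2020-01", "A", 0.6, 15)]
        )
        e = rc.method_evidence(corpus, "A")
        t1 = 0.6 * math.sqrt(15)
        assert e.combined_t == pytest.approx(t1, rel=1e-12)
        assert e.log_bf10 == pytest.approx(rc.log_bf10(t1, 15, 15.0), rel=1e-12)

    def test_order_invariance(self, table1):
        shuffled = rc.CalibrationCorpus(list(reversed([
            row for e in table1 for row in (
                rc.StudySummary(e.study_id, e.date, m, e.cohen_d(m), e.n_subjects(m))
                for m in sorted(e.methods_available)
            )
        ])))
        for m in table1.methods:
            a = rc.method_evidence(table1, m)
            b = rc.method_evidence(shuffled, m)
            assert a.combined_t == pytest.approx(b.combined_t, rel=1e-12)
            assert a.studies_used == b.studies_used

    def test_low_df_study_excluded_with_bookkeeping(self, caplog):
        corpus = rc.CalibrationCorpus(
            [
                rc.StudySummary("big", "2020-01", "A", 0.5, 20),
                rc.StudySummary("tiny", "2020-02", "A", 0.5, 3),  # df=2
            ]
        )
        with caplog.at_level("WARNING"):
            e = rc.method_evidence(corpus, "A")
        assert e.studies_used == ("big",)
        assert e.studies_excluded == ("tiny",)
        assert e.total_n == 20
        assert any("tiny" in r.message for r in caplog.records)

    def test_unknown_method_raises(self, table1):
        with pytest.raises(rc.AvailabilityError):
            rc.method_evidence(table1, "EEG")

    def test_g_rule_fixed(self, table1):
        e = rc.method_evidence(table1, "SCR", g_rule=50.0)
        assert e.g_param == 50.0
        assert e.log_bf10 == pytest.approx(
            rc.log_bf10(e.combined_t, 209, 50.0), rel=1e-12
        )

    def test_pooled_r_consistency(self, table1):
        e = rc.method_evidence(table1, "HPR")
        assert e.pooled_r == pytest.approx(
            rc.r_from_t(e.combined_t, e.total_n - 2), rel=1e-12
        )


class TestOverlap:
    def test_fixture_pair_counts(self, table1):
        ov = rc.overlap_matrix(table1)
        assert ov["HPR", "PSR"] == 114
        assert ov["HPR", "RAR"] == 149
        assert ov["HPR", "SCR"] == 175

    def test_symmetry_and_diagonal_bound(self, table1):
        ov = rc.overlap_matrix(table1).to_frame()
        assert (ov.values == ov.values.T).all()
        diag = np.diag(ov.values)
        for i in range(len(diag)):
            for j in range(len(diag)):
                assert ov.values[i, j] <= min(diag[i], diag[j])

    def test_diagonal_is_total_n(self, table1):
        ov = rc.overlap_matrix(table1)
        for m in table1.methods:
            assert ov[m, m] == rc.method_evidence(table1, m).total_n


class TestRestrictToOverlap:
    def test_full_method_set(self, table1):
        sub = rc.restrict_to_overlap(table1, ["SCR", "PSR", "RAR", "HPR"])
        assert sorted(sub.study_ids) == ["FER02", "PubFe", "SC4B"]

    def test_single_method(self, table1):
        sub = rc.restrict_to_overlap(table1, ["PSR"])
        assert len(sub) == 6

    def test_restriction_gives_full_overlap(self, table1):
        sub = rc.restrict_to_overlap(table1, ["SCR", "PSR", "RAR", "HPR"])
        ov = rc.overlap_matrix(sub).to_frame()
        assert (ov.values == ov.values[0, 0]).all()

    def test_no_common_study_is_diagnostic_error(self):
        corpus = rc.CalibrationCorpus(
            [
                rc.StudySummary("s1", "2020-01", "A", 0.5, 10),
                rc.StudySummary("s2", "2020-02", "B", 0.5, 10),
            ]
        )
        with pytest.raises(rc.EmptyCorpusError, match="s1"):
            rc.restrict_to_overlap(corpus, ["A", "B"])


class TestRanking:
    def test_delta_and_tie_break(self):
        evs = [
            rc.EvidenceResult("b", ("x",), 1.0, 10, 10.0, 3.0, 0.3),
            rc.EvidenceResult("a", ("x",), 1.0, 10, 10.0, 3.0, 0.3),
            rc.EvidenceResult("c", ("x",), 2.0, 10, 10.0, 5.0, 0.5),
        ]
        ranks = rc.rank_methods(evs)
        assert [r.method for r in ranks] == ["c", "a", "b"]
        assert [r.delta_log_bf10 for r in ranks] == pytest.approx([0.0, 2.0, 2.0])

    def test_single_method(self):
        ranks = rc.rank_methods([rc.EvidenceResult("a", ("x",), 1.0, 10, 10.0, 3.0, 0.3)])
        assert ranks[0].delta_log_bf10 == 0.0

    def test_fixture_ranks_hpr_first(self, table1):
        evs = rc.all_method_evidence(table1)
        ranks = rc.rank_methods(evs, overlap=rc.overlap_matrix(table1))
        assert ranks[0].method == "HPR"
        assert ranks[0].overlap_with_best == 175  # its own total N


class TestAccumulation:
    def test_carry_forward_when_method_absent(self):
        corpus = rc.CalibrationCorpus(
            [
                rc.StudySummary("s1", "2020-01", "A", 0.5, 10),
                rc.StudySummary("s2", "2020-02", "B", 0.5, 10),
                rc.StudySummary("s3", "2020-03", "B", 0.5, 10),
            ]
        )
        traj = rc.accumulate_evidence(corpus, "A")
        assert len(traj) == 3
        assert traj[1] is traj[0] and traj[2] is traj[0]
        assert traj[0].studies_used == ("s1",)

    def test_none_before_first_appearance(self):
        corpus = rc.CalibrationCorpus(
            [
                rc.StudySummary("s1", "2020-01", "B", 0.5, 10),
                rc.StudySummary("s2", "2020-02", "A", 0.5, 10),
            ]
        )
        traj = rc.accumulate_evidence(corpus, "A")
        assert traj[0] is None and traj[1] is not None

    def test_last_stage_equals_full_corpus(self, table1):
        for m in table1.methods:
            traj = rc.accumulate_evidence(table1, m)
            full = rc.method_evidence(table1, m)
            assert traj[-1].log_bf10 == pytest.approx(full.log_bf10, rel=1e-12)
            assert traj[-1].studies_used == full.studies_used

    def test_total_n_nondecreasing(self, table1):
        for m in table1.methods:
            ns = [e.total_n for e in rc.accumulate_evidence(table1, m) if e]
            assert all(b >= a for a, b in zip(ns, ns[1:]))


class TestRawStudySynthesisIntegration:
    def test_raw_and_summary_studies_combine(self):
        raw = make_two_condition_study(
            [1.0, 2.0, 3.0, 1.5, 2.5], bases=[0, 1, 2, 3, 4],
            study_id="raw1", date="2020-01",
        )
        summary = rc.StudySummary("sum1", "2020-02", "M", 0.8, 12)
        corpus = rc.CalibrationCorpus([raw, summary])
        e = rc.method_evidence(corpus, "M")
        assert set(e.studies_used) == {"raw1", "sum1"}
        assert e.total_n == 17
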