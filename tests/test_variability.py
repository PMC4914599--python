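"""CV machinery: per-cell intra/inter-subject estimators and aggregation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_table
from mrsrepro.study_data import load_paper_fixture
from mrsrepro.variability import (
    CVResult,
    ResamplingConfig,
    aggregate_report,
    cv,
    inter_subject_cv_resampled,
    intra_subject_cv,
)

# the exhaustive value for subjects {1,3} and {2,4}: avg mean 2.5, avg SD 1.0607
TOY_ENUM_CV = 42.426406871192846


class TestCv:
    def test_constant_series_is_zero(self):
        assert cv([5, 5, 5, 5]) == 0.0

    def test_closed_form_example(self):
        # sample SD 1.2910 over mean 2.5
        assert cv([1, 2, 3, 4]) == pytest.approx(51.6398, abs=1e-3)

    def test_errors(self):
        with pytest.raises(ValueError):
            cv([1.0])
        with pytest.raises(ZeroDivisionError):
            cv([-1.0, 1.0])

    @given(
        st.lists(st.floats(0.1, 100), min_size=2, max_size=20),
        st.floats(0.01, 50),
    )
    def test_scale_invariance(self, values, k):
        try:
            base = cv(values)
        except ZeroDivisionError:
            return
        assert cv([k * v for v in values]) == pytest.approx(base, rel=1e-9, abs=1e-9)


class TestIntraSubjectCv:
    def test_constant_within_subject_gives_zero(self):
        t = make_table(np.array([[7.0, 7.0], [3.0, 3.0]]))
        sd, icv = intra_subject_cv(t, "aMCC", "Glu")
        assert sd == 0.0 and icv == 0.0

    def test_two_subject_hand_computed_case(self):
        """Subjects {10,10} and {8,12}: per-subject CVs 0 and 28.28 average to 14.14."""
        t = make_table(np.array([[10.0, 10.0], [8.0, 12.0]]))
        sd, icv = intra_subject_cv(t, "aMCC", "Glu")
        assert icv == pytest.approx(14.1421, abs=1e-3)
        assert sd == pytest.approx(np.std([8, 12], ddof=1) / 2, abs=1e-9)

    def test_ratio_of_means_variant(self):
        t = make_table(np.array([[10.0, 10.0], [8.0, 12.0]]))
        _, icv = intra_subject_cv(t, "aMCC", "Glu", method="mean_sd_over_mean")
        assert icv == pytest.approx(np.std([8, 12], ddof=1) / 2 / 10 * 100, abs=1e-9)

    def test_single_session_subject_dropped_with_warning(self):
        t = make_table(np.array([[10.0, 10.0], [8.0, 12.0], [5.0, 5.0]]))
        frame = t.frame[~((t.frame.subject == "s2") & (t.frame.session == 2))]
        from mrsrepro.study_data import StudyTable

        with pytest.warns(UserWarning, match="s2"):
            _, icv = intra_subject_cv(StudyTable(frame), "aMCC", "Glu")
        assert icv == pytest.approx(14.1421, abs=1e-3)


class TestInterSubjectCvResampled:
    def test_degenerate_sessions_equal_plain_cross_subject_cv(self):
        vals = np.array([[4.0, 4.0, 4.0], [5.0, 5.0, 5.0], [7.0, 7.0, 7.0]])
        t = make_table(vals)
        expected = cv([4.0, 5.0, 7.0])
        for method in ("exhaustive", "monte_carlo"):
            _, ecv = inter_subject_cv_resampled(
                t, "aMCC", "Glu", ResamplingConfig(n_iter=50, seed=3, method=method)
            )
            assert ecv == pytest.approx(expected, rel=1e-12)

    def test_toy_enumeration_is_exact(self, toy_table):
        sd, ecv = inter_subject_cv_resampled(
            toy_table, "aMCC", "Glu", ResamplingConfig(method="exhaustive")
        )
        assert ecv == pytest.approx(TOY_ENUM_CV, rel=1e-12)
        assert sd == pytest.approx(1.06066, abs=1e-5)

    def test_auto_uses_enumeration_below_cap(self, toy_table):
        _, auto = inter_subject_cv_resampled(
            toy_table, "aMCC", "Glu", ResamplingConfig(method="auto", n_iter=3, seed=0)
        )
        assert auto == pytest.approx(TOY_ENUM_CV, rel=1e-12)

    def test_monte_carlo_converges_to_enumeration(self, toy_table):
        """5000 draws land within 3 delta-method SEs of the exhaustive value."""
        n_iter = 5000
        _, mc = inter_subject_cv_resampled(
            toy_table, "aMCC", "Glu",
            ResamplingConfig(n_iter=n_iter, seed=17, method="monte_carlo"),
        )
        se = _toy_mc_se(n_iter)
        assert abs(mc - TOY_ENUM_CV) < 3 * se

    def test_seed_reproducibility_and_seed_sensitivity(self, toy_table):
        cfg = ResamplingConfig(n_iter=200, seed=5, method="monte_carlo")
        a = inter_subject_cv_resampled(toy_table, "aMCC", "Glu", cfg)
        b = inter_subject_cv_resampled(toy_table, "aMCC", "Glu", cfg)
        assert a == b
        c = inter_subject_cv_resampled(
            toy_table, "aMCC", "Glu", ResamplingConfig(n_iter=200, seed=6, method="monte_carlo")
        )
        assert a != c

    def test_mc_error_shrinks_with_iterations(self, toy_table):
        """Across seeds, the MC estimator's SD scales like 1/sqrt(n_iter)."""
        def spread(n_iter):
            ests = [
                inter_subject_cv_resampled(
                    toy_table, "aMCC", "Glu",
                    ResamplingConfig(n_iter=n_iter, seed=s, method="monte_carlo"),
                )[1]
                for s in range(40)
            ]
            return np.std(ests)

        s_small, s_big = spread(50), spread(800)
        assert s_big < s_small / 2  # expect ratio ~ 1/4

    def test_shared_timepoint_mode_enumerates_sessions(self, toy_table):
        """Shared draws have only S outcomes: columns {1,2} and {3,4}."""
        _, ecv = inter_subject_cv_resampled(
            toy_table, "aMCC", "Glu",
            ResamplingConfig(mode="shared_timepoint", method="exhaustive"),
        )
        ms = [np.mean([1, 2]), np.mean([3, 4])]
        sds = [np.std([1, 2], ddof=1), np.std([3, 4], ddof=1)]
        assert ecv == pytest.approx(np.mean(sds) / np.mean(ms) * 100, rel=1e-12)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ResamplingConfig(n_iter=0)
        with pytest.raises(ValueError):
            ResamplingConfig(mode="bogus")


def _toy_mc_se(n_iter: int) -> float:
    """Delta-method SE of the toy MC estimator from the enumerated population."""
    ms, sds = [], []
    for c in itertools.product([1.0, 3.0], [2.0, 4.0]):
        ms.append(np.mean(c))
        sds.append(np.std(c, ddof=1))
    ms, sds = np.array(ms), np.array(sds)
    mbar, sbar = ms.mean(), sds.mean()
    g = np.array([1 / mbar, -sbar / mbar**2])  # d(s/m)/d(s,m)
    cov = np.cov(np.stack([sds, ms]), ddof=0) / n_iter
    return float(100 * np.sqrt(g @ cov @ g))


class TestAggregateReport:
    def _fixture_results(self):
        t3 = load_paper_fixture("table3")
        return [
            CVResult(
                region=r.region, metabolite=r.metabolite,
                mean_concentration=r.mean_concentration,
                intra_sd=r.intra_sd, intra_cv_percent=r.intra_cv_percent,
                inter_sd=r.inter_sd, inter_cv_percent=r.inter_cv_percent,
                n_subjects=9, n_sessions=4,
            )
            for r in t3.itertuples()
        ]

    def test_single_result_aggregates_to_itself(self):
        res = self._fixture_results()[:1]
        rep = aggregate_report(res)
        assert rep.study_intra_cv == res[0].intra_cv_percent
        assert rep.study_inter_cv == res[0].inter_cv_percent

    def test_aggregates_are_means_of_constituents(self):
        rep = aggregate_report(self._fixture_results())
        f = rep.to_frame()
        for region, row in rep.region_means.iterrows():
            expected = f[f.region == region]["intra_cv_percent"].mean()
            assert row["intra_cv_percent"] == pytest.approx(expected, rel=1e-12)
        assert rep.study_intra_cv == pytest.approx(
            rep.region_means["intra_cv_percent"].mean(), rel=1e-12
        )

    def test_left_posterior_insula_region_mean(self):
        rep = aggregate_report(self._fixture_results())
        assert rep.region_means.loc["pIL", "intra_cv_percent"] == pytest.approx(7.3, abs=0.05)

    def test_tnaa_metabolite_mean_across_regions(self):
        rep = aggregate_report(self._fixture_results())
        assert rep.metabolite_means.loc["tNAA", "inter_cv_percent"] == pytest.approx(7.18, abs=0.01)

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            aggregate_report([])

    def test_long_frame_contains_all_levels(self):
        long = aggregate_report(self._fixture_results()).to_long_frame()
        assert set(long["level"]) == {"cell", "region", "metabolite", "study"}
        assert (long[long.level == "study"].statistic == "intra_inter_gap").any()
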