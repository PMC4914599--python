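"""Repeated-measures ANOVA, ANCOVA partial F tests, CRLB-CV correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_table
from mrsrepro.inferential import (
    COVARIATES,
    ancova_covariates,
    crlb_cv_correlation,
    rm_anova_sessions,
)
from mrsrepro.study_data import StudyTable, load_paper_fixture


def rng_table(seed, n=9, S=4, mu=10.0, sigma=1.0, subject_sd=0.0, session_offsets=None):
    rng = np.random.default_rng(seed)
    y = mu + rng.normal(0, sigma, size=(n, S))
    if subject_sd:
        y += rng.normal(0, subject_sd, size=(n, 1))
    if session_offsets is not None:
        y += np.asarray(session_offsets)[None, :]
    return make_table(np.abs(y))


class TestRmAnova:
    def test_constant_sessions_give_f_zero_p_one(self):
        t = make_table(np.array([[5.0, 5.0, 5.0], [8.0, 8.0, 8.0]]))
        res = rm_anova_sessions(t, "aMCC", "Glu")
        assert res.F == 0.0 and res.p == 1.0

    def test_dof_match_design(self):
        res = rm_anova_sessions(rng_table(0), "aMCC", "Glu")
        assert (res.df_num, res.df_den) == (3, 24)

    def test_invariant_under_per_subject_shift(self):
        t = rng_table(1)
        mat = t.frame.pivot_table(index="subject", columns="session", values="concentration")
        shifted = mat + np.arange(len(mat))[:, None] * 5.0
        res0 = rm_anova_sessions(t, "aMCC", "Glu")
        res1 = rm_anova_sessions(make_table(shifted.to_numpy()), "aMCC", "Glu")
        assert res1.F == pytest.approx(res0.F, rel=1e-9)

    def test_matches_pingouin_oracle(self):
        """Closed-form sums of squares agree with an independent implementation."""
        pingouin = pytest.importorskip("pingouin")
        t = rng_table(2, session_offsets=[0.0, 0.4, -0.2, 0.1])
        res = rm_anova_sessions(t, "aMCC", "Glu", gg_correction=True)
        aov = pingouin.rm_anova(
            data=t.frame, dv="concentration", within="session", subject="subject",
            correction=True,
        )
        assert res.F == pytest.approx(float(aov["F"].iloc[0]), rel=1e-9)
        assert res.p == pytest.approx(float(aov["p_unc"].iloc[0]), rel=1e-9)
        assert res.gg_epsilon == pytest.approx(float(aov["eps"].iloc[0]), rel=1e-6)
        assert res.p_gg == pytest.approx(float(aov["p_GG_corr"].iloc[0]), rel=1e-6)

    def test_gg_epsilon_in_valid_range(self):
        res = rm_anova_sessions(rng_table(3), "aMCC", "Glu", gg_correction=True)
        assert 1 / (res.n_sessions - 1) <= res.gg_epsilon <= 1.0

    def test_too_small_design_rejected(self):
        with pytest.raises(ValueError, match="2 subjects"):
            rm_anova_sessions(make_table(np.array([[1.0, 2.0]])), "aMCC", "Glu")

    def test_incomplete_subject_dropped_with_warning(self):
        t = rng_table(4)
        frame = t.frame[~((t.frame.subject == "s0") & (t.frame.session == 2))]
        with pytest.warns(UserWarning, match="s0"):
            res = rm_anova_sessions(StudyTable(frame), "aMCC", "Glu")
        assert res.n_subjects == 8

    def test_null_rejection_rate_near_alpha(self):
        """Type-I error of the session test is ~5% on null Gaussian data."""
        R = 400
        rejections = sum(
            rm_anova_sessions(rng_table(100 + i), "aMCC", "Glu").p < 0.05 for i in range(R)
        )
        rate = rejections / R
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / R)

    def test_power_against_noncentral_f_oracle(self):
        """With a last-session offset of one within-subject SD at n=9 the
        empirical rejection rate matches the closed-form noncentral-F power."""
        offsets = [0.0, 0.0, 0.0, 1.0]
        n, S, R = 9, 4, 300
        lam = n * np.sum((np.array(offsets) - np.mean(offsets)) ** 2)  # sigma = 1
        crit = stats.f.isf(0.05, S - 1, (S - 1) * (n - 1))
        analytic = stats.ncf.sf(crit, S - 1, (S - 1) * (n - 1), lam)
        rejections = sum(
            rm_anova_sessions(
                rng_table(200 + i, session_offsets=offsets), "aMCC", "Glu"
            ).p < 0.05
            for i in range(R)
        )
        rate = rejections / R
        assert abs(rate - analytic) < 3 * np.sqrt(analytic * (1 - analytic) / R)


def study_with_covariates(seed, slope=0.0, cov_name="gm_wm_ratio", sigma=1.0):
    """One-metabolite study over 4 regions plus independent covariates."""
    rng = np.random.default_rng(seed)
    rows, cov_rows = [], []
    for i in range(9):
        for s in range(1, 5):
            day = rng.uniform(16, 22)
            d = rng.gamma(4.0, 0.2)
            for region in ("aMCC", "pgACC", "pIL", "pIR"):
                g = rng.normal(9.0, 1.5)
                c = 10.0 + 0.5 * i + rng.normal(0, sigma)
                cov_rows.append(
                    {"subject": f"s{i}", "session": s, "region": region,
                     "gm_wm_ratio": g, "daytime_hours": day, "displacement_d": d}
                )
                cov = {"gm_wm_ratio": g, "daytime_hours": day, "displacement_d": d}[cov_name]
                rows.append(
                    {"subject": f"s{i}", "session": s, "region": region,
                     "metabolite": "Glu", "concentration": max(c + slope * cov, 0.0),
                     "crlb_percent": 5.0}
                )
    return StudyTable(pd.DataFrame(rows)), pd.DataFrame(cov_rows)


class TestAncova:
    def test_partial_f_is_squared_t(self):
        table, cov = study_with_covariates(0)
        (res,) = ancova_covariates(table, cov)
        for term in COVARIATES:
            assert res.terms[term]["F"] == pytest.approx(res.terms[term]["t"] ** 2, rel=1e-12)
            assert res.terms[term]["df_num"] == 1

    def test_matches_statsmodels_type2_anova(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        table, cov = study_with_covariates(1, slope=0.3)
        (res,) = ancova_covariates(table, cov)
        data = table.frame.merge(cov, on=["subject", "session", "region"])
        fit = smf.ols(
            "concentration ~ C(subject) + C(region) + gm_wm_ratio + daytime_hours"
            " + displacement_d",
            data=data,
        ).fit()
        aov = sm.stats.anova_lm(fit, typ=2)
        for term in COVARIATES:
            assert res.terms[term]["F"] == pytest.approx(float(aov.loc[term, "F"]), rel=1e-8)
            assert res.terms[term]["p"] == pytest.approx(float(aov.loc[term, "PR(>F)"]), rel=1e-8)

    def test_covariate_orthogonal_to_residuals_has_zero_f(self):
        """Covariates orthogonalized against the fixed-effects residual carry
        no partial signal, so every partial F collapses to ~0."""
        table, cov = study_with_covariates(2)
        data = table.frame.merge(cov, on=["subject", "session", "region"])
        X0 = pd.get_dummies(data[["subject", "region"]], drop_first=False).to_numpy(float)
        y = data["concentration"].to_numpy()
        resid = y - X0 @ np.linalg.lstsq(X0, y, rcond=None)[0]
        r = resid / np.linalg.norm(resid)
        cov2 = cov.copy()
        for term in COVARIATES:
            c = data[term].to_numpy()
            cov2[term] = c - (c @ r) * r
        (res,) = ancova_covariates(table, cov2)
        for term in COVARIATES:
            assert res.terms[term]["F"] == pytest.approx(0.0, abs=1e-16)

    def test_rank_deficiency_names_aliased_column(self):
        table, cov = study_with_covariates(3)
        cov = cov.copy()
        cov["daytime_hours"] = 2.0 * cov["gm_wm_ratio"]  # exact collinearity
        with pytest.raises(np.linalg.LinAlgError, match="aliased"):
            ancova_covariates(table, cov)

    def test_missing_covariate_rows_rejected(self):
        table, cov = study_with_covariates(4)
        with pytest.raises(ValueError, match="missing"):
            ancova_covariates(table, cov[cov.session != 2])

    def test_null_rejection_rate_near_alpha(self):
        """With covariates independent of the response, each partial test
        rejects at ~alpha."""
        R = 250
        rej = {term: 0 for term in COVARIATES}
        for i in range(R):
            table, cov = study_with_covariates(500 + i)
            (res,) = ancova_covariates(table, cov)
            for term in COVARIATES:
                rej[term] += res.terms[term]["p"] < 0.05
        for term in COVARIATES:
            assert abs(rej[term] / R - 0.05) < 3 * np.sqrt(0.05 * 0.95 / R), term

    def test_strong_injected_covariate_detected(self):
        """A GM/WM-ratio slope explaining ~half the residual variance is
        essentially always significant."""
        hits = 0
        R = 60
        for i in range(R):
            # slope * sd(g) = sigma -> covariate variance ~ residual variance
            table, cov = study_with_covariates(900 + i, slope=1.0 / 1.5, sigma=1.0)
            (res,) = ancova_covariates(table, cov)
            hits += res.terms["gm_wm_ratio"]["p"] < 0.05
        assert hits >= 0.95 * R

    def test_pooled_variant_standardizes_within_metabolite(self, default_study):
        results = ancova_covariates(
            default_study["table"], default_study["covariates"], pooled=True
        )
        assert len(results) == 1 and results[0].metabolite == "pooled"
        assert results[0].n_obs == len(default_study["table"])


class TestCrlbCvCorrelation:
    def test_perfect_linear_relation(self):
        x = pd.Series({(r, m): v for v, (r, m) in enumerate(
            [("a", "x"), ("a", "y"), ("b", "x"), ("b", "y")])})
        res = crlb_cv_correlation(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        res_neg = crlb_cv_correlation(x, -x)
        assert res_neg.r == pytest.approx(-1.0)

    def test_affine_invariance(self):
        t3 = load_paper_fixture("table3").set_index(["region", "metabolite"])
        a = crlb_cv_correlation(t3["mean_crlb_percent"], t3["intra_cv_percent"])
        b = crlb_cv_correlation(3 * t3["mean_crlb_percent"] + 7, t3["intra_cv_percent"] / 2)
        assert a.r == pytest.approx(b.r, rel=1e-12)

    def test_zero_variance_margin_rejected(self):
        idx = [("a", "x"), ("a", "y"), ("b", "x")]
        with pytest.raises(ZeroDivisionError):
            crlb_cv_correlation(
                pd.Series(1.0, index=idx), pd.Series([1.0, 2.0, 3.0], index=idx)
            )

    def test_too_few_points_rejected(self):
        idx = [("a", "x"), ("a", "y")]
        with pytest.raises(ValueError, match="3 paired"):
            crlb_cv_correlation(pd.Series([1, 2.], index=idx), pd.Series([1, 2.], index=idx))
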