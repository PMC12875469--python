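"""Inference stage: correlations, stepwise selection, partial correlations,
and the dependent-correlation bootstrap."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest

from modsense.cohort import CohortParams, generate_cohort
from modsense.inference import (
    OUTCOME_VARS,
    THRESHOLD_VARS,
    analyze_cohort,
    corr_diff_boot,
    correlation_table,
    partial_correlation,
    partial_correlation_recursive,
    pearson,
    p_stars,
    report_to_markdown,
    ses_index,
    stepwise_forward,
    validate_cohort,
)


def textbook_r(x, y):
    """Independent oracle: product-moment formula written out."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    num = n * np.sum(x * y) - np.sum(x) * np.sum(y)
    den = np.sqrt(n * np.sum(x**2) - np.sum(x) ** 2) * np.sqrt(
        n * np.sum(y**2) - np.sum(y) ** 2
    )
    return num / den


class TestSESIndex:
    def test_bounds(self):
        assert ses_index(1, 1) == 1
        assert ses_index(8, 8) == 64

    @pytest.mark.parametrize("edu,occ", [(0, 4), (9, 4), (4, 0), (4, 9)])
    def test_out_of_scale(self, edu, occ):
        with pytest.raises(ValueError):
            ses_index(edu, occ)


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, p = pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_four_point_example(self):
        r, _ = pearson([1, 2, 3, 4], [2, 1, 4, 3])
        assert r == pytest.approx(0.6, abs=1e-12)

    def test_matches_textbook_formula(self, rng):
        for _ in range(20):
            x, y = rng.standard_normal((2, 50))
            assert pearson(x, y)[0] == pytest.approx(textbook_r(x, y), abs=1e-12)

    def test_independent_large_n(self, rng):
        x, y = rng.standard_normal((2, 10_000))
        assert abs(pearson(x, y)[0]) < 0.05

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestCorrelationTable:
    def test_self_correlation(self, cohort10k):
        tab = correlation_table(cohort10k, ["ses_index"], ["ses_index"])
        assert tab.loc["ses_index", "ses_index"]["r"] == 1.0

    def test_transpose_symmetry(self, cohort10k):
        a = correlation_table(cohort10k, ["ses_index"], ["vocab_raw"])
        b = correlation_table(cohort10k, ["vocab_raw"], ["ses_index"])
        assert a.loc["ses_index", "vocab_raw"]["r"] == pytest.approx(
            b.loc["vocab_raw", "ses_index"]["r"]
        )

    def test_matches_generating_correlations(self, cohort10k):
        """Generator ground truth: r(threshold, outcome) = -lambda*(b1+b2*a1)
        ~= -0.53 before boundary clipping; allow clipping attenuation."""
        tab = correlation_table(cohort10k, THRESHOLD_VARS, OUTCOME_VARS)
        for t in THRESHOLD_VARS:
            for y in OUTCOME_VARS:
                assert tab.loc[t, y]["r"] == pytest.approx(-0.53, abs=0.05)

    def test_unknown_variable(self, cohort10k):
        with pytest.raises(KeyError):
            correlation_table(cohort10k, ["nope"], ["vocab_raw"])


class TestStars:
    def test_convention(self):
        assert p_stars(0.0005) == "***"
        assert p_stars(0.005) == "**"
        assert p_stars(0.04) == "*"
        assert p_stars(0.2) == ""


class TestStepwise:
    def test_single_predictor_beta_equals_r(self, rng):
        x = rng.standard_normal(200)
        y = 0.8 * x + 0.3 * rng.standard_normal(200)
        res = stepwise_forward(y, {"x": x})
        assert len(res.steps) == 1
        assert res.steps[0].betas["x"] == pytest.approx(pearson(x, y)[0], abs=1e-10)

    def test_noise_predictor_excluded(self, rng):
        x1, x2 = rng.standard_normal((2, 1000))
        y = x1 + 0.5 * rng.standard_normal(1000)
        res = stepwise_forward(y, {"x1": x1, "x2": x2})
        assert res.selected == ("x1",)

    def test_orthogonal_predictors_r2_additive(self, rng):
        # exactly sample-orthogonal predictors make the identity exact
        X = exact_corr_data(np.eye(2), n=500, seed=9)
        x1, x2 = X[:, 0], X[:, 1]
        y = 0.5 * x1 + 0.5 * x2 + rng.standard_normal(500)
        res = stepwise_forward(y, {"x1": x1, "x2": x2})
        assert set(res.selected) == {"x1", "x2"}
        r2_1 = pearson(x1, y)[0] ** 2
        r2_2 = pearson(x2, y)[0] ** 2
        assert res.r2 == pytest.approx(r2_1 + r2_2, abs=1e-10)

    def test_r2_nondecreasing(self, cohort10k):
        sub = cohort10k.iloc[:500]
        res = stepwise_forward(
            sub["icc_pct"].to_numpy(), {t: sub[t].to_numpy() for t in THRESHOLD_VARS}
        )
        r2s = [s.r2 for s in res.steps]
        assert all(b >= a for a, b in zip(r2s, r2s[1:]))

    def test_no_entry_gives_zero_steps(self, rng):
        y, x = rng.standard_normal((2, 100))
        res = stepwise_forward(y, {"x": x}, p_enter=1e-12)
        assert res.steps == ()


def exact_corr_data(R, n=100, seed=0):
    """Vectors whose *sample* correlation matrix equals R exactly: whiten a
    random draw, then color with chol(R)."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, R.shape[0]))
    X = X - X.mean(axis=0)
    # exact sample-whitening
    cov = X.T @ X / (n - 1)
    X = X @ np.linalg.inv(np.linalg.cholesky(cov)).T
    X = X @ np.linalg.cholesky(R).T
    return X


class TestPartialCorrelation:
    def test_closed_form_example(self):
        """r_xy.z = (r_xy - r_xz*r_yz)/sqrt((1-r_xz^2)(1-r_yz^2)) with
        r_xy=.5, r_xz=r_yz=.6 gives 0.21875 exactly."""
        R = np.array([[1.0, 0.5, 0.6], [0.5, 1.0, 0.6], [0.6, 0.6, 1.0]])
        X = exact_corr_data(R)
        res = partial_correlation(X[:, 1], X[:, 0], {"z": X[:, 2]})
        assert res.r_partial == pytest.approx(0.21875, abs=1e-10)
        assert res.df == 100 - 2 - 1

    def test_no_controls_equals_pearson(self, rng):
        x, y = rng.standard_normal((2, 60))
        res = partial_correlation(y, x, {})
        assert res.r_partial == pytest.approx(pearson(x, y)[0], abs=1e-12)
        assert res.df == 58

    def test_null_control_limit(self, rng):
        x, y, z = rng.standard_normal((3, 10_000))
        y = 0.5 * x + y
        simple = pearson(x, y)[0]
        res = partial_correlation(y, x, {"z": z})
        assert res.r_partial == pytest.approx(simple, abs=0.03)

    def test_residual_vs_recursive_oracle(self, rng):
        for _ in range(20):
            data = rng.standard_normal((4, 80))
            y, x, z1, z2 = data
            y = y + 0.4 * z1
            x = x + 0.3 * z2
            a = partial_correlation(y, x, {"z1": z1, "z2": z2}).r_partial
            b = partial_correlation_recursive(y, x, [z1, z2])
            assert a == pytest.approx(b, abs=1e-10)

    def test_matches_pingouin(self, rng):
        data = rng.standard_normal((4, 120))
        y, x, z1, z2 = data
        df = pd.DataFrame({"x": x, "y": y + 0.4 * z1, "z1": z1, "z2": z2})
        mine = partial_correlation(df["y"], df["x"], {"z1": z1, "z2": z2})
        ref = pg.partial_corr(df, x="x", y="y", covar=["z1", "z2"])
        assert mine.r_partial == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)
        assert mine.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-8)

    def test_collinear_controls_rejected(self, rng):
        x, y, z = rng.standard_normal((3, 50))
        with pytest.raises(ValueError):
            partial_correlation(y, x, {"z": z, "z2": 2 * z})


class TestCorrDiffBoot:
    def _null_frame(self, seed=0, n=104):
        rng = np.random.default_rng(seed)
        L = np.linalg.cholesky(np.array([[1, 0.5, 0.5], [0.5, 1, 0.6], [0.5, 0.6, 1]]))
        Z = rng.standard_normal((n, 3)) @ L.T
        return pd.DataFrame(Z, columns=["x", "y1", "y2"])

    def test_identical_outcomes_null(self):
        df = self._null_frame()
        df["y2"] = df["y1"]
        res = corr_diff_boot(df, "x", "y1", "y2", n_boot=500, seed=1)
        assert res.statistic == 0.0
        assert res.p == pytest.approx(0.5)

    def test_deterministic_under_seed(self):
        df = self._null_frame(3)
        a = corr_diff_boot(df, "x", "y1", "y2", n_boot=600, seed=7)
        b = corr_diff_boot(df, "x", "y1", "y2", n_boot=600, seed=7)
        assert (a.statistic, a.se_boot, a.p) == (b.statistic, b.se_boot, b.p)

    def test_relabeling_flips_sign(self):
        df = self._null_frame(4)
        a = corr_diff_boot(df, "x", "y1", "y2", n_boot=800, seed=5)
        b = corr_diff_boot(df, "x", "y2", "y1", n_boot=800, seed=5)
        assert b.statistic == pytest.approx(-a.statistic, rel=0.2)
        assert np.sign(a.statistic) == np.sign(a.r1 - a.r2)

    def test_se_stable_when_doubling_replicates(self):
        df = self._null_frame(6)
        a = corr_diff_boot(df, "x", "y1", "y2", n_boot=2000, seed=8)
        b = corr_diff_boot(df, "x", "y1", "y2", n_boot=4000, seed=8)
        assert abs(b.se_boot - a.se_boot) / a.se_boot < 0.05

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            corr_diff_boot(self._null_frame(), "x", "y1", "y2", n_boot=100, seed=0)


@pytest.fixture(scope="module")
def report():
    cohort = generate_cohort(CohortParams(n=104), seed=11)
    return analyze_cohort(cohort, n_boot=500, seed=2)


class TestAnalyzeCohort:
    def test_report_structure(self, report):
        assert report.modulation_language_corr.shape == (3, 4)
        assert set(report.stepwise) == set(OUTCOME_VARS)
        assert len(report.corr_diffs) == 12  # 3 thresholds x 2 lex x 2 phon
        assert report.risk_factor_corr.shape == (2, 7)
        assert set(report.ses_partials) == set(OUTCOME_VARS)
        assert set(report.ga_partials) == set(OUTCOME_VARS)

    def test_partial_controls_follow_stepwise(self, report):
        for outcome, cell in report.ses_partials.items():
            selected = report.stepwise[outcome].selected or THRESHOLD_VARS
            assert set(cell) == {"ses_index", *selected}

    def test_markdown_render(self, report):
        md = report_to_markdown(report)
        assert "Stepwise regression" in md and "|" in md

    def test_mediation_contrast_large_n(self, cohort10k):
        """Full-mediation generator: gestational-age partials controlling
        the thresholds collapse to ~0 while threshold partials controlling
        gestational age stay strongly negative."""
        ctrl = {t: cohort10k[t].to_numpy() for t in THRESHOLD_VARS}
        ga = cohort10k["gestational_age_weeks"].to_numpy()
        for y in OUTCOME_VARS:
            yv = cohort10k[y].to_numpy()
            assert abs(partial_correlation(yv, ga, ctrl).r_partial) < 0.05
            thr = partial_correlation(yv, cohort10k["spectral_dB"].to_numpy(), {"ga": ga})
            assert thr.r_partial < -0.3

    def test_ses_direct_path_survives(self, cohort10k):
        """Partial mediation of SES: a direct SES->language path keeps the
        SES partials positive and significant after controlling thresholds."""
        ctrl = {t: cohort10k[t].to_numpy() for t in THRESHOLD_VARS}
        for y in OUTCOME_VARS:
            res = partial_correlation(
                cohort10k[y].to_numpy(), cohort10k["ses_index"].to_numpy(), ctrl
            )
            assert res.r_partial > 0.2 and res.p < 0.001


class TestValidateCohort:
    def test_rejects_out_of_range(self, cohort10k):
        bad = cohort10k.iloc[:50].copy()
        bad.loc[bad.index[0], "ses_index"] = 70
        with pytest.raises(ValueError):
            validate_cohort(bad)

    def test_rejects_missing_column(self, cohort10k):
        with pytest.raises(KeyError):
            validate_cohort(cohort10k.drop(columns=["vocab_raw"]))
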