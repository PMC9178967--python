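"""Mixed-model machinery: coding, standardization, fits, post hoc adjustment."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.stats import studentized_range

from wmh_penumbra import phantom as ph
from wmh_penumbra import stats as st


class TestStandardize:
    def test_within_group_mean_zero_sd_one(self):
        tab = ph.simulate_roi_table(5, 5, seed=0)
        out = st.standardize_predictors(tab, predictors=("age", "moca"))
        for g, sub in out.groupby("group"):
            assert sub["age_z"].mean() == pytest.approx(0.0, abs=1e-12)
            assert sub["age_z"].std() == pytest.approx(1.0, rel=1e-9)

    def test_groups_with_different_means_both_centered(self):
        df = pd.DataFrame(
            {
                "group": ["a"] * 3 + ["b"] * 3,
                "age": [60.0, 65.0, 70.0, 40.0, 45.0, 50.0],
            }
        )
        out = st.standardize_predictors(df, predictors=("age",))
        assert out.groupby("group")["age_z"].mean().abs().max() <= 1e-12

    def test_hand_computed_four_row_example(self):
        df = pd.DataFrame({"group": ["a", "a", "b", "b"], "age": [10.0, 20.0, 1.0, 3.0]})
        out = st.standardize_predictors(df, predictors=("age",))
        sa = np.std([10.0, 20.0], ddof=1)
        sb = np.std([1.0, 3.0], ddof=1)
        np.testing.assert_allclose(
            out["age_z"], [-5.0 / sa, 5.0 / sa, -1.0 / sb, 1.0 / sb]
        )

    def test_zero_variance_names_predictor(self):
        df = pd.DataFrame({"group": ["a", "a"], "age": [60.0, 60.0]})
        with pytest.raises(ValueError, match="age"):
            st.standardize_predictors(df, predictors=("age",))


class TestLogVolume:
    def test_values(self):
        assert st.log_wmh_volume(1.0) == 0.0
        assert st.log_wmh_volume(np.e) == pytest.approx(1.0)

    def test_monotone(self):
        v = np.array([0.1, 0.5, 2.0, 9.0])
        assert np.all(np.diff(st.log_wmh_volume(v)) > 0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            st.log_wmh_volume(0.0)


class TestQuadraticContrast:
    def test_orthogonal_zero_sum_unit_norm(self):
        codes = st.quadratic_contrast()
        lin, quad = codes["dist_lin"].values, codes["dist_quad"].values
        assert abs(lin @ quad) <= 1e-12
        assert abs(lin.sum()) <= 1e-12 and abs(quad.sum()) <= 1e-12
        assert np.linalg.norm(lin) == pytest.approx(1.0)
        assert np.linalg.norm(quad) == pytest.approx(1.0)

    def test_quadratic_symmetric_about_middle(self):
        quad = st.quadratic_contrast()["dist_quad"].values
        np.testing.assert_allclose(quad, quad[::-1], atol=1e-12)
        assert quad[0] > 0  # U-shape convention

    def test_equals_gram_schmidt_of_powers(self):
        x = np.arange(1.0, 7.0)
        ones = np.ones(6) / np.sqrt(6)
        v1 = x - (x @ ones) * ones
        v1 /= np.linalg.norm(v1)
        v2 = x**2 - (x**2 @ ones) * ones - (x**2 @ v1) * v1
        v2 /= np.linalg.norm(v2)
        codes = st.quadratic_contrast()
        np.testing.assert_allclose(np.abs(codes["dist_lin"]), np.abs(v1), atol=1e-12)
        np.testing.assert_allclose(np.abs(codes["dist_quad"]), np.abs(v2), atol=1e-12)


class TestDistanceGroupModel:
    def test_programmed_gradient_detected_with_correct_sign(self):
        tab = ph.simulate_roi_table(20, 14, seed=3)
        fit = st.fit_distance_group(tab, "GMT2")
        b, _, p = fit.term("dist_quad")
        assert p < 0.05 and b > 0  # convex decrease away from the lesion
        fa = st.fit_distance_group(tab, "FA")
        assert fa.term("dist_quad")[2] < 0.05 and fa.term("dist_quad")[0] < 0

    def test_mwf_interaction_detected(self):
        tab = ph.simulate_roi_table(20, 14, seed=3)
        fit = st.fit_distance_group(tab, "MWF")
        assert fit.pvalues["dist_quad:group_oa"] < 0.05

    def test_missing_level_rejected(self):
        tab = ph.simulate_roi_table(5, 5, seed=0)
        broken = tab[tab["distance_level"] != "6"]
        with pytest.raises(ValueError, match="6"):
            st.fit_distance_group(broken, "FA")

    def test_too_few_subjects_rejected(self):
        tab = ph.simulate_roi_table(1, 5, seed=0)
        tab = tab[
            ~((tab["group"] == "older_adult") & (tab["subject_id"] != "sub-001"))
        ]
        with pytest.raises(ValueError):
            st.fit_distance_group(tab, "FA")

    def test_balanced_zero_variance_matches_ols(self):
        """With no scanner/subject variance in the generator, mixed-model
        fixed effects coincide with OLS on the same balanced design."""
        import statsmodels.formula.api as smf

        # FA has no subject-level severity coupling, so with zero scanner and
        # subject random variance the data are purely fixed-effects + iid noise
        tab = ph.simulate_roi_table(
            8, 8, seed=5, scanner_sd_frac=0.0, subject_sd_frac=0.0
        )
        fit = st.fit_distance_group(tab, "FA")
        df = tab[tab["metric"] == "FA"].copy()
        df = st.standardize_predictors(df, predictors=("age", "moca"))
        df = df.join(st.quadratic_contrast(), on="distance_level")
        df["group_oa"] = (df["group"] == "older_adult").astype(float)
        ols = smf.ols(
            "value ~ age_z + moca_z + dist_lin + dist_quad + group_oa"
            " + dist_lin:group_oa + dist_quad:group_oa",
            df,
        ).fit()
        for term in fit.params.index:
            assert fit.params[term] == pytest.approx(ols.params[term], abs=1e-6)


class TestHemisphereModel:
    @staticmethod
    def hemi_table(offset, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        codes = ["WMH", "2", "4", "6", "8", "10"]
        for i in range(12):
            base = 80.0 + rng.normal(0, 1.0)
            for hemi, off in (("ipsilesional", offset), ("contralesional", 0.0)):
                for lev, d in zip(codes, (0, 1, 3, 5, 7, 9)):
                    rows.append(
                        {
                            "subject_id": f"s{i}",
                            "group": "stroke",
                            "scanner": "A_32echo" if i % 2 else "B_48echo",
                            "hemisphere": hemi,
                            "distance_level": lev,
                            "metric": "GMT2",
                            "value": base + 20 * max(0, 1 - d / 6) ** 2 + off + rng.normal(0, 1.0),
                            "age": rng.uniform(50, 80),
                            "moca": rng.integers(20, 30),
                        }
                    )
        return pd.DataFrame(rows)

    def test_programmed_ipsilesional_offset_detected(self):
        fit = st.fit_distance_hemisphere(self.hemi_table(offset=4.0), "GMT2")
        assert fit.pvalues["hemi_contra"] < 0.05
        assert fit.params["hemi_contra"] < 0  # contralesional lower

    def test_symmetric_hemispheres_null(self):
        fit = st.fit_distance_hemisphere(self.hemi_table(offset=0.0, seed=8), "GMT2")
        assert fit.pvalues["hemi_contra"] > 0.05

    def test_distance_gradient_still_detected(self):
        fit = st.fit_distance_hemisphere(self.hemi_table(offset=0.0), "GMT2")
        assert fit.pvalues["dist_quad"] < 0.05

    def test_missing_hemisphere_column_rejected(self):
        tab = ph.simulate_roi_table(3, 3, seed=0)
        with pytest.raises(ValueError, match="hemisphere"):
            st.fit_distance_hemisphere(tab, "GMT2")


class TestVolumeModel:
    def test_severity_coupling_signs(self):
        tab = ph.simulate_roi_table(20, 14, seed=47)
        for metric, sign in (("MD", +1), ("GMT2", +1), ("MWF", -1)):
            fit = st.fit_wmh_volume_model(tab, metric)
            b, _, p = fit.term("log_wmh_volume_z")
            assert np.sign(b) == sign, metric
            assert p < 0.05, metric

    def test_shuffled_volumes_are_null(self):
        tab = ph.simulate_roi_table(20, 14, seed=47)
        rng = np.random.default_rng(0)
        vols = tab.drop_duplicates("subject_id").set_index("subject_id")["wmh_volume_ml"]
        shuffled = pd.Series(rng.permutation(vols.values), index=vols.index)
        tab = tab.copy()
        tab["wmh_volume_ml"] = tab["subject_id"].map(shuffled)
        fit = st.fit_wmh_volume_model(tab, "GMT2")
        assert fit.term("log_wmh_volume_z")[2] > 0.05

    def test_duplicate_subject_rows_rejected(self):
        tab = ph.simulate_roi_table(5, 5, seed=0)
        doubled = pd.concat([tab, tab.iloc[:24]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            st.fit_wmh_volume_model(doubled, "GMT2")


@pytest.fixture(scope="module")
def fit():
    tab = ph.simulate_roi_table(10, 8, seed=7)
    return st.fit_distance_group(tab, "GMT2")


class TestTukey:

    def test_adjusted_p_dominates_raw(self, fit):
        for c in st.tukey_posthoc(fit, family="distance"):
            assert c.p_adjusted >= c.p_raw

    def test_family_sizes(self, fit):
        assert len(st.tukey_posthoc(fit, family="distance")) == 15  # C(6,2)
        assert len(st.tukey_posthoc(fit, family="interaction")) == 36  # 2*15 + 6

    def test_adjustment_matches_independent_implementation(self, fit):
        """The studentized-range correction agrees with statsmodels' Tukey
        table (psturng) on every contrast of a fixed fit."""
        from statsmodels.stats.libqsturng import psturng

        # the adjustment function itself, over a grid of statistics
        for q in (3.0, 3.5, 4.0, 4.5, 5.0):
            mine = float(studentized_range.sf(q, 6, 100))
            ref = float(np.atleast_1d(psturng(q, 6, 100))[0])
            assert mine == pytest.approx(ref, abs=0.005)
        # and on the fit's own contrasts, where the interpolation table applies
        df = fit.model_result.nobs - len(fit.model_result.fe_params)
        for c in st.tukey_posthoc(fit, family="distance"):
            if not 0.001 <= c.p_adjusted <= 0.9:
                continue
            q = abs(c.estimate / c.se) * np.sqrt(2)
            ref = float(np.atleast_1d(psturng(q, 6, df))[0])
            assert c.p_adjusted == pytest.approx(ref, abs=0.03)

    def test_wmh_vs_rings_most_extreme(self, fit):
        cons = {c.label: c for c in st.tukey_posthoc(fit, family="distance")}
        assert cons["WMH - 10"].estimate > 0
        assert cons["WMH - 10"].p_adjusted < 0.05


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not installed")
def test_mixed_model_agrees_with_lme4(tmp_path):
    """Cross-implementation oracle: REML fixed effects from our fit match
    lme4 on the same data (same model formula and nesting) to 4 decimals."""
    tab = ph.simulate_roi_table(8, 6, seed=13)
    fit = st.fit_distance_group(tab, "GMT2")
    df = tab[tab["metric"] == "GMT2"].copy()
    df = st.standardize_predictors(df, predictors=("age", "moca"))
    df = df.join(st.quadratic_contrast(), on="distance_level")
    df["group_oa"] = (df["group"] == "older_adult").astype(float)
    csv = tmp_path / "d.csv"
    df.to_csv(csv, index=False)
    rscript = f"""
    suppressMessages(library(lme4))
    d <- read.csv("{csv}")
    m <- lmer(value ~ age_z + moca_z + dist_lin + dist_quad + group_oa
              + dist_lin:group_oa + dist_quad:group_oa
              + (1 | scanner) + (1 | scanner:subject_id), data = d, REML = TRUE)
    cat(fixef(m), sep = "\\n")
    """
    r = subprocess.run(
        ["Rscript", "-e", rscript], capture_output=True, text=True, timeout=300
    )
    assert r.returncode == 0, r.stderr
    ref = np.array([float(x) for x in r.stdout.split()])
    ours = fit.params[
        ["Intercept", "age_z", "moca_z", "dist_lin", "dist_quad", "group_oa",
         "dist_lin:group_oa", "dist_quad:group_oa"]
    ].values
    np.testing.assert_allclose(ours, ref, atol=2e-3, rtol=1e-3)
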