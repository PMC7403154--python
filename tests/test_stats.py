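"""Outlier screening, mixed model, OLS, Bland-Altman, descriptives."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pwmillusion import (SimulationConfig, bland_altman, descriptive_summary,
                         fit_mixed_model, fit_ols, load_measurements,
                         mahalanobis_screen, replicate_bcva,
                         simulate_subjects)


def _table(sf, va, dtype="plus_lens", level="+1D"):
    return pd.DataFrame({
        "subject_id": [f"S{i}" for i in range(len(sf))],
        "degradation_type": dtype,
        "degradation_level": level,
        "limiting_sf_cpd": sf,
        "va_logmar": va,
    })


class TestMahalanobisScreen:
    def test_point_at_mean_never_excluded(self):
        rng = np.random.default_rng(0)
        sf = rng.normal(4, 0.5, 30)
        va = rng.normal(0.3, 0.1, 30)
        df = _table(np.append(sf, sf.mean()), np.append(va, va.mean()))
        mask = mahalanobis_screen(df, per_level=False)
        assert mask[-1]

    def test_gross_outlier_flagged(self):
        rng = np.random.default_rng(1)
        sf = rng.normal(4, 0.5, 40)
        va = 0.3 + 0.1 * rng.normal(size=40)
        sf[0] = sf.mean() + 10 * sf.std()
        df = _table(sf, va)
        mask = mahalanobis_screen(df, per_level=False)
        assert not mask[0]
        # brute-force distance agrees with the decision
        x = df[["limiting_sf_cpd", "va_logmar"]].to_numpy()
        inv = np.linalg.inv(np.cov(x, rowvar=False))
        mu = x.mean(axis=0)
        d2 = np.array([(r - mu) @ inv @ (r - mu) for r in x])
        np.testing.assert_array_equal(mask, d2 <= sps.chi2.ppf(0.975, 2))

    def test_affine_invariance(self):
        df = simulate_subjects(SimulationConfig(seed=2, outlier_rate=0.05))
        mask1 = mahalanobis_screen(df)
        scaled = df.copy()
        scaled["limiting_sf_cpd"] *= 37.5
        np.testing.assert_array_equal(mask1, mahalanobis_screen(scaled))

    def test_too_few_rows_rejected(self):
        df = _table([1.0, 2.0], [0.1, 0.2])
        with pytest.raises(ValueError):
            mahalanobis_screen(df, per_level=False)


class TestMixedModel:
    def test_known_slope_recovered_and_null_terms_quiet(self):
        # equal generating lines for both types: no type effect, no
        # interactions; the SF slope CI should cover the truth
        coeffs = {"occlusion_foil": (1.3, -0.25), "plus_lens": (1.3, -0.25)}
        cover = 0
        type_quiet = 0
        inter_quiet = 0
        n_rep = 30
        for seed in range(n_rep):
            df = simulate_subjects(SimulationConfig(seed=seed,
                                                    coefficients=coeffs))
            res = fit_mixed_model(df)
            lo, hi = res.slope_sf_ci
            cover += lo <= -0.25 <= hi
            ft = res.f_tests.set_index("term")
            type_quiet += ft.loc["degradation_type", "p"] > 0.05
            inter_quiet += \
                ft.loc["limiting_sf_cpd:degradation_type", "p"] > 0.05
        assert cover >= int(0.9 * n_rep)
        assert type_quiet >= int(0.9 * n_rep)
        assert inter_quiet >= int(0.9 * n_rep)

    def test_reml_matches_closed_form_anova(self):
        # balanced one-way random-intercept data: REML variance components
        # equal the ANOVA moment estimators
        import statsmodels.formula.api as smf
        rng = np.random.default_rng(0)
        k, n = 12, 8
        b = rng.normal(0, 0.3, k)
        y = np.concatenate([bi + rng.normal(0, 0.5, n) for bi in b])
        df = pd.DataFrame({"y": y, "g": np.repeat(np.arange(k), n)})
        fit = smf.mixedlm("y ~ 1", df, groups=df["g"]).fit(
            reml=True, method="powell", maxiter=2000)
        gm = df.groupby("g")["y"].mean()
        msw = float(sum(((df[df.g == i].y - gm[i]) ** 2).sum()
                        for i in range(k)) / (k * (n - 1)))
        msb = float(n * ((gm - gm.mean()) ** 2).sum() / (k - 1))
        assert fit.scale == pytest.approx(msw, abs=1e-6)
        assert float(fit.cov_re.iloc[0, 0]) == \
            pytest.approx((msb - msw) / n, abs=1e-6)

    def test_diagnostics_reported(self):
        res = fit_mixed_model(simulate_subjects(SimulationConfig(seed=3)))
        assert 0 <= res.shapiro_p <= 1
        assert 0 <= res.brown_forsythe_p <= 1
        assert (res.vif >= 1).all()
        assert "residual" in res.df_method
        assert set(res.f_tests["term"]) == {
            "limiting_sf_cpd", "degradation_type", "level_in_type",
            "limiting_sf_cpd:degradation_type",
            "limiting_sf_cpd:level_in_type"}

    def test_single_subject_rejected(self):
        df = simulate_subjects(SimulationConfig(seed=0))
        with pytest.raises(ValueError):
            fit_mixed_model(df[df.subject_id == "S01"])


class TestOls:
    def test_exact_line(self):
        sf = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = fit_ols(_table(sf, 1.0 - 0.2 * sf))
        assert res.slope == pytest.approx(-0.2)
        assert res.intercept == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_three_point_hand_arithmetic(self):
        res = fit_ols(_table([1.0, 2.0, 3.0], [0.9, 0.7, 0.6]))
        assert res.slope == pytest.approx(-0.15)
        assert res.intercept == pytest.approx(31.0 / 30.0)
        assert res.r_squared == pytest.approx(27.0 / 28.0)
        assert res.df_num == 1 and res.df_den == 1

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_ols(_table([2.0, 2.0, 2.0], [0.1, 0.2, 0.3]))


class TestBlandAltman:
    def test_identical_series(self):
        r = bland_altman([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert r.mean_diff == 0 and r.loa_lower == 0 and r.loa_upper == 0
        assert r.t_statistic == 0 and r.p_value == 1.0

    def test_ols_predictions_have_zero_mean_difference(self):
        # OLS residuals sum to zero, so predicted-vs-observed agreement is
        # centered exactly at 0 with t = 0
        df = simulate_subjects(SimulationConfig(seed=11))
        sub = replicate_bcva(df)
        sub = sub[sub.degradation_type == "occlusion_foil"]
        res = fit_ols(sub)
        r = bland_altman(res.predict(sub["limiting_sf_cpd"]), sub["va_logmar"])
        assert r.mean_diff == pytest.approx(0.0, abs=1e-12)
        assert r.t_statistic == pytest.approx(0.0, abs=1e-10)
        assert r.p_value == pytest.approx(1.0, abs=1e-9)

    def test_hand_arithmetic_loa(self):
        r = bland_altman([0.0, 1.0, 2.0], [1.0, 1.0, 1.0])
        assert r.mean_diff == pytest.approx(0.0)
        assert r.sd_diff == pytest.approx(1.0)
        assert r.loa_lower == pytest.approx(-1.96)
        assert r.loa_upper == pytest.approx(1.96)
        assert r.loa_lower <= r.mean_diff <= r.loa_upper

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0], [1.0, 2.0, 3.0])


class TestDescriptives:
    def test_median_of_three(self):
        df = _table([2.9, 3.7, 5.1], [0.1, 0.2, 0.3])
        out = descriptive_summary(df)
        assert out.loc[0, "sf_median"] == pytest.approx(3.7)

    def test_quartile_convention(self):
        df = _table([1.0, 2.0, 3.0, 4.0], [0.0, 0.0, 0.1, 0.1])
        out = descriptive_summary(df)
        assert out.loc[0, "sf_q1"] == pytest.approx(1.75)
        assert out.loc[0, "sf_q3"] == pytest.approx(3.25)

    def test_groups_by_type_and_level(self):
        df = simulate_subjects(SimulationConfig(seed=0))
        out = descriptive_summary(df)
        assert len(out) == 5
        assert (out["n"] == 21).all()


class TestLoader:
    def test_round_trip_and_column_map(self, tmp_path):
        df = simulate_subjects(SimulationConfig(seed=4))
        p = tmp_path / "data.csv"
        df.rename(columns={"limiting_sf_cpd": "LSF (cpd)"}).to_csv(p, index=False)
        loaded = load_measurements(p, column_map={"LSF (cpd)": "limiting_sf_cpd"})
        pd.testing.assert_frame_equal(loaded, df)

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        pd.DataFrame({"subject_id": ["a"]}).to_csv(p, index=False)
        with pytest.raises(ValueError, match="missing"):
            load_measurements(p)
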