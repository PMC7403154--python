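"""Full statistical pipeline on a synthetic subject table.

Generates 21 subjects x 5 viewing conditions with acuity following the
published per-degradation-type regression lines, screens bivariate
outliers by Mahalanobis distance, fits the REML mixed model of acuity on
limiting spatial frequency, refits the per-type prediction lines by OLS,
and checks predicted-vs-measured agreement with Bland-Altman limits.
"""

from pwmillusion import (SimulationConfig, bland_altman, descriptive_summary,
                         fit_mixed_model, fit_ols, mahalanobis_screen,
                         replicate_bcva, simulate_subjects)

df = simulate_subjects(SimulationConfig(n_subjects=21, seed=7))
mask = mahalanobis_screen(df)
df = df[mask].reset_index(drop=True)
print(f"{mask.sum()} of {len(mask)} rows kept after Mahalanobis screening")

desc = descriptive_summary(df)
bcva = desc[desc.degradation_type == "none"].iloc[0]
print(f"best-corrected limiting SF median [Q1; Q3] = "
      f"{bcva.sf_median:.1f} [{bcva.sf_q1:.1f}; {bcva.sf_q3:.1f}] cpd")

mm = fit_mixed_model(df)
sf_row = mm.f_tests.set_index("term").loc["limiting_sf_cpd"]
print(f"mixed model: SF slope = {mm.slope_sf:.3f} logMAR/cpd, "
      f"F({sf_row.df_num:.0f}, {sf_row.df_den:.0f}) = {sf_row.F:.2f}, "
      f"p = {sf_row.p:.4f}  [{mm.df_method}]")

rep = replicate_bcva(df)
for dtype in ("occlusion_foil", "plus_lens"):
    sub = rep[rep.degradation_type == dtype]
    ols = fit_ols(sub)
    ba = bland_altman(ols.predict(sub.limiting_sf_cpd), sub.va_logmar)
    print(f"{dtype}: VA = {ols.intercept:.4f} {ols.slope:+.4f} * SF, "
          f"R^2 = {ols.r_squared:.4f}; "
          f"LoA [{ba.loa_lower:+.2f}, {ba.loa_upper:+.2f}] logMAR, "
          f"t({ba.t_df}) = {ba.t_statistic:.1f}, p = {ba.p_value:.1f}")
# The Bland-Altman mean difference is exactly 0 for OLS predictions; the
# limits of agreement show the +-1.96 SD envelope of prediction errors.
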