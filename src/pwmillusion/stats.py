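"""Statistical pipeline for limiting-spatial-frequency / acuity data.

Covers the full analysis chain used for the illusion-based acuity study
design: Mahalanobis-distance outlier screening of (SF, VA) pairs, a REML
linear mixed model of acuity on limiting spatial frequency with degradation
type and level (level nested in type) and a per-subject random intercept,
per-type ordinary least squares prediction lines, Bland–Altman agreement of
predicted versus measured acuity, and descriptive summaries.

Input schema
------------
A tidy table with one row per (subject, condition):

    subject_id, degradation_type, degradation_level, limiting_sf_cpd, va_logmar

``degradation_type`` is one of ``none`` (best-corrected), ``plus_lens`` or
``occlusion_foil``.  Best-corrected rows are replicated into both types when
the mixed model or the per-type regressions are fitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "REQUIRED_COLUMNS",
    "load_measurements",
    "replicate_bcva",
    "mahalanobis_screen",
    "MixedModelResult",
    "fit_mixed_model",
    "OlsResult",
    "fit_ols",
    "BlandAltmanResult",
    "bland_altman",
    "descriptive_summary",
]

REQUIRED_COLUMNS = ("subject_id", "degradation_type", "degradation_level",
                    "limiting_sf_cpd", "va_logmar")

VALID_TYPES = ("none", "plus_lens", "occlusion_foil")


def load_measurements(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read a measurement CSV, optionally renaming columns of a foreign
    layout (e.g. a supplementary raw-data export) via ``column_map``
    ({source_name: canonical_name})."""
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    bad = set(df["degradation_type"]) - set(VALID_TYPES)
    if bad:
        raise ValueError(f"unknown degradation types: {sorted(bad)}")
    if (df["limiting_sf_cpd"] <= 0).any():
        raise ValueError("limiting_sf_cpd must be positive")
    return df[list(REQUIRED_COLUMNS)].copy()


def replicate_bcva(df: pd.DataFrame) -> pd.DataFrame:
    """Duplicate best-corrected (type 'none') rows into both degradation
    types, so each type's model sees the undegraded baseline."""
    bcva = df[df["degradation_type"] == "none"]
    rest = df[df["degradation_type"] != "none"]
    out = [rest]
    for t in ("plus_lens", "occlusion_foil"):
        rep = bcva.copy()
        rep["degradation_type"] = t
        out.append(rep)
    return pd.concat(out, ignore_index=True)


def mahalanobis_screen(df: pd.DataFrame,
                       threshold: float | None = None,
                       per_level: bool = True,
                       cols: tuple = ("limiting_sf_cpd", "va_logmar"),
                       ) -> np.ndarray:
    """Inclusion mask for bivariate (SF, VA) outlier screening.

    Squared Mahalanobis distances to the sample mean are compared against
    ``threshold`` (default: the 97.5th percentile of chi-square with 2 df,
    the standard bivariate cutoff).  With ``per_level`` the screen runs
    within each (type, level) cell, otherwise globally.  The decision is
    affine-invariant: rescaling either variable changes nothing.
    """
    if threshold is None:
        threshold = float(sps.chi2.ppf(0.975, df=len(cols)))
    include = np.ones(len(df), dtype=bool)
    if per_level:
        groups = df.groupby(["degradation_type", "degradation_level"],
                            sort=False).indices.values()
    else:
        groups = [np.arange(len(df))]
    x_all = df[list(cols)].to_numpy(dtype=float)
    for idx in groups:
        idx = np.asarray(idx)
        x = x_all[idx]
        if len(x) < 3:
            raise ValueError("need at least 3 rows per screened group")
        mu = x.mean(axis=0)
        cov = np.cov(x, rowvar=False)
        if np.linalg.matrix_rank(cov) < len(cols) or np.linalg.det(cov) <= 0:
            raise ValueError("singular covariance; cannot screen this group")
        d2 = np.einsum("ij,jk,ik->i", x - mu, np.linalg.inv(cov), x - mu)
        include[idx] = d2 <= threshold
    return include


@dataclass(frozen=True)
class MixedModelResult:
    """REML mixed-model fit with marginal Wald F tests and diagnostics.

    ``df_method`` names the denominator-df approximation used for the F
    tests ('residual': n minus fixed-effect rank).  Software packages differ
    here (Satterthwaite, Kenward–Roger, containment); F statistics are
    comparable across packages only approximately.
    """

    fixed_effects: pd.Series
    random_intercept_var: float
    residual_var: float
    f_tests: pd.DataFrame            # term, F, df_num, df_den, p
    df_method: str
    shapiro_w: float
    shapiro_p: float
    brown_forsythe_f: float
    brown_forsythe_p: float
    vif: pd.Series
    slope_sf: float                  # marginal limiting-SF coefficient
    slope_sf_ci: tuple
    n_obs: int
    converged: bool


def fit_mixed_model(df: pd.DataFrame, reml: bool = True) -> MixedModelResult:
    """Fit VA ~ SF + type + level(type) + SF:type + SF:level(type) with a
    per-subject random intercept, by REML.

    Best-corrected rows are replicated into both types first (pass data
    without 'none' rows to skip).  Marginal F tests use Wald statistics
    with a residual denominator-df approximation; Shapiro–Wilk normality
    and Brown–Forsythe homoscedasticity checks of the residuals and
    variance inflation factors of the fixed-effect columns are reported
    alongside.
    """
    data = df.copy()
    baseline = data["degradation_type"] == "none"
    if baseline.any():
        data["_baseline"] = baseline
        data = replicate_bcva(data)
    else:
        data["_baseline"] = False
    if data["subject_id"].nunique() < 2:
        raise ValueError("mixed model needs at least 2 subjects")
    if data["degradation_type"].nunique() < 2:
        raise ValueError("mixed model needs both degradation types")
    # nested coding: the replicated best-corrected rows are the shared
    # reference level of both types, so type and level(type) stay full rank
    data["level_in_type"] = np.where(
        data["_baseline"], "0:baseline",
        data["degradation_type"].astype(str) + ":"
        + data["degradation_level"].astype(str))
    # center the covariate so the interaction columns are well conditioned
    # (the slope estimate is unaffected; main effects are evaluated at the
    # mean limiting SF)
    data["sf_c"] = data["limiting_sf_cpd"] - data["limiting_sf_cpd"].mean()
    formula = ("va_logmar ~ sf_c + C(degradation_type) "
               "+ C(level_in_type) + sf_c:C(degradation_type) "
               "+ sf_c:C(level_in_type)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data, groups=data["subject_id"])
        fit = None
        for method in ("powell", "nm", "bfgs"):
            try:
                fit = model.fit(reml=reml, method=method, maxiter=2000)
            except np.linalg.LinAlgError:
                continue
            if fit.converged:
                break
        if fit is None:
            raise RuntimeError("mixed model failed to converge with any optimizer")
    fe = fit.fe_params
    exog = pd.DataFrame(model.exog, columns=model.exog_names)
    n = len(data)
    rank = np.linalg.matrix_rank(model.exog)
    df_den = n - rank
    terms = {
        "limiting_sf_cpd": [c for c in exog.columns if c == "sf_c"],
        "degradation_type": [c for c in exog.columns
                             if c.startswith("C(degradation_type)")],
        "level_in_type": [c for c in exog.columns
                          if c.startswith("C(level_in_type)")],
        "limiting_sf_cpd:degradation_type": [
            c for c in exog.columns
            if "sf_c:C(degradation_type)" in c],
        "limiting_sf_cpd:level_in_type": [
            c for c in exog.columns
            if "sf_c:C(level_in_type)" in c],
    }
    rows = []
    cov = fit.cov_params().loc[fe.index, fe.index]
    for term, cols in terms.items():
        cols = [c for c in cols if c in fe.index]
        if not cols:
            continue
        beta = fe[cols].to_numpy()
        v = cov.loc[cols, cols].to_numpy()
        try:
            w = float(beta @ np.linalg.solve(v, beta))
        except np.linalg.LinAlgError:
            w = float(beta @ np.linalg.pinv(v) @ beta)
        q = len(cols)
        fstat = w / q
        p = float(sps.f.sf(fstat, q, df_den))
        rows.append({"term": term, "F": fstat, "df_num": q,
                     "df_den": df_den, "p": p})
    ftests = pd.DataFrame(rows)
    resid = np.asarray(fit.resid)
    sw = sps.shapiro(resid if len(resid) <= 5000 else resid[:5000])
    # Brown–Forsythe: homogeneity of residual spread across degradation levels
    groups = [resid[data["level_in_type"].to_numpy() == g]
              for g in data["level_in_type"].unique()]
    bf = sps.levene(*[g for g in groups if len(g) > 1], center="median")
    vif = _vif(exog.drop(columns=["Intercept"], errors="ignore"))
    ci = fit.conf_int().loc["sf_c"]
    return MixedModelResult(
        fixed_effects=fe,
        random_intercept_var=float(fit.cov_re.iloc[0, 0]),
        residual_var=float(fit.scale),
        f_tests=ftests,
        df_method="residual (n - rank(X)); Wald F",
        shapiro_w=float(sw.statistic), shapiro_p=float(sw.pvalue),
        brown_forsythe_f=float(bf.statistic), brown_forsythe_p=float(bf.pvalue),
        vif=vif,
        slope_sf=float(fe["sf_c"]),
        slope_sf_ci=(float(ci[0]), float(ci[1])),
        n_obs=n,
        converged=bool(fit.converged),
    )


def _vif(x: pd.DataFrame) -> pd.Series:
    """Variance inflation factors of each column against the others."""
    out = {}
    arr = x.to_numpy(dtype=float)
    for i, name in enumerate(x.columns):
        others = np.delete(arr, i, axis=1)
        others = np.column_stack([np.ones(len(arr)), others])
        beta, *_ = np.linalg.lstsq(others, arr[:, i], rcond=None)
        pred = others @ beta
        ss_res = float(np.sum((arr[:, i] - pred) ** 2))
        ss_tot = float(np.sum((arr[:, i] - arr[:, i].mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        out[name] = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="VIF")


@dataclass(frozen=True)
class OlsResult:
    n: int
    slope: float
    intercept: float
    r_squared: float
    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    residuals: np.ndarray
    shapiro_p: float

    def predict(self, sf):
        return self.intercept + self.slope * np.asarray(sf, dtype=float)


def fit_ols(df: pd.DataFrame,
            x: str = "limiting_sf_cpd", y: str = "va_logmar") -> OlsResult:
    """Simple least-squares line of acuity on limiting spatial frequency
    for one degradation type's data."""
    if len(df) < 3:
        raise ValueError("need at least 3 rows")
    xv = df[x].to_numpy(dtype=float)
    yv = df[y].to_numpy(dtype=float)
    if np.ptp(xv) == 0:
        raise ValueError("constant predictor")
    fit = sm.OLS(yv, sm.add_constant(xv)).fit()
    resid = np.asarray(fit.resid)
    return OlsResult(
        n=len(df),
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        f_statistic=float(fit.fvalue),
        df_num=int(fit.df_model),
        df_den=int(fit.df_resid),
        p_value=float(fit.f_pvalue),
        residuals=resid,
        shapiro_p=float(sps.shapiro(resid).pvalue) if len(resid) >= 3 else np.nan,
    )


@dataclass(frozen=True)
class BlandAltmanResult:
    """Agreement between two paired measurement series.

    Differences are ``predicted − observed``; limits of agreement are
    mean ± 1.96·SD with exact t-based confidence intervals.
    """

    n: int
    mean_diff: float
    mean_diff_ci: tuple
    loa_lower: float
    loa_upper: float
    loa_lower_ci: tuple
    loa_upper_ci: tuple
    sd_diff: float
    t_statistic: float
    t_df: int
    p_value: float


def bland_altman(predicted, observed, loa_z: float = 1.96) -> BlandAltmanResult:
    """Bland–Altman agreement analysis with a paired t test of the mean
    difference.

    The LoA confidence intervals use the variance of a limit,
    Var(LoA) ≈ SD²·(1/n + z²/(2(n−1))), with a t quantile on n−1 df.
    """
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise ValueError("predicted and observed must have equal length")
    n = len(p)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    d = p - o
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    tq = float(sps.t.ppf(0.975, n - 1))
    se_mean = sd / np.sqrt(n)
    se_loa = sd * np.sqrt(1.0 / n + loa_z ** 2 / (2.0 * (n - 1)))
    lo = mean - loa_z * sd
    hi = mean + loa_z * sd
    if sd > 0:
        tstat = mean / se_mean
        pval = float(2.0 * sps.t.sf(abs(tstat), n - 1))
    else:
        tstat, pval = 0.0, 1.0
    return BlandAltmanResult(
        n=n,
        mean_diff=mean,
        mean_diff_ci=(mean - tq * se_mean, mean + tq * se_mean),
        loa_lower=lo, loa_upper=hi,
        loa_lower_ci=(lo - tq * se_loa, lo + tq * se_loa),
        loa_upper_ci=(hi - tq * se_loa, hi + tq * se_loa),
        sd_diff=sd,
        t_statistic=float(tstat), t_df=n - 1, p_value=pval,
    )


def descriptive_summary(df: pd.DataFrame) -> pd.DataFrame:
    """Median and quartiles (linear-interpolation convention) of limiting
    spatial frequency and acuity per (type, level) cell."""
    rows = []
    for (t, lvl), g in df.groupby(["degradation_type", "degradation_level"],
                                  sort=False):
        if g.empty:
            warnings.warn(f"empty group {(t, lvl)}; omitted", stacklevel=2)
            continue
        row = {"degradation_type": t, "degradation_level": lvl, "n": len(g)}
        for col, tag in (("limiting_sf_cpd", "sf"), ("va_logmar", "va")):
            v = g[col].to_numpy(dtype=float)
            row[f"{tag}_median"] = float(np.median(v))
            row[f"{tag}_q1"] = float(np.percentile(v, 25))
            row[f"{tag}_q3"] = float(np.percentile(v, 75))
        rows.append(row)
    return pd.DataFrame(rows)
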