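"""Longitudinal kinetics of post-excision optical endpoints.

Each measured site contributes a short time series of endpoint values
starting minutes after excision.  A linear mixed-effects model with fixed
effects for time and histological subtype and correlated random
intercept+slope per site yields sample-specific (BLUP) lines; the percent
change statistic -- 100 * slope / |intercept| * horizon -- makes kinetics
comparable across endpoints with different units.  Wilcoxon rank-sum tests
compare cauterized lumpectomy surfaces against incised mastectomy tissue,
likelihood-ratio tests ask whether kinetic rates depend on diagnosis, and
Spearman correlations probe first-measurement-vs-delay association.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
import statsmodels.formula.api as smf

#: endpoints fitted linearly by default; oxy-/deoxy-Hb and HbSat are
#: excluded because they are not linear over the measurement window
DEFAULT_ENDPOINTS = ("beta_carotene", "mean_musp", "ratio_bc_musp", "thb",
                     "ratio_thb_musp")

#: endpoints whose zeros mark values at the physical detection floor
#: (washed-out mapping dye) rather than informative measurements
FLOORED_ENDPOINTS = ("dye",)


@dataclass
class KineticsFit:
    """Per-site BLUP lines plus the fixed-effect summary for one endpoint."""

    endpoint: str
    per_site: pd.DataFrame      # site_id, intercept, slope, diagnosis, ...
    fixed_effects: pd.Series
    cov_re: pd.DataFrame | None
    loglike: float
    converged: bool
    singular: bool
    n_sites: int
    model: str = "mixed"        # mixed | ols (degenerate single-site case)


@dataclass
class PercentChange:
    """Percent change at a horizon: 100 * slope / |intercept| * horizon."""

    endpoint: str
    horizon_min: float
    per_site: pd.DataFrame      # site_id, percent_change (NaN when flagged)
    median: float
    n_flagged: int


def _prepare(cohort_obs: pd.DataFrame, endpoint: str,
             drop_floor_zeros: bool | None = None) -> pd.DataFrame:
    """Long frame (site_id, t, y, histology, diagnosis) for one endpoint."""
    if endpoint not in cohort_obs.columns:
        raise KeyError(f"endpoint {endpoint!r} not in cohort")
    df = cohort_obs[["site_id", "t_min", endpoint, "histology",
                     "diagnosis"]].rename(columns={endpoint: "y",
                                                   "t_min": "t"})
    if not np.all(np.isfinite(df["y"])):
        raise ValueError(f"endpoint {endpoint!r} contains non-finite values")
    if drop_floor_zeros is None:
        drop_floor_zeros = endpoint in FLOORED_ENDPOINTS
    if drop_floor_zeros:
        df = df[df["y"] > 0]
        enough = df.groupby("site_id")["t"].transform("size") >= 2
        df = df[enough]
    return df.reset_index(drop=True)


def _fit_mixedlm(df: pd.DataFrame, formula: str, reml: bool):
    """Fit a random-intercept+slope mixed model, stabilized.

    Time is centered and the response standardized before fitting (the
    likelihood-ratio statistic and the back-transformed coefficients are
    invariant), and the variance components start from the empirical
    covariance of per-site OLS lines -- without this the ML surface routinely
    strands the default optimizer.  Returns (result, t_center, y_scale).
    """
    from statsmodels.regression.mixed_linear_model import MixedLMParams

    d = df.copy()
    t_center = float(d["t"].mean())
    y_scale = float(d["y"].std())
    if y_scale <= 0:
        y_scale = 1.0
    d["t"] = d["t"] - t_center
    d["y"] = d["y"] / y_scale
    rows = []
    resid_ss = 0.0
    n_tot = 0
    for _, sub in d.groupby("site_id"):
        if len(sub) >= 2 and sub["t"].nunique() > 1:
            co = np.polyfit(sub["t"], sub["y"], 1)
            rows.append([co[1], co[0]])
            r = sub["y"] - np.polyval(co, sub["t"])
            resid_ss += float((r ** 2).sum())
            n_tot += len(sub)
    scale0 = max(resid_ss / max(n_tot, 1), 1e-10)
    cov0 = np.cov(np.asarray(rows).T) if len(rows) > 2 else np.eye(2)
    cov0 = cov0 + 1e-8 * np.eye(2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, d, groups=d["site_id"], re_formula="~t")
        start = MixedLMParams.from_components(
            fe_params=np.zeros(len(model.exog_names)), cov_re=cov0 / scale0)
        fit = model.fit(reml=reml, start_params=start,
                        method=["lbfgs", "bfgs"], maxiter=2000)
    return fit, t_center, y_scale


def fit_longitudinal(cohort_obs: pd.DataFrame, endpoint: str,
                     include_interaction: bool = False,
                     reml: bool = True,
                     drop_floor_zeros: bool | None = None) -> KineticsFit:
    """Linear mixed model with per-site random intercept and slope.

    Fixed effects: time, histological subtype and (optionally) a
    diagnosis x time interaction; random effects: correlated intercept and
    slope per site; REML estimates by default.  Per-site lines are BLUPs
    (fixed + random parts), reported in original units at original time
    zero (excision).  For a single-site input the model degenerates to
    ordinary least squares.  Floored-at-zero observations of washout
    endpoints are treated as below the detection limit and excluded (see
    ``FLOORED_ENDPOINTS``).
    """
    df = _prepare(cohort_obs, endpoint, drop_floor_zeros)
    sites = df["site_id"].unique()
    meta = df.groupby("site_id").first()[["histology", "diagnosis"]]
    if len(sites) == 0:
        raise ValueError("no usable sites for endpoint " + endpoint)
    if len(sites) == 1:
        x = df["t"].to_numpy()
        res = np.polyfit(x, df["y"].to_numpy(), 1)
        per_site = pd.DataFrame({"site_id": sites, "intercept": [res[1]],
                                 "slope": [res[0]]}).merge(
            meta, on="site_id")
        return KineticsFit(endpoint=endpoint, per_site=per_site,
                           fixed_effects=pd.Series(
                               {"Intercept": res[1], "t": res[0]}),
                           cov_re=None, loglike=np.nan, converged=True,
                           singular=False, n_sites=1, model="ols")

    formula = "y ~ t + C(histology)"
    n_diag = df["diagnosis"].nunique()
    if include_interaction:
        if n_diag < 2:
            raise ValueError("interaction model needs both diagnosis classes")
        formula += " + t:C(diagnosis)"
    fit, t_center, y_scale = _fit_mixedlm(df, formula, reml)
    singular = bool(np.any(np.linalg.eigvalsh(fit.cov_re) < 1e-10))

    fe = fit.fe_params
    rows = []
    for sid in sites:
        sub = df[df["site_id"] == sid].iloc[0]
        covars = {"histology": sub["histology"],
                  "diagnosis": sub["diagnosis"]}
        re = fit.random_effects[sid]
        re_int = float(re.iloc[0])
        re_slope = float(re.iloc[1]) if len(re) > 1 else 0.0

        def pred(t_orig):
            tc = t_orig - t_center
            d_row = _design_row(fe.index, dict(covars, t=tc))
            return y_scale * (float(np.dot(fe.to_numpy(), d_row))
                              + re_int + re_slope * tc)

        y0 = pred(0.0)
        rows.append({"site_id": sid, "intercept": y0,
                     "slope": pred(1.0) - y0})
    per_site = pd.DataFrame(rows).merge(meta, on="site_id")
    return KineticsFit(endpoint=endpoint, per_site=per_site,
                       fixed_effects=fe, cov_re=fit.cov_re,
                       loglike=float(fit.llf), converged=bool(fit.converged),
                       singular=singular, n_sites=len(sites))


def _design_row(fe_index, covariates: dict) -> np.ndarray:
    """Fixed-effect design row from patsy-style coefficient names."""
    row = np.zeros(len(fe_index))
    for i, name in enumerate(fe_index):
        if name == "Intercept":
            row[i] = 1.0
        elif name == "t":
            row[i] = covariates["t"]
        elif name.startswith("C(histology)[T."):
            level = name[len("C(histology)[T."):-1]
            row[i] = 1.0 if covariates["histology"] == level else 0.0
        elif name.startswith("t:C(diagnosis)[T."):
            level = name[len("t:C(diagnosis)[T."):-1]
            row[i] = (covariates["t"]
                      if covariates["diagnosis"] == level else 0.0)
        elif name.startswith("C(diagnosis)[T."):
            level = name[len("C(diagnosis)[T."):-1]
            row[i] = 1.0 if covariates["diagnosis"] == level else 0.0
        else:
            raise ValueError(f"unrecognized fixed-effect term {name!r}")
    return row


def percent_change(fit: KineticsFit, horizon_min: float) -> PercentChange:
    """Per-site percent change at a horizon plus the cohort median.

    Sites with a zero fitted intercept are flagged (NaN) and excluded from
    the median.  The statistic is exactly linear in the horizon.
    """
    ps = fit.per_site.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * ps["slope"] / np.abs(ps["intercept"]) * horizon_min
    pct = pct.where(np.abs(ps["intercept"]) > 0, np.nan)
    n_flagged = int(pct.isna().sum())
    if n_flagged:
        warnings.warn(f"{n_flagged} site(s) with zero intercept excluded "
                      f"from the {fit.endpoint} percent-change median")
    ps["percent_change"] = pct
    return PercentChange(endpoint=fit.endpoint, horizon_min=horizon_min,
                         per_site=ps[["site_id", "percent_change"]],
                         median=float(np.nanmedian(pct)),
                         n_flagged=n_flagged)


def time_to_contrast_loss(pct_change_at_horizon: float, horizon_min: float,
                          pct_difference: float) -> dict:
    """Minutes until the percent change catches up with a tissue contrast.

    Linear extrapolation: t* = horizon * |difference| / |change at
    horizon|.  Reported rounded to the nearest minute; the exact value is
    retained.
    """
    if pct_change_at_horizon == 0:
        return {"minutes": np.inf, "minutes_rounded": None,
                "flag": "zero-rate"}
    t_star = horizon_min * abs(pct_difference) / abs(pct_change_at_horizon)
    return {"minutes": t_star, "minutes_rounded": int(round(t_star)),
            "flag": None}


def _site_window_slopes(obs: pd.DataFrame, endpoint: str,
                        window_min: float) -> pd.DataFrame:
    """Per-site OLS slope restricted to ``window_min`` minutes after each
    site's first measurement."""
    rows = []
    for sid, sub in obs.groupby("site_id"):
        sub = sub.sort_values("t_min")
        t0 = sub["t_min"].iloc[0]
        win = sub[sub["t_min"] <= t0 + window_min]
        if len(win) < 2:
            continue
        slope = np.polyfit(win["t_min"], win[endpoint], 1)[0]
        rows.append({"site_id": sid, "slope": slope})
    return pd.DataFrame(rows)


def compare_cautery(lump_obs: pd.DataFrame, mast_obs: pd.DataFrame,
                    endpoint: str, window_min: float = 10.0) -> dict:
    """Lumpectomy (cauterized) vs mastectomy (incised) benign sites.

    Wilcoxon rank-sum tests on (a) first-measurement values and (b) per-site
    rates constrained to the first ``window_min`` minutes.  The exact null
    distribution is used for small samples without ties, the tie-corrected
    normal approximation otherwise.
    """
    if lump_obs.empty or mast_obs.empty:
        raise ValueError("both groups must be non-empty")
    out = {"endpoint": endpoint, "window_min": window_min}
    for tag, extract in (
            ("first_value", lambda df: df.sort_values("t_min")
             .groupby("site_id")[endpoint].first()),
            ("rate", lambda df: _site_window_slopes(df, endpoint, window_min)
             .set_index("site_id")["slope"])):
        a = np.asarray(extract(lump_obs), dtype=float)
        b = np.asarray(extract(mast_obs), dtype=float)
        res = rank_sum_test(a, b)
        out[tag] = res
    return out


def rank_sum_test(a: np.ndarray, b: np.ndarray,
                  alternative: str = "two-sided") -> dict:
    """Wilcoxon rank-sum (Mann-Whitney U) with automatic method choice."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    all_tied = len(np.unique(pooled)) == 1
    method = "asymptotic" if (has_ties or min(a.size, b.size) > 25) \
        else "exact"
    if all_tied:
        return {"statistic": np.nan, "p_value": 1.0, "method": method,
                "flag": "all-tied"}
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return {"statistic": float(res.statistic), "p_value": float(res.pvalue),
            "method": method, "flag": None}


def interaction_lrt(cohort_obs: pd.DataFrame, endpoint: str) -> dict:
    """Likelihood-ratio test for a diagnosis x time interaction.

    Both models are fit by maximum likelihood (not REML -- the fixed
    effects differ); the statistic is referred to chi-square with df equal
    to the added interaction terms.
    """
    if cohort_obs["diagnosis"].nunique() < 2:
        raise ValueError("both diagnosis classes required")
    df = _prepare(cohort_obs, endpoint)
    null, _, _ = _fit_mixedlm(df, "y ~ t + C(diagnosis)", reml=False)
    full, _, _ = _fit_mixedlm(df, "y ~ t + C(diagnosis) + t:C(diagnosis)",
                              reml=False)
    df_diff = len(full.fe_params) - len(null.fe_params)
    lrt = 2.0 * (full.llf - null.llf)
    lrt = max(lrt, 0.0)
    p = float(stats.chi2.sf(lrt, df_diff))
    flag = None
    if not (null.converged and full.converged):
        flag = "non-converged"
    return {"endpoint": endpoint, "statistic": float(lrt), "df": df_diff,
            "p_value": p, "flag": flag}


def spearman_test(x: np.ndarray, y: np.ndarray) -> dict:
    """Spearman rank correlation with an exact small-sample p-value.

    For n <= 8 without ties the null distribution of rho is enumerated over
    all permutations; larger samples use the asymptotic approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if len(np.unique(x)) == 1 or len(np.unique(y)) == 1:
        return {"rho": np.nan, "p_value": np.nan, "n": int(x.size),
                "method": None, "flag": "constant-input"}
    rho = float(stats.spearmanr(x, y).statistic)
    no_ties = (len(np.unique(x)) == x.size and len(np.unique(y)) == y.size)
    if x.size <= 8 and no_ties:
        from itertools import permutations

        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        count = 0
        total = 0
        for perm in permutations(range(x.size)):
            r = float(stats.pearsonr(rx, ry[list(perm)]).statistic)
            count += abs(r) >= abs(rho) - 1e-12
            total += 1
        return {"rho": rho, "p_value": count / total, "n": int(x.size),
                "method": "exact", "flag": None}
    p = float(stats.spearmanr(x, y).pvalue)
    return {"rho": rho, "p_value": p, "n": int(x.size),
            "method": "asymptotic", "flag": None}


def first_measurement_correlation(cohort_obs: pd.DataFrame,
                                  endpoint: str) -> dict:
    """Spearman correlation of first-measurement value vs its delay."""
    firsts = (cohort_obs.sort_values("t_min").groupby("site_id")
              .first()[["t_min", endpoint]])
    if len(firsts) < 3:
        raise ValueError("need at least 3 sites")
    res = spearman_test(firsts["t_min"].to_numpy(),
                        firsts[endpoint].to_numpy())
    return {"endpoint": endpoint, **res}


def contrast_decay_map(margin_map: np.ndarray, pct_at_horizon: float,
                       upsample: int = 1) -> np.ndarray:
    """Apply a median percent change to an endpoint map.

    Every pixel is multiplied by (1 + pct/100); a change at or below -100%
    clips at zero with a warning.  ``upsample`` > 1 renders the result with
    bicubic interpolation (the display convention for margin maps).
    """
    arr = np.asarray(margin_map, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("margin map contains non-finite values")
    factor = 1.0 + pct_at_horizon / 100.0
    if factor < 0:
        warnings.warn("percent change at or below -100%; clipping at zero")
        factor = 0.0
    out = arr * factor
    if upsample > 1:
        out = ndimage.zoom(out, upsample, order=3)
    return out
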