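"""Statistical layer: regressions and clustered group comparisons.

Reporting conventions follow the source-study style: linear fits report
slope/intercept with 95% CIs, R^2 and Pearson's r; binary (logistic)
regressions report the odds ratio per unit predictor together with a
response-scale coefficient of determination (1 - SSE/SST computed on the
0/1 response against fitted probabilities; McFadden's pseudo-R^2 is
reported alongside but is secondary); group comparisons use a linear
mixed-effects model with a random intercept per mouse (ML, not REML) and
report the estimated group difference Delta with 95% CI [LL, UL], t(df)
and a two-sided p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps


class StatsError(ValueError):
    pass


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    r_squared: float
    pearson_r: float
    p_slope: float
    p_intercept: float
    n: int
    # cross-group contrasts (two-group interaction parameterisation)
    delta_slope: float | None = None
    p_delta_slope: float | None = None
    delta_intercept: float | None = None
    p_delta_intercept: float | None = None
    group_results: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "slope_ci": list(self.slope_ci),
            "intercept_ci": list(self.intercept_ci),
            "r_squared": self.r_squared,
            "pearson_r": self.pearson_r,
            "p_slope": self.p_slope,
            "p_intercept": self.p_intercept,
            "n": self.n,
            "delta_slope": self.delta_slope,
            "p_delta_slope": self.p_delta_slope,
            "delta_intercept": self.delta_intercept,
            "p_delta_intercept": self.p_delta_intercept,
            "groups": {k: v.to_dict() for k, v in self.group_results.items()},
        }


@dataclass
class BinaryRegressionResult:
    slope: float
    intercept: float
    odds_ratio: float
    odds_ratio_ci: tuple[float, float]
    r_squared_response: float
    r_squared_mcfadden: float
    p_slope: float
    n: int
    separation_flagged: bool = False

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "odds_ratio": self.odds_ratio,
            "odds_ratio_ci": list(self.odds_ratio_ci),
            "r_squared_response": self.r_squared_response,
            "r_squared_mcfadden": self.r_squared_mcfadden,
            "p_slope": self.p_slope,
            "n": self.n,
            "separation_flagged": self.separation_flagged,
        }


@dataclass
class ComparisonResult:
    group_estimates: dict[str, float]
    delta: float
    delta_ci: tuple[float, float]
    t_statistic: float
    df: float
    p_value: float
    n: int
    clustering: str = "mouse"
    confounded_clusters: bool = False

    def to_dict(self) -> dict:
        return {
            "group_estimates": self.group_estimates,
            "delta": self.delta,
            "delta_ci": list(self.delta_ci),
            "t": self.t_statistic,
            "df": self.df,
            "p": self.p_value,
            "n": self.n,
            "clustering": self.clustering,
            "confounded_clusters": self.confounded_clusters,
        }


# ---------------------------------------------------------------------------
# linear regression


def linear_fit(
    x,
    y,
    groups=None,
    cluster_ids=None,
) -> RegressionResult:
    """OLS fit y = slope*x + intercept with slope/intercept inference.

    With a two-level ``groups`` factor, slopes and intercepts are also
    compared across groups via the interaction parameterisation
    y ~ x * group.  With ``cluster_ids`` (mouse), cluster-robust standard
    errors are used throughout.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise StatsError("x and y must have equal length")
    if x.size < 3:
        raise StatsError("linear_fit requires n >= 3")
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
        raise StatsError("x and y must be finite")
    if np.ptp(x) == 0:
        raise StatsError("x is constant; slope is unidentifiable")

    def _fit(xs, ys, cl):
        X = sm.add_constant(xs)
        model = sm.OLS(ys, X)
        if cl is not None:
            res = model.fit(cov_type="cluster", cov_kwds={"groups": np.asarray(cl)})
        else:
            res = model.fit()
        ci = res.conf_int(alpha=0.05)
        r = float(np.corrcoef(xs, ys)[0, 1]) if np.ptp(ys) > 0 else 0.0
        return RegressionResult(
            slope=float(res.params[1]),
            intercept=float(res.params[0]),
            slope_ci=(float(ci[1][0]), float(ci[1][1])),
            intercept_ci=(float(ci[0][0]), float(ci[0][1])),
            r_squared=float(res.rsquared),
            pearson_r=r,
            p_slope=float(res.pvalues[1]),
            p_intercept=float(res.pvalues[0]),
            n=int(xs.size),
        )

    cluster = np.asarray(cluster_ids) if cluster_ids is not None else None
    result = _fit(x, y, cluster)

    if groups is not None:
        g = np.asarray(groups)
        levels = list(pd.unique(g))
        if len(levels) != 2:
            raise StatsError("cross-group contrasts require exactly two groups")
        ind = (g == levels[1]).astype(float)
        X = np.column_stack([np.ones_like(x), x, ind, x * ind])
        model = sm.OLS(y, X)
        if cluster is not None:
            res = model.fit(cov_type="cluster", cov_kwds={"groups": cluster})
        else:
            res = model.fit()
        result.delta_intercept = float(res.params[2])
        result.p_delta_intercept = float(res.pvalues[2])
        result.delta_slope = float(res.params[3])
        result.p_delta_slope = float(res.pvalues[3])
        for level in levels:
            mask = g == level
            result.group_results[str(level)] = _fit(
                x[mask], y[mask], cluster[mask] if cluster is not None else None
            )
    return result


# ---------------------------------------------------------------------------
# binary (logistic) regression


def binary_fit(x, y01, cluster_ids=None) -> BinaryRegressionResult:
    """Logistic regression of a 0/1 outcome on one predictor.

    Reports OR = exp(slope) per unit predictor and the response-scale R^2
    (1 - SSE/SST of the binary response against fitted probabilities), with
    McFadden's pseudo-R^2 as the secondary measure.  Complete separation is
    flagged and handled with a weak-ridge fallback fit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y01, dtype=float)
    if x.size != y.size:
        raise StatsError("x and y must have equal length")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise StatsError("y must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise StatsError("both outcome classes must be present")
    X = sm.add_constant(x)
    separation = False
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        params = res.params
        bse = res.bse
        llf, llnull = float(res.llf), float(res.llnull)
        with np.errstate(all="ignore"):
            p_fit = 1.0 / (1.0 + np.exp(-(X @ np.asarray(params))))
        perfectly_split = (
            p_fit[y == 1].min(initial=1.0) > 1 - 1e-6
            and p_fit[y == 0].max(initial=0.0) < 1e-6
        )
        if not np.all(np.isfinite(bse)) or perfectly_split:
            raise np.linalg.LinAlgError
    except Exception:
        separation = True
        res = sm.Logit(y, X).fit_regularized(alpha=1e-4, disp=0, maxiter=500)
        params = np.asarray(res.params)
        bse = np.full(2, np.nan)
        eta = X @ params
        p = 1.0 / (1.0 + np.exp(-eta))
        eps = 1e-12
        llf = float(np.sum(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
        pbar = y.mean()
        llnull = float(x.size * (pbar * math.log(pbar) + (1 - pbar) * math.log(1 - pbar)))
    eta = X @ np.asarray(params)
    p = 1.0 / (1.0 + np.exp(-eta))
    sse = float(np.sum((y - p) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2_response = 1.0 - sse / sst if sst > 0 else float("nan")
    r2_mcfadden = 1.0 - llf / llnull if llnull != 0 else float("nan")
    slope = float(np.asarray(params)[1])
    se = float(bse[1]) if np.all(np.isfinite(bse)) else float("nan")
    if cluster_ids is not None and not separation:
        # cluster-robust slope inference via the sandwich estimator
        with np.errstate(all="ignore"):
            res_c = sm.GLM(y, X, family=sm.families.Binomial()).fit(
                cov_type="cluster", cov_kwds={"groups": np.asarray(cluster_ids)}
            )
        se = float(res_c.bse[1])
    if math.isfinite(se) and se > 0:
        z = slope / se
        p_slope = 2.0 * sps.norm.sf(abs(z))
        or_ci = (
            math.exp(min(slope - 1.96 * se, 700.0)),
            math.exp(min(slope + 1.96 * se, 700.0)),
        )
    else:
        p_slope = float("nan")
        or_ci = (float("nan"), float("nan"))
    return BinaryRegressionResult(
        slope=slope,
        intercept=float(np.asarray(params)[0]),
        odds_ratio=math.exp(min(slope, 700.0)),
        odds_ratio_ci=or_ci,
        r_squared_response=r2_response,
        r_squared_mcfadden=r2_mcfadden,
        p_slope=float(p_slope),
        n=int(x.size),
        separation_flagged=separation,
    )


# ---------------------------------------------------------------------------
# clustered group comparison (linear mixed model)


def group_compare(values, group, mouse_ids) -> ComparisonResult:
    """Two-group comparison with a random intercept per mouse (ML).

    Individual segments are the statistical units; animals are the random
    effect, as in the source study's mixed-effects contract.  Reports the
    model's estimate of the group difference Delta with 95% CI, t(df)
    (residual-df approximation) and a two-sided p-value.
    """
    df = pd.DataFrame(
        {
            "value": np.asarray(values, dtype=float),
            "group": np.asarray(group),
            "mouse": np.asarray(mouse_ids),
        }
    )
    levels = list(pd.unique(df["group"]))
    if len(levels) < 2:
        raise StatsError("group_compare requires at least two groups")
    if len(levels) > 2:
        raise StatsError("group_compare handles exactly two groups; subset first")
    confounded = any(
        df.loc[df["group"] == lv, "mouse"].nunique() == 1 and df["mouse"].nunique() > 1
        for lv in levels
    )
    df["g"] = (df["group"] == levels[1]).astype(float)
    if np.ptp(df["value"].to_numpy()) == 0:
        # degenerate: identical values in all groups
        means = {str(lv): float(df.loc[df["group"] == lv, "value"].mean()) for lv in levels}
        return ComparisonResult(
            group_estimates=means,
            delta=0.0,
            delta_ci=(0.0, 0.0),
            t_statistic=0.0,
            df=float(len(df) - 2),
            p_value=1.0,
            n=len(df),
            confounded_clusters=confounded,
        )
    import warnings

    try:
        model = smf.mixedlm("value ~ g", df, groups=df["mouse"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = model.fit(reml=False)
            except np.linalg.LinAlgError:
                res = model.fit(reml=False, method="lbfgs")
        delta = float(res.params["g"])
        se = float(res.bse["g"])
        intercept = float(res.params["Intercept"])
        if not (np.isfinite(delta) and np.isfinite(se) and se > 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        # degenerate clustering (e.g., a group confined to one mouse):
        # fall back to OLS with cluster-robust standard errors
        X = sm.add_constant(df["g"].to_numpy())
        ols = sm.OLS(df["value"].to_numpy(), X).fit(
            cov_type="cluster", cov_kwds={"groups": df["mouse"].to_numpy()}
        )
        delta = float(ols.params[1])
        se = float(ols.bse[1])
        intercept = float(ols.params[0])
    dof = float(len(df) - df["mouse"].nunique() - 1)
    tval = delta / se if se > 0 else 0.0
    pval = 2.0 * sps.t.sf(abs(tval), dof) if se > 0 else 1.0
    tcrit = sps.t.ppf(0.975, dof)
    base = intercept
    return ComparisonResult(
        group_estimates={str(levels[0]): base, str(levels[1]): base + delta},
        delta=delta,
        delta_ci=(delta - tcrit * se, delta + tcrit * se),
        t_statistic=float(tval),
        df=dof,
        p_value=float(pval),
        n=len(df),
        confounded_clusters=confounded,
    )


# ---------------------------------------------------------------------------
# paired t-test


def paired_compare(a, b) -> ComparisonResult:
    """Two-sided paired t-test, segments paired across conditions."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise StatsError("paired_compare requires equal-length paired samples")
    if a.size < 2:
        raise StatsError("paired_compare requires n >= 2")
    diff = a - b
    n = a.size
    mean_d = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if sd == 0:
        t_stat, p = 0.0, 1.0
        ci = (mean_d, mean_d)
    else:
        se = sd / math.sqrt(n)
        t_stat = mean_d / se
        p = float(2.0 * sps.t.sf(abs(t_stat), n - 1))
        tcrit = sps.t.ppf(0.975, n - 1)
        ci = (mean_d - tcrit * se, mean_d + tcrit * se)
    return ComparisonResult(
        group_estimates={"a": float(a.mean()), "b": float(b.mean())},
        delta=mean_d,
        delta_ci=ci,
        t_statistic=float(t_stat),
        df=float(n - 1),
        p_value=p,
        n=int(n),
        clustering="paired-by-segment",
    )
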