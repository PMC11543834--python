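"""Bulk expression and methylation models, and relapse survival analysis.

Bulk cohorts contain several tissue samples per patient, so group contrasts
(non-cancer vs cancer, relapse-free vs relapse, LG vs HG) use a
random-intercept linear mixed model

    y = X beta + u_patient + eps,   u ~ N(0, sigma_u^2), eps ~ N(0, sigma_e^2),

adjusted for stroma-content and age categories as fixed covariates.  The
model is solved by profiled REML: the variance ratio lambda = sigma_u^2 /
sigma_e^2 is found by 1-D bounded optimization over log(lambda), with GLS
fixed effects at the optimum; no general mixed-model machinery is used.
Contrasts are tested by t with containment-style degrees of freedom
n - rank(X) - (n_patients - 1) (OLS df when the variance ratio collapses to
the boundary), floored at 1.

Methylation sites are aggregated into promoter (TSS1500, TSS200, 5'UTR,
1stExon) and gene-body (3'UTR, Body) means; site-level differential
methylation reuses the same random-intercept model with BH adjustment.

Survival uses the Kaplan-Meier product-limit estimator and the two-group
log-rank test, with the biomarker cutoff chosen by an exhaustive scan of
candidate thresholds minimizing the log-rank p (the minimized p is reported
unadjusted, with an overfitting warning).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import optimize
from scipy import stats as sps

from .config import PipelineConfig
from .deglm import benjamini_hochberg

PROMOTER_REGIONS = ("TSS1500", "TSS200", "5'UTR", "1stExon")
BODY_REGIONS = ("3'UTR", "Body")

STROMA_CATEGORIES = ("<=35%", "36-64%", ">=65%")
AGE_CATEGORIES = ("51-58", "59-64", "65-73")


# ---------------------------------------------------------------------------
# random-intercept LMM by profiled REML
# ---------------------------------------------------------------------------

@dataclass
class LMMFit:
    beta: np.ndarray
    se: np.ndarray
    names: list[str]
    sigma_u2: float
    sigma_e2: float
    contrast: np.ndarray
    estimate: float
    estimate_se: float
    t: float
    df: float
    p: float
    ci_low: float
    ci_high: float
    boundary: bool  # lambda collapsed to 0 (sigma_u2 = 0)


def _group_index(patient_ids) -> list[np.ndarray]:
    s = pd.Series(np.asarray(patient_ids))
    return [np.flatnonzero((s == g).to_numpy()) for g in s.unique()]


def _vinv_apply(x: np.ndarray, groups: list[np.ndarray], lam: float) -> np.ndarray:
    """(I + lam * Z Z')^{-1} x for a block random-intercept structure."""
    out = x.astype(float).copy()
    for idx in groups:
        m = len(idx)
        shrink = lam / (1.0 + lam * m)
        out[idx] -= shrink * x[idx].sum(axis=0)
    return out


def _reml_neg2(lam, y, X, groups):
    n, p = X.shape
    ViX = _vinv_apply(X, groups, lam)
    Viy = _vinv_apply(y[:, None], groups, lam)[:, 0]
    XtViX = X.T @ ViX
    sign, logdet_xvx = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return np.inf, None, None
    beta = np.linalg.solve(XtViX, X.T @ Viy)
    r = y - X @ beta
    quad = float(r @ _vinv_apply(r[:, None], groups, lam)[:, 0])
    sigma_e2 = quad / (n - p)
    logdet_v = float(sum(np.log1p(lam * len(idx)) for idx in groups))
    crit = (n - p) * np.log(max(sigma_e2, 1e-300)) + logdet_v + logdet_xvx
    return crit, beta, sigma_e2


def fit_random_intercept(
    y,
    X,
    patient_ids,
    contrast=None,
    names: list[str] | None = None,
    alpha: float = 0.05,
    log_lambda_bounds: tuple[float, float] = (-12.0, 10.0),
) -> LMMFit:
    """REML fit of a single-random-intercept linear mixed model.

    ``contrast`` is a vector over the fixed effects (default: the last
    coefficient).  The profiled REML criterion is optimized over log(lambda);
    if the optimum is not better than the lambda -> 0 boundary the model
    reduces to OLS and sigma_u2 = 0 is reported.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is singular")
    groups = _group_index(patient_ids)
    if len(groups) < 2:
        raise ValueError("need at least 2 patients")

    def neg2(loglam):
        return _reml_neg2(np.exp(loglam), y, X, groups)[0]

    res = optimize.minimize_scalar(
        neg2, bounds=log_lambda_bounds, method="bounded", options={"xatol": 1e-6}
    )
    lam = float(np.exp(res.x))
    crit_opt = res.fun
    crit_zero, _, _ = _reml_neg2(0.0, y, X, groups)
    boundary = crit_zero <= crit_opt + 1e-10 or res.x <= log_lambda_bounds[0] + 1e-6
    if boundary:
        lam = 0.0
        warnings.warn("variance ratio at boundary: sigma_u2 = 0 reported", stacklevel=2)
    _, beta, sigma_e2 = _reml_neg2(lam, y, X, groups)
    ViX = _vinv_apply(X, groups, lam)
    cov = sigma_e2 * np.linalg.inv(X.T @ ViX)
    se = np.sqrt(np.diag(cov))

    c = np.zeros(p)
    if contrast is None:
        c[-1] = 1.0
    else:
        c = np.asarray(contrast, float)
    est = float(c @ beta)
    est_se = float(np.sqrt(c @ cov @ c))
    if lam > 0:
        df = max(n - p - (len(groups) - 1), 1)
    else:
        df = max(n - p, 1)
    tval = est / est_se if est_se > 0 else np.nan
    pval = float(2.0 * sps.t.sf(abs(tval), df)) if np.isfinite(tval) else np.nan
    tq = sps.t.ppf(1 - alpha / 2, df)
    return LMMFit(
        beta=beta,
        se=se,
        names=names or [f"b{i}" for i in range(p)],
        sigma_u2=lam * sigma_e2,
        sigma_e2=float(sigma_e2),
        contrast=c,
        estimate=est,
        estimate_se=est_se,
        t=float(tval),
        df=float(df),
        p=pval,
        ci_low=est - tq * est_se,
        ci_high=est + tq * est_se,
        boundary=bool(boundary),
    )


def _design_from_table(
    table: pd.DataFrame,
    group_col: str,
    g1: str,
    g2: str,
    covariates: tuple[str, ...] = ("stroma_category", "age_category"),
) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Treatment-coded design: intercept, covariate dummies (first level as
    reference), group indicator (g2 = 1) last."""
    sub = table[table[group_col].isin([g1, g2])].copy()
    if (sub[group_col] == g1).sum() == 0 or (sub[group_col] == g2).sum() == 0:
        raise ValueError(f"comparison {g1} vs {g2}: one group is empty")
    cols = [np.ones(len(sub))]
    names = ["intercept"]
    for cov in covariates:
        if cov not in sub.columns:
            continue
        dummies = pd.get_dummies(sub[cov], prefix=cov, drop_first=True)
        for cname in dummies.columns:
            col = dummies[cname].to_numpy(float)
            if np.ptp(col) == 0:
                continue  # level absent in this subset
            cols.append(col)
            names.append(cname)
    cols.append((sub[group_col] == g2).to_numpy(float))
    names.append(f"{group_col}[{g2}]")
    return sub, np.column_stack(cols), names


def bulk_comparison(
    table: pd.DataFrame,
    group_col: str,
    g1: str,
    g2: str,
    value_col: str = "expression",
    covariates: tuple[str, ...] = ("stroma_category", "age_category"),
    cfg: PipelineConfig | None = None,
) -> LMMFit:
    cfg = cfg or PipelineConfig()
    sub, X, names = _design_from_table(table, group_col, g1, g2, covariates)
    return fit_random_intercept(
        sub[value_col].to_numpy(float),
        X,
        sub["patient_id"].to_numpy(),
        names=names,
        alpha=cfg.lmm_alpha,
    )


#: the four standard bulk contrasts: (label, group column, g1, g2, subset column/value)
STANDARD_COMPARISONS = [
    ("non-cancer vs cancer", "cancer_status", "non-cancer", "cancer", None),
    ("relapse-free vs relapse", "relapse_status", "relapse-free", "relapse", None),
    ("LG vs HG", "grade", "LG", "HG", ("cancer_status", "cancer")),
    (
        "relapse-free cancer vs relapse cancer",
        "relapse_status",
        "relapse-free",
        "relapse",
        ("cancer_status", "cancer"),
    ),
]


def bulk_de(
    table: pd.DataFrame,
    comparisons=None,
    value_col: str = "expression",
    cfg: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Run the standard LMM contrasts on one gene's bulk expression."""
    cfg = cfg or PipelineConfig()
    comparisons = comparisons or STANDARD_COMPARISONS
    rows = []
    for label, col, g1, g2, subset in comparisons:
        sub = table if subset is None else table[table[subset[0]] == subset[1]]
        fit = bulk_comparison(sub, col, g1, g2, value_col=value_col, cfg=cfg)
        rows.append(
            {
                "comparison": label,
                "estimate": fit.estimate,
                "se": fit.estimate_se,
                "t": fit.t,
                "df": fit.df,
                "p": fit.p,
                "ci_low": fit.ci_low,
                "ci_high": fit.ci_high,
                "sigma_u2": fit.sigma_u2,
                "sigma_e2": fit.sigma_e2,
                "n1": int((sub[col] == g1).sum()),
                "n2": int((sub[col] == g2).sum()),
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = benjamini_hochberg(out["p"].to_numpy())
    out["significant"] = out["p_adj"] < cfg.lmm_alpha
    return out


# ---------------------------------------------------------------------------
# methylation
# ---------------------------------------------------------------------------

def aggregate_regions(betas: pd.DataFrame, regions: pd.Series) -> pd.DataFrame:
    """Per-sample mean beta over promoter sites and over gene-body sites."""
    regions = regions.reindex(betas.index)
    prom = regions.isin(PROMOTER_REGIONS)
    body = regions.isin(BODY_REGIONS)
    out = pd.DataFrame(index=betas.columns)
    out["promoter_mean"] = betas.loc[prom].mean(axis=0) if prom.any() else np.nan
    out["body_mean"] = betas.loc[body].mean(axis=0) if body.any() else np.nan
    return out


def methylation_expression_correlation(
    betas: pd.DataFrame,
    regions: pd.Series,
    expression: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Spearman correlation of each site's beta (and of the promoter / body
    means) with expression across samples; BH across sites."""
    expr = expression.reindex(betas.columns)
    if expr.isna().any():
        raise ValueError("expression missing for some samples")
    e = expr.to_numpy(float)
    rows = []
    for site in betas.index:
        b = betas.loc[site].to_numpy(float)
        if np.ptp(b) == 0 or np.ptp(e) == 0:
            rows.append((site, regions.get(site, ""), np.nan, np.nan))
            continue
        rho, p = sps.spearmanr(e, b)
        rows.append((site, regions.get(site, ""), float(rho), float(p)))
    out = pd.DataFrame(rows, columns=["site", "region", "rho", "p"])
    valid = out["p"].notna()
    out["p_adj"] = np.nan
    out.loc[valid, "p_adj"] = benjamini_hochberg(out.loc[valid, "p"].to_numpy())
    out["significant"] = out["p_adj"] < alpha

    agg = aggregate_regions(betas, regions)
    means = []
    for label in ("promoter_mean", "body_mean"):
        v = agg[label].to_numpy(float)
        if np.all(np.isfinite(v)) and np.ptp(v) > 0 and np.ptp(e) > 0:
            rho, p = sps.spearmanr(e, v)
        else:
            rho, p = np.nan, np.nan
        means.append((label, label.split("_")[0], float(rho), float(p), np.nan, p < alpha))
    mean_rows = pd.DataFrame(
        means, columns=["site", "region", "rho", "p", "p_adj", "significant"]
    )
    return pd.concat([out, mean_rows], ignore_index=True)


def differential_methylation(
    betas: pd.DataFrame,
    sample_table: pd.DataFrame,
    group_col: str,
    g1: str,
    g2: str,
    covariates: tuple[str, ...] = ("stroma_category", "age_category"),
    alpha: float = 0.05,
    cfg: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Per-site random-intercept LMM contrast of beta values, BH-adjusted.

    ``sample_table`` is indexed by sample id with patient_id, group and
    covariate columns; sites with constant beta are flagged and skipped.
    """
    cfg = cfg or PipelineConfig()
    samples = betas.columns
    meta = sample_table.loc[samples]
    rows = []
    for site in betas.index:
        y = betas.loc[site, samples].to_numpy(float)
        if np.ptp(y) == 0:
            rows.append({"site": site, "estimate": np.nan, "p": np.nan, "flag": "constant"})
            continue
        tab = meta.assign(beta=y)
        fit = bulk_comparison(
            tab, group_col, g1, g2, value_col="beta", covariates=covariates, cfg=cfg
        )
        rows.append(
            {
                "site": site,
                "estimate": fit.estimate,
                "se": fit.estimate_se,
                "t": fit.t,
                "df": fit.df,
                "p": fit.p,
                "flag": "",
            }
        )
    out = pd.DataFrame(rows)
    valid = out["p"].notna()
    out["p_adj"] = np.nan
    out.loc[valid, "p_adj"] = benjamini_hochberg(out.loc[valid, "p"].to_numpy())
    out["significant"] = out["p_adj"] < alpha
    return out


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Stepwise product-limit survival estimate."""

    times: np.ndarray  # step locations (event times)
    survival: np.ndarray  # S(t) just after each step

    def __call__(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, float))
        if self.times.size == 0:
            return np.ones_like(t)
        idx = np.searchsorted(self.times, t, side="right") - 1
        return np.where(idx >= 0, self.survival[np.clip(idx, 0, None)], 1.0)


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator; steps only at event times."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    if np.any(times <= 0):
        raise ValueError("event/censoring times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    t = sf.index.to_numpy(float)
    s = sf.iloc[:, 0].to_numpy(float)
    event_times = np.unique(times[events])
    surv_at = np.array([s[t <= et][-1] for et in event_times]) if event_times.size else np.array([])
    return KMCurve(times=event_times, survival=surv_at)


def logrank(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test: (chi-squared, p) with 1 df."""
    res = logrank_test(
        np.asarray(times_a, float),
        np.asarray(times_b, float),
        event_observed_A=np.asarray(events_a, bool),
        event_observed_B=np.asarray(events_b, bool),
    )
    return float(res.test_statistic), float(res.p_value)


def representative_sample(
    bulk_table: pd.DataFrame, value_col: str = "expression"
) -> pd.DataFrame:
    """One row per patient: the sample with the highest expression of the
    gene of interest (ties broken by sample id order)."""
    df = bulk_table.sort_values(["patient_id", "sample_id"]).reset_index(drop=True)
    idx = df.groupby("patient_id")[value_col].idxmax()
    return df.loc[idx].reset_index(drop=True)


@dataclass
class SurvivalCutoffResult:
    cutoff: float
    n_high: int
    n_low: int
    chi2: float
    p: float
    km_high: KMCurve
    km_low: KMCurve
    scan: pd.DataFrame = field(repr=False)
    warning: str = (
        "cutoff chosen by exhaustive log-rank scan; the minimized p-value is "
        "reported unadjusted and is optimistically biased"
    )


def optimal_cutoff(
    expression, times, events, min_group: int | None = None
) -> SurvivalCutoffResult:
    """Exhaustive scan for the expression cutoff with the smallest log-rank p.

    Candidate cutoffs are midpoints between consecutive sorted unique
    expression values leaving at least ``min_group`` patients on each side
    (default max(3, 10% of patients)).
    """
    x = np.asarray(expression, float)
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    n = x.size
    if min_group is None:
        min_group = max(3, int(np.ceil(0.1 * n)))
    if n < 2 * min_group:
        raise ValueError(f"need at least {2 * min_group} patients")
    uniq = np.unique(x)
    if uniq.size < 2:
        raise ValueError("constant expression: no valid cutoff")
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    rows = []
    for c in mids:
        hi = x > c
        n_hi, n_lo = int(hi.sum()), int((~hi).sum())
        if n_hi < min_group or n_lo < min_group:
            continue
        chi2, p = logrank(times[hi], events[hi], times[~hi], events[~hi])
        rows.append((float(c), n_hi, n_lo, chi2, p))
    if not rows:
        raise ValueError("no cutoff satisfies the minimum group size")
    scan = pd.DataFrame(rows, columns=["cutoff", "n_high", "n_low", "chi2", "p"])
    best = scan.loc[scan["p"].idxmin()]
    hi = x > best["cutoff"]
    return SurvivalCutoffResult(
        cutoff=float(best["cutoff"]),
        n_high=int(best["n_high"]),
        n_low=int(best["n_low"]),
        chi2=float(best["chi2"]),
        p=float(best["p"]),
        km_high=km_estimate(times[hi], events[hi]),
        km_low=km_estimate(times[~hi], events[~hi]),
        scan=scan,
    )


def percentile_rank(feature_sums, target_feature) -> float:
    """Percentile of one feature's total among all features' totals
    (average-rank ties): 100 * rank / n."""
    sums = pd.Series(feature_sums)
    if target_feature not in sums.index:
        raise KeyError(f"{target_feature!r} not among features")
    ranks = sps.rankdata(sums.to_numpy(float), method="average")
    r = float(ranks[sums.index.get_loc(target_feature)])
    return 100.0 * r / len(sums)
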