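"""Negative-binomial quasi-likelihood differential expression.

Spot-level counts are modelled gene-wise as NB(mu, phi) with a log link,

    log mu_gs = x_s' beta_g + offset_s,        var = mu + phi * mu^2,

where each spot is one replicate of its histology group.  The fit has three
stages, mirroring the quasi-likelihood strategy used for over-dispersed
count data:

1. genewise NB dispersion phi_g by Cox-Reid adjusted profile likelihood,
   shrunk on the log scale toward the all-gene common dispersion with a
   configurable prior weight;
2. IRLS fit of beta_g at the shrunk dispersion;
3. a quasi-dispersion s2_g = residual deviance / df, moderated toward its
   trimmed mean with a prior df, which scales the covariance of beta_g and
   sets the t reference distribution's df.

Significance uses the fold-change threshold construction (TREAT): for a
contrast estimate b with standard error s and threshold tau,

    p = P(T > (|b| - tau)/s) + P(T > (|b| + tau)/s),

so a gene is called only if its fold change credibly exceeds tau, not merely
zero.  At tau = 0 this reduces exactly to the ordinary two-sided t-test.
p-values are Benjamini-Hochberg adjusted across genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig

LN2 = np.log(2.0)
_PHI_FLOOR = 1e-6
_MU_FLOOR = 1e-8


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up adjusted p-values, input order preserved, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# single-gene machinery
# ---------------------------------------------------------------------------

def _irls(y, X, offset, phi, beta0=None, max_iter=50, tol=1e-8):
    """IRLS for the NB log-linear model at fixed dispersion.

    Returns (beta, mu, XtWX, converged).
    """
    n, p = X.shape
    if beta0 is None:
        # moment start: intercept at log mean, slopes 0
        mu0 = max(float(np.mean(y / np.exp(offset))), _MU_FLOOR)
        beta = np.zeros(p)
        beta[0] = np.log(mu0)
    else:
        beta = beta0.copy()
    eta = np.clip(X @ beta + offset, -30.0, 30.0)
    mu = np.maximum(np.exp(eta), _MU_FLOOR)
    dev_old = np.inf
    converged = False
    XtWX = None
    for _ in range(max_iter):
        w = mu / (1.0 + phi * mu)
        z = (eta - offset) + (y - mu) / mu
        Xw = X * w[:, None]
        XtWX = X.T @ Xw
        try:
            beta = np.linalg.solve(XtWX, Xw.T @ z)
        except np.linalg.LinAlgError:
            break
        eta = np.clip(X @ beta + offset, -30.0, 30.0)
        mu = np.maximum(np.exp(eta), _MU_FLOOR)
        dev = _nb_deviance(y, mu, phi)
        if abs(dev - dev_old) < tol * (abs(dev) + 0.1):
            converged = True
            dev_old = dev
            break
        dev_old = dev
    w = mu / (1.0 + phi * mu)
    XtWX = X.T @ (X * w[:, None])
    return beta, mu, XtWX, converged


def _nb_loglik(y, mu, phi):
    if phi < _PHI_FLOOR:
        return float(np.sum(y * np.log(mu) - mu - special.gammaln(y + 1)))
    k = 1.0 / phi
    return float(
        np.sum(
            special.gammaln(y + k)
            - special.gammaln(k)
            - special.gammaln(y + 1)
            + k * np.log(k / (k + mu))
            + y * np.log(mu / (k + mu))
        )
    )


def _nb_deviance(y, mu, phi):
    """2 * (saturated - fitted) NB log-likelihood."""
    yl = np.where(y > 0, y * np.log(np.maximum(y, 1) / mu), 0.0)
    if phi < _PHI_FLOOR:
        return float(2.0 * np.sum(yl - (y - mu)))
    k = 1.0 / phi
    return float(2.0 * np.sum(yl - (y + k) * np.log((y + k) / (mu + k))))


def _adjusted_profile_loglik(log_phi, y, X, offset, beta_warm):
    """Cox-Reid adjusted profile log-likelihood of the dispersion."""
    phi = np.exp(log_phi)
    beta, mu, XtWX, _ = _irls(y, X, offset, phi, beta0=beta_warm)
    sign, logdet = np.linalg.slogdet(XtWX)
    if sign <= 0:
        logdet = -50.0
    return _nb_loglik(y, mu, phi) - 0.5 * logdet, beta


def estimate_dispersion(y, X, offset, log_phi_bounds=(-10.0, 3.0)):
    """Genewise NB dispersion by maximizing the Cox-Reid adjusted profile
    likelihood over log(phi)."""
    warm = {"beta": None}

    def neg(lp):
        val, beta = _adjusted_profile_loglik(lp, y, X, offset, warm["beta"])
        warm["beta"] = beta
        return -val

    res = optimize.minimize_scalar(
        neg, bounds=log_phi_bounds, method="bounded", options={"xatol": 1e-3}
    )
    return float(np.exp(res.x))


# ---------------------------------------------------------------------------
# container
# ---------------------------------------------------------------------------

@dataclass
class NBQLFits:
    """Genewise NB QL fits for one design."""

    genes: list[str]
    design: np.ndarray
    beta: np.ndarray  # (G, p), natural-log scale
    cov_unscaled: np.ndarray  # (G, p, p): (X'WX)^-1
    dispersion: np.ndarray  # (G,) shrunk NB dispersion phi
    dispersion_raw: np.ndarray  # (G,) genewise APL estimates
    common_dispersion: float
    s2_post: np.ndarray  # (G,) moderated quasi-dispersion
    df_residual: float
    df_prior: float
    converged: np.ndarray  # (G,) bool
    ok: np.ndarray  # (G,) bool: fit usable for testing

    @property
    def df_total(self) -> float:
        return self.df_residual + self.df_prior


def fit_nb_ql(
    counts,
    design: np.ndarray,
    offsets: np.ndarray | None = None,
    cfg: PipelineConfig | None = None,
) -> NBQLFits:
    """Fit the NB quasi-likelihood GLM to every gene of a counts matrix.

    Parameters
    ----------
    counts : DataFrame (genes x spots) or 2-D array
    design : (n_spots, p) full-rank design matrix
    offsets : optional per-spot log offsets (e.g. centered log library size)
    """
    cfg = cfg or PipelineConfig()
    if isinstance(counts, pd.DataFrame):
        genes = [str(g) for g in counts.index]
        Y = counts.to_numpy(float)
    else:
        Y = np.asarray(counts, float)
        genes = [f"g{i}" for i in range(Y.shape[0])]
    X = np.asarray(design, float)
    n, p = X.shape
    if Y.shape[1] != n:
        raise ValueError("counts and design disagree on the number of spots")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is not full rank")
    offset = np.zeros(n) if offsets is None else np.asarray(offsets, float)
    G = Y.shape[0]
    df_res = float(n - p)
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")

    ok = Y.sum(axis=1) > 0
    phi_raw = np.full(G, np.nan)
    for g in np.flatnonzero(ok):
        phi_raw[g] = estimate_dispersion(Y[g], X, offset)

    # common dispersion: mean log genewise estimate; shrink on the log scale
    usable = ok & np.isfinite(phi_raw)
    logs = np.log(np.maximum(phi_raw[usable], _PHI_FLOOR))
    common = float(np.exp(logs.mean())) if logs.size else _PHI_FLOOR
    w0 = float(cfg.dispersion_prior_weight)
    phi = np.full(G, common)
    phi[usable] = np.exp(
        (df_res * np.log(np.maximum(phi_raw[usable], _PHI_FLOOR)) + w0 * np.log(common))
        / (df_res + w0)
    )

    beta = np.zeros((G, p))
    cov_u = np.zeros((G, p, p))
    s2 = np.full(G, np.nan)
    conv = np.zeros(G, bool)
    for g in np.flatnonzero(ok):
        b, mu, XtWX, c = _irls(Y[g], X, offset, phi[g])
        try:
            cov = np.linalg.inv(XtWX)
        except np.linalg.LinAlgError:
            ok[g] = False
            continue
        beta[g] = b
        cov_u[g] = cov
        conv[g] = c
        s2[g] = _nb_deviance(Y[g], mu, phi[g]) / df_res
    ok &= conv

    # moderate quasi-dispersions toward their trimmed mean
    d0 = float(cfg.ql_prior_df)
    vals = s2[ok & np.isfinite(s2)]
    s2_0 = float(stats.trim_mean(vals, 0.2)) if vals.size else 1.0
    s2_post = np.where(
        np.isfinite(s2), (d0 * s2_0 + df_res * s2) / (d0 + df_res), np.nan
    )

    return NBQLFits(
        genes=genes,
        design=X,
        beta=beta,
        cov_unscaled=cov_u,
        dispersion=phi,
        dispersion_raw=phi_raw,
        common_dispersion=common,
        s2_post=s2_post,
        df_residual=df_res,
        df_prior=d0,
        converged=conv,
        ok=ok,
    )


def treat_test(
    fits: NBQLFits,
    contrast,
    tau: float | None = None,
    alpha: float | None = None,
    cfg: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Fold-change threshold test of a contrast for every fitted gene.

    ``tau`` is in log2 units (default: config de_lfc_threshold).  Returns a
    DataFrame with gene, log2FC, dispersion, se, p_raw, p_adj, significant.
    """
    cfg = cfg or PipelineConfig()
    tau = cfg.de_lfc_threshold if tau is None else float(tau)
    alpha = cfg.de_alpha if alpha is None else float(alpha)
    if tau < 0:
        raise ValueError("tau must be non-negative")
    c = np.asarray(contrast, float)
    G = len(fits.genes)
    b_ln = fits.beta @ c
    var_u = np.einsum("i,gij,j->g", c, fits.cov_unscaled, c)
    se_ln = np.sqrt(np.maximum(fits.s2_post, 0.0) * var_u)
    # work on the log2 scale, where tau is stated
    b2 = b_ln / LN2
    se2 = se_ln / LN2

    p = np.full(G, np.nan)
    testable = fits.ok & np.isfinite(se2) & (se2 > 0)
    df = fits.df_total
    t1 = (np.abs(b2[testable]) - tau) / se2[testable]
    t2 = (np.abs(b2[testable]) + tau) / se2[testable]
    p[testable] = stats.t.sf(t1, df) + stats.t.sf(t2, df)

    p_adj = np.full(G, np.nan)
    if testable.any():
        p_adj[testable] = benjamini_hochberg(p[testable])
    out = pd.DataFrame(
        {
            "gene": fits.genes,
            "log2FC": b2,
            "dispersion": fits.dispersion,
            "se": se2,
            "p_raw": p,
            "p_adj": p_adj,
            "significant": p_adj < alpha,
            "ok": testable,
        }
    )
    return out


def pairwise_de(
    norm_counts: pd.DataFrame,
    calls: pd.Series,
    comparisons: list[tuple[str, str]],
    cfg: PipelineConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Run the NB QL + threshold test for each pair of histology groups.

    ``calls`` maps spot id -> histology call; spots within a group are treated
    as biological replicates.  log2FC is group2 relative to group1.
    """
    cfg = cfg or PipelineConfig()
    calls = calls.reindex(norm_counts.columns)
    results: dict[str, pd.DataFrame] = {}
    for g1, g2 in comparisons:
        sel1 = calls == g1
        sel2 = calls == g2
        if sel1.sum() == 0 or sel2.sum() == 0:
            raise ValueError(f"comparison {g1} vs {g2}: one group has no spots")
        sub = norm_counts.loc[:, sel1 | sel2]
        grp2 = calls.loc[sub.columns].eq(g2).to_numpy(float)
        X = np.column_stack([np.ones(sub.shape[1]), grp2])
        offsets = None
        if cfg.use_library_offset:
            tot = sub.sum(axis=0).to_numpy(float)
            tot = np.maximum(tot, 1.0)
            offsets = np.log(tot) - np.log(tot).mean()
        fits = fit_nb_ql(sub, X, offsets=offsets, cfg=cfg)
        tab = treat_test(fits, [0.0, 1.0], cfg=cfg)
        tab.insert(1, "comparison", f"{g1} vs {g2}")
        results[f"{g1} vs {g2}"] = tab
    return results
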