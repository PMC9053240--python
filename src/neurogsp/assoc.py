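"""Partial correlation, bootstrap mediation, and moderation analysis.

These are the interpretation-stage models linking band-energy features to
age, serum NfL, personality (PAI) scores and structural measures.

* ``partial_corr`` — Pearson correlation of the OLS residuals of x and y
  on the covariates, p from the t distribution on n−k−2 df.
* ``mediate`` — the three-regression path model: a from M ~ X, b and c′
  from Y ~ X + M, c (total) from Y ~ X, indirect effect ab = a·b, with the
  exact OLS identity c = c′ + a·b. Path significance by case-resampling
  bootstrap (10000 samples in the source protocol) with percentile
  two-sided p-values; a bias-corrected option is available.
* ``moderate`` — OLS of Y on [covariates, X, W, X·W]; the product-term
  coefficient (translation-invariant) is the moderation effect, and simple
  slopes of Y on X are reported at W = mean ± SD.

Variables enter in raw units by default; mediation offers a
standardization flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from neurogsp.univariate import bh_fdr

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PartialCorrelation:
    rho: float
    p_value: float
    n: int
    covariates: tuple = ()


@dataclass(frozen=True)
class PathEstimate:
    coef: float
    se: float
    p_ols: float
    p_boot: float = np.nan


@dataclass(frozen=True)
class MediationResult:
    """Mediation paths with bootstrap p-values.

    ``a``: X → M;  ``b``: M → Y adjusted for X;  ``c_prime``: direct X → Y;
    ``ab``: indirect effect; ``c_total``: unadjusted X → Y. The OLS
    identity c_total = c_prime + a·b holds exactly (same covariate set in
    every regression).
    """

    a: PathEstimate
    b: PathEstimate
    c_prime: PathEstimate
    ab: PathEstimate
    c_total: PathEstimate
    n: int
    n_boot: int
    seed: int
    roles: dict = field(default_factory=dict)
    standardized: bool = False


@dataclass(frozen=True)
class ModerationResult:
    """OLS moderation fit with simple slopes at moderator mean ± SD."""

    params: pd.DataFrame = field(repr=False)
    interaction: PathEstimate = None
    simple_slopes: pd.DataFrame = field(repr=False, default=None)
    n: int = 0
    centered: bool = True
    moderator_mean: float = np.nan
    moderator_sd: float = np.nan


def _clean_vectors(*arrays):
    out = [np.asarray(a, dtype=float) for a in arrays]
    n = out[0].shape[0]
    for a in out:
        if a.shape[0] != n:
            raise ValueError("inputs differ in length")
        if not np.all(np.isfinite(a)):
            raise ValueError("non-finite values; supply complete cases")
    return out


def partial_corr(x, y, covariates=None, covariate_names=()) -> PartialCorrelation:
    """Partial Pearson correlation of x and y given covariates.

    With an empty covariate set this is the plain Pearson correlation.
    """
    if covariates is None or (hasattr(covariates, "size") and covariates.size == 0):
        C = None
        x, y = _clean_vectors(x, y)
        k = 0
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        x, y = _clean_vectors(x, y)
        if C.shape[0] != len(x) or not np.all(np.isfinite(C)):
            raise ValueError("bad covariate matrix")
        k = C.shape[1]
    n = len(x)
    if n <= k + 2:
        raise ValueError(f"need n > k+2 (n={n}, k={k})")
    if C is not None:
        Z = np.column_stack([np.ones(n), C])
        if np.linalg.matrix_rank(Z) < Z.shape[1]:
            raise ValueError("rank-deficient covariate matrix")
        rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
        ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    else:
        rx, ry = x - x.mean(), y - y.mean()
    # a residual that is numerically zero relative to its source carries no
    # signal (e.g. y exactly equal to a covariate): report rho = 0
    tiny = 1e-10
    if np.linalg.norm(rx) <= tiny * max(np.linalg.norm(x), 1.0) or \
            np.linalg.norm(ry) <= tiny * max(np.linalg.norm(y), 1.0):
        return PartialCorrelation(rho=0.0, p_value=1.0, n=n,
                                  covariates=tuple(covariate_names))
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    rho = float(np.clip((rx @ ry) / denom, -1.0, 1.0))
    df = n - k - 2
    if abs(rho) == 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt(df / (1.0 - rho ** 2))
        p = float(2 * stats.t.sf(abs(t), df))
    return PartialCorrelation(rho=rho, p_value=p, n=n,
                              covariates=tuple(covariate_names))


def _ols(y, Z):
    """Coefficients, SEs and two-sided p for OLS y ~ Z (Z includes 1)."""
    n, k = Z.shape
    beta, _, rank, _ = np.linalg.lstsq(Z, y, rcond=None)
    if rank < k:
        raise ValueError("rank-deficient design")
    resid = y - Z @ beta
    df = n - k
    s2 = (resid @ resid) / df
    cov = s2 * np.linalg.inv(Z.T @ Z)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df)
    return beta, se, p


def _boot_paths(X, M, Y, C, idx):
    """Vectorized a, b, c' over bootstrap index matrix (B × n)."""
    B, n = idx.shape
    ones = np.ones((B, n))
    # a from M ~ [1, X, C]
    Za = np.stack([ones, X[idx]] + [c[idx] for c in C], axis=2)  # B×n×k
    Ma = M[idx]
    Ga = np.einsum("bnk,bnl->bkl", Za, Za)
    ga = np.einsum("bnk,bn->bk", Za, Ma)
    a = np.linalg.solve(Ga, ga[..., None])[:, 1, 0]
    # b, c' from Y ~ [1, X, M, C]
    Zb = np.stack([ones, X[idx], M[idx]] + [c[idx] for c in C], axis=2)
    Yb = Y[idx]
    Gb = np.einsum("bnk,bnl->bkl", Zb, Zb)
    gb = np.einsum("bnk,bn->bk", Zb, Yb)
    coefs = np.linalg.solve(Gb, gb[..., None])[..., 0]
    c_prime, b = coefs[:, 1], coefs[:, 2]
    return a, b, c_prime


def _percentile_p(draws):
    lo = np.count_nonzero(draws <= 0)
    hi = np.count_nonzero(draws >= 0)
    return float(min(1.0, 2.0 * min(lo, hi) / draws.size))


def _bc_p(draws, point):
    """Bias-corrected two-sided bootstrap p for H0: θ = 0 (no acceleration)."""
    B = draws.size
    clip = lambda f: min(max(f, 1.0 / (2 * B)), 1 - 1.0 / (2 * B))
    z0 = stats.norm.ppf(clip(np.count_nonzero(draws < point) / B))
    z_theta = stats.norm.ppf(clip(np.count_nonzero(draws <= 0) / B))
    p_one = stats.norm.cdf(z_theta - 2 * z0)
    return float(min(1.0, 2 * min(p_one, 1 - p_one)))


def mediate(X, M, Y, covariates=None, n_boot: int = 10000, seed: int = None,
            standardized: bool = False, bias_corrected: bool = False,
            roles=None) -> MediationResult:
    """Bootstrap mediation of X → M → Y.

    Complete cases required; ``seed`` is mandatory. Resamples subjects with
    replacement; per-path p-values are percentile two-sided by default
    (``bias_corrected=True`` switches to the bias-corrected variant).
    """
    if seed is None:
        raise ValueError("mediate requires an explicit seed")
    X, M, Y = _clean_vectors(X, M, Y)
    for name, v in (("X", X), ("M", M), ("Y", Y)):
        if v.std() == 0:
            raise ValueError(f"zero variance in mediation role {name}")
    if covariates is None:
        C = []
    else:
        Cm = np.asarray(covariates, dtype=float)
        if Cm.ndim == 1:
            Cm = Cm[:, None]
        C = [Cm[:, j] for j in range(Cm.shape[1])]
    if standardized:
        X, M, Y = ((v - v.mean()) / v.std(ddof=1) for v in (X, M, Y))
    n = len(X)
    ones = np.ones(n)
    Za = np.column_stack([ones, X] + C)
    Zb = np.column_stack([ones, X, M] + C)
    beta_a, se_a, p_a = _ols(M, Za)
    beta_b, se_b, p_b = _ols(Y, Zb)
    beta_c, se_c, p_c = _ols(Y, Za)
    a_hat, b_hat = beta_a[1], beta_b[2]
    c_prime_hat, c_hat = beta_b[1], beta_c[1]
    ab_hat = a_hat * b_hat

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    a_s, b_s, cp_s = _boot_paths(X, M, Y, C, idx)
    ab_s = a_s * b_s
    c_s = cp_s + ab_s
    pfun = (lambda d, pt: _bc_p(d, pt)) if bias_corrected else \
           (lambda d, pt: _percentile_p(d))
    # Sobel-style SE for ab reported from the bootstrap spread
    return MediationResult(
        a=PathEstimate(float(a_hat), float(se_a[1]), float(p_a[1]),
                       pfun(a_s, a_hat)),
        b=PathEstimate(float(b_hat), float(se_b[2]), float(p_b[2]),
                       pfun(b_s, b_hat)),
        c_prime=PathEstimate(float(c_prime_hat), float(se_b[1]), float(p_b[1]),
                             pfun(cp_s, c_prime_hat)),
        ab=PathEstimate(float(ab_hat), float(ab_s.std(ddof=1)), np.nan,
                        pfun(ab_s, ab_hat)),
        c_total=PathEstimate(float(c_hat), float(se_c[1]), float(p_c[1]),
                             pfun(c_s, c_hat)),
        n=n, n_boot=n_boot, seed=seed, roles=dict(roles or {}),
        standardized=standardized,
    )


def moderate(Y, X, W, covariates=None, center: bool = True,
             covariate_names=()) -> ModerationResult:
    """Moderation of the X → Y relationship by W via the X·W product term.

    The interaction coefficient is invariant to translation (centering) of
    X and W; centering (default) only makes the main effects interpretable
    at the moderator mean. Simple slopes dY/dX are evaluated at W equal to
    its mean − SD, mean, and mean + SD, with delta-method SEs.
    """
    Y, X, W = _clean_vectors(Y, X, W)
    n = len(Y)
    if covariates is None:
        C = np.empty((n, 0))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    w_mean, w_sd = float(W.mean()), float(W.std(ddof=1))
    Xd = X - X.mean() if center else X
    Wd = W - w_mean if center else W
    names = (["intercept"] + [covariate_names[j] if j < len(covariate_names)
                              else f"cov{j}" for j in range(C.shape[1])]
             + ["x", "w", "x_w"])
    Z = np.column_stack([np.ones(n), C, Xd, Wd, Xd * Wd])
    if n <= Z.shape[1] + 1:
        raise ValueError("too few observations for the moderation design")
    cond = np.linalg.cond(Z)
    if cond > 1e8:
        log.warning("moderation design condition number %.2e; estimates may "
                    "be unstable", cond)
    res = sm.OLS(Y, Z).fit()
    params = pd.DataFrame(
        {"coef": res.params, "se": res.bse, "p": res.pvalues}, index=names
    )
    i_x, i_int = names.index("x"), names.index("x_w")
    cov = np.asarray(res.cov_params())
    rows = []
    for label, w_val in (("mean-sd", w_mean - w_sd), ("mean", w_mean),
                         ("mean+sd", w_mean + w_sd)):
        wd = w_val - w_mean if center else w_val
        slope = res.params[i_x] + res.params[i_int] * wd
        var = (cov[i_x, i_x] + wd ** 2 * cov[i_int, i_int]
               + 2 * wd * cov[i_x, i_int])
        se = float(np.sqrt(var))
        t = slope / se
        rows.append((label, w_val, float(slope), se,
                     float(2 * stats.t.sf(abs(t), res.df_resid))))
    slopes = pd.DataFrame(rows, columns=["at", "w_value", "slope", "se", "p"])
    interaction = PathEstimate(float(res.params[i_int]), float(res.bse[i_int]),
                               float(res.pvalues[i_int]))
    return ModerationResult(params=params, interaction=interaction,
                            simple_slopes=slopes, n=n, centered=center,
                            moderator_mean=w_mean, moderator_sd=w_sd)


def fdr_over_tests(named_p_values: dict, alpha: float = 0.05) -> dict:
    """BH-FDR over an explicitly declared family of named tests.

    Returns a dict with per-test q-values and rejection flags plus the
    recorded family membership, so the correction family is auditable.
    """
    if not named_p_values:
        raise ValueError("empty test family")
    names = list(named_p_values)
    q, reject = bh_fdr(np.array([named_p_values[k] for k in names]), alpha=alpha)
    return {
        "family": names,
        "alpha": alpha,
        "q_values": dict(zip(names, map(float, q))),
        "reject": dict(zip(names, map(bool, reject))),
    }
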