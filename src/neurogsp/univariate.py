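"""Univariate feature selection and nonparametric group comparisons.

``f_select`` regresses the outcome (serum NfL) on each band-energy feature
separately; the F statistic F = (n−2)·r²/(1−r²) on (1, n−2) df is the
two-model ANOVA comparison of the simple regression against the intercept-
only model. ``bh_fdr`` applies the Benjamini-Hochberg step-up correction
over the declared feature family. ``rank_sum`` is the Wilcoxon rank-sum /
Mann-Whitney U comparison used for cohort differences, exact by
enumeration at small total n and normal-approximate (midrank ties,
tie-corrected variance) otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.feature_selection import f_regression
from statsmodels.stats.multitest import multipletests

#: total sample size at or below which the rank-sum p-value is exact.
EXACT_RANKSUM_N = 12


@dataclass(frozen=True)
class GroupTestResult:
    """Mann-Whitney U (and equivalent rank-sum W) with two-sided p."""

    u_statistic: float
    rank_sum_w: float
    p_value: float
    n_a: int
    n_b: int
    method: str


def f_select(features, y, feature_names=None) -> pd.DataFrame:
    """Per-feature simple-regression F test of association with ``y``.

    Returns a DataFrame indexed by feature with columns ``F``, ``p``,
    ``q`` (BH-adjusted over all supplied features), ``rank`` (1 = largest
    F) and ``constant`` (True for zero-variance features, which get
    F = NaN rather than being silently dropped). A perfect fit reports
    F = +inf, p = 0.
    """
    X = np.asarray(features, dtype=float)
    if isinstance(features, pd.DataFrame) and feature_names is None:
        feature_names = list(features.columns)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be 2-D (subjects × features)")
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if y.shape != (n,):
        raise ValueError("outcome length does not match feature rows")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("missing or non-finite values")
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(p)]

    constant = X.std(axis=0) == 0
    F = np.full(p, np.nan)
    pv = np.full(p, np.nan)
    ok = ~constant
    if ok.any():
        with np.errstate(divide="ignore", invalid="ignore"):
            F[ok], pv[ok] = f_regression(X[:, ok], y)
        # perfect fits (|r| = 1): report F = +inf, p = 0 explicitly
        Xc = X[:, ok] - X[:, ok].mean(axis=0)
        yc = y - y.mean()
        ynorm = np.linalg.norm(yc)
        if ynorm > 0:
            r = (Xc.T @ yc) / (np.linalg.norm(Xc, axis=0) * ynorm)
            perfect = ok.copy()
            perfect[ok] = np.abs(r) >= 1.0 - 1e-12
            F[perfect] = np.inf
            pv[perfect] = 0.0
    out = pd.DataFrame({"F": F, "p": pv, "constant": constant},
                       index=pd.Index(feature_names, name="feature"))
    valid = out["p"].notna()
    q = np.full(p, np.nan)
    if valid.any():
        q[valid.to_numpy()] = bh_fdr(out.loc[valid, "p"].to_numpy())[0]
    out["q"] = q
    out["rank"] = out["F"].rank(ascending=False, method="min")
    return out


def bh_fdr(p_values, alpha: float = 0.05):
    """Benjamini-Hochberg step-up adjusted q-values and rejection set.

    Returns ``(q_values, reject)``; rejections are at q ≤ alpha. Tied
    adjusted values are legal output of the step-up enforcement.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a nonempty 1-D vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


def rank_sum(group_a, group_b) -> GroupTestResult:
    """Two-sided Wilcoxon rank-sum / Mann-Whitney U test.

    Exact enumeration when the combined sample is small
    (n_a + n_b ≤ ``EXACT_RANKSUM_N``) and tie-free; otherwise the normal
    approximation with midrank tie correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    total = a.size + b.size
    has_ties = np.unique(np.concatenate([a, b])).size < total
    method = "exact" if (total <= EXACT_RANKSUM_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    w = res.statistic + a.size * (a.size + 1) / 2.0  # rank-sum of group A
    return GroupTestResult(
        u_statistic=float(res.statistic),
        rank_sum_w=float(w),
        p_value=float(res.pvalue),
        n_a=int(a.size),
        n_b=int(b.size),
        method=method,
    )
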