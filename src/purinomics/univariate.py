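"""Per-metabolite hypothesis tests, multiplicity control, and the
significance filter.

Two-group comparisons use the Mann-Whitney U test (exact when feasible)
alongside Welch's t; three or more groups use one-way ANOVA with Fisher's
protected least-significant-difference post hoc.  Multiplicity is handled
by Benjamini-Hochberg step-up adjustment and Storey's q-value with a
smoother pi0 estimate.  The headline filter declares a metabolite changed
when FDR < fdr_max AND VIP >= vip_min AND Welch-t p < p_max.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import make_smoothing_spline
from statsmodels.stats.multitest import multipletests

from .preprocess import ZScoreMatrix

#: Largest combined sample size at which the exact U distribution is used.
EXACT_MW_LIMIT = 16


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Mann-Whitney U statistic of ``x`` and a two-sided p value.

    Exact enumeration when n_x + n_y <= 16 and there are no ties across
    the pooled sample; otherwise the normal approximation with midrank tie
    correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= EXACT_MW_LIMIT and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def welch_t(x, y) -> tuple[float, float]:
    """Welch two-sample t statistic and two-sided p."""
    res = stats.ttest_ind(np.asarray(x, float), np.asarray(y, float), equal_var=False)
    return float(res.statistic), float(res.pvalue)


def anova_fisher_lsd(
    groups: list, alpha: float = 0.05
) -> tuple[float, float, np.ndarray]:
    """One-way ANOVA F with Fisher's protected LSD pairwise p matrix.

    Pairwise LSD t tests share the pooled mean-square error with N - k
    degrees of freedom; being "protected", the pairwise matrix is all NaN
    unless the omnibus p falls below ``alpha``.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError(f"need >= 3 groups, got {len(groups)}")
    for i, g in enumerate(groups):
        if g.size < 2:
            raise ValueError(f"group {i} has {g.size} values; need >= 2")
    k = len(groups)
    N = sum(g.size for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = k - 1, N - k
    if ss_within == 0:
        if ss_between == 0:  # all observations identical
            return 0.0, 1.0, np.full((k, k), np.nan)
        F, p = np.inf, 0.0
    else:
        F = (ss_between / df_b) / (ss_within / df_w)
        p = float(stats.f.sf(F, df_b, df_w))
    if ss_between == 0:
        F, p = 0.0, 1.0
    lsd = np.full((k, k), np.nan)
    if p < alpha and ss_within > 0:
        mse = ss_within / df_w
        for i in range(k):
            for j in range(i + 1, k):
                se = np.sqrt(mse * (1 / groups[i].size + 1 / groups[j].size))
                t = (groups[i].mean() - groups[j].mean()) / se
                pij = 2 * stats.t.sf(abs(t), df_w)
                lsd[i, j] = lsd[j, i] = pij
    return float(F), float(p), lsd


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


#: Default lambda grid for pi0 estimation.
DEFAULT_LAMBDA_GRID = np.round(np.arange(0.05, 0.96, 0.05), 2)

#: Minimum number of p values for data-driven pi0 estimation.
MIN_M_FOR_PI0 = 20


def estimate_pi0(pvals, lambda_grid=DEFAULT_LAMBDA_GRID) -> float:
    """Storey's smoother estimate of the null proportion pi0.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is smoothed with a cubic
    smoothing spline and evaluated at the largest lambda, then clipped to
    (0, 1].
    """
    p = np.asarray(pvals, dtype=float)
    lam = np.asarray(lambda_grid, dtype=float)
    m = p.size
    if m < MIN_M_FOR_PI0:
        warnings.warn(
            f"only {m} p values; falling back to pi0 = 1", stacklevel=2
        )
        return 1.0
    pi0_lam = np.array([(p > l).sum() / (m * (1.0 - l)) for l in lam])
    spline = make_smoothing_spline(lam, pi0_lam)
    pi0 = float(spline(lam.max()))
    return float(np.clip(pi0, 1.0 / m, 1.0))


def storey_q(pvals, lambda_grid=DEFAULT_LAMBDA_GRID, pi0: float | None = None
             ) -> np.ndarray:
    """Storey q values: q_i = min over t >= p_i of pi0 * m * t / #{p <= t}.

    ``pi0`` overrides the smoother estimate; with pi0 = 1 the q values
    reduce to Benjamini-Hochberg adjusted p values.  q is monotone
    non-decreasing in p by construction.
    """
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    if pi0 is None:
        pi0 = estimate_pi0(p, lambda_grid)
    order = np.argsort(p, kind="mergesort")
    q_sorted = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0, 1)
    return q


def univariate_table(zmat: ZScoreMatrix, treated_group: str | None = None
                     ) -> pd.DataFrame:
    """Per-metabolite two-group statistics for a control-vs-treated cohort.

    Returns a DataFrame indexed by metabolite with mean treated z, U and
    its p, Welch-t p, BH FDR (on the Mann-Whitney p values), Storey q,
    Spearman association of z with treatment, and direction.
    """
    ctrl_mask = zmat.groups == zmat.control_group
    if treated_group is None:
        trt_mask = ~ctrl_mask
    else:
        trt_mask = zmat.groups == treated_group
    if trt_mask.sum() < 2 or ctrl_mask.sum() < 2:
        raise ValueError("need >= 2 samples in each of control and treated")
    label = trt_mask.astype(int).to_numpy()
    rows = {}
    for met in zmat.z.columns:
        zc = zmat.z.loc[ctrl_mask, met].to_numpy()
        zt = zmat.z.loc[trt_mask, met].to_numpy()
        U, u_p = mann_whitney_u(zt, zc)
        _, t_p = welch_t(zt, zc)
        rho = stats.spearmanr(zmat.z[met].to_numpy()[ctrl_mask | trt_mask],
                              label[ctrl_mask | trt_mask]).statistic
        mean_z = float(zt.mean())
        rows[met] = {
            "mean_z": mean_z,
            "U": U,
            "U_p": u_p,
            "t_p": t_p,
            "spearman_r": float(rho),
            "direction": "up" if mean_z > 0 else ("down" if mean_z < 0 else "flat"),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "metabolite"
    out["fdr"] = bh_fdr(out["U_p"].to_numpy())
    out["q"] = storey_q(out["U_p"].to_numpy())
    return out


def significance_filter(
    results: pd.DataFrame,
    vip: pd.Series,
    fdr_max: float = 0.05,
    vip_min: float = 0.9,
    p_max: float = 0.05,
) -> tuple[pd.Series, int, float]:
    """Headline changed-metabolite filter: FDR < fdr_max AND VIP >= vip_min
    AND Welch-t p < p_max.

    Returns the boolean pass mask (indexed like ``results``), the count of
    passing metabolites, and the passing fraction of the total.
    """
    missing = results.index.difference(vip.index)
    if len(missing):
        raise ValueError(f"VIP missing for metabolite {missing[0]!r}")
    vip = vip.reindex(results.index)
    # Probability thresholds of exactly 1 are degenerate "accept all" settings;
    # a strict < there would reject p = 1.0 on a technicality.
    fdr_ok = results["fdr"] < fdr_max if fdr_max < 1 else results["fdr"] <= 1
    p_ok = results["t_p"] < p_max if p_max < 1 else results["t_p"] <= 1
    mask = fdr_ok & (vip >= vip_min) & p_ok
    count = int(mask.sum())
    return mask, count, count / len(results) if len(results) else 0.0
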