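"""Enrichment statistics against brute-force enumeration oracles."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from assembly_buffer import (
    GeneRecord,
    abundance_quartiles,
    bootstrap_shift,
    fisher_exact,
    gen_gene_table,
    group_compare,
    holm_bonferroni,
    hypergeom_test,
    jeffreys_interval,
    odds_ratio_ci,
    ppm_to_molar,
)
from assembly_buffer.errors import ParameterError, ZeroCellError

# ---------------------------------------------------------------- oracles


def hypergeom_pmf(k1, n1, k2, n2):
    """P of exactly k1 successes in group 1 given all margins fixed."""
    K = k1 + k2
    return (
        math.comb(n1, k1) * math.comb(n2, K - k1) / math.comb(n1 + n2, K)
    )


def hypergeom_tail_oracle(k1, n1, k2, n2):
    """One-sided tail in the observed direction by pmf summation."""
    K = k1 + k2
    lo, hi = max(0, K - n2), min(n1, K)
    if k1 / n1 <= k2 / n2:
        ks = range(lo, k1 + 1)
    else:
        ks = range(k1, hi + 1)
    return sum(hypergeom_pmf(k, n1, K - k, n2) for k in ks)


def fisher_two_sided_oracle(a, b, c, d):
    """Two-sided Fisher P: sum of all fixed-margin tables no more probable."""
    n1, n2, K = a + b, c + d, a + c
    lo, hi = max(0, K - n2), min(n1, K)
    p_obs = hypergeom_pmf(a, n1, K - a, n2)
    total = 0.0
    for k in range(lo, hi + 1):
        p = hypergeom_pmf(k, n1, K - k, n2)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return total


def beta_quantile_bisect(q, alpha, beta, tol=1e-12):
    """Quantile of Beta(alpha, beta) by bisection on the regularized
    incomplete beta function."""
    from scipy.special import betainc

    lo, hi = 0.0, 1.0
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if betainc(alpha, beta, mid) < q:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


# ----------------------------------------------------------- hypergeom


def test_hypergeom_single_most_extreme_table():
    # 0/5 vs 5/5: only one table is as extreme, P = 1/C(10,5)
    assert hypergeom_test(0, 5, 5, 5) == pytest.approx(1 / 252, rel=1e-12)


def test_hypergeom_identical_groups_p_one():
    assert hypergeom_test(3, 10, 3, 10) == pytest.approx(
        hypergeom_tail_oracle(3, 10, 3, 10), rel=1e-12
    )
    # the whole lower tail including the observed table sums to ~1-ish mass
    assert hypergeom_test(5, 10, 5, 10) > 0.5


def test_hypergeom_depletion_example():
    assert hypergeom_test(2, 10, 8, 10) == pytest.approx(
        hypergeom_tail_oracle(2, 10, 8, 10), rel=1e-12
    )


@pytest.mark.parametrize("n1,n2", [(5, 5), (8, 12), (12, 12)])
def test_hypergeom_matches_enumeration_full_sweep(n1, n2):
    for k1 in range(n1 + 1):
        for k2 in range(n2 + 1):
            assert hypergeom_test(k1, n1, k2, n2) == pytest.approx(
                hypergeom_tail_oracle(k1, n1, k2, n2), rel=1e-10
            )


def test_hypergeom_validates_counts():
    with pytest.raises(ParameterError):
        hypergeom_test(1, 0, 1, 5)
    with pytest.raises(ParameterError):
        hypergeom_test(6, 5, 1, 5)


# ----------------------------------------------------------- odds ratio


def test_odds_ratio_from_reported_proportions():
    orr, lo, hi = odds_ratio_ci(p1=0.240, p2=0.356)
    assert round(orr, 2) == 0.57
    assert math.isnan(lo) and math.isnan(hi)


def test_odds_ratio_identity_and_cross_product():
    assert odds_ratio_ci(p1=0.3, p2=0.3)[0] == pytest.approx(1.0)
    orr, lo, hi = odds_ratio_ci(2, 10, 8, 10)
    assert orr == pytest.approx((2 * 2) / (8 * 8))
    assert lo < orr < hi


def test_odds_ratio_reciprocal_property():
    a = odds_ratio_ci(p1=0.24, p2=0.356)[0]
    b = odds_ratio_ci(p1=0.356, p2=0.24)[0]
    assert a * b == pytest.approx(1.0, rel=1e-12)


def test_odds_ratio_zero_cell_raises():
    with pytest.raises(ZeroCellError):
        odds_ratio_ci(0, 10, 5, 10)


def test_odds_ratio_ci_matches_se_formula():
    a, b, c, d = 24, 76, 36, 64
    orr, lo, hi = odds_ratio_ci(a, a + b, c, c + d)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = 1.959963984540054
    assert lo == pytest.approx(orr * math.exp(-z * se), rel=1e-9)
    assert hi == pytest.approx(orr * math.exp(z * se), rel=1e-9)


# ------------------------------------------------------------- jeffreys


@pytest.mark.parametrize("k,n", [(0, 10), (5, 10), (24, 100), (99, 100)])
def test_jeffreys_matches_bisection_oracle(k, n):
    lo, hi = jeffreys_interval(k, n, level=0.68)
    assert lo == pytest.approx(beta_quantile_bisect(0.16, k + 0.5, n - k + 0.5), abs=1e-9)
    assert hi == pytest.approx(beta_quantile_bisect(0.84, k + 0.5, n - k + 0.5), abs=1e-9)


def test_jeffreys_symmetry_and_boundaries():
    lo, hi = jeffreys_interval(5, 10)
    assert lo + hi == pytest.approx(1.0, abs=1e-9)  # Beta symmetry at k=n-k
    lo0, hi0 = jeffreys_interval(0, 10)
    assert 0 <= lo0 < 0.01 and hi0 < 1


def test_jeffreys_contains_point_estimate_and_shrinks():
    lo, hi = jeffreys_interval(24, 100)
    assert lo < 0.24 < hi
    lo2, hi2 = jeffreys_interval(240, 1000)
    assert (hi2 - lo2) < (hi - lo)


# --------------------------------------------------------------- fisher


def test_fisher_diagonal_table():
    _, p = fisher_exact(5, 0, 0, 5)
    assert p == pytest.approx(2 / 252, rel=1e-9)


def test_fisher_balanced_table():
    _, p = fisher_exact(3, 3, 3, 3)
    assert p == pytest.approx(1.0)


@pytest.mark.parametrize(
    "table",
    [(2, 8, 8, 2), (1, 9, 5, 5), (0, 12, 6, 6), (7, 3, 2, 8), (4, 4, 4, 4)],
)
def test_fisher_matches_enumeration(table):
    a, b, c, d = table
    _, p = fisher_exact(a, b, c, d)
    assert p == pytest.approx(fisher_two_sided_oracle(a, b, c, d), rel=1e-9)


# ----------------------------------------------------------------- holm


def test_holm_hand_stepped_example():
    adj = holm_bonferroni([0.01, 0.04, 0.03])
    assert np.allclose(adj, [0.03, 0.06, 0.06])


def test_holm_single_and_ties():
    assert holm_bonferroni([0.2])[0] == pytest.approx(0.2)
    assert np.allclose(holm_bonferroni([0.3, 0.3, 0.3]), [0.9, 0.9, 0.9])
    assert np.all(holm_bonferroni([0.5, 0.5, 0.5, 0.5]) <= 1.0)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=8))
def test_holm_dominates_raw_pvalues(ps):
    adj = holm_bonferroni(ps)
    assert np.all(adj >= np.asarray(ps) - 1e-12)
    assert np.all(adj <= 1.0 + 1e-12)
    order = np.argsort(ps)
    assert np.all(np.diff(adj[order]) >= -1e-12)


def test_holm_rejects_out_of_range():
    with pytest.raises(ParameterError):
        holm_bonferroni([0.5, 1.5])


# -------------------------------------------------------- group compare


def test_group_compare_recovers_generated_odds_ratio():
    table = gen_gene_table(
        {"AD": 20000, "AR": 20000}, {"AD": 0.240, "AR": 0.356}, seed=2
    )
    res = group_compare(
        table.records,
        lambda r: r.inheritance == "AD",
        lambda r: r.inheritance == "AR",
    )
    se = math.sqrt(1 / res.k1 + 1 / (res.n1 - res.k1) + 1 / res.k2 + 1 / (res.n2 - res.k2))
    assert abs(math.log(res.odds_ratio) - math.log(0.57)) < 3 * se
    assert res.p_value < 1e-100  # massive depletion at n=20000 per class


def test_group_compare_null_is_or_one():
    table = gen_gene_table({"AD": 5000, "AR": 5000}, {"AD": 0.3, "AR": 0.3}, seed=5)
    res = group_compare(
        table.records,
        lambda r: r.inheritance == "AD",
        lambda r: r.inheritance == "AR",
    )
    assert 0.85 < res.odds_ratio < 1.18


def test_group_compare_empty_stratum_warns_and_skips():
    table = gen_gene_table({"AD": 10}, {"AD": 0.5}, seed=1)
    with pytest.warns(UserWarning):
        res = group_compare(
            table.records,
            lambda r: r.inheritance == "AD",
            lambda r: r.inheritance == "AR",
        )
    assert res is None


def test_group_compare_zero_cell_propagates():
    table = gen_gene_table({"AD": 20, "AR": 20}, {"AD": 0.0, "AR": 1.0}, seed=1)
    with pytest.raises(ZeroCellError):
        group_compare(
            table.records,
            lambda r: r.inheritance == "AD",
            lambda r: r.inheritance == "AR",
        )


# ------------------------------------------------------------ quartiles


def _records_with_abundance(values):
    return [
        GeneRecord(gene_id=f"g{i:05d}", abundance_ppm=v) for i, v in enumerate(values)
    ]


def test_quartiles_equal_count_split():
    recs = _records_with_abundance([8, 7, 6, 5, 4, 3, 2, 1])
    q = abundance_quartiles(recs)
    sizes = [sum(1 for v in q.values() if v == b) for b in (1, 2, 3, 4)]
    assert sizes == [2, 2, 2, 2]
    assert q["g00007"] == 1 and q["g00000"] == 4  # lowest abundance in bin 1


def test_quartiles_all_ties_stable_order():
    recs = _records_with_abundance([5.0] * 8)
    q = abundance_quartiles(recs)
    assert [q[f"g{i:05d}"] for i in range(8)] == [1, 1, 2, 2, 3, 3, 4, 4]


def test_quartile_bin_sizes_differ_by_at_most_one():
    rng = np.random.default_rng(0)
    recs = _records_with_abundance(rng.lognormal(size=101))
    q = abundance_quartiles(recs)
    sizes = [sum(1 for v in q.values() if v == b) for b in (1, 2, 3, 4)]
    assert max(sizes) - min(sizes) <= 1


def test_quartiles_require_four_records():
    with pytest.raises(ParameterError):
        abundance_quartiles(_records_with_abundance([1, 2, 3]))


# ---------------------------------------------------------- ppm to molar


def test_ppm_conversion_linear_and_order_preserving():
    assert ppm_to_molar(0.0) == 0.0
    assert ppm_to_molar(10.0) == pytest.approx(2 * ppm_to_molar(5.0))
    ppm = np.array([3.0, 1.0, 2.0])
    nm = ppm_to_molar(ppm)
    assert np.array_equal(np.argsort(ppm), np.argsort(nm))
    with pytest.raises(ParameterError):
        ppm_to_molar(-1.0)


# ------------------------------------------------------------- bootstrap


def test_bootstrap_zero_variance_stratum():
    obs = [("DN", 0.55)] * 20  # every shift exactly +6% vs basemean 0.49
    res = bootstrap_shift(obs, basemean=0.49, B=1000, seed=0)["DN"]
    assert res.point_shift == pytest.approx(6.0)
    assert res.ci_low == pytest.approx(6.0) and res.ci_high == pytest.approx(6.0)
    assert res.p_boot == pytest.approx(1 / 1001)


def test_bootstrap_symmetric_null_p_near_half():
    rng = np.random.default_rng(3)
    ps = []
    for _ in range(10):
        shifts = rng.normal(0.0, 0.05, size=400)
        obs = [("S", 0.5 + s) for s in shifts]
        ps.append(bootstrap_shift(obs, basemean=0.5, B=500, seed=1)["S"].p_boot)
    assert 0.2 < float(np.median(ps)) < 0.8


def test_bootstrap_ci_orders_and_b_minimum():
    rng = np.random.default_rng(5)
    obs = [("S", 0.5 + s) for s in rng.normal(0.06, 0.2, size=50)]
    res = bootstrap_shift(obs, basemean=0.5, B=2000, seed=2)["S"]
    assert res.ci_low <= res.point_shift <= res.ci_high
    assert 1 / (res.B + 1) <= res.p_boot <= 1
    with pytest.raises(ParameterError):
        bootstrap_shift(obs, basemean=0.5, B=10)


def test_bootstrap_per_stratum_basemean_mapping():
    obs = [("A", 0.6), ("A", 0.6), ("B", 0.5), ("B", 0.5)]
    res = bootstrap_shift(obs, basemean={"A": 0.5, "B": 0.5}, B=200, seed=0)
    assert res["A"].point_shift == pytest.approx(10.0)
    assert res["B"].point_shift == pytest.approx(0.0)
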