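"""Unit and property tests for the rank statistics.

The Mann-Whitney implementation is checked against an independent
pair-counting + permutation oracle and against scipy; Spearman against
the explicit rank-covariance formula and scipy; chi-square against the
hand formula and its symmetry invariances.
"""

import itertools
import math

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from mirovary import chi_square_2x2, mann_whitney_u, spearman_rho
from mirovary.stats import age_expression_report


# --- independent oracle: U by pair counting, p by exhaustive enumeration ---

def oracle_u(x, y):
    u1 = sum((xi > yj) + 0.5 * (xi == yj) for xi in x for yj in y)
    return min(u1, len(x) * len(y) - u1)


def oracle_exact_p(x, y):
    pooled = list(x) + list(y)
    n1 = len(x)
    u_obs = oracle_u(x, y)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        gx = [pooled[i] for i in idx]
        gy = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        hits += oracle_u(gx, gy) <= u_obs + 1e-9
    return hits / total


values = st.lists(st.integers(0, 8), min_size=1, max_size=5)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(values, values)
def test_mwu_matches_exhaustive_enumeration(x, y):
    """For n1+n2 <= 10 the U statistic and exact p equal the brute-force
    permutation oracle, ties included."""
    res = mann_whitney_u(x, y)
    assert res.u_statistic == pytest.approx(oracle_u(x, y))
    assert res.exact
    assert res.p_two_tailed == pytest.approx(oracle_exact_p(x, y))
    assert 0 <= res.u_statistic <= len(x) * len(y) / 2


def test_mwu_complete_separation_and_symmetry():
    assert mann_whitney_u([1, 2, 3], [4, 5, 6]).u_statistic == 0
    res = mann_whitney_u([1, 2, 3], [1, 2, 3])
    assert res.u_statistic == pytest.approx(9 / 2)
    ident = mann_whitney_u([5, 5, 5], [5, 5, 5])
    assert ident.p_two_tailed == 1.0


def test_mwu_small_example_against_oracle():
    res = mann_whitney_u([1, 2, 4], [3, 5])
    assert res.u_statistic == pytest.approx(1.0)
    assert res.p_two_tailed == pytest.approx(oracle_exact_p([1, 2, 4], [3, 5]))


def test_mwu_normal_approximation_matches_scipy():
    rng = np.random.default_rng(42)
    for _ in range(20):
        x = rng.integers(0, 40, size=rng.integers(8, 30)).tolist()
        y = rng.integers(0, 40, size=rng.integers(8, 30)).tolist()
        res = mann_whitney_u(x, y)
        ref = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert res.u_statistic == pytest.approx(min(ref.statistic, len(x) * len(y) - ref.statistic))
        assert res.p_two_tailed == pytest.approx(ref.pvalue, rel=1e-6)


def test_spearman_perfect_and_reversed():
    assert spearman_rho([1, 2, 3, 4], [10, 20, 30, 40]).rho == pytest.approx(1.0)
    assert spearman_rho([1, 2, 3, 4], [4, 3, 2, 1]).rho == pytest.approx(-1.0)


def test_spearman_tied_example_matches_rank_formula_and_scipy():
    x = [1, 2, 2, 4, 5, 6]
    y = [3, 3, 5, 1, 6, 6]
    res = spearman_rho(x, y)
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    manual = float(
        np.sum((rx - rx.mean()) * (ry - ry.mean()))
        / math.sqrt(np.sum((rx - rx.mean()) ** 2) * np.sum((ry - ry.mean()) ** 2))
    )
    assert res.rho == pytest.approx(manual)
    ref = scipy.stats.spearmanr(x, y)
    assert res.rho == pytest.approx(ref.statistic)
    assert res.p_two_tailed == pytest.approx(ref.pvalue, rel=1e-6)


def test_spearman_constant_input_flagged_undefined():
    res = spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])
    assert not res.defined
    assert not math.isnan(res.rho)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.integers(-100, 100), min_size=4, max_size=20, unique=True))
def test_spearman_invariant_under_monotone_transform(x):
    """rho depends only on ranks: exp-transforming one input changes nothing,
    flipping the age coding negates rho exactly."""
    y = [v * 2 - 3 for v in x[::-1]]
    base = spearman_rho(x, y)
    transformed = spearman_rho([math.exp(v / 10) for v in x], y)
    assert transformed.rho == pytest.approx(base.rho)
    flipped = spearman_rho([-v for v in x], y)
    assert flipped.rho == pytest.approx(-base.rho)


def test_chi_square_identical_proportions_is_zero():
    res = chi_square_2x2([[10, 30], [20, 60]])
    assert res.chi_square == pytest.approx(0.0)
    assert res.p == pytest.approx(1.0)


def test_chi_square_hand_computed_and_swap_invariance():
    table = [[10, 10], [20, 0]]
    obs = np.array(table, float)
    expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
    manual = ((obs - expected) ** 2 / expected).sum()
    res = chi_square_2x2(table)
    assert res.chi_square == pytest.approx(manual)
    for variant in ([[20, 0], [10, 10]], [[10, 10], [0, 20]][::-1]):
        assert chi_square_2x2(variant).chi_square == pytest.approx(manual)
    with pytest.raises(ValueError):
        chi_square_2x2([[0, 0], [5, 5]])


def test_age_expression_report_flags_empty_group():
    expr = {"s1": {"g1": 5.0, "g2": 7.0}}
    ann = {"g1": "conserved", "g2": "conserved"}
    rep = age_expression_report(expr, ann)
    assert rep.not_computable == ["s1"]


def test_age_expression_report_runs_both_tests():
    rng = np.random.default_rng(0)
    genes = {f"g{i}": float(v) for i, v in enumerate(rng.lognormal(0, 1, 30))}
    ann = {g: ("conserved" if i % 2 else "lineage_specific") for i, g in enumerate(genes)}
    rep = age_expression_report({"s": genes}, ann, subset=list(genes)[:10], reference_genes=list(genes))
    assert "s" in rep.mwu and "s" in rep.spearman
    assert rep.composition is not None
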