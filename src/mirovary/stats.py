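"""Nonparametric statistics for the age--expression analysis.

Self-contained implementations of the three tests used to relate miRNA
evolutionary age to expression level:

* a two-tailed Mann-Whitney U test (conserved vs lineage-specific read
  counts), reported in the smaller-U convention with tie-corrected normal
  approximation and exact permutation enumeration at small sample sizes;
* Spearman's rank correlation (age indicator vs read count), tie-safe via
  Pearson correlation of average ranks, p from the t approximation;
* a 2x2 chi-square test of age-class composition between a gene subset
  (e.g. ovary-expressed) and a reference set, without continuity correction.

scipy is used only for distribution functions and ranking; the statistics
themselves are computed here.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import chi2 as _chi2_dist
from scipy.stats import norm as _norm_dist
from scipy.stats import rankdata
from scipy.stats import t as _t_dist

#: conserved genes are coded 1, lineage-specific 0, in every age indicator.
AGE_CODING = {"conserved": 1, "lineage_specific": 0}

#: below this combined sample size the Mann-Whitney p-value is computed by
#: exhaustive enumeration of group assignments instead of the normal
#: approximation.
EXACT_ENUMERATION_LIMIT = 12


@dataclass(frozen=True)
class RankTestResult:
    """Mann-Whitney U test result (smaller-U convention)."""

    u_statistic: float
    n1: int
    n2: int
    z: float
    p_two_tailed: float
    exact: bool = False


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman rank correlation. ``defined`` is False when either input
    has zero rank variance (rho is then meaningless, not NaN-propagated)."""

    rho: float
    n: int
    p_two_tailed: float
    defined: bool = True


@dataclass(frozen=True)
class ProportionTestResult:
    """2x2 chi-square test of proportions, df = 1."""

    chi_square: float
    counts: tuple = ()
    p: float = 1.0


def _u_from_ranks(ranks: np.ndarray, idx1: Sequence[int], n1: int, n2: int) -> float:
    r1 = float(ranks[list(idx1)].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    return min(u1, n1 * n2 - u1)


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> RankTestResult:
    """Two-tailed Mann-Whitney U test.

    Ties receive average ranks. The reported U is min(U1, U2), so
    0 <= U <= n1*n2/2. For n1 + n2 <= EXACT_ENUMERATION_LIMIT the p-value
    is the exact permutation probability P(min-U <= observed) over all
    C(n1+n2, n1) group assignments of the pooled values; otherwise a
    normal approximation with tie-corrected variance and a 0.5 continuity
    correction is used.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("mann_whitney_u requires at least one value per group")
    pooled = np.concatenate([x, y])
    n = n1 + n2
    ranks = rankdata(pooled, method="average")
    u = _u_from_ranks(ranks, range(n1), n1, n2)

    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var = (n1 * n2 / 12.0) * ((n + 1) - tie_term / (n * (n - 1)))

    if n <= EXACT_ENUMERATION_LIMIT:
        total = 0
        at_most = 0
        for idx in itertools.combinations(range(n), n1):
            total += 1
            if _u_from_ranks(ranks, idx, n1, n2) <= u + 1e-9:
                at_most += 1
        return RankTestResult(u, n1, n2, float("nan"), at_most / total, exact=True)

    if var <= 0:  # all pooled values identical
        return RankTestResult(u, n1, n2, 0.0, 1.0, exact=False)

    z = (u - mu + 0.5) / math.sqrt(var)
    p = min(1.0, 2.0 * float(_norm_dist.cdf(z)))
    return RankTestResult(u, n1, n2, z, p, exact=False)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman's rank correlation with average ranks for ties.

    rho is the Pearson correlation of the rank vectors; the two-tailed
    p-value uses the t approximation with n - 2 degrees of freedom. When
    either vector is constant in rank the result is flagged undefined.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) != len(y):
        raise ValueError("spearman_rho requires paired vectors of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("spearman_rho requires at least 3 pairs")
    rx = rankdata(x, method="average")
    ry = rankdata(y, method="average")
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return CorrelationResult(0.0, n, 1.0, defined=False)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) == 1.0:
        p = 0.0
    else:
        t_stat = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = 2.0 * float(_t_dist.sf(abs(t_stat), n - 2))
    return CorrelationResult(rho, n, min(1.0, p))


def chi_square_2x2(table: Sequence[Sequence[float]]) -> ProportionTestResult:
    """Pearson chi-square on a 2x2 count table, df = 1, no continuity
    correction. Raises on any zero marginal (expected counts undefined)."""
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("chi_square_2x2 expects a 2x2 table")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("chi_square_2x2 requires all marginals > 0")
    expected = np.outer(row, col) / obs.sum()
    stat = float(((obs - expected) ** 2 / expected).sum())
    p = float(_chi2_dist.sf(stat, 1))
    return ProportionTestResult(stat, tuple(map(tuple, obs.tolist())), p)


@dataclass
class AgeExpressionReport:
    """Per-sample rank tests plus a composition comparison."""

    mwu: dict = field(default_factory=dict)
    spearman: dict = field(default_factory=dict)
    composition: ProportionTestResult | None = None
    not_computable: list = field(default_factory=list)


def age_expression_report(
    expression: Mapping[str, Mapping[str, float]],
    annotations: Mapping[str, str],
    subset: Sequence[str] | None = None,
    reference_genes: Sequence[str] | None = None,
) -> AgeExpressionReport:
    """Run the age--expression analysis over one or more samples.

    Parameters
    ----------
    expression
        sample_id -> {gene_id -> total read count}. Every gene must be
        annotated.
    annotations
        gene_id -> "conserved" | "lineage_specific".
    subset, reference_genes
        Optional gene sets whose conserved/lineage-specific composition is
        compared by chi-square (e.g. ovary-expressed genes vs the full
        catalogue). Skipped when either is None.
    """
    report = AgeExpressionReport()
    for sample_id, counts in expression.items():
        missing = [g for g in counts if g not in annotations]
        if missing:
            raise KeyError(f"unannotated genes in sample {sample_id}: {missing[:3]}")
        cons = [v for g, v in counts.items() if annotations[g] == "conserved"]
        lin = [v for g, v in counts.items() if annotations[g] == "lineage_specific"]
        if not cons or not lin:
            report.not_computable.append(sample_id)
            continue
        report.mwu[sample_id] = mann_whitney_u(cons, lin)
        ages = [AGE_CODING[annotations[g]] for g in counts]
        report.spearman[sample_id] = spearman_rho(ages, list(counts.values()))
    if subset is not None and reference_genes is not None:
        report.composition = chi_square_2x2(
            [_age_counts(subset, annotations), _age_counts(reference_genes, annotations)]
        )
    return report


def _age_counts(genes: Sequence[str], annotations: Mapping[str, str]) -> list:
    cons = sum(1 for g in genes if annotations[g] == "conserved")
    return [cons, len(genes) - cons]
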