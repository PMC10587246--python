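"""Nonparametric group comparisons and inter-grader agreement.

Kruskal-Wallis H with the standard tie correction, Dunn's pairwise
z-procedure with Bonferroni adjustment, unweighted Cohen's kappa, and the
cohort-share arithmetic used for severity-level percentages.  The H and z
statistics are computed directly from mid-ranks so the tie handling is
explicit; p-values use the usual chi-square / normal approximations.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class KWResult:
    H: float
    df: int
    p: float
    group_ns: tuple[int, ...]


@dataclass
class DunnResult:
    """Pairwise Dunn z statistics and Bonferroni-adjusted p values.

    ``z``, ``p_raw`` and ``p_adjusted`` are symmetric k x k DataFrames
    indexed by group label; diagonals are NaN.
    """

    z: pd.DataFrame
    p_raw: pd.DataFrame
    p_adjusted: pd.DataFrame


@dataclass
class KappaResult:
    kappa: float
    observed_agreement: float
    expected_agreement: float


def _ranks_and_ties(groups: list[np.ndarray]) -> tuple[list[np.ndarray], float, int]:
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    out, start = [], 0
    for g in groups:
        out.append(ranks[start : start + len(g)])
        start += len(g)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(tie_counts**3 - tie_counts))
    return out, tie_sum, len(pooled)


def _check_groups(groups) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in gs):
        raise ValueError("all groups must be non-empty")
    return gs


def kruskal_wallis(groups) -> KWResult:
    """Kruskal-Wallis H on mid-ranks with tie correction, chi-square p.

    When every pooled observation is identical there is no rank variation;
    H = 0 and p = 1 by convention.
    """
    gs = _check_groups(groups)
    rank_groups, tie_sum, n = _ranks_and_ties(gs)
    k = len(gs)
    correction = 1.0 - tie_sum / (n**3 - n) if n > 1 else 1.0
    if correction == 0.0:  # all values identical
        return KWResult(H=0.0, df=k - 1, p=1.0, group_ns=tuple(len(g) for g in gs))
    h = 12.0 / (n * (n + 1)) * sum(
        len(r) * (r.mean() - (n + 1) / 2.0) ** 2 for r in rank_groups
    )
    h /= correction
    p = float(sps.chi2.sf(h, k - 1))
    return KWResult(H=float(h), df=k - 1, p=p, group_ns=tuple(len(g) for g in gs))


def dunn_bonferroni(groups, labels=None) -> DunnResult:
    """Dunn's pairwise mean-rank z tests with Bonferroni correction.

    The tie-corrected rank variance is N(N+1)/12 - T/(12(N-1)) with
    T = sum(t^3 - t) over tie groups; the adjusted p is the raw two-sided
    normal p times k(k-1)/2, capped at 1.
    """
    gs = _check_groups(groups)
    k = len(gs)
    if labels is None:
        labels = list(range(k))
    rank_groups, tie_sum, n = _ranks_and_ties(gs)
    mean_ranks = [r.mean() for r in rank_groups]
    var_term = n * (n + 1) / 12.0 - tie_sum / (12.0 * (n - 1)) if n > 1 else 0.0
    m = k * (k - 1) // 2
    z = np.full((k, k), np.nan)
    p_raw = np.full((k, k), np.nan)
    p_adj = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(var_term * (1.0 / len(gs[i]) + 1.0 / len(gs[j])))
            zij = 0.0 if se == 0.0 else (mean_ranks[i] - mean_ranks[j]) / se
            pij = float(2.0 * sps.norm.sf(abs(zij)))
            z[i, j] = z[j, i] = zij if i < j else -zij
            z[j, i] = -z[i, j]
            p_raw[i, j] = p_raw[j, i] = pij
            p_adj[i, j] = p_adj[j, i] = min(1.0, pij * m)
    idx = pd.Index(labels)
    return DunnResult(
        z=pd.DataFrame(z, index=idx, columns=idx),
        p_raw=pd.DataFrame(p_raw, index=idx, columns=idx),
        p_adjusted=pd.DataFrame(p_adj, index=idx, columns=idx),
    )


def cohen_kappa(labels_a, labels_b) -> KappaResult:
    """Unweighted Cohen's kappa from the k x k contingency table."""
    la, lb = list(labels_a), list(labels_b)
    if len(la) != len(lb) or len(la) == 0:
        raise ValueError("label lists must have equal, nonzero length")
    cats = sorted(set(la) | set(lb), key=str)
    index = {c: i for i, c in enumerate(cats)}
    table = np.zeros((len(cats), len(cats)))
    for a, b in zip(la, lb):
        table[index[a], index[b]] += 1
    return kappa_from_table(table)


def kappa_from_table(table: np.ndarray) -> KappaResult:
    """Kappa from a contingency table of rater A (rows) vs rater B (cols)."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    if n == 0:
        raise ValueError("empty contingency table")
    po = float(np.trace(table) / n)
    pe = float((table.sum(axis=1) / n) @ (table.sum(axis=0) / n))
    if pe >= 1.0:
        raise ValueError("degenerate marginals: expected agreement is 1, kappa undefined")
    return KappaResult(
        kappa=(po - pe) / (1.0 - pe), observed_agreement=po, expected_agreement=pe
    )


def cohort_shares(level_counts) -> list[float]:
    """Per-level percentages of the cohort, rounded half-up to one decimal."""
    counts = [int(c) for c in level_counts]
    if any(c < 0 for c in counts):
        raise ValueError("counts must be nonnegative")
    total = sum(counts)
    if total == 0:
        raise ValueError("total count is zero")
    shares = []
    for c in counts:
        pct = Decimal(100 * c) / Decimal(total)
        shares.append(float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)))
    return shares
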