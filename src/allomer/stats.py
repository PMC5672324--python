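"""Rank-based test utilities used by the factor screen.

Thin, validated fronts over SciPy's tie-corrected Kruskal–Wallis H test and
the two-sided Mann–Whitney rank-sum test (exact null distribution for small
untied samples, normal approximation with tie and continuity correction
otherwise), plus a compact-letter-display pass for reporting pairwise
significance groupings.
"""

from __future__ import annotations

from typing import Mapping, Sequence, Tuple

import numpy as np
from scipy import stats as sps


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> Tuple[float, float]:
    """Kruskal–Wallis H (tie-corrected) and its chi-square p value.

    Requires at least two non-empty groups and a total of at least three
    observations. When every value across all groups is identical the test
    degenerates to H = 0, p = 1 (no evidence of any group difference).
    """
    if len(groups) < 2:
        raise ValueError("kruskal_wallis needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("kruskal_wallis: empty group")
    pooled = np.concatenate(arrays)
    if pooled.size < 3:
        raise ValueError("kruskal_wallis needs a total of at least 3 values")
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


def rank_sum_test(sample_a: Sequence[float], sample_b: Sequence[float]) -> float:
    """Two-sided Mann–Whitney rank-sum p value for two independent samples.

    Uses the exact permutation null distribution when the combined size is
    at most 20 and there are no ties, otherwise the normal approximation
    with tie correction and continuity correction.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("rank_sum_test: empty sample")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= 20 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(min(res.pvalue, 1.0))


def compact_letter_display(
    levels: Sequence[str],
    pairwise_p: Mapping[Tuple[str, str], float],
    alpha: float = 0.05,
) -> dict[str, str]:
    """Assign significance letters: levels sharing a letter do not differ.

    Standard insert-and-absorb construction: start from one set holding all
    levels, split it at every significantly different pair, drop sets that
    became subsets of another, then letter the surviving sets in order of
    their first level.
    """
    levels = list(levels)

    def p_of(x: str, y: str) -> float:
        return pairwise_p.get((x, y), pairwise_p.get((y, x), 1.0))

    sets: list[set[str]] = [set(levels)]
    for i, x in enumerate(levels):
        for y in levels[i + 1:]:
            if p_of(x, y) < alpha:
                new_sets: list[set[str]] = []
                for s in sets:
                    if x in s and y in s:
                        new_sets.append(s - {x})
                        new_sets.append(s - {y})
                    else:
                        new_sets.append(s)
                # absorb: drop empty sets and subsets of other sets
                sets = []
                for s in new_sets:
                    if s and not any(s < t or (s == t and t in sets) for t in new_sets if t is not s):
                        if s not in sets:
                            sets.append(s)
    order = {lvl: k for k, lvl in enumerate(levels)}
    sets.sort(key=lambda s: min(order[l] for l in s))
    letters = {lvl: "" for lvl in levels}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for letter, s in zip(alphabet, sets):
        for lvl in levels:
            if lvl in s:
                letters[lvl] += letter
    return letters
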