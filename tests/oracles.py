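"""Independent brute-force oracles for the phylogenetic and rank statistics.

These deliberately avoid the package's edge-index machinery: each branch of
the tree is enumerated with its full descendant tip set, and the metric
definitions are applied literally. ANOSIM ranks are computed with explicit
double loops and the exact permutation p-value enumerates every labelling.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def branch_table(sktree):
    """List of (branch_length, frozenset of descendant tip names) over all
    non-root nodes of a skbio TreeNode."""
    out = []
    for node in sktree.traverse(include_self=False):
        tips = frozenset(t.name for t in node.tips()) or frozenset([node.name])
        out.append((float(node.length or 0.0), tips))
    return out


def brute_faith_pd(sktree, present: set[str]) -> float:
    if not present:
        return 0.0
    return sum(b for b, tips in branch_table(sktree) if tips & present)


def brute_unifrac(sktree, counts1: dict[str, float], counts2: dict[str, float],
                  weighted: bool, normalized: bool = True) -> float:
    t1 = sum(counts1.values())
    t2 = sum(counts2.values())
    branches = branch_table(sktree)
    if weighted:
        num = 0.0
        den = 0.0
        for b, tips in branches:
            p1 = sum(counts1.get(t, 0.0) for t in tips) / t1
            p2 = sum(counts2.get(t, 0.0) for t in tips) / t2
            num += b * abs(p1 - p2)
            den += b * (p1 + p2)
        if not normalized:
            return num
        return num / den if den > 0 else 0.0
    present1 = {t for t, c in counts1.items() if c > 0}
    present2 = {t for t, c in counts2.items() if c > 0}
    unique = 0.0
    union = 0.0
    for b, tips in branches:
        in1 = bool(tips & present1)
        in2 = bool(tips & present2)
        if in1 or in2:
            union += b
        if in1 != in2:
            unique += b
    return unique / union if union > 0 else 0.0


def _avg_ranks(values: list[float]) -> list[float]:
    """Average ranks (1-based) with explicit tie handling, no scipy."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def brute_anosim_r(d: np.ndarray, labels: list) -> float:
    n = len(labels)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    ranks = _avg_ranks([float(d[i, j]) for i, j in pairs])
    within = [labels[i] == labels[j] for i, j in pairs]
    M = len(pairs)
    r_w = sum(r for r, w in zip(ranks, within) if w) / sum(within)
    r_b = sum(r for r, w in zip(ranks, within) if not w) / (M - sum(within))
    return (r_b - r_w) / (M / 2)


def brute_anosim_exact_p(d: np.ndarray, labels: list) -> float:
    """Exact permutation p: fraction of distinct labellings with R >= observed."""
    r_obs = brute_anosim_r(d, labels)
    seen = set()
    n_ge = 0
    for perm in itertools.permutations(labels):
        if perm in seen:
            continue
        seen.add(perm)
        if brute_anosim_r(d, list(perm)) >= r_obs - 1e-12:
            n_ge += 1
    return n_ge / len(seen)
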