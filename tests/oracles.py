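"""Independent brute-force oracles for the semantic-similarity pipeline.

Everything here is recomputed from first principles — recursive parent
walks, direct gene recounts, exhaustive max/mean loops, literal tie-rule
transcriptions — deliberately sharing no code path with the package.
"""

from __future__ import annotations

import math
from fractions import Fraction


def brute_ancestors(parent_map: dict[str, frozenset[str]], term: str) -> set[str]:
    """Proper ancestors by recursive DFS over parent edges."""
    out: set[str] = set()
    for p in parent_map[term]:
        out.add(p)
        out |= brute_ancestors(parent_map, p)
    return out


def brute_propagated(
    parent_map: dict[str, frozenset[str]], direct: dict[str, frozenset[str]]
) -> dict[str, set[str]]:
    """Term -> genes, recounted gene by gene via the true-path rule."""
    out: dict[str, set[str]] = {}
    for gene, terms in direct.items():
        for t in terms:
            for a in brute_ancestors(parent_map, t) | {t}:
                out.setdefault(a, set()).add(gene)
    return out


def brute_ic(
    parent_map: dict[str, frozenset[str]], direct: dict[str, frozenset[str]], term: str
) -> float:
    prop = brute_propagated(parent_map, direct)
    return -math.log(len(prop[term]) / len(direct))


def brute_term_similarity(
    parent_map: dict[str, frozenset[str]],
    direct: dict[str, frozenset[str]],
    p1: str,
    p2: str,
) -> float:
    if p1 == p2:
        return brute_ic(parent_map, direct, p1)
    prop = brute_propagated(parent_map, direct)
    common = brute_ancestors(parent_map, p1) & brute_ancestors(parent_map, p2)
    ics = [
        -math.log(len(prop[a]) / len(direct)) for a in common if a in prop
    ]
    return max(ics, default=0.0)


def brute_asymmetric(
    parent_map, direct, query: list[str], target: list[str]
) -> float:
    total = 0.0
    for q in query:
        total += max(brute_term_similarity(parent_map, direct, q, t) for t in target)
    return total / len(query)


def brute_symmetric(parent_map, direct, P1: list[str], P2: list[str]) -> float:
    return 0.5 * (
        brute_asymmetric(parent_map, direct, P1, P2)
        + brute_asymmetric(parent_map, direct, P2, P1)
    )


def brute_score_ranks(scores: dict[str, float]) -> dict[str, int]:
    """Descending-score ranks; equal scores take floor(mean positions)."""
    ordered = sorted(scores, key=lambda g: (-scores[g], g))
    positions = {g: i + 1 for i, g in enumerate(ordered)}
    ranks: dict[str, int] = {}
    for g in scores:
        block = [positions[h] for h in scores if scores[h] == scores[g]]
        ranks[g] = int(Fraction(sum(block), len(block)))  # Fraction -> floor via int()
    return ranks


def brute_pvalue_ranks(
    pvalues: dict[str, float], scores: dict[str, float]
) -> dict[str, int]:
    """Ascending-p ranks; p ties ordered by descending score (rank i-1+s_r);
    residual equal-(p, score) runs take floor(mean positions)."""
    ordered = sorted(pvalues, key=lambda g: (pvalues[g], -scores[g], g))
    ranks: dict[str, int] = {}
    i = 0
    while i < len(ordered):
        j = i
        while j < len(ordered) and pvalues[ordered[j]] == pvalues[ordered[i]]:
            j += 1
        block = ordered[i:j]  # one p-value tie block at positions i+1 .. j
        by_score = sorted(block, key=lambda g: (-scores[g], g))
        for s_r, g in enumerate(by_score, start=1):
            ranks[g] = (i + 1) - 1 + s_r
        # residual ties: same p and same score -> floored mean of positions
        for g in block:
            same = [h for h in block if scores[h] == scores[g]]
            if len(same) > 1:
                pos = [ranks_pos for h, ranks_pos in ((h, ranks[h]) for h in same)]
                floored = int(Fraction(sum(pos), len(pos)))
                for h in same:
                    ranks[h] = floored
        i = j
    return ranks
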