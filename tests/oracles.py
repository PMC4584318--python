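"""Independent brute-force oracles used only by the test suite.

Deliberately naive implementations kept separate from the package code
paths they validate: a full Smith-Waterman DP, exhaustive enumeration of
nested RNA structures, and combinatorial hypergeometric tails.
"""

from __future__ import annotations

import math
from itertools import combinations

_PAIRABLE = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def smith_waterman_score(a: str, b: str, match=2, mismatch=-3, gap_open=-5, gap_extend=-2) -> int:
    """Best local alignment score with affine gaps, full O(nm) DP."""
    n, m = len(a), len(b)
    NEG = -(10**9)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (horizontal)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (vertical)
    best = 0
    for i in range(1, n + 1):
        Hi, Hp = H[i], H[i - 1]
        Ei, Fi, Fp = E[i], F[i], F[i - 1]
        ai = a[i - 1]
        for j in range(1, m + 1):
            Ei[j] = max(Ei[j - 1] + gap_extend, Hi[j - 1] + gap_open)
            Fi[j] = max(Fp[j] + gap_extend, Hp[j] + gap_open)
            s = match if ai == b[j - 1] else mismatch
            h = max(0, Hp[j - 1] + s, Ei[j], Fi[j])
            Hi[j] = h
            if h > best:
                best = h
    return best


def _pair_score(x: str, y: str, scores) -> int:
    if (x, y) in _PAIRABLE:
        key = "".join(sorted((x, y)))
        return {"CG": scores["GC"], "AU": scores["AU"], "GU": scores["GU"]}[key]
    return 0


def enumerate_best_structure(seq: str, min_hairpin: int = 3,
                             scores={"GC": 3, "AU": 2, "GU": 1}) -> int:
    """Maximum weighted-pair score over ALL nested structures (exponential)."""
    rna = seq.upper().replace("T", "U")
    n = len(rna)

    from functools import lru_cache

    @lru_cache(maxsize=None)
    def best(positions: tuple[int, ...]) -> int:
        if len(positions) < 2:
            return 0
        i = positions[0]
        # i unpaired
        result = best(positions[1:])
        rest = positions[1:]
        for idx, j in enumerate(rest):
            if j - i - 1 < min_hairpin:
                continue
            ps = _pair_score(rna[i], rna[j], scores)
            if ps == 0:
                continue
            inside = tuple(p for p in rest[:idx])
            outside = tuple(p for p in rest[idx + 1 :])
            result = max(result, ps + best(inside) + best(outside))
        return result

    return best(tuple(range(n)))


def hypergeom_right_tail(k: int, K: int, n: int, N: int):
    """P(X >= k) by direct combinatorial summation with exact fractions."""
    total = math.comb(N, n)
    acc = 0
    for x in range(k, min(K, n) + 1):
        acc += math.comb(K, x) * math.comb(N - K, n - x)
    from fractions import Fraction

    return Fraction(acc, total)


def best_nonoverlapping_subset(hits, max_overlap_frac=0.5):
    """Best-score subset of <=~10 hits under the pairwise-overlap constraint,
    by exhaustive subset enumeration."""
    def compatible(a, b):
        ov = min(a.end, b.end) - max(a.start, b.start)
        return ov <= max_overlap_frac * min(a.length, b.length)

    best_set, best_score = [], -1
    for r in range(len(hits) + 1):
        for subset in combinations(hits, r):
            if all(compatible(a, b) for a, b in combinations(subset, 2)):
                score = sum(h.score for h in subset)
                if score > best_score:
                    best_set, best_score = list(subset), score
    return best_set, best_score
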