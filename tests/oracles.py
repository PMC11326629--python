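"""Independent brute-force oracles used to check the implementation.

These deliberately avoid the production code paths: the alignment oracle
is a plain O(n*m) dynamic program (the production path uses the Myers
bit-vector algorithm via edlib), and the identity oracle derives from it.
"""

from __future__ import annotations

import math


def semiglobal_edit_distance(query: str, target: str) -> int:
    """Unit-cost edit distance of ``query`` against the best-matching infix
    of ``target`` (free leading/trailing gaps on the target), by full DP."""
    m, n = len(query), len(target)
    prev = [0] * (n + 1)  # free prefix gap on target
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        qi = query[i - 1]
        for j in range(1, n + 1):
            cost = 0 if qi == target[j - 1] else 1
            cur[j] = min(prev[j - 1] + cost, prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return min(prev)  # free suffix gap on target


def identity_oracle(a: str, b: str) -> float:
    """Full-coverage identity: shorter aligned end-to-end to the longer,
    (|S| - d) / |S| clamped at zero."""
    s, l = (a, b) if len(a) <= len(b) else (b, a)
    d = semiglobal_edit_distance(s, l)
    return max(0.0, (len(s) - d) / len(s))


def jc_pairwise_match_probability(divergence: float) -> float:
    """Probability that a site agrees between two sequences independently
    derived from a common ancestor under the single-hit substitution model
    (each hit moves to one of the 3 other bases uniformly)."""
    d = divergence
    return (1 - d) ** 2 + (d**2) / 3


def hamming_identity(a: str, b: str) -> float:
    assert len(a) == len(b)
    return sum(x == y for x, y in zip(a, b)) / len(a)


def expected_identity_mc(
    divergence: float, length: int, n_replicates: int, rng
) -> float:
    """Monte-Carlo expectation of Hamming identity between two species'
    genes mutated independently from a shared ancestor; a brute-force
    re-simulation independent of the generator."""
    import numpy as np

    total = 0.0
    for _ in range(n_replicates):
        anc = rng.integers(0, 4, size=length)
        seqs = []
        for _ in range(2):
            hits = rng.random(length) < divergence
            s = anc.copy()
            n = int(hits.sum())
            if n:
                s[hits] = (s[hits] + rng.integers(1, 4, size=n)) % 4
            seqs.append(s)
        total += float((seqs[0] == seqs[1]).mean())
    return total / n_replicates
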