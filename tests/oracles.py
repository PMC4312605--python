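"""Independent reference implementations used only by the tests.

Each oracle recomputes a quantity by a route deliberately different from
the package implementation: plain-float direct summation for the exact
Poisson test, explicit enumeration of all nested structures for the
folder, and enumeration of all single-bulge alignments for the duplex
scorer.
"""

from __future__ import annotations

import math

_PAIR_SCORE = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "T"): 2, ("T", "A"): 2,
    ("G", "T"): 1, ("T", "G"): 1,
}


def ac_pmf(y: int, x: int, f: float) -> float:
    """p(y | x) of the exact Poisson two-library model, plain floats."""
    return math.exp(
        y * math.log(f) + math.lgamma(x + y + 1) - math.lgamma(x + 1)
        - math.lgamma(y + 1) - (x + y + 1) * math.log1p(f))


def ac_test_by_summation(x: int, n1: int, y: int, n2: int) -> float:
    """Two-sided exact Poisson p by term-by-term summation to tolerance."""
    f = n2 / n1
    lower = sum(ac_pmf(t, x, f) for t in range(y + 1))
    upper, t = 0.0, y
    while True:
        term = ac_pmf(t, x, f)
        upper += term
        t += 1
        if t > (x + 1) * f + 10 and term < upper * 1e-18:
            break
    return min(1.0, 2.0 * min(lower, upper))


def enumerate_structures(n: int, min_loop: int = 3):
    """Yield every nested pair set over positions 0..n-1 (loop > min_loop)."""

    def rec(positions: tuple[int, ...]):
        if not positions:
            yield []
            return
        first, rest = positions[0], positions[1:]
        # first unpaired
        for s in rec(rest):
            yield s
        # first paired with any admissible partner
        for k, q in enumerate(rest):
            if q - first <= min_loop:
                continue
            inside = tuple(p for p in rest[:k] if first < p < q)
            outside = tuple(p for p in rest[k + 1:])
            for s_in in rec(inside):
                for s_out in rec(outside):
                    yield [(first, q)] + s_in + s_out

    yield from rec(tuple(range(n)))


def best_fold_by_enumeration(seq: str, min_loop: int = 3) -> int:
    """Maximum weighted pairing score over all nested structures."""
    best = 0
    for pairs in enumerate_structures(len(seq), min_loop):
        score = sum(_PAIR_SCORE.get((seq[i], seq[j]), 0) for i, j in pairs)
        if any((seq[i], seq[j]) not in _PAIR_SCORE for i, j in pairs):
            continue
        best = max(best, score)
    return best


def duplex_penalty(m: str, t: str, position: int, scheme) -> float:
    if (m, t) in {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}:
        base = 0.0
    elif (m, t) in {("G", "T"), ("T", "G")}:
        base = scheme.wobble
    else:
        base = scheme.mismatch
    return base * scheme.multiplier(position)


def best_alignment_by_enumeration(mirna: str, window: str, scheme) -> float:
    """Minimum penalty over all alignments with at most one bulge."""
    m = mirna[:scheme.scoring_length]
    w = window[::-1]
    n, L = len(m), len(w)
    scores = []
    if L == n:
        scores.append(sum(duplex_penalty(m[i], w[i], i + 1, scheme)
                          for i in range(n)))
    if L == n + 1:      # one bulged site base, skipped at slot k
        for k in range(n + 1):
            cost = scheme.gap * scheme.multiplier(min(k + 1, n))
            cost += sum(duplex_penalty(m[i], w[i], i + 1, scheme)
                        for i in range(k))
            cost += sum(duplex_penalty(m[i], w[i + 1], i + 1, scheme)
                        for i in range(k, n))
            scores.append(cost)
    if L == n - 1:      # one bulged miRNA base g
        for g in range(n):
            cost = scheme.gap * scheme.multiplier(g + 1)
            cost += sum(duplex_penalty(m[i], w[i], i + 1, scheme)
                        for i in range(g))
            cost += sum(duplex_penalty(m[i], w[i - 1], i + 1, scheme)
                        for i in range(g + 1, n))
            scores.append(cost)
    if not scores:
        raise ValueError("incompatible lengths")
    return min(scores)
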