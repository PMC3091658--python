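"""Independent brute-force oracles used to freeze expected values.

Everything here is deliberately naive — exhaustive enumeration or exact
rational arithmetic — and shares no code with the implementation it checks.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def windows_below(quals: list[int], window: int, min_mean_q: float) -> list[tuple[int, int]]:
    """Union of all sliding windows with mean quality below threshold."""
    n = len(quals)
    if n == 0:
        return []
    w = min(window, n)
    masked = [False] * n
    for j in range(n - w + 1):
        if sum(quals[j : j + w]) / w < min_mean_q:
            for p in range(j, j + w):
                masked[p] = True
    return _runs(masked)


def purity_union(bases: str, base: str, min_run: int, purity: float) -> list[tuple[int, int]]:
    """Union of all intervals of length >= min_run with base fraction >= purity."""
    n = len(bases)
    masked = [False] * n
    for i in range(n):
        for j in range(i + min_run, n + 1):
            if bases[i:j].count(base) >= purity * (j - i):
                for p in range(i, j):
                    masked[p] = True
    return _runs(masked)


def longest_clean(length: int, masks: list[tuple[int, int]]) -> tuple[int, int] | None:
    """Leftmost longest interval intersecting no mask, by full enumeration."""
    blocked = [False] * length
    for s, e in masks:
        for p in range(s, e):
            blocked[p] = True
    best = None
    for s in range(length):
        for e in range(s + 1, length + 1):
            if not any(blocked[s:e]) and (best is None or e - s > best[1] - best[0]):
                best = (s, e)
    return best


def _runs(flags: list[bool]) -> list[tuple[int, int]]:
    out = []
    start = None
    for i, f in enumerate(flags):
        if f and start is None:
            start = i
        elif not f and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, len(flags)))
    return out


# --- exact Audic-Claverie arithmetic --------------------------------------

def ac_term_exact(k: int, x: int, n1: int, n2: int) -> Fraction:
    """p(k | x) as an exact rational: r^k C(x+k,k) (1+r)^-(x+k+1), r = n2/n1."""
    r = Fraction(n2, n1)
    return r**k * comb(x + k, k) * (Fraction(1) / (1 + r)) ** (x + k + 1)


def ac_pvalue_exact(x: int, y: int, n_a: int, n_b: int) -> Fraction:
    """Two-tailed AC p-value in exact rational arithmetic.

    Same orientation convention as the implementation (condition on the side
    with the larger normalized count) but summed with Fractions, so any
    floating-point defect in the implementation is exposed.
    """
    if x * n_b >= y * n_a:
        X, NX, Y, NY = x, n_a, y, n_b
    else:
        X, NX, Y, NY = y, n_b, x, n_a
    r = Fraction(NY, NX)
    term = (Fraction(1) / (1 + r)) ** (X + 1)
    total = term
    for k in range(1, Y + 1):
        term *= r * (X + k) / (k * (1 + r))
        total += term
    return min(Fraction(1), 2 * total)
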