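"""Digital differential display: count tables, per-10,000 normalization and
the Audic-Claverie (AC) two-library tag-count test.

The AC statistic gives, for a tag observed x times among N1 reads of one
library, the probability of observing k occurrences among the N2 reads of the
other under equal underlying expression:

    p(k | x) = (N2/N1)^k * C(x+k, k) * (1 + N2/N1)^-(x+k+1)

computed here in log space via log-gamma so that arbitrarily large counts
stay finite. The two-tailed p-value conditions on the side with the larger
*normalized* count (X, N_X) and doubles the lower tail over the other side's
count Y: p = min(1, 2 * sum_{k=0..Y} p(k | X)). Conditioning on the larger
normalized rather than raw count is what reproduces published two-library
EST tables, including the equal-raw-count case with unequal library sizes.

Normalized values are ESTs per 10,000 library reads, truncated (not rounded)
to two decimals — the convention the published tables follow.
"""

from __future__ import annotations

import warnings
from math import exp, lgamma, log, log1p

import numpy as np
import pandas as pd

from .model import DERecord, LibraryTotals


def normalize_count(c: int, N: int, per: int = 10000) -> float:
    """Count per ``per`` reads, truncated to 2 decimals (exact integer floor)."""
    if N <= 0:
        raise ValueError("library total must be > 0")
    if c < 0:
        raise ValueError("count must be >= 0")
    return (c * per * 100 // N) / 100


def ac_probability(k: int, x: int, n1: int, n2: int) -> float:
    """p(k | x): probability of k tags among n2 reads given x among n1."""
    if k < 0 or x < 0:
        raise ValueError("counts must be >= 0")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be > 0")
    log_r = log(n2) - log(n1)
    logp = (
        k * log_r
        + lgamma(x + k + 1) - lgamma(k + 1) - lgamma(x + 1)
        - (x + k + 1) * log1p(n2 / n1)
    )
    return exp(logp)


def ac_pvalue(x: int, y: int, n_a: int, n_b: int) -> float:
    """Two-tailed AC p-value for counts x (library A, total n_a) vs y (B, n_b).

    The tail is conditioned on the side with the larger normalized count and
    summed over k = 0..(other side's count), then doubled and capped at 1.
    The degenerate x = y = 0 case is defined as 1.0 with a warning.
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be >= 0")
    if x == 0 and y == 0:
        warnings.warn("ac_pvalue(0, 0): no observations; p defined as 1.0", stacklevel=2)
        return 1.0
    if x * n_b >= y * n_a:  # x/n_a >= y/n_b without division
        big_x, big_n, small_x, small_n = x, n_a, y, n_b
    else:
        big_x, big_n, small_x, small_n = y, n_b, x, n_a
    # iterate p(k|X) via the term ratio to avoid small_x+1 lgamma evaluations
    log_ratio_base = log(small_n) - log(big_n) - log1p(small_n / big_n)
    log_term = -(big_x + 1) * log1p(small_n / big_n)  # k = 0
    total = exp(log_term)
    for k in range(1, small_x + 1):
        # p(k)/p(k-1) = r * (X+k) / (k * (1+r))
        log_term += log_ratio_base + log(big_x + k) - log(k)
        total += exp(log_term)
    return min(1.0, 2.0 * total)


def ac_pvalues(
    xs, ys, n_a: int, n_b: int, cache: dict[tuple[int, int], float] | None = None
) -> np.ndarray:
    """Vector of AC p-values; de-duplicates repeated (x, y) pairs via a cache."""
    xs = np.asarray(xs, dtype=int)
    ys = np.asarray(ys, dtype=int)
    memo = cache if cache is not None else {}
    out = np.empty(xs.size, dtype=float)
    for i, (x, y) in enumerate(zip(xs.tolist(), ys.tolist())):
        key = (x, y)
        if key not in memo:
            memo[key] = ac_pvalue(x, y, n_a, n_b)
        out[i] = memo[key]
    return out


def count_table(memberships: pd.DataFrame, libraries: list[LibraryTotals]) -> pd.DataFrame:
    """Per-unisequence, per-library read counts from a membership table.

    ``memberships`` has columns (unisequence_id, read_id, library). Every
    library label must be declared; unisequences absent from a library get 0.
    """
    names = [lib.name for lib in libraries]
    if memberships.empty:
        return pd.DataFrame(columns=names).rename_axis("unisequence_id")
    unknown = set(memberships["library"]) - set(names)
    if unknown:
        raise ValueError(f"unknown library label(s): {sorted(unknown)}")
    table = (
        memberships.groupby(["unisequence_id", "library"], sort=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=names, fill_value=0)
    )
    table.columns.name = None
    return table.astype(int)


def de_table(
    counts: pd.DataFrame,
    lib_a: LibraryTotals,
    lib_b: LibraryTotals,
    alpha: float = 0.05,
    bh: bool = False,
) -> list[DERecord]:
    """One DERecord per unisequence with at least one observation, sorted by p.

    ``alpha`` is carried for downstream filtering/report labels; records are
    not filtered here. With ``bh=True`` the p field holds Benjamini-Hochberg
    adjusted values (off by default: published two-library EST tables report
    raw p-values).
    """
    cache: dict[tuple[int, int], float] = {}
    sub = counts[(counts[lib_a.name] + counts[lib_b.name]) >= 1]
    xs = sub[lib_a.name].to_numpy()
    ys = sub[lib_b.name].to_numpy()
    ps = ac_pvalues(xs, ys, lib_a.N, lib_b.N, cache)
    if bh and len(ps):
        from statsmodels.stats.multitest import multipletests

        ps = multipletests(ps, method="fdr_bh")[1]
    records = []
    for uid, x, y, p in zip(sub.index, xs.tolist(), ys.tolist(), ps.tolist()):
        # direction from exact normalized rates; truncation could mask ties
        rate_a, rate_b = x * lib_b.N, y * lib_a.N
        direction = "balanced" if rate_a == rate_b else ("A-enriched" if rate_a > rate_b else "B-enriched")
        records.append(
            DERecord(str(uid), int(x), int(y), normalize_count(x, lib_a.N), normalize_count(y, lib_b.N), float(p), direction)
        )
    records.sort(key=lambda r: (r.p, r.unisequence_id))
    return records


def rank_top(de: list[DERecord], library: str, lib_names: tuple[str, str], n: int = 20) -> list[DERecord]:
    """Top-n records by raw count in one library; ties by ascending p then id."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if library == lib_names[0]:
        key = lambda r: (-r.x, r.p, r.unisequence_id)
    elif library == lib_names[1]:
        key = lambda r: (-r.y, r.p, r.unisequence_id)
    else:
        raise ValueError(f"unknown library {library!r}; expected one of {lib_names}")
    return sorted(de, key=key)[:n]


def de_frame(records: list[DERecord], lib_a: str, lib_b: str) -> pd.DataFrame:
    """DERecords as a TSV-ready frame; p in 4-significant-digit scientific notation."""
    return pd.DataFrame(
        {
            "unisequence_id": [r.unisequence_id for r in records],
            f"count_{lib_a}": [r.x for r in records],
            f"count_{lib_b}": [r.y for r in records],
            f"norm_{lib_a}": [f"{r.n_a:.2f}" for r in records],
            f"norm_{lib_b}": [f"{r.n_b:.2f}" for r in records],
            "p": [f"{r.p:.3e}" for r in records],
            "direction": [r.direction for r in records],
        }
    )
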