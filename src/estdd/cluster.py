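"""Unisequence clustering: single-linkage closure of a pairwise overlap criterion.

Two cleaned ESTs are similar when a local alignment covers at least
``min_overlap`` columns at identity >= ``min_id`` (matches / aligned columns,
gaps counted as columns). Connected components of this relation are the
unisequences: components of size >= 2 become contigs with a plurality-vote
consensus, size-1 components are singletons. This replaces a full
overlap-layout-consensus assembler: the clustering role of the similarity
criterion is reproduced, the assembly internals are deliberately simpler.

A shared-k-mer prefilter keeps the number of alignments near-linear; the
k-mer size is derived from (min_id, min_overlap) so that any qualifying
overlap is guaranteed to contain at least one exact shared k-mer.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .model import Read, Unisequence
from .preprocess import _make_aligner

log = logging.getLogger(__name__)


@dataclass
class OverlapSummary:
    """Best local alignment between two sequences."""

    score: float
    columns: int
    matches: int
    identity: float
    span_a: tuple[int, int]
    span_b: tuple[int, int]


def pairwise_similar(
    a: str, b: str, min_id: float = 0.95, min_overlap: int = 50
) -> tuple[bool, OverlapSummary]:
    """True iff the best local alignment of a and b qualifies; symmetric."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aligner = _make_aligner()
    alns = aligner.align(a, b)
    if alns.score <= 0:
        return False, OverlapSummary(0.0, 0, 0, 0.0, (0, 0), (0, 0))
    aln = alns[0]
    c = aln.counts()
    columns = c.identities + c.mismatches + c.gaps
    identity = c.identities / columns if columns else 0.0
    ta, tb = aln.aligned
    summary = OverlapSummary(
        float(alns.score), int(columns), int(c.identities), float(identity),
        (int(ta[0][0]), int(ta[-1][1])), (int(tb[0][0]), int(tb[-1][1])),
    )
    return columns >= min_overlap and identity >= min_id, summary


def _safe_kmer_size(min_id: float, min_overlap: int, cap: int = 24) -> int:
    """Largest k such that every qualifying overlap shares an exact k-mer.

    An overlap of L columns at identity >= min_id has at most
    floor((1 - min_id) * L) non-match columns, which split the matches into
    runs; the longest run has length >= ceil((L - e) / (e + 1)). The minimum
    of that bound over practical L gives a safe k.
    """
    bound = min(
        math.ceil((L - math.floor((1 - min_id) * L)) / (math.floor((1 - min_id) * L) + 1))
        for L in range(min_overlap, max(2000, 4 * min_overlap))
    )
    return max(4, min(cap, bound))


class _DSU:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _candidate_pairs(seqs: list[str], k: int) -> list[tuple[int, int]]:
    index: dict[str, list[int]] = {}
    for i, s in enumerate(seqs):
        for kmer in {s[j : j + k] for j in range(len(s) - k + 1)}:
            index.setdefault(kmer, []).append(i)
    pairs = set()
    for members in index.values():
        if len(members) > 1:
            for ai in range(len(members)):
                for bi in range(ai + 1, len(members)):
                    pairs.add((members[ai], members[bi]))
    return sorted(pairs)


def cluster_reads(
    reads: list[Read], min_id: float = 0.95, min_overlap: int = 50
) -> list[Unisequence]:
    """Partition cleaned reads into unisequences (contigs + singletons).

    Deterministic: candidate pairs are processed in input order, components
    are numbered by their first-seen member, and consensus tie-breaks are
    fixed (plurality, then summed quality, then alphabetical).
    """
    if not reads:
        return []
    seqs = [r.bases for r in reads]
    k = _safe_kmer_size(min_id, min_overlap)
    dsu = _DSU(len(reads))
    n_aligned = 0
    for i, j in _candidate_pairs(seqs, k):
        if dsu.find(i) == dsu.find(j):
            continue
        ok, _ = pairwise_similar(seqs[i], seqs[j], min_id, min_overlap)
        n_aligned += 1
        if ok:
            dsu.union(i, j)
    components: dict[int, list[int]] = {}
    for i in range(len(reads)):
        components.setdefault(dsu.find(i), []).append(i)

    out: list[Unisequence] = []
    contig_n = 0
    for root in sorted(components, key=lambda r: min(components[r])):
        idxs = sorted(components[root])
        members = [(reads[i].id, reads[i].library) for i in idxs]
        if len(idxs) >= 2:
            contig_n += 1
            consensus = build_consensus([reads[i] for i in idxs], min_id, min_overlap)
            out.append(Unisequence(f"Contig{contig_n}", members, consensus, True))
        else:
            r = reads[idxs[0]]
            out.append(Unisequence(r.id, members, r.bases, False))
    log.info(
        "cluster: %d reads -> %d contigs + %d singletons (%d alignments)",
        len(reads), contig_n, len(out) - contig_n, n_aligned,
    )
    return out


def build_consensus(members: list[Read], min_id: float = 0.95, min_overlap: int = 50) -> str:
    """Plurality-vote consensus over an ungapped star layout.

    The longest member anchors the layout; every other member is placed by
    its best qualifying local alignment against an already-placed member
    (anchor first), using the alignment's largest aligned block to derive an
    ungapped offset. Per column the consensus base is the plurality vote;
    ties go to the highest summed phred quality, then alphabetically. A
    member with no qualifying overlap is appended unaligned at the end and
    logged.
    """
    if not members:
        raise ValueError("cluster must be non-empty")
    if len(members) == 1:
        return members[0].bases
    order = sorted(range(len(members)), key=lambda i: (-len(members[i]), i))
    anchor = order[0]
    offsets: dict[int, int] = {anchor: 0}
    pending = order[1:]
    appended: list[int] = []
    for i in pending:
        placed_at = None
        for j in [anchor] + [p for p in offsets if p != anchor]:
            ok, summ = pairwise_similar(members[j].bases, members[i].bases, min_id, min_overlap)
            if ok:
                placed_at = offsets[j] + summ.span_a[0] - summ.span_b[0]
                break
        if placed_at is None:
            appended.append(i)
        else:
            offsets[i] = placed_at
    shift = -min(offsets.values())
    width = max(offsets[i] + shift + len(members[i]) for i in offsets)
    for i in appended:
        log.warning("consensus: read %s has no qualifying overlap; appended unaligned", members[i].id)
        offsets[i] = width - shift  # starts at the current layout end
        width += len(members[i])

    votes: list[dict[str, list]] = [dict() for _ in range(width)]
    for i, off in offsets.items():
        start = off + shift
        for p, (base, q) in enumerate(zip(members[i].bases, members[i].quals)):
            col = votes[start + p]
            if base not in col:
                col[base] = [0, 0]
            col[base][0] += 1
            col[base][1] += q
    out = []
    for col in votes:
        if not col:
            out.append("N")  # uncovered column (only possible around appended members)
            continue
        best = sorted(col.items(), key=lambda kv: (-kv[1][0], -kv[1][1], kv[0]))[0][0]
        out.append(best)
    return "".join(out)
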