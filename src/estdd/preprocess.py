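"""Raw-EST cleaning: cause-labelled masking and largest-clean-region extraction.

A read is screened for four artefact classes — vector/primer carryover,
poly-A/poly-T runs, low-quality stretches and slippage echoes — and the
longest interval free of all masks is kept. Survivors must retain at least
``min_clean_len`` clean bases (default 100).

All intervals are 0-based half-open in read coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields

import numpy as np
from Bio import Align

from .model import Interval, MaskReport, Read

log = logging.getLogger(__name__)


@dataclass
class CleaningConfig:
    """Tunable thresholds for the masking stages (all exposed on the CLI)."""

    window: int = 10
    min_mean_q: float = 20.0
    polya_min_run: int = 12
    polya_purity: float = 0.9
    vector_min_id: float = 0.9
    vector_min_len: int = 20
    slip_probe_len: int = 30
    slip_max_offset: int = 200
    slip_min_id: float = 0.9
    min_clean_len: int = 100

    @classmethod
    def from_dict(cls, d: dict) -> "CleaningConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown cleaning options: {sorted(unknown)}")
        return cls(**d)


def merge_intervals(intervals: list[Interval]) -> list[Interval]:
    """Union of half-open intervals as a sorted, disjoint list."""
    out: list[Interval] = []
    for s, e in sorted(i for i in intervals if i[0] < i[1]):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def mask_low_quality(read: Read, window: int = 10, min_mean_q: float = 20.0) -> list[Interval]:
    """Union of all sliding windows whose mean phred quality is below threshold.

    Positions covered only by windows at/above threshold stay unmasked. Reads
    shorter than the window are judged by a single whole-read window.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    n = len(read)
    if n == 0:
        return []
    w = min(window, n)
    q = np.asarray(read.quals, dtype=float)
    sums = np.convolve(q, np.ones(w), mode="valid")  # n - w + 1 windows; exact for int quals
    below = np.flatnonzero(sums < min_mean_q * w)
    return merge_intervals([(int(j), int(j) + w) for j in below])


def _purity_union(match: np.ndarray, min_run: int, purity: float) -> list[Interval]:
    """Exact union of all intervals of length >= min_run with match fraction >= purity.

    O(L^2) bool matrix over interval endpoints; L is a read length so this
    stays small. For a fixed start the qualifying end-points form a set whose
    union is [start, max end); taking that per start and merging gives the
    exact union of all qualifying intervals.
    """
    L = match.size
    P = np.concatenate([[0], np.cumsum(match)])
    j = np.arange(L + 1)
    span = j[None, :] - j[: L, None]  # end - start
    good = (P[None, :] - P[:L, None] >= purity * span) & (span >= min_run)
    has = good.any(axis=1)
    if not has.any():
        return []
    jmax = (L + 1) - 1 - np.argmax(good[:, ::-1], axis=1)
    return merge_intervals([(int(i), int(jmax[i])) for i in np.flatnonzero(has)])


def mask_homopolymer_tails(read: Read, min_run: int = 12, purity: float = 0.9) -> list[tuple[int, int, str]]:
    """Poly-A and poly-T intervals: length >= min_run, base fraction >= purity.

    Returns cause-labelled intervals (``polyA``/``polyT``), each the maximal
    extension of a qualifying interval. N never counts toward purity.
    """
    if min_run < 5:
        raise ValueError("min_run must be >= 5")
    if not 0.5 < purity <= 1.0:
        raise ValueError("purity must lie in (0.5, 1]")
    if len(read) == 0:
        return []
    arr = np.frombuffer(read.bases.encode(), dtype=np.uint8)
    out: list[tuple[int, int, str]] = []
    for base, cause in ((ord("A"), "polyA"), (ord("T"), "polyT")):
        match = (arr == base).astype(int)
        # cheap pre-screen: a qualifying interval at purity >= 0.8 always
        # contains an exact run of >= 5 bases; skip the quadratic scan if none
        if purity >= 0.8:
            run = 0
            seen = False
            for m in match:
                run = run + 1 if m else 0
                if run >= 5:
                    seen = True
                    break
            if not seen:
                continue
        for s, e in _purity_union(match, min_run, purity):
            out.append((s, e, cause))
    return sorted(out)


_VECTOR_FILLER = "x"  # never matches A/C/G/T; used to blank found hits


_ALIGNER: Align.PairwiseAligner | None = None


def _make_aligner() -> Align.PairwiseAligner:
    """Shared local aligner: +1 match, -2 mismatch, -4/-2 gaps."""
    global _ALIGNER
    if _ALIGNER is None:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score = 1
        aligner.mismatch_score = -2
        aligner.open_gap_score = -4
        aligner.extend_gap_score = -2
        _ALIGNER = aligner
    return _ALIGNER


def _alignment_stats(aln) -> tuple[int, int, tuple[int, int]]:
    """(matches, aligned columns, target span) of a local alignment."""
    c = aln.counts()
    columns = c.identities + c.mismatches + c.gaps
    t_blocks = aln.aligned[0]
    span = (int(t_blocks[0][0]), int(t_blocks[-1][1]))
    return int(c.identities), int(columns), span


def mask_vector(
    read: Read, vector_seqs: list[str], min_id: float = 0.9, min_len: int = 20
) -> list[Interval]:
    """Local-alignment hits against any vector sequence, merged.

    A hit qualifies with identity >= min_id over >= min_len aligned columns.
    Found spans are blanked and the alignment repeated, so multiple disjoint
    hits on one read are all reported.
    """
    if not vector_seqs:
        raise ValueError("vector_seqs must be non-empty")
    if len(read) == 0:
        return []
    aligner = _make_aligner()
    hits: list[Interval] = []
    target = read.bases
    for vec in vector_seqs:
        work = target
        for _ in range(8):  # cap repeated-hit search
            alns = aligner.align(work, vec)
            if alns.score <= 0:
                break
            matches, columns, span = _alignment_stats(alns[0])
            if columns < min_len or matches / columns < min_id:
                break
            hits.append(span)
            work = work[: span[0]] + _VECTOR_FILLER * (span[1] - span[0]) + work[span[1]:]
    return merge_intervals(hits)


def detect_slippage(
    read: Read, probe_len: int = 30, max_offset: int = 200, min_id: float = 0.9
) -> list[Interval]:
    """Mask a 5' echo: the read prefix re-occurring a short distance downstream.

    If the first ``probe_len`` bases reappear at offset s <= max_offset with
    (ungapped) identity >= min_id, the duplicated span [0, s) is masked. This
    echo heuristic stands in for the slippage detector of chromatogram-era
    cleaning pipelines, whose exact rule is not public.
    """
    if probe_len < 10:
        raise ValueError("probe_len must be >= 10")
    n = len(read)
    if n < probe_len + 1:
        return []
    arr = np.frombuffer(read.bases.encode(), dtype=np.uint8)
    probe = arr[:probe_len]
    windows = np.lib.stride_tricks.sliding_window_view(arr, probe_len)
    last = min(max_offset, windows.shape[0] - 1)
    if last < 1:
        return []
    ident = (windows[1 : last + 1] == probe).mean(axis=1)
    qualifying = np.flatnonzero(ident >= min_id)
    if qualifying.size == 0:
        return []
    s = int(qualifying[0]) + 1
    return [(0, s)]


def extract_clean_region(
    read: Read, masks: list[Interval], min_clean_len: int = 100, causes: list[tuple[int, int, str]] | None = None
) -> MaskReport:
    """Longest contiguous unmasked interval (leftmost on ties) and pass verdict."""
    merged = merge_intervals(list(masks))
    for s, e in merged:
        if s < 0 or e > len(read):
            raise ValueError(f"mask ({s}, {e}) outside read of length {len(read)}")
    gaps: list[Interval] = []
    pos = 0
    for s, e in merged:
        if s > pos:
            gaps.append((pos, s))
        pos = max(pos, e)
    if pos < len(read):
        gaps.append((pos, len(read)))
    clean = max(gaps, key=lambda g: g[1] - g[0], default=None)  # max is leftmost on ties
    passed = clean is not None and clean[1] - clean[0] >= min_clean_len
    return MaskReport(read.id, sorted(causes or []), clean, passed)


def clean_read(read: Read, vector_seqs: list[str], config: CleaningConfig | None = None) -> MaskReport:
    """Apply all four masking stages to one read and extract its clean region."""
    cfg = config or CleaningConfig()
    causes: list[tuple[int, int, str]] = []
    for s, e in mask_low_quality(read, cfg.window, cfg.min_mean_q):
        causes.append((s, e, "low_quality"))
    causes.extend(mask_homopolymer_tails(read, cfg.polya_min_run, cfg.polya_purity))
    if vector_seqs:
        for s, e in mask_vector(read, vector_seqs, cfg.vector_min_id, cfg.vector_min_len):
            causes.append((s, e, "vector"))
    for s, e in detect_slippage(read, cfg.slip_probe_len, cfg.slip_max_offset, cfg.slip_min_id):
        causes.append((s, e, "slippage"))
    return extract_clean_region(read, [(s, e) for s, e, _ in causes], cfg.min_clean_len, causes)


def clean_reads(
    reads: list[Read], vector_seqs: list[str], config: CleaningConfig | None = None
) -> tuple[list[Read], list[MaskReport], dict]:
    """Clean a batch; returns trimmed survivors, per-read reports, and a summary."""
    cfg = config or CleaningConfig()
    survivors: list[Read] = []
    reports: list[MaskReport] = []
    for read in reads:
        rep = clean_read(read, vector_seqs, cfg)
        reports.append(rep)
        if rep.passed:
            survivors.append(read.slice(*rep.clean_region))
    mean_len = float(np.mean([len(r) for r in survivors])) if survivors else 0.0
    summary = {
        "input": len(reads),
        "discarded": len(reads) - len(survivors),
        "survivors": len(survivors),
        "mean_trimmed_length": round(mean_len, 1),
    }
    log.info(
        "clean: %d in, %d discarded, %d out, mean trimmed length %.1f",
        summary["input"], summary["discarded"], summary["survivors"], summary["mean_trimmed_length"],
    )
    return survivors, reports, summary
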