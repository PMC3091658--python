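"""Synthetic two-library Sanger EST simulator with known ground truth.

Emulates 5'-sequenced cDNA reads: each read is a 5' window of a source
transcript, optionally carrying a 5' vector/primer fragment and a 3' poly-A
run, with substitution errors and a phred profile that is high over the read
body and decays over the final ~10% of bases — the artefacts the cleaning
stage exists to remove. Every sampling step is driven by one seeded
generator, so a fixed seed gives byte-identical FASTA/qual output.
"""

from __future__ import annotations

import numpy as np

from .model import LibraryModel, Read, SimTruth, Transcript

BASES = "ACGT"

#: Universal M13 forward sequencing primer; vector carryover in a 5' read
#: ends with this motif.
M13F = "TGTAAAACGACGGCCAGT"

#: Synthetic cloning-vector fragment (invented sequence, not from any real
#: plasmid) ending in the M13F primer, mimicking the polylinker context a
#: 5' read can run through.
DEFAULT_VECTOR = (
    "GCTTCCGGCTCGTATGTTGTGTGGAATTGTGAGCGGATAACAATTTCACACAGGAAACAGCT"
    "ATGACCATGATTACGCCAAGCTTGCATGCCTGCAGGTCGACTCTAGA" + M13F
)

# poly-A run length range (inclusive) appended with polyA_prob
_POLYA_RANGE = (15, 40)
# vector fragment length range (inclusive) prepended with vector_prob
_VECTOR_RANGE = (30, 60)
# quality profile: plateau level +- jitter, then linear decay over the final
# tail fraction of the read down to Q~3
_Q_PLATEAU = 40
_Q_JITTER = 3
_DECAY_FRACTION = 0.10
_Q_DECAY_TOP = 28
_Q_DECAY_BOTTOM = 3


def simulate_transcriptome(
    n: int, length_dist: tuple[float, float] = (1000.0, 150.0), seed: int = 0
) -> list[Transcript]:
    """Draw ``n`` i.i.d. uniform-base transcripts with Normal(mean, sd) lengths.

    Lengths are floored at 200 bases. Deterministic for a fixed seed.
    """
    mean, sd = length_dist
    if n < 1:
        raise ValueError("n must be >= 1")
    if mean < 200:
        raise ValueError("mean transcript length must be >= 200")
    rng = np.random.default_rng(seed)
    lengths = np.maximum(200, np.rint(rng.normal(mean, sd, size=n)).astype(int))
    width = len(str(n))
    out = []
    for i, length in enumerate(lengths):
        seq = "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])
        out.append(Transcript(f"TX{i + 1:0{width}d}", seq))
    return out


def sample_abundances(transcript_ids: list[str], seed: int = 0, sigma: float = 1.0) -> dict[str, float]:
    """Skewed (log-normal) relative abundances, normalized to sum to 1."""
    rng = np.random.default_rng(seed)
    w = rng.lognormal(mean=0.0, sigma=sigma, size=len(transcript_ids))
    w /= w.sum()
    return dict(zip(transcript_ids, w.tolist()))


def _quality_profile(length: int, rng: np.random.Generator) -> list[int]:
    """Plateau ~Q40 with jitter, decaying linearly to <10 over the final ~10%."""
    decay = max(1, round(length * _DECAY_FRACTION))
    plateau = length - decay
    q = np.empty(length, dtype=int)
    q[:plateau] = _Q_PLATEAU + rng.integers(-_Q_JITTER, _Q_JITTER + 1, size=plateau)
    ramp = np.linspace(_Q_DECAY_TOP, _Q_DECAY_BOTTOM, decay)
    q[plateau:] = np.rint(ramp).astype(int) + rng.integers(-1, 2, size=decay)
    return np.clip(q, 2, 93).tolist()


def _substitute(seq: np.ndarray, error_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitution errors at ``error_rate`` per base (never the same base)."""
    if error_rate <= 0.0:
        return seq
    hits = np.flatnonzero(rng.random(seq.size) < error_rate)
    if hits.size:
        # shift by 1..3 in base space: uniform over the three other bases
        lut = np.frombuffer(b"ACGT", dtype=np.uint8)
        idx = np.searchsorted(lut, seq[hits])
        seq = seq.copy()
        seq[hits] = lut[(idx + rng.integers(1, 4, size=hits.size)) % 4]
    return seq


def simulate_library(
    transcripts: list[Transcript],
    model: LibraryModel,
    vector: str = DEFAULT_VECTOR,
) -> tuple[list[Read], dict[str, int]]:
    """Sample one library of reads; returns the reads and realized counts.

    Each read picks a transcript by abundance weight, takes a 5' window of
    Normal(read_length_mean, read_length_sd) length (clipped to [40, transcript
    length]), applies substitution errors, appends a poly-A run with
    ``polyA_prob`` and prepends a 3'-anchored vector fragment (ending in M13F)
    with ``vector_prob``. Reads carry their planted structure in
    ``annotations`` for truth-based tests.
    """
    if not transcripts:
        raise ValueError("transcript list must be non-empty")
    by_id = {t.id: t for t in transcripts}
    missing = set(model.abundance) - set(by_id)
    if missing:
        raise ValueError(f"abundance refers to unknown transcripts: {sorted(missing)[:5]}")

    rng = np.random.default_rng(model.seed)
    ids = sorted(model.abundance)
    weights = np.array([model.abundance[t] for t in ids])
    counts_vec = rng.multinomial(model.n_reads, weights)
    counts = {t: int(c) for t, c in zip(ids, counts_vec)}

    reads: list[Read] = []
    i = 0
    for tid, c in zip(ids, counts_vec):
        tx = by_id[tid]
        for _ in range(c):
            length = int(np.rint(rng.normal(model.read_length_mean, model.read_length_sd)))
            length = max(40, min(length, tx.length))
            core = np.frombuffer(tx.sequence[:length].encode(), dtype=np.uint8)
            core = _substitute(core, model.error_rate, rng)

            vec_frag = ""
            if rng.random() < model.vector_prob:
                vlen = int(rng.integers(_VECTOR_RANGE[0], _VECTOR_RANGE[1] + 1))
                vec_frag = vector[-vlen:]
            polya = ""
            if rng.random() < model.polyA_prob:
                polya = "A" * int(rng.integers(_POLYA_RANGE[0], _POLYA_RANGE[1] + 1))

            bases = vec_frag + core.tobytes().decode() + polya
            quals = _quality_profile(len(bases), rng)
            ann = {
                "transcript": tid,
                "vector_end": len(vec_frag),
                "insert_end": len(vec_frag) + length,
                "polya_len": len(polya),
                "decay_start": len(bases) - max(1, round(len(bases) * _DECAY_FRACTION)),
            }
            reads.append(Read(f"{model.name}{i + 1:05d}", model.name, bases, quals, ann))
            i += 1
    return reads, counts


def simulate_pair(
    transcripts: list[Transcript],
    model_a: LibraryModel,
    model_b: LibraryModel,
    vector: str = DEFAULT_VECTOR,
    fold_threshold: float = 2.0,
) -> tuple[list[Read], list[Read], SimTruth]:
    """Simulate two libraries over one transcriptome and the joint truth."""
    reads_a, counts_a = simulate_library(transcripts, model_a, vector)
    reads_b, counts_b = simulate_library(transcripts, model_b, vector)
    truth = SimTruth(
        model_a.name, model_b.name, dict(model_a.abundance), dict(model_b.abundance),
        counts_a, counts_b, fold_threshold,
    )
    return reads_a, reads_b, truth
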