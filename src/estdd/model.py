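"""Core domain records shared across pipeline stages.

Coordinates are 0-based, half-open everywhere. Qualities are phred-scale
integers in [0, 93].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

Interval = tuple[int, int]

#: Mask causes recognised by the cleaning stage.
MASK_CAUSES = ("vector", "polyA", "polyT", "low_quality", "slippage")


@dataclass
class Read:
    """A single 5'-sequenced EST read with per-base phred qualities."""

    id: str
    library: str
    bases: str
    quals: list[int]
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.id}: {len(self.bases)} bases but {len(self.quals)} qualities"
            )
        if self.quals and not all(0 <= q <= 93 for q in self.quals):
            raise ValueError(f"read {self.id}: qualities outside [0, 93]")

    def __len__(self) -> int:
        return len(self.bases)

    def slice(self, start: int, end: int) -> "Read":
        """Sub-read over [start, end); records original coordinates."""
        if not (0 <= start <= end <= len(self)):
            raise ValueError(f"slice [{start}, {end}) outside read of length {len(self)}")
        ann = dict(self.annotations)
        base = ann.pop("origin", (0, 0))[0] if "origin" in self.annotations else 0
        ann["origin"] = (base + start, base + end)
        return Read(self.id, self.library, self.bases[start:end], self.quals[start:end], ann)


@dataclass
class MaskReport:
    """Outcome of cleaning one read: cause-labelled masks and the clean region."""

    read_id: str
    masks: list[tuple[int, int, str]]
    clean_region: Optional[Interval]
    passed: bool


@dataclass
class Transcript:
    """A seed transcript used as simulation ground truth."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 200:
            raise ValueError(f"transcript {self.id}: length {len(self.sequence)} < 200")
        if set(self.sequence) - set("ACGT"):
            raise ValueError(f"transcript {self.id}: alphabet not restricted to A/C/G/T")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class LibraryModel:
    """Sampling model for one cDNA library.

    ``abundance`` maps transcript id to a non-negative sampling weight; weights
    must sum to 1. ``error_rate`` is substitutions per base. ``polyA_prob`` and
    ``vector_prob`` are the per-read probabilities of a 3' poly-A run and of 5'
    vector/primer carryover.
    """

    name: str
    n_reads: int
    abundance: dict[str, float]
    read_length_mean: float = 560.0
    read_length_sd: float = 90.0
    error_rate: float = 0.01
    polyA_prob: float = 0.6
    vector_prob: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads <= 0:
            raise ValueError("n_reads must be > 0")
        if any(w < 0 for w in self.abundance.values()):
            raise ValueError("abundance weights must be non-negative")
        total = sum(self.abundance.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"abundance weights sum to {total}, expected 1")
        if not 0.0 <= self.error_rate <= 0.2:
            raise ValueError("error_rate must lie in [0, 0.2]")
        for p, nm in ((self.polyA_prob, "polyA_prob"), (self.vector_prob, "vector_prob")):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{nm} must lie in [0, 1]")


@dataclass
class SimTruth:
    """Planted per-transcript abundances, realized counts and DE labels."""

    library_a: str
    library_b: str
    abundance_a: dict[str, float]
    abundance_b: dict[str, float]
    counts_a: dict[str, int]
    counts_b: dict[str, int]
    fold_threshold: float = 2.0

    def de_flag(self, transcript_id: str) -> bool:
        a = self.abundance_a[transcript_id]
        b = self.abundance_b[transcript_id]
        if a == 0.0 and b == 0.0:
            return False
        if min(a, b) == 0.0:
            return True
        return max(a, b) / min(a, b) > self.fold_threshold

    @property
    def de_flags(self) -> dict[str, bool]:
        return {t: self.de_flag(t) for t in self.abundance_a}


@dataclass
class Unisequence:
    """A non-redundant transcript representative: contig or singleton."""

    id: str
    members: list[tuple[str, str]]  # (read_id, library)
    consensus: str
    is_contig: bool

    def __post_init__(self) -> None:
        if self.is_contig != (len(self.members) >= 2):
            raise ValueError(f"{self.id}: is_contig inconsistent with {len(self.members)} members")


@dataclass
class LibraryTotals:
    """Post-cleaning EST total for one library."""

    name: str
    N: int

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise ValueError(f"library {self.name}: total must be > 0")


@dataclass
class DERecord:
    """Per-unisequence counts, per-10,000 normalized values and AC p-value."""

    unisequence_id: str
    x: int  # count in library A
    y: int  # count in library B
    n_a: float  # normalized per 10,000, truncated to 2 decimals
    n_b: float
    p: float
    direction: str  # "A-enriched" | "B-enriched" | "balanced"
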