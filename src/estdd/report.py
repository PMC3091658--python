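"""Category aggregation, summary arithmetic, and end-to-end orchestration.

``aggregate_category`` produces the enzyme/category tables: per-unisequence
rows (counts, normalized values, AC p-value) and per-symbol rollups where
normalized values are computed from the summed raw counts and truncated
once. ``run_pipeline`` chains clean -> cluster -> count -> DE -> reports and
writes a machine-readable run summary.
"""

from __future__ import annotations

import json
import logging
import tomllib
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import io as eio
from .cluster import cluster_reads
from .model import LibraryTotals, Read
from .preprocess import CleaningConfig, clean_reads
from .tagcount import ac_pvalues, count_table, de_frame, de_table, normalize_count, rank_top

log = logging.getLogger(__name__)


@dataclass
class AssemblySummary:
    """Headline clustering numbers; unisequences = contigs + singletons."""

    contigs: int
    singletons: int

    @property
    def unisequences(self) -> int:
        return self.contigs + self.singletons


def percent(part: int, whole: int) -> float:
    """Share of ``whole`` as a percentage, rounded to one decimal."""
    if whole <= 0:
        raise ValueError("whole must be > 0")
    return round(100.0 * part / whole, 1)


def aggregate_category(
    category_map: pd.DataFrame,
    counts: pd.DataFrame,
    lib_a: LibraryTotals,
    lib_b: LibraryTotals,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate unisequence counts by category symbol.

    ``category_map`` has columns (unisequence_id, symbol, description).
    Returns (per_symbol, per_unisequence). Unisequences missing from
    ``counts`` are ignored with a warning; symbols with zero counts in both
    libraries are excluded. Per-symbol normalized values come from the
    summed raw counts, truncated once.
    """
    required = {"unisequence_id", "symbol"}
    if not required <= set(category_map.columns):
        raise ValueError(f"category map needs columns {sorted(required)}")
    if category_map.empty:
        cols = ["symbol", "n_unisequences", f"count_{lib_a.name}", f"count_{lib_b.name}",
                f"norm_{lib_a.name}", f"norm_{lib_b.name}"]
        return pd.DataFrame(columns=cols), pd.DataFrame()
    dup = category_map.duplicated(["unisequence_id", "symbol"])
    if dup.any():
        raise ValueError("a unisequence may map to a symbol at most once")
    known = category_map["unisequence_id"].isin(counts.index)
    for uid in category_map.loc[~known, "unisequence_id"]:
        log.warning("category map: unisequence %s not in count table; ignored", uid)
    cmap = category_map[known]

    per_uni = cmap.merge(
        counts[[lib_a.name, lib_b.name]], left_on="unisequence_id", right_index=True
    )
    per_uni = per_uni[(per_uni[lib_a.name] + per_uni[lib_b.name]) >= 1].copy()
    per_uni["p"] = ac_pvalues(per_uni[lib_a.name], per_uni[lib_b.name], lib_a.N, lib_b.N)
    per_uni[f"norm_{lib_a.name}"] = [normalize_count(c, lib_a.N) for c in per_uni[lib_a.name]]
    per_uni[f"norm_{lib_b.name}"] = [normalize_count(c, lib_b.N) for c in per_uni[lib_b.name]]

    rows = []
    for symbol, grp in per_uni.groupby("symbol", sort=True):
        ca, cb = int(grp[lib_a.name].sum()), int(grp[lib_b.name].sum())
        rows.append(
            {
                "symbol": symbol,
                "n_unisequences": len(grp),
                f"count_{lib_a.name}": ca,
                f"count_{lib_b.name}": cb,
                f"norm_{lib_a.name}": normalize_count(ca, lib_a.N),
                f"norm_{lib_b.name}": normalize_count(cb, lib_b.N),
            }
        )
    return pd.DataFrame(rows), per_uni.reset_index(drop=True)


def load_config(path: str | Path) -> dict:
    with open(path, "rb") as fh:
        return tomllib.load(fh)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """clean -> cluster -> count -> DE -> reports; returns the run summary.

    ``config`` follows the TOML layout::

        [input.JD]
        fasta = "jd.fasta"
        qual = "jd.qual"       # or: fastq = "jd.fastq"
        [input]                # ordering of libraries = TOML order
        vector = "vector.fasta"
        [clean]                # CleaningConfig fields
        min_clean_len = 100
        [cluster]
        min_id = 0.95
        min_overlap = 50
        [de]
        alpha = 0.05
        top = 20
        bh = false
        [aggregate]
        map = "categories.tsv" # optional

    All outputs are TSV/FASTA/qual under ``out_dir``; identical inputs give
    byte-identical outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = config.get("input", {})
    lib_specs = {k: v for k, v in inputs.items() if isinstance(v, dict)}
    if len(lib_specs) < 2:
        raise PipelineError("input", "need at least two [input.<library>] sections")

    reads: list[Read] = []
    for lib, files in lib_specs.items():
        try:
            if "fastq" in files:
                batch = eio.read_fastq(files["fastq"], lib)
            else:
                batch = eio.read_fasta_qual(files["fasta"], files["qual"], lib)
        except (OSError, KeyError, ValueError) as exc:
            raise PipelineError("input", f"library {lib}: {exc}") from exc
        if not batch:
            raise PipelineError("input", f"library {lib}: no reads")
        reads.extend(batch)

    vector_seqs = []
    if inputs.get("vector"):
        vector_seqs = list(eio.read_fasta(inputs["vector"]).values())

    cfg = CleaningConfig.from_dict(config.get("clean", {}))
    survivors, reports, clean_summary = clean_reads(reads, vector_seqs, cfg)
    if not survivors:
        raise PipelineError("clean", "no read retained a clean region")
    eio.write_mask_report(reports, out / "mask_report.tsv")
    for lib in lib_specs:
        lib_reads = [r for r in survivors if r.library == lib]
        eio.write_fasta_qual(lib_reads, out / f"trimmed_{lib}.fasta", out / f"trimmed_{lib}.qual")

    ccfg = config.get("cluster", {})
    unis = cluster_reads(survivors, ccfg.get("min_id", 0.95), ccfg.get("min_overlap", 50))
    eio.write_membership(
        [(u.id, rid, lib) for u in unis for rid, lib in u.members], out / "membership.tsv"
    )
    eio.write_fasta({u.id: u.consensus for u in unis}, out / "unisequences.fasta")

    memberships = pd.DataFrame(
        [(u.id, rid, lib) for u in unis for rid, lib in u.members],
        columns=["unisequence_id", "read_id", "library"],
    )
    lib_names = list(lib_specs)
    totals = [
        LibraryTotals(lib, int((memberships["library"] == lib).sum())) for lib in lib_names
    ]
    counts = count_table(memberships, totals)
    counts.to_csv(out / "counts.tsv", sep="\t")

    dcfg = config.get("de", {})
    lib_a, lib_b = totals[0], totals[1]
    records = de_table(counts, lib_a, lib_b, dcfg.get("alpha", 0.05), dcfg.get("bh", False))
    de_frame(records, lib_a.name, lib_b.name).to_csv(out / "de.tsv", sep="\t", index=False)
    top_n = dcfg.get("top", 20)
    for lib in (lib_a.name, lib_b.name):
        top = rank_top(records, lib, (lib_a.name, lib_b.name), top_n)
        de_frame(top, lib_a.name, lib_b.name).to_csv(out / f"top_{lib}.tsv", sep="\t", index=False)

    if config.get("aggregate", {}).get("map"):
        cmap = pd.read_csv(config["aggregate"]["map"], sep="\t", dtype=str)
        per_symbol, per_uni = aggregate_category(cmap, counts, lib_a, lib_b)
        per_symbol.to_csv(out / "categories.tsv", sep="\t", index=False)
        per_uni.to_csv(out / "categories_per_unisequence.tsv", sep="\t", index=False)

    contigs = sum(1 for u in unis if u.is_contig)
    asm = AssemblySummary(contigs, len(unis) - contigs)
    summary = {
        "input_reads": clean_summary["input"],
        "trimmed_reads": clean_summary["survivors"],
        "mean_trimmed_length": clean_summary["mean_trimmed_length"],
        "contigs": asm.contigs,
        "singletons": asm.singletons,
        "unisequences": asm.unisequences,
        "library_totals": {t.name: t.N for t in totals},
        "total_ests": sum(t.N for t in totals),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
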