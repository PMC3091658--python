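# estdd

EST cleaning, unisequence clustering and **d**igital **d**ifferential
**d**isplay for two-library cDNA studies.

Before RNA-seq, expression in contrasting tissues was compared by
single-pass Sanger sequencing of clones from two non-normalised cDNA
libraries: each transcript's clone count is a direct (if noisy) readout of
its abundance. This package implements that complete analysis chain for
studies such as the developing-vs-germinating oilseed endosperm comparison
it is calibrated against (libraries "JD" and "JG" of 7,320 and 5,929 ESTs):

1. **Cleaning** (`estdd.preprocess`) — mask vector/primer carryover,
   poly-A/T runs, low-quality stretches and slippage echoes; keep the
   largest clean region; discard reads with fewer than 100 clean bases.
2. **Clustering** (`estdd.cluster`) — single-linkage closure of a pairwise
   criterion (local alignment identity ≥ 95% over ≥ 50 bp) into
   *unisequences*: multi-read contigs with a quality-weighted consensus,
   plus singletons.
3. **Counting and testing** (`estdd.tagcount`) — per-library counts,
   normalization to ESTs per 10,000 reads (truncated to two decimals, the
   convention of the published tables), and the Audic–Claverie significance
   test for count differences between libraries of unequal size:

       p(k | x) = (N2/N1)^k · C(x+k, k) · (1 + N2/N1)^-(x+k+1)

       p-value  = min(1, 2 · Σ_{k=0..Y} p(k | X))

   where `(X, N_X)` is the side with the larger normalized count and `Y`
   the other side's count. Computed in log space; validated against an
   exact rational-arithmetic oracle and against published tables.
4. **Reporting** (`estdd.report`) — per-category (enzyme symbol) rollups,
   run summaries, and a TOML-configured end-to-end pipeline.
5. **Simulation** (`estdd.simulate`) — a seeded two-library Sanger EST
   generator (transcript sampling, 5' vector + M13F primer carryover,
   poly-A tails, substitution errors, decaying phred profile) with full
   ground truth, so every stage is testable without chromatogram data.

See `docs/methods.md` for the model, conventions, numerical choices, and
the simulator's scope.

## Worked example

```python
from estdd import LibraryModel, run_pipeline
from estdd import io as eio
from estdd.simulate import (DEFAULT_VECTOR, sample_abundances,
                            simulate_pair, simulate_transcriptome)

# two libraries over 200 transcripts; five planted 10-fold down in JG
txs = simulate_transcriptome(200, (1000, 150), seed=1)
ids = [t.id for t in txs]
ab_a = sample_abundances(ids, seed=2)
ab_b = dict(ab_a)
for tid in ids[:5]:
    ab_b[tid] = ab_a[tid] / 10
s = sum(ab_b.values())
ab_b = {t: w / s for t, w in ab_b.items()}

reads_a, reads_b, truth = simulate_pair(
    txs, LibraryModel("JD", 800, ab_a, seed=10),
         LibraryModel("JG", 650, ab_b, seed=11))
eio.write_fasta_qual(reads_a, "jd.fasta", "jd.qual")
eio.write_fasta_qual(reads_b, "jg.fasta", "jg.qual")
eio.write_fasta({"vector": DEFAULT_VECTOR}, "vector.fasta")

summary = run_pipeline(
    {"input": {"vector": "vector.fasta",
               "JD": {"fasta": "jd.fasta", "qual": "jd.qual"},
               "JG": {"fasta": "jg.fasta", "qual": "jg.qual"}}},
    "out")
```

The run summary (`out/summary.json`) reports:

```json
{
  "contigs": 165,
  "input_reads": 1450,
  "library_totals": {"JD": 800, "JG": 650},
  "mean_trimmed_length": 531.3,
  "singletons": 21,
  "total_ests": 1450,
  "trimmed_reads": 1450,
  "unisequences": 186
}
```

All 1,450 reads retain a ≥100 bp clean region (noise here is mild), and the
186 unisequences are fewer than the 200 transcripts because the skewed
abundances leave some transcripts unsampled. The top of `out/de.tsv`:

```text
unisequence_id  count_JD  count_JG  norm_JD  norm_JG  p          direction
Contig3         15        0         187.50   0.00     1.474e-04  A-enriched
Contig40        5         15        62.50    230.76   7.126e-03  B-enriched
Contig43        7         0         87.50    0.00     1.717e-02  A-enriched
Contig1         6         0         75.00    0.00     3.112e-02  A-enriched
Contig162       0         4         0.00     61.53    3.620e-02  B-enriched
```

`norm_*` are counts per 10,000 library reads (truncated); `p` is the
two-tailed AC p-value. The top hit (15 vs 0 reads) is one of the five
planted transcripts, as is the 6-vs-0 row; the other three planted
transcripts drew 0–3 reads in this small run — too few for the test to see,
which is exactly the small-count power limit quantified in
`docs/methods.md`.

The same stages are available from the shell:

```sh
estdd simulate --transcripts 200 --lib JD=800 --lib JG=650 --seed 1 --out sim/
estdd clean --in sim/JD.fasta --qual sim/JD.qual --library JD --vector sim/vector.fasta --out work/
estdd cluster --in work/trimmed_JD.fasta --qual work/trimmed_JD.qual \
              --in work/trimmed_JG.fasta --qual work/trimmed_JG.qual --out work/
estdd de --membership work/membership.tsv --totals JD=7320,JG=5929 --out work/
estdd run --config pipeline.toml --out out/
```

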