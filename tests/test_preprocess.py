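"""Cleaning stage: each masker against a brute-force oracle, plus pipeline
invariants (clean region maximality, idempotence, planted-core recovery)."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from _oracles import longest_clean, purity_union, windows_below
from conftest import random_dna
from estdd.model import LibraryModel, Read
from estdd.preprocess import (
    CleaningConfig,
    clean_read,
    clean_reads,
    detect_slippage,
    extract_clean_region,
    mask_homopolymer_tails,
    mask_low_quality,
    mask_vector,
    merge_intervals,
)
from estdd.simulate import DEFAULT_VECTOR, simulate_library, simulate_transcriptome


def flat_read(bases: str, q: int = 40, rid: str = "r", lib: str = "JD") -> Read:
    return Read(rid, lib, bases, [q] * len(bases))


class TestLowQuality:
    def test_uniformly_high_and_low(self):
        assert mask_low_quality(flat_read("A" * 50, 40), 10, 20) == []
        assert mask_low_quality(flat_read("A" * 50, 5), 10, 20) == [(0, 50)]

    def test_dip_matches_exhaustive_window_evaluation(self):
        quals = [40] * 50 + [2] * 10 + [40] * 40
        read = Read("r", "JD", "A" * 100, quals)
        assert mask_low_quality(read, 10, 20) == windows_below(quals, 10, 20)

    @given(st.lists(st.integers(0, 60), min_size=1, max_size=80), st.integers(2, 12))
    def test_agrees_with_bruteforce(self, quals, window):
        quals = [min(q, 93) for q in quals]
        read = Read("r", "JD", "A" * len(quals), quals)
        assert mask_low_quality(read, window, 20) == windows_below(quals, window, 20)


class TestHomopolymer:
    def test_no_run(self):
        assert mask_homopolymer_tails(flat_read("ACGT" * 50), 12, 0.9) == []

    def test_pure_terminal_run(self):
        read = flat_read("ACGTC" * 6 + "A" * 20)
        masks = mask_homopolymer_tails(read, 12, 0.9)
        assert len(masks) == 1
        s, e, cause = masks[0]
        assert cause == "polyA" and s <= 30 and e == 50

    def test_impure_tail_matches_exhaustive_substring_scan(self):
        seq = "CGCGTGCGTCGTGCGTGTGCGTGCGTCGCG" + "AAAAACAAAAAACAAAAA"
        read = flat_read(seq)
        got = [(s, e) for s, e, c in mask_homopolymer_tails(read, 12, 0.88) if c == "polyA"]
        assert got == purity_union(seq, "A", 12, 0.88)
        assert len(got) == 1

    def test_polyt_reported_with_own_cause(self):
        seq = "T" * 20 + "GCGCA" * 20
        masks = mask_homopolymer_tails(flat_read(seq), 12, 0.9)
        assert masks == [(s, e, "polyT") for s, e in purity_union(seq, "T", 12, 0.9)]
        assert masks[0][:2] == (0, 22)  # maximal extension spans the 0.909-pure "GC"

    @given(st.integers(0, 2**31 - 1))
    def test_union_matches_bruteforce_on_random_tails(self, seed):
        rng = np.random.default_rng(seed)
        # A-rich tail appended to random core: the hard case for maximality
        core = random_dna(int(rng.integers(20, 60)), rng)
        tail = "".join(rng.choice(list("ACGT"), p=[0.85, 0.05, 0.05, 0.05], size=30))
        seq = core + tail
        read = flat_read(seq)
        for base, cause in (("A", "polyA"), ("T", "polyT")):
            got = [(s, e) for s, e, c in mask_homopolymer_tails(read, 12, 0.9) if c == cause]
            assert got == purity_union(seq, base, 12, 0.9)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            mask_homopolymer_tails(flat_read("ACGT"), 4, 0.9)
        with pytest.raises(ValueError):
            mask_homopolymer_tails(flat_read("ACGT"), 12, 0.4)


class TestVector:
    def test_exact_hit_covered(self, rng):
        frag = DEFAULT_VECTOR[-40:]
        seq = random_dna(100, rng) + frag + random_dna(100, rng)
        masks = mask_vector(flat_read(seq), [DEFAULT_VECTOR], 0.9, 20)
        assert len(masks) == 1
        s, e = masks[0]
        assert s <= 100 and e >= 140 and e - s >= 40

    def test_unrelated_vector_no_hit(self, rng):
        read = flat_read(random_dna(500, rng))
        vec = random_dna(100, rng)
        assert mask_vector(read, [vec], 0.95, 20) == []

    def test_pure_vector_read_fails_downstream(self):
        read = flat_read(DEFAULT_VECTOR)
        rep = clean_read(read, [DEFAULT_VECTOR])
        assert not rep.passed and rep.clean_region is None

    def test_two_disjoint_hits_both_masked(self, rng):
        frag = DEFAULT_VECTOR[-35:]
        seq = frag + random_dna(200, rng) + frag
        masks = mask_vector(flat_read(seq), [DEFAULT_VECTOR], 0.9, 20)
        assert len(masks) == 2


class TestSlippage:
    def test_exact_echo_masks_one_copy(self, rng):
        P = random_dna(30, rng)
        read = flat_read(P + P + random_dna(100, rng))
        assert detect_slippage(read, 30, 200, 0.9) == [(0, 30)]

    def test_random_read_clean(self, rng):
        read = flat_read(random_dna(500, rng))
        assert detect_slippage(read, 30, 200, 0.9) == []

    def test_below_identity_threshold_ignored(self, rng):
        P = random_dna(30, rng)
        echo = list(P)
        for i in range(0, 30, 5):  # 6 mismatches -> identity 0.8
            echo[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[echo[i]]
        read = flat_read(P + "".join(echo) + random_dna(80, rng))
        assert detect_slippage(read, 30, 200, 0.9) == []


class TestCleanRegion:
    def test_unmasked_read_passes_whole(self):
        read = flat_read("G" * 848)
        rep = extract_clean_region(read, [], 100)
        assert rep.clean_region == (0, 848) and rep.passed

    def test_99_clean_bases_discarded(self):
        read = flat_read("C" * 119)
        rep = extract_clean_region(read, [(0, 10), (109, 119)], 100)
        assert rep.clean_region == (10, 109) and not rep.passed

    def test_two_masks_spec_layout(self):
        read = flat_read("A" * 120)
        rep = extract_clean_region(read, [(0, 10), (50, 60)], 100)
        assert rep.clean_region == (60, 120) and not rep.passed

    def test_leftmost_on_ties(self):
        read = flat_read("A" * 50)
        rep = extract_clean_region(read, [(20, 30)], 10)
        assert rep.clean_region == (0, 20)

    @given(st.integers(0, 2**31 - 1))
    def test_matches_bruteforce_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        length = int(rng.integers(5, 80))
        masks = []
        for _ in range(int(rng.integers(0, 5))):
            s = int(rng.integers(0, length))
            masks.append((s, int(rng.integers(s, length + 1))))
        rep = extract_clean_region(flat_read("A" * length), masks, 10)
        assert rep.clean_region == longest_clean(length, masks)

    def test_out_of_bounds_mask_rejected(self):
        with pytest.raises(ValueError):
            extract_clean_region(flat_read("A" * 10), [(0, 11)], 5)


@pytest.fixture(scope="module")
def sim_reads():
    txs = simulate_transcriptome(10, (700, 60), seed=31)
    ab = {t.id: 0.1 for t in txs}
    model = LibraryModel("JD", 80, ab, error_rate=0.0, seed=32)
    reads, _ = simulate_library(txs, model)
    return reads


class TestPipeline:
    def test_planted_core_recovered(self, rng):
        # vector + clean core + polyA at uniform high quality: the clean
        # region starts exactly at the planted core; the 3' boundary may be
        # clipped by at most the poly-A masker's maximal-extension allowance
        # (a run of L extra As tolerates ~L*(1-p)/p adjacent clean bases),
        # and must match the brute-force mask oracle exactly
        for _ in range(20):
            vec = DEFAULT_VECTOR[-int(rng.integers(30, 61)) :]
            core = random_dna(int(rng.integers(150, 400)), rng)
            tail = "A" * int(rng.integers(15, 41))
            seq = vec + core + tail
            read = flat_read(seq)
            rep = clean_read(read, [DEFAULT_VECTOR])
            assert rep.passed
            oracle_masks = [(0, len(vec))]
            oracle_masks += purity_union(seq, "A", 12, 0.9)
            oracle_masks += purity_union(seq, "T", 12, 0.9)
            assert rep.clean_region == longest_clean(len(seq), oracle_masks)
            s, e = rep.clean_region
            core_end = len(vec) + len(core)
            assert s == len(vec)
            assert 0 <= core_end - e <= 30

    def test_clean_region_never_intersects_masks(self, sim_reads):
        for read in sim_reads:
            rep = clean_read(read, [DEFAULT_VECTOR])
            if rep.clean_region is None:
                continue
            s, e = rep.clean_region
            for ms, me, _ in rep.masks:
                assert me <= s or ms >= e

    def test_idempotent_on_survivors(self, sim_reads):
        survivors, _, _ = clean_reads(sim_reads, [DEFAULT_VECTOR])
        assert survivors
        again, reports, _ = clean_reads(survivors, [DEFAULT_VECTOR])
        assert len(again) == len(survivors)
        for before, after, rep in zip(survivors, again, reports):
            assert rep.clean_region == (0, len(before))
            assert after.bases == before.bases and after.quals == before.quals

    def test_survivor_length_floor_and_count(self, sim_reads):
        survivors, reports, summary = clean_reads(sim_reads, [DEFAULT_VECTOR])
        assert len(survivors) <= len(sim_reads)
        assert all(len(r) >= 100 for r in survivors)
        assert summary["survivors"] + summary["discarded"] == summary["input"]

    def test_trimmed_read_records_origin(self, sim_reads):
        survivors, reports, _ = clean_reads(sim_reads, [DEFAULT_VECTOR])
        by_id = {rep.read_id: rep for rep in reports}
        for r in survivors:
            assert r.annotations["origin"] == by_id[r.id].clean_region


def test_merge_intervals_basic():
    assert merge_intervals([(5, 9), (0, 3), (2, 6), (12, 12)]) == [(0, 9)]
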