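"""Anchor scanning, tag extraction, error correction, and tabulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonetrace.extract import (
    DEFAULT_ANCHOR,
    MULTIPLET,
    UNASSIGNED,
    AnchorConfig,
    ReadRecord,
    assign_clones,
    build_cell_clone_table,
    correct_tags,
    extract_clone_tag,
    locate_anchor,
    reconstruct_full_barcode,
    revcomp,
)
from clonetrace.synth import ReadSimConfig, simulate_reads

from conftest import random_dna

DOMINANT_TAG = "GTTGAACGACCACAA"  # 15-nt 3' suffix of a known dominant clone


def brute_force_scan(seq: str, anchor: str):
    """All-window Hamming oracle: (leftmost min position, mismatches)."""
    la = len(anchor)
    if len(seq) < la:
        return None
    best = None
    for i in range(len(seq) - la + 1):
        m = sum(a != b for a, b in zip(seq[i : i + la], anchor))
        if best is None or m < best[1]:
            best = (i, m)
    return best


class TestLocateAnchor:
    def test_exact_placement(self, anchor):
        hit = locate_anchor("GG" + anchor + "TT", AnchorConfig(max_mismatch=0))
        assert hit == (2, "+", 0)

    def test_one_mismatch_respected(self, anchor):
        mutated = anchor[:5] + ("A" if anchor[5] != "A" else "C") + anchor[6:]
        seq = "T" * 10 + mutated + "A" * 5
        assert locate_anchor(seq, AnchorConfig(max_mismatch=1)) == (10, "+", 1)
        assert locate_anchor(seq, AnchorConfig(max_mismatch=0)) is None

    def test_reverse_strand_hit(self, anchor):
        tag = DOMINANT_TAG
        seq = revcomp("CC" + tag + anchor + "GG")
        hit = locate_anchor(seq)
        assert hit.strand == "-"
        # position is reported in the anchor-strand orientation
        assert hit.position == 2 + len(tag)
        assert hit.mismatches == 0

    def test_short_sequence_returns_none(self, anchor):
        assert locate_anchor(anchor[:10]) is None

    def test_forward_preferred_on_tie(self, anchor):
        # A palindromic-free anchor present exactly on both strands: forward wins.
        seq = anchor + "AAAA" + revcomp(anchor)
        assert locate_anchor(seq).strand == "+"

    def test_matches_brute_force_on_random_fixtures(self, anchor, rng):
        cfg = AnchorConfig(scan_revcomp=False, max_mismatch=2)
        for _ in range(300):
            seq = random_dna(rng, 120)
            if rng.random() < 0.5:  # implant a corrupted anchor
                pos = rng.integers(0, 120 - len(anchor))
                a = list(anchor)
                for j in rng.choice(len(anchor), size=rng.integers(0, 3), replace=False):
                    a[j] = "ACGT"[rng.integers(4)]
                seq = seq[:pos] + "".join(a) + seq[pos + len(anchor) :]
            expected = brute_force_scan(seq, anchor)
            hit = locate_anchor(seq, cfg)
            if expected[1] <= 2:
                assert (hit.position, hit.mismatches) == expected
            else:
                assert hit is None


class TestExtractCloneTag:
    def test_named_dominant_clone_tag(self, anchor):
        read = ReadRecord("r1", random_dna(np.random.default_rng(0), 30) + DOMINANT_TAG + anchor)
        assert extract_clone_tag(read) == DOMINANT_TAG

    def test_truncated_read_yields_none(self, anchor):
        assert extract_clone_tag(ReadRecord("r1", anchor)) is None

    def test_reverse_complemented_read_same_tag(self, anchor):
        fwd = random_dna(np.random.default_rng(1), 20) + DOMINANT_TAG + anchor + "ACGT"
        assert extract_clone_tag(ReadRecord("r", revcomp(fwd))) == DOMINANT_TAG

    def test_after_anchor_side(self, anchor):
        cfg = AnchorConfig(tag_side="after_anchor")
        read = ReadRecord("r", "GG" + anchor + DOMINANT_TAG + "TT")
        assert extract_clone_tag(read, cfg) == DOMINANT_TAG

    def test_ambiguous_base_discarded(self, anchor):
        tag = DOMINANT_TAG[:-1] + "N"
        assert extract_clone_tag(ReadRecord("r", "AC" + tag + anchor)) is None


class TestCorrectTags:
    def test_shadow_merged_into_parent(self):
        t1, t2 = "A" * 14 + "T", "A" * 15  # Hamming 1
        corrected, log = correct_tags({t1: 100, t2: 1})
        assert corrected == {t1: 101}
        assert log == [(t2, t1, 1)]

    def test_coabundant_tags_untouched(self):
        t1, t2 = "A" * 15, "A" * 14 + "T"
        corrected, _ = correct_tags({t1: 10, t2: 10})
        assert corrected == {t1: 10, t2: 10}

    def test_singleton_identity(self):
        assert correct_tags({"ACGTA": 3}) == ({"ACGTA": 3}, [])

    def test_boundary_of_ratio_rule(self):
        # count(a) >= 2*count(b) - 1: 19 vs 10 merges, 18 vs 10 does not.
        a, b = "C" * 15, "C" * 14 + "G"
        assert correct_tags({a: 19, b: 10})[0] == {a: 29}
        assert correct_tags({a: 18, b: 10})[0] == {a: 18, b: 10}

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            correct_tags({"AAA": 2, "AAAA": 1})

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_conserves_counts_idempotent_order_free(self, seed):
        rng = np.random.default_rng(seed)
        base = [random_dna(rng, 8) for _ in range(5)]
        counts = {}
        for t in base:
            counts[t] = counts.get(t, 0) + int(rng.integers(5, 200))
            for _ in range(rng.integers(0, 4)):  # sprinkle 1-off shadows
                i = rng.integers(8)
                shadow = t[:i] + "ACGT"[rng.integers(4)] + t[i + 1 :]
                if shadow not in counts:
                    counts[shadow] = int(rng.integers(1, 4))
        corrected, _ = correct_tags(counts)
        assert sum(corrected.values()) == sum(counts.values())
        again, log2 = correct_tags(corrected)
        assert again == corrected and log2 == []
        shuffled = dict(sorted(counts.items(), key=lambda kv: kv[0], reverse=True))
        assert correct_tags(shuffled)[0] == corrected


class TestBuildTable:
    def test_three_reads_one_cell(self, anchor):
        reads = [
            ReadRecord(f"r{i}", "AC" + DOMINANT_TAG + anchor, cell_tag="AACCGGTT", umi=u)
            for i, u in enumerate(["AAA", "CCC", "GGG"])
        ]
        res = build_cell_clone_table(reads)
        assert res.table.to_dict("records") == [
            {"cell_tag": "AACCGGTT", "clone_tag": DOMINANT_TAG, "read_count": 3, "umi_count": 3}
        ]

    def test_error_free_round_trip(self):
        sim = simulate_reads(ReadSimConfig(n_clones=25, cells_per_clone=4,
                                           reads_per_cell=3, error_rate=0.0, seed=2))
        res = build_cell_clone_table(sim.reads)
        assert res.table.equals(sim.truth_table)

    def test_strand_invariance(self):
        sim = simulate_reads(ReadSimConfig(n_clones=10, cells_per_clone=2,
                                           reads_per_cell=2, error_rate=0.01, seed=3))
        res = build_cell_clone_table(sim.reads)
        flipped = [
            ReadRecord(r.read_id, revcomp(r.sequence), r.cell_tag, r.umi)
            for r in sim.reads
        ]
        res_flipped = build_cell_clone_table(flipped)
        assert res.table.equals(res_flipped.table)

    def test_reads_without_cell_tag_counted_not_tabulated(self, anchor):
        reads = [
            ReadRecord("r1", "AC" + DOMINANT_TAG + anchor, cell_tag="AACCGGTT", umi="AAA"),
            ReadRecord("r2", "AC" + DOMINANT_TAG + anchor),
        ]
        res = build_cell_clone_table(reads)
        assert res.n_no_cell_tag == 1
        assert len(res.table) == 1

    def test_noisy_round_trip_recovers_pairs(self):
        sim = simulate_reads(ReadSimConfig(n_clones=30, cells_per_clone=4,
                                           reads_per_cell=6, error_rate=0.01, seed=4))
        res = build_cell_clone_table(sim.reads)
        truth_pairs = set(zip(sim.truth_table.cell_tag, sim.truth_table.clone_tag))
        got_pairs = set(zip(res.table.cell_tag, res.table.clone_tag))
        recovered = len(truth_pairs & got_pairs) / len(truth_pairs)
        assert recovered >= 0.99


class TestAssignClones:
    def _table(self, rows):
        import pandas as pd

        return pd.DataFrame(rows, columns=["cell_tag", "clone_tag", "read_count", "umi_count"])

    def test_single_candidate(self):
        t = self._table([("c1", "T1", 12, 10)])
        out = assign_clones(t)
        assert out.loc[0, "assignment"] == "T1"

    def test_multiplet_rule(self):
        t = self._table([("c1", "T1", 12, 10), ("c1", "T2", 10, 9)])
        assert assign_clones(t).loc[0, "assignment"] == MULTIPLET

    def test_dominant_clone_when_second_is_minor(self):
        t = self._table([("c1", "T1", 100, 100), ("c1", "T2", 3, 3)])
        assert assign_clones(t).loc[0, "assignment"] == "T1"

    def test_unassigned_below_min_umi(self):
        t = self._table([("c1", "T1", 1, 1)])
        assert assign_clones(t, min_umi=2).loc[0, "assignment"] == UNASSIGNED

    def test_read_counts_used_without_umis(self):
        t = self._table([("c1", "T1", 5, 0)])
        assert assign_clones(t, min_umi=2).loc[0, "assignment"] == "T1"


class TestReconstruct:
    def test_identical_reads_full_cover(self, anchor, rng):
        body = random_dna(rng, 250)
        barcode = body + DOMINANT_TAG
        reads = [ReadRecord(f"r{i}", barcode + anchor) for i in range(3)]
        assert reconstruct_full_barcode(reads, DOMINANT_TAG) == barcode

    def test_majority_vote_restores_base(self, anchor, rng):
        body = random_dna(rng, 250)
        barcode = body + DOMINANT_TAG
        mutated = ("A" if body[0] != "A" else "C") + barcode[1:]
        reads = [
            ReadRecord("r1", barcode + anchor),
            ReadRecord("r2", barcode + anchor),
            ReadRecord("r3", mutated + anchor),
        ]
        assert reconstruct_full_barcode(reads, DOMINANT_TAG) == barcode

    def test_uncovered_positions_are_n(self, anchor):
        # reads only cover the 15-nt tag abutting the anchor
        reads = [ReadRecord("r1", DOMINANT_TAG + anchor)]
        out = reconstruct_full_barcode(reads, DOMINANT_TAG)
        assert len(out) == 265
        assert out[:250] == "N" * 250
        assert out[250:] == DOMINANT_TAG

    def test_no_matching_reads_rejected(self, anchor):
        reads = [ReadRecord("r1", DOMINANT_TAG + anchor)]
        with pytest.raises(ValueError, match="no read"):
            reconstruct_full_barcode(reads, "A" * 15)

    def test_vote_tie_is_n(self, anchor, rng):
        body = random_dna(rng, 250)
        barcode = body + DOMINANT_TAG
        alt = ("A" if body[0] != "A" else "C") + barcode[1:]
        reads = [ReadRecord("r1", barcode + anchor), ReadRecord("r2", alt + anchor)]
        out = reconstruct_full_barcode(reads, DOMINANT_TAG)
        assert out[0] == "N" and out[1:] == barcode[1:]
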