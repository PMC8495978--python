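"""Demultiplexing: linker location, barcode windows, correction, merging."""

import numpy as np
import pytest

from oracles import correct_barcode_oracle, levenshtein
from conftest import build_read

from splitlr.demux import (
    DemuxStatus,
    Orientation,
    assign_cell,
    assign_priming,
    correct_barcode,
    demux_read,
    demux_reads,
    extract_barcodes,
    locate_linkers,
    merge_priming_pairs,
    reverse_complement,
    status_counts,
    trimmed_read,
)
from splitlr.layout import Priming
from splitlr.simulate import simulate_barcoded_reads


def pick_barcodes(layout):
    r1 = sorted(layout.rounds[0].whitelist.values())[0]
    r2 = sorted(layout.rounds[1].whitelist.values())[0]
    r3 = sorted(layout.rounds[2].whitelist.values())[0]
    return r1, r2, r3


class TestLocateLinkers:
    def test_exact_construction_forward(self, tiny_layout):
        bc1, bc2, bc3 = pick_barcodes(tiny_layout)
        read = build_read(tiny_layout, bc1, bc2, bc3, "A" * 10, "G" * 50)
        hits = locate_linkers(read, tiny_layout)
        assert hits is not None and hits.orientation is Orientation.FORWARD
        l1, l2 = tiny_layout.linkers
        l1_start = 50 + 10 + 8
        assert hits.spans[0] == (l1_start, l1_start + len(l1))
        l2_start = l1_start + len(l1) + 8
        assert hits.spans[1] == (l2_start, l2_start + len(l2))
        assert hits.total_errors == 0

    def test_reverse_complement_symmetry(self, tiny_layout):
        bc1, bc2, bc3 = pick_barcodes(tiny_layout)
        read = build_read(tiny_layout, bc1, bc2, bc3, "A" * 10, "G" * 50)
        hits = locate_linkers(reverse_complement(read), tiny_layout)
        assert hits is not None
        assert hits.orientation is Orientation.REVERSE_COMPLEMENT
        # spans refer to the oriented (re-complemented) read: identical hits
        fwd = locate_linkers(read, tiny_layout)
        assert hits.spans == fwd.spans

    def test_linker_over_error_budget_fails(self, tiny_layout):
        bc1, bc2, bc3 = pick_barcodes(tiny_layout)
        l1 = tiny_layout.linkers[0]
        broken = "T" + l1[1] + "A" + l1[3:-1] + ("A" if l1[-1] != "A" else "C")
        assert levenshtein(broken, l1) == 3  # 3 substitutions > budget of 2
        read = "G" * 50 + "A" * 10 + bc3 + broken + bc2 + tiny_layout.linkers[1] + bc1
        assert locate_linkers(read, tiny_layout) is None

    def test_empty_read_rejected(self, tiny_layout):
        with pytest.raises(ValueError):
            locate_linkers("", tiny_layout)


class TestExtractBarcodes:
    def test_exact_recovery(self, tiny_layout):
        bc1, bc2, bc3 = pick_barcodes(tiny_layout)
        umi = "ACGTACGTAC"
        read = build_read(tiny_layout, bc1, bc2, bc3, umi, "G" * 40)
        hits = locate_linkers(read, tiny_layout)
        (r1, r2, r3), got_umi, trim_end = extract_barcodes(read, hits, tiny_layout)
        assert (r1, r2, r3) == (bc1, bc2, bc3)
        assert got_umi == umi
        assert trim_end == 40

    def test_insertion_in_linker_shifts_windows(self, tiny_layout):
        bc1, bc2, bc3 = pick_barcodes(tiny_layout)
        umi = "ACGTACGTAC"
        l1, l2 = tiny_layout.linkers
        l1_ins = l1[:8] + "A" + l1[8:]
        read = "G" * 40 + umi + bc3 + l1_ins + bc2 + l2 + bc1
        hits = locate_linkers(read, tiny_layout)
        assert hits is not None
        (r1, r2, r3), got_umi, _ = extract_barcodes(read, hits, tiny_layout)
        assert (r1, r2, r3) == (bc1, bc2, bc3)
        assert got_umi == umi

    def test_too_short_read_fails(self, tiny_layout):
        bc1, bc2, bc3 = pick_barcodes(tiny_layout)
        # no cDNA and no UMI: the UMI window would start before the read
        read = bc3 + tiny_layout.linkers[0] + bc2 + tiny_layout.linkers[1] + bc1
        rec = demux_read("r", read, tiny_layout)
        assert rec.status is DemuxStatus.NO_LINKERS


class TestCorrectBarcode:
    WL = {"AAAAAAAA", "CCCCCCCC"}

    def test_single_substitution(self):
        assert correct_barcode("AAAAAAAT", self.WL, 3) == ("AAAAAAAA", "OK")

    def test_beyond_budget_uncorrectable(self):
        # distance 4 to both entries, above the budget of 3
        assert correct_barcode("AAAACCCC", self.WL, 3) == (None, "UNCORRECTABLE")

    def test_identity(self):
        assert correct_barcode("CCCCCCCC", self.WL, 3) == ("CCCCCCCC", "OK")

    def test_tie_is_ambiguous(self):
        assert correct_barcode("AACC", {"AAAA", "CCCC"}, 3) == (None, "AMBIGUOUS")

    def test_empty_whitelist_error(self):
        with pytest.raises(ValueError):
            correct_barcode("AAAA", set(), 3)

    def test_agrees_with_brute_force_oracle(self, layout):
        rng = np.random.default_rng(5)
        whitelist = sorted(layout.rounds[0].whitelist.values())
        assert len(whitelist) <= 96
        bases = np.array(list("ACGT"))
        for _ in range(300):
            if rng.random() < 0.5:
                raw = "".join(rng.choice(bases, size=rng.integers(12, 20)))
            else:  # corrupted whitelist entry
                raw = list(whitelist[rng.integers(len(whitelist))])
                for _ in range(rng.integers(0, 6)):
                    raw[rng.integers(len(raw))] = str(bases[rng.integers(4)])
                raw = "".join(raw)
            assert correct_barcode(raw, whitelist, 3) == correct_barcode_oracle(
                raw, whitelist, 3
            )


class TestCellAssignment:
    def _ok_record(self, tiny_layout):
        bc1, bc2, bc3 = pick_barcodes(tiny_layout)
        read = build_read(tiny_layout, bc1, bc2, bc3, "A" * 10, "G" * 30)
        return demux_read("r", read, tiny_layout), (bc1, bc2, bc3)

    def test_combo_present_is_ok(self, tiny_layout):
        rec, triple = self._ok_record(tiny_layout)
        assert rec.status is DemuxStatus.OK

    def test_combo_absent_filtered(self, tiny_layout):
        bc1, bc2, bc3 = pick_barcodes(tiny_layout)
        read = build_read(tiny_layout, bc1, bc2, bc3, "A" * 10, "G" * 30)
        rec = demux_read("r", read, tiny_layout, illumina_combos={("X", "Y", "Z")})
        assert rec.status is DemuxStatus.NOT_IN_ILLUMINA
        assert rec.cell_id is None

    def test_filter_disabled_passes_all(self, tiny_layout):
        rec, _ = self._ok_record(tiny_layout)  # illumina_combos=None
        assert rec.status is DemuxStatus.OK and rec.cell_id is not None

    def test_priming_lookup(self, tiny_layout):
        assert assign_priming("AAAAAAAA", tiny_layout) is Priming.OLIGO_DT
        assert assign_priming("CCCCCCCC", tiny_layout) is Priming.RANDOM_HEXAMER
        with pytest.raises(KeyError):
            assign_priming("NNNNNNNN", tiny_layout)


class TestMergePrimingPairs:
    def test_pair_collapses_to_one_cell_and_partition_inverts(self, tiny_layout):
        reads = []
        for i in range(10):
            reads.append((f"dt{i}", build_read(tiny_layout, "AAAAAAAA", "ACACACAC", "AACCGGTT", "A" * 10, "G" * 30)))
        for i in range(5):
            reads.append((f"hx{i}", build_read(tiny_layout, "CCCCCCCC", "ACACACAC", "AACCGGTT", "A" * 10, "G" * 30)))
        for i in range(3):
            reads.append((f"w2{i}", build_read(tiny_layout, "GGGGGGGG", "GTGTGTGT", "AACCGGTT", "A" * 10, "G" * 30)))
        recs = demux_reads(reads, tiny_layout, merge_wells=True)
        cells = {}
        for r in recs:
            cells.setdefault(r.cell_id, []).append(r)
        assert len(cells) == 2
        merged = cells["w01_ACACACAC_AACCGGTT"]
        assert len(merged) == 15
        by_priming = {p: sum(1 for r in merged if r.priming is p) for p in (Priming.OLIGO_DT, Priming.RANDOM_HEXAMER)}
        assert by_priming == {Priming.OLIGO_DT: 10, Priming.RANDOM_HEXAMER: 5}


class TestRoundTrip:
    def test_status_classes_partition_reads(self, layout):
        reads, truth, layout = simulate_barcoded_reads(
            layout=layout, n_reads=500, substitution_rate=0.03, indel_rate=0.01, seed=3
        )
        recs = demux_reads([(r[0], r[1]) for r in reads], layout)
        counts = status_counts(recs)
        assert sum(counts.values()) == len(reads)

    def test_noiseless_reads_fully_recovered(self, layout):
        reads, truth, layout = simulate_barcoded_reads(
            layout=layout, n_reads=300, substitution_rate=0.0, indel_rate=0.0, seed=4
        )
        recs = demux_reads([(r[0], r[1]) for r in reads], layout)
        tmap = dict(zip(truth.read_id, truth.cell_id))
        assert all(r.status is DemuxStatus.OK for r in recs)
        assert all(r.cell_id == tmap[r.read_id] for r in recs)

    def test_no_misassignment_under_noise(self, layout):
        reads, truth, layout = simulate_barcoded_reads(
            layout=layout, n_reads=1000, substitution_rate=0.01, indel_rate=0.002, seed=5
        )
        recs = demux_reads([(r[0], r[1]) for r in reads], layout)
        tmap = dict(zip(truth.read_id, truth.cell_id))
        ok = [r for r in recs if r.status is DemuxStatus.OK]
        assert len(ok) / len(recs) > 0.95
        assert all(r.cell_id == tmap[r.read_id] for r in ok)

    def test_orientation_symmetry(self, layout):
        reads, truth, layout = simulate_barcoded_reads(
            layout=layout, n_reads=50, substitution_rate=0.01, indel_rate=0.002, seed=6
        )
        for rid, seq, _ in reads:
            a = demux_read(rid, seq, layout)
            b = demux_read(rid, reverse_complement(seq), layout)
            assert a.status == b.status
            if a.status is DemuxStatus.OK:
                assert a.cell_id == b.cell_id and a.umi == b.umi
                assert a.orientation != b.orientation

    def test_trimmed_read_strips_barcode_block(self, tiny_layout):
        bc1, bc2, bc3 = pick_barcodes(tiny_layout)
        cdna = "G" * 37
        read = build_read(tiny_layout, bc1, bc2, bc3, "A" * 10, cdna)
        rec = demux_read("r", read, tiny_layout)
        rec = merge_priming_pairs([rec], tiny_layout)[0]
        seq, qual, suffix = trimmed_read(read, "I" * len(read), rec)
        assert seq == cdna and len(qual) == len(cdna)
        assert suffix.startswith("cell:w01_") and ";pr:dT" in suffix
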