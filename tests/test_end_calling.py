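"""End calling: novelty filters, window chaining, gene filters, validation."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest

from oracles import cluster_positions_oracle

from splitlr.end_calling import (
    EndCallConfig,
    EndPeak,
    TES_NOVELTY,
    TSS_NOVELTY,
    assign_peak_gene,
    call_end_peaks,
    call_ends,
    collect_end_positions,
    filter_peaks_by_gene_fraction,
    filter_reads_by_novelty,
    intersect_with_validation,
    name_peaks,
    short_read_tes_filter,
    short_read_tss_filter,
)
from splitlr.simulate import GeneModel, simulate_end_annotations


def make_annotations(rows):
    cols = ["read_id", "cell_id", "chrom", "strand", "five_prime_pos",
            "three_prime_pos", "gene_id", "transcript_id", "novelty", "priming", "dataset"]
    df = pd.DataFrame(rows, columns=["chrom", "strand", "five_prime_pos",
                                     "three_prime_pos", "gene_id", "novelty"])
    df["read_id"] = [f"r{i}" for i in range(len(df))]
    df["cell_id"] = "c1"
    df["transcript_id"] = "t"
    df["priming"] = "NA"
    df["dataset"] = "d"
    return df[cols]


def peak(chrom="chr1", strand="+", wide=(100, 150), summit=100, count=10,
         gene="G", name=None, end_type="TSS"):
    return EndPeak(chrom=chrom, strand=strand, wide_start=wide[0], wide_end=wide[1],
                   narrow_start=max(wide[0], summit - 25), narrow_end=min(wide[1], summit + 26),
                   summit=summit, read_count=count, end_type=end_type, gene_id=gene, name=name)


class TestNoveltyFilter:
    def test_tss_drops_genomic_and_suffix_ism(self):
        df = make_annotations([
            ("chr1", "+", 100, 500, "G", "KNOWN"),
            ("chr1", "+", 100, 500, "G", "GENOMIC"),
            ("chr1", "+", 100, 500, "G", "ISM_PREFIX"),
            ("chr1", "+", 100, 500, "G", "ISM_SUFFIX"),
        ])
        tss = filter_reads_by_novelty(df, EndCallConfig.tss_single_cell())
        assert sorted(tss["novelty"]) == ["ISM_PREFIX", "KNOWN"]
        tes = filter_reads_by_novelty(df, EndCallConfig.tes())
        assert sorted(tes["novelty"]) == ["ISM_SUFFIX", "KNOWN"]

    def test_empty_input(self):
        df = make_annotations([])
        assert len(filter_reads_by_novelty(df, EndCallConfig.tss_single_cell())) == 0

    def test_novelty_sets_match_end_semantics(self):
        assert "ISM_PREFIX" in TSS_NOVELTY and "ISM_SUFFIX" not in TSS_NOVELTY
        assert "ISM_SUFFIX" in TES_NOVELTY and "ISM_PREFIX" not in TES_NOVELTY


class TestCollectEndPositions:
    def test_counts_and_strand_separation(self):
        df = make_annotations([
            ("chr1", "+", 100, 500, "G", "KNOWN"),
            ("chr1", "+", 100, 500, "G", "KNOWN"),
            ("chr1", "+", 100, 500, "G", "KNOWN"),
            ("chr1", "-", 100, 50, "H", "KNOWN"),
        ])
        out = collect_end_positions(df, "TSS")
        assert sum(out[("chr1", "+")][100].values()) == 3
        assert sum(out[("chr1", "-")][100].values()) == 1

    def test_tes_uses_three_prime_field(self):
        df = make_annotations([("chr1", "-", 500, 200, "G", "KNOWN")])
        out = collect_end_positions(df, "TES")
        assert list(out[("chr1", "-")]) == [200]


class TestCallEndPeaks:
    def as_counts(self, d, key=("chr1", "+")):
        return {key: {p: Counter({"G": c}) for p, c in d.items()}}

    def test_two_clusters_with_summits(self):
        cfg = EndCallConfig.tss_single_cell()
        peaks = call_end_peaks(self.as_counts({100: 5, 103: 3, 400: 4}), cfg)
        assert len(peaks) == 2
        p1, p2 = peaks
        assert (p1.summit, p1.read_count, p1.wide_start, p1.wide_end) == (100, 8, 100, 104)
        assert (p2.summit, p2.read_count, p2.wide_start, p2.wide_end) == (400, 4, 400, 401)

    def test_min_reads_drops_singletons(self):
        cfg = EndCallConfig.tss_single_cell()
        assert call_end_peaks(self.as_counts({100: 1}), cfg) == []
        assert len(call_end_peaks(self.as_counts({100: 2}), cfg)) == 1

    def test_gap_boundary_at_window_size(self):
        cfg = EndCallConfig.tss_single_cell()
        assert len(call_end_peaks(self.as_counts({100: 2, 151: 2}), cfg)) == 2
        assert len(call_end_peaks(self.as_counts({100: 2, 150: 2}), cfg)) == 1

    def test_summit_tie_breaks_to_five_prime_most(self):
        cfg = EndCallConfig.tss_single_cell()
        plus = call_end_peaks(self.as_counts({100: 3, 110: 3}), cfg)[0]
        minus = call_end_peaks(self.as_counts({100: 3, 110: 3}, key=("chr1", "-")), cfg)[0]
        assert plus.summit == 100 and minus.summit == 110

    def test_matches_exhaustive_oracle_on_random_instances(self):
        rng = np.random.default_rng(11)
        cfg = EndCallConfig.tss_single_cell()
        for _ in range(200):
            n = rng.integers(1, 40)
            positions = np.unique(rng.integers(0, 2000, size=n))
            counts = {int(p): int(rng.integers(1, 10)) for p in positions}
            strand = "+" if rng.random() < 0.5 else "-"
            got = call_end_peaks(self.as_counts(counts, key=("chr1", strand)), cfg)
            want = cluster_positions_oracle(counts, cfg.window_size, cfg.min_reads, strand)
            assert len(got) == len(want)
            for g, w in zip(got, want):
                assert (g.wide_start, g.wide_end) == w["wide"]
                assert (g.narrow_start, g.narrow_end) == w["narrow"]
                assert g.summit == w["summit"] and g.read_count == w["count"]

    def test_count_conservation(self):
        rng = np.random.default_rng(12)
        counts = {int(p): int(rng.integers(1, 6)) for p in rng.choice(5000, 100, replace=False)}
        cfg = EndCallConfig(end_type="TSS", min_reads=1)
        peaks = call_end_peaks(self.as_counts(counts), cfg)
        assert sum(p.read_count for p in peaks) == sum(counts.values())

    def test_strand_mirror_invariance(self):
        rng = np.random.default_rng(13)
        counts = {int(p): int(rng.integers(1, 6)) for p in rng.choice(3000, 50, replace=False)}
        cfg = EndCallConfig.tss_single_cell()
        M = 10_000
        mirrored = {M - p: c for p, c in counts.items()}
        fwd = call_end_peaks(self.as_counts(counts), cfg)
        rev = call_end_peaks(self.as_counts(mirrored, key=("chr1", "-")), cfg)
        assert len(fwd) == len(rev)
        for f, r in zip(fwd, rev[::-1]):
            assert r.summit == M - f.summit
            assert (r.wide_start, r.wide_end) == (M - f.wide_end + 1, M - f.wide_start + 1)
            assert r.read_count == f.read_count


class TestGeneAssignmentAndFilters:
    def test_majority_gene_wins(self):
        p = peak()
        p.gene_votes.update({"A": 7, "B": 1})
        assert assign_peak_gene(p).gene_id == "A"

    def test_tie_breaks_by_genome_wide_total(self):
        p = peak()
        p.gene_votes.update({"A": 2, "B": 2})
        assert assign_peak_gene(p, {"A": 100, "B": 50}).gene_id == "A"
        assert assign_peak_gene(p, {"A": 50, "B": 100}).gene_id == "B"

    def test_ungened_peak_dropped(self):
        p = peak()
        p.gene_votes.update({None: 5})
        assert assign_peak_gene(p) is None

    @pytest.mark.parametrize(
        "counts,fraction,kept",
        [
            ([100, 12, 9], 0.10, [100, 12]),   # 12 > 10 kept, 9 < 10 dropped
            ([100, 10], 0.10, [100]),          # 10 > 10 is false: dropped
            ([50, 41], 0.80, [50, 41]),        # TES: 41 > 40 kept
            ([50, 40], 0.80, [50]),
        ],
    )
    def test_gene_fraction_strict_inequality(self, counts, fraction, kept):
        peaks = [peak(wide=(i * 1000, i * 1000 + 10), summit=i * 1000, count=c)
                 for i, c in enumerate(counts)]
        out = filter_peaks_by_gene_fraction(peaks, fraction)
        assert sorted(p.read_count for p in out) == sorted(kept)

    def test_fraction_filter_monotone_in_threshold(self):
        rng = np.random.default_rng(21)
        peaks = [peak(wide=(i * 100, i * 100 + 10), summit=i * 100,
                      count=int(rng.integers(1, 100))) for i in range(20)]
        prev = None
        for f in (0.05, 0.1, 0.3, 0.5, 0.8, 0.95):
            kept = {(p.wide_start, p.read_count) for p in filter_peaks_by_gene_fraction(peaks, f)}
            if prev is not None:
                assert kept <= prev
            prev = kept

    def test_naming_by_summit_coordinate_and_idempotence(self):
        peaks = [peak(wide=(500, 510), summit=500), peak(wide=(100, 110), summit=100)]
        named = name_peaks(peaks)
        by_name = {p.name: p.summit for p in named}
        assert by_name == {"G_1": 100, "G_2": 500}
        assert {p.name: p.summit for p in name_peaks(named)} == by_name

    def test_single_peak_named_one(self):
        assert name_peaks([peak()])[0].name == "G_1"


class TestShortReadFilters:
    TSO = "AACGCAGAGTGAATGGG"

    def test_exact_tso_prefix(self):
        assert short_read_tss_filter(self.TSO + "ACGT" * 10)

    def test_internal_tso_allowed(self):
        assert short_read_tss_filter("TTTT" + self.TSO + "ACGT" * 10)

    def test_single_substitution_rejected(self):
        assert not short_read_tss_filter("AACGCAGAGTGAATGGA" + "ACGT" * 10)

    def test_tso_absent(self):
        assert not short_read_tss_filter("ACGT" * 20)

    def test_polya_window(self):
        assert short_read_tes_filter("AAAAAAAAAACCCCCCCCCC")
        assert not short_read_tes_filter("C" * 20)

    def test_nine_as_per_window_rejected(self):
        # A at every other position: any 20-bp window holds at most 10... use 9
        seq = ("AC" * 9 + "CC") * 3  # 9 A's per 20-bp window at most
        windows = [seq[i:i + 20] for i in range(len(seq) - 19)]
        assert max(w.count("A") for w in windows) == 9
        assert not short_read_tes_filter(seq)


class TestValidationIntersect:
    def test_one_bp_overlap_supports(self):
        p = peak(wide=(100, 150), name="G_1")
        table, summary = intersect_with_validation([p], {"ccre": [("chr1", 149, 200)]})
        assert bool(table["supported"].iloc[0])
        assert summary["fraction_supported"] == 1.0

    def test_half_open_adjacency_does_not_support(self):
        p = peak(wide=(100, 150), name="G_1")
        table, _ = intersect_with_validation([p], {"ccre": [("chr1", 150, 200)]})
        assert not bool(table["supported"].iloc[0])

    def test_upset_combination_counts(self):
        p = peak(wide=(100, 150), name="G_1")
        q = peak(wide=(5000, 5010), summit=5000, name="G_2")
        _, summary = intersect_with_validation(
            [p, q],
            {"a": [("chr1", 120, 130)], "b": [("chr1", 140, 160)]},
        )
        assert summary["upset_counts"] == {"a+b": 1, "(none)": 1}


class TestPlantedRecovery:
    def test_planted_summits_recovered_without_spurious_peaks(self):
        models = [
            GeneModel(
                gene_id=f"g{k}", chrom="chr1", strand="+",
                tss_positions=[10_000 * (k + 1), 10_000 * (k + 1) + 400],
                tss_usage=[0.5, 0.5],
                tes_positions=[10_000 * (k + 1) + 5000], tes_usage=[1.0],
                n_reads=120, jitter_sd=5.0,
            )
            for k in range(5)
        ]
        ann, _ = simulate_end_annotations(models, seed=31)
        peaks = call_ends(ann, EndCallConfig.tss_single_cell(), apply_gene_filter=False)
        planted = [p for m in models for p in m.tss_positions]
        for site in planted:
            assert any(abs(p.summit - site) <= 10 for p in peaks)
        for p in peaks:
            assert any(abs(p.summit - site) <= 50 for site in planted)
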