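"""Calling transcription start and end sites from long-read ends.

Aligned long-read 5' and 3' termini cluster around genuine TSSs and TESs.
Reads are first filtered by transcript novelty class — 5' ends are trusted
only for reads whose class preserves the transcript 5' region (known, NIC,
NNC, prefix-ISM), 3' ends for classes preserving the 3' region (known, NIC,
NNC, suffix-ISM). Surviving end positions are scanned per (chromosome,
strand) with a fixed window: consecutive distinct positions are chained into
a cluster whenever their gap is at most the window size; each cluster yields
a peak with a wide extent (full span), a narrow extent (summit +/- half
window, clipped) and a summit (the most-supported position, ties resolved to
the 5'-most base in transcript orientation).

Peaks are then filtered by absolute read support and, within each gene, by a
fraction of the read count of the gene's strongest peak (strict inequality),
and named ``<gene>_<k>`` by ascending summit coordinate.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd
from intervaltree import IntervalTree


class Novelty(str, Enum):
    KNOWN = "KNOWN"
    ISM_PREFIX = "ISM_PREFIX"
    ISM_SUFFIX = "ISM_SUFFIX"
    ISM_OTHER = "ISM_OTHER"
    NIC = "NIC"
    NNC = "NNC"
    ANTISENSE = "ANTISENSE"
    INTERGENIC = "INTERGENIC"
    GENOMIC = "GENOMIC"


TSS_NOVELTY = frozenset(
    {Novelty.KNOWN.value, Novelty.NIC.value, Novelty.NNC.value, Novelty.ISM_PREFIX.value}
)
TES_NOVELTY = frozenset(
    {Novelty.KNOWN.value, Novelty.NIC.value, Novelty.NNC.value, Novelty.ISM_SUFFIX.value}
)

#: template-switching oligo used to select short reads carrying a true 5' end
DEFAULT_TSO = "AACGCAGAGTGAATGGG"


@dataclass
class EndCallConfig:
    """Parameters of one end-calling run.

    ``gene_fraction`` is the within-gene retention threshold: a peak must
    exceed this fraction of the gene's strongest peak (strictly). ``None``
    disables the gene-level filter (short-read mode).
    """

    end_type: str = "TSS"  # "TSS" | "TES"
    window_size: int = 50
    min_reads: int = 2
    gene_fraction: Optional[float] = 0.10
    novelty_filter: frozenset = TSS_NOVELTY

    def __post_init__(self) -> None:
        if self.end_type not in ("TSS", "TES"):
            raise ValueError("end_type must be 'TSS' or 'TES'")
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        if self.gene_fraction is not None and not (0 < self.gene_fraction < 1):
            raise ValueError("gene_fraction must lie in (0, 1)")

    @classmethod
    def tss_single_cell(cls, **kw) -> "EndCallConfig":
        return cls(end_type="TSS", min_reads=2, gene_fraction=0.10, novelty_filter=TSS_NOVELTY, **kw)

    @classmethod
    def tss_bulk(cls, **kw) -> "EndCallConfig":
        return cls(end_type="TSS", min_reads=2, gene_fraction=0.05, novelty_filter=TSS_NOVELTY, **kw)

    @classmethod
    def tes(cls, **kw) -> "EndCallConfig":
        return cls(end_type="TES", min_reads=2, gene_fraction=0.80, novelty_filter=TES_NOVELTY, **kw)

    @classmethod
    def short_read(cls, end_type: str = "TSS", **kw) -> "EndCallConfig":
        # short-read mode: support-only filtering, no novelty classes available
        nov = frozenset(n.value for n in Novelty)
        return cls(end_type=end_type, min_reads=20, gene_fraction=None, novelty_filter=nov, **kw)


@dataclass
class EndPeak:
    """A called TSS or TES peak (0-based half-open coordinates)."""

    chrom: str
    strand: str
    wide_start: int
    wide_end: int
    narrow_start: int
    narrow_end: int
    summit: int
    read_count: int
    end_type: str
    gene_id: Optional[str] = None
    name: Optional[str] = None
    gene_votes: Counter = field(default_factory=Counter, repr=False, compare=False)

    def __post_init__(self) -> None:
        ok = (
            self.wide_start <= self.narrow_start <= self.summit < self.narrow_end <= self.wide_end
        )
        if not ok:
            raise ValueError(f"inconsistent peak extents: {self}")


def filter_reads_by_novelty(annotations: pd.DataFrame, config: EndCallConfig) -> pd.DataFrame:
    """Keep reads whose novelty class is trusted for this end type."""
    return annotations[annotations["novelty"].isin(config.novelty_filter)]


PositionCounts = Dict[Tuple[str, str], Dict[int, Counter]]


def collect_end_positions(annotations: pd.DataFrame, end_type: str) -> PositionCounts:
    """Tally read ends per (chrom, strand) position.

    TSS mode counts 5' positions, TES mode 3' positions; the value at each
    position is a Counter of contributing gene ids (None for un-gened reads)
    whose total is the raw read count.
    """
    col = "five_prime_pos" if end_type == "TSS" else "three_prime_pos"
    out: PositionCounts = {}
    genes = annotations["gene_id"] if "gene_id" in annotations else pd.Series(index=annotations.index, dtype=object)
    for chrom, strand, pos, gene in zip(
        annotations["chrom"], annotations["strand"], annotations[col], genes
    ):
        key = (chrom, strand)
        site = out.setdefault(key, {}).setdefault(int(pos), Counter())
        site[gene if isinstance(gene, str) and gene else None] += 1
    return out


def call_end_peaks(position_counts: PositionCounts, config: EndCallConfig) -> List[EndPeak]:
    """Chain end positions into peaks and apply the read-support filter.

    Distinct positions on one (chrom, strand) are clustered greedily left to
    right: a position joins the open cluster when its gap to the previous
    position is <= window_size. Clusters supported by fewer than
    ``config.min_reads`` reads are dropped.
    """
    half = config.window_size // 2
    peaks: List[EndPeak] = []
    for (chrom, strand) in sorted(position_counts):
        sites = position_counts[(chrom, strand)]
        positions = sorted(sites)
        clusters: List[List[int]] = []
        for pos in positions:
            if clusters and pos - clusters[-1][-1] <= config.window_size:
                clusters[-1].append(pos)
            else:
                clusters.append([pos])
        for cluster in clusters:
            counts = {p: sum(sites[p].values()) for p in cluster}
            total = sum(counts.values())
            if total < config.min_reads:
                continue
            best = max(counts.values())
            tied = [p for p in cluster if counts[p] == best]
            # 5'-most in transcript orientation: leftmost on +, rightmost on -
            summit = min(tied) if strand == "+" else max(tied)
            wide = (cluster[0], cluster[-1] + 1)
            narrow = (max(wide[0], summit - half), min(wide[1], summit + half + 1))
            votes: Counter = Counter()
            for p in cluster:
                votes.update(sites[p])
            peaks.append(
                EndPeak(
                    chrom=chrom,
                    strand=strand,
                    wide_start=wide[0],
                    wide_end=wide[1],
                    narrow_start=narrow[0],
                    narrow_end=narrow[1],
                    summit=summit,
                    read_count=total,
                    end_type=config.end_type,
                    gene_votes=votes,
                )
            )
    return peaks


def assign_peak_gene(
    peak: EndPeak, gene_totals: Optional[Mapping[str, int]] = None
) -> Optional[EndPeak]:
    """Assign the majority gene of a peak's supporting reads.

    Ties are broken by the gene's genome-wide total read count
    (``gene_totals``), then lexicographically. Returns ``None`` when no
    supporting read carries a gene (the peak is dropped).
    """
    votes = {g: c for g, c in peak.gene_votes.items() if g is not None}
    if not votes:
        return None
    best = max(votes.values())
    tied = sorted(g for g, c in votes.items() if c == best)
    if len(tied) > 1 and gene_totals:
        top_total = max(gene_totals.get(g, 0) for g in tied)
        tied = [g for g in tied if gene_totals.get(g, 0) == top_total]
    return replace(peak, gene_id=tied[0])


def filter_peaks_by_gene_fraction(peaks: Sequence[EndPeak], gene_fraction: float) -> List[EndPeak]:
    """Within each gene, keep peaks strictly above ``gene_fraction`` of the
    gene's strongest peak; the strongest peak itself is always retained."""
    by_gene: Dict[str, List[EndPeak]] = {}
    for p in peaks:
        if p.gene_id is None:
            raise ValueError("gene-fraction filtering requires gene-assigned peaks")
        by_gene.setdefault(p.gene_id, []).append(p)
    kept: List[EndPeak] = []
    for plist in by_gene.values():
        m = max(p.read_count for p in plist)
        kept.extend(p for p in plist if p.read_count == m or p.read_count > gene_fraction * m)
    kept.sort(key=lambda p: (p.chrom, p.wide_start, p.wide_end, p.strand))
    return kept


def name_peaks(peaks: Sequence[EndPeak]) -> List[EndPeak]:
    """Name peaks ``<gene>_<k>`` with k by ascending summit within each gene."""
    by_gene: Dict[str, List[EndPeak]] = {}
    for p in peaks:
        if p.gene_id is None:
            raise ValueError("naming requires gene-assigned peaks")
        by_gene.setdefault(p.gene_id, []).append(p)
    named: List[EndPeak] = []
    for gene, plist in by_gene.items():
        for k, p in enumerate(sorted(plist, key=lambda p: (p.chrom, p.summit)), start=1):
            named.append(replace(p, name=f"{gene}_{k}"))
    named.sort(key=lambda p: (p.chrom, p.wide_start, p.wide_end, p.strand))
    return named


def call_ends(
    annotations: pd.DataFrame, config: EndCallConfig, apply_gene_filter: bool = True
) -> List[EndPeak]:
    """Full end-calling pass: novelty filter, peak calling, gene assignment,
    gene-fraction filter, naming."""
    reads = filter_reads_by_novelty(annotations, config)
    gene_totals = reads["gene_id"].value_counts().to_dict() if "gene_id" in reads else {}
    counts = collect_end_positions(reads, config.end_type)
    peaks = call_end_peaks(counts, config)
    gened = [assign_peak_gene(p, gene_totals) for p in peaks]
    peaks = [p for p in gened if p is not None]
    if apply_gene_filter and config.gene_fraction is not None:
        peaks = filter_peaks_by_gene_fraction(peaks, config.gene_fraction)
    return name_peaks(peaks)


def short_read_tss_filter(read_sequence: str, tso: str = DEFAULT_TSO) -> bool:
    """True iff the full template-switching oligo occurs exactly in the read.

    Mirrors a cutadapt ``-g <TSO> -e 0 -O <len>`` query: no errors tolerated,
    the complete oligo required, internal occurrences allowed.
    """
    return tso in read_sequence.upper()


def short_read_tes_filter(read_sequence: str, window: int = 20, min_a: int = 10) -> bool:
    """True iff some ``window``-bp stretch contains at least ``min_a`` 'A's,
    the signature of an (internal or true) polyA priming site."""
    seq = read_sequence.upper()
    if len(seq) < window:
        return False
    count = sum(1 for b in seq[:window] if b == "A")
    if count >= min_a:
        return True
    for i in range(window, len(seq)):
        count += (seq[i] == "A") - (seq[i - window] == "A")
        if count >= min_a:
            return True
    return False


def intersect_with_validation(
    peaks: Sequence[EndPeak],
    validation_sets: Mapping[str, Iterable[Tuple[str, int, int]]],
) -> Tuple[pd.DataFrame, dict]:
    """Flag peaks overlapping external validation intervals by >= 1 bp.

    ``validation_sets`` maps a source name to (chrom, start, end) intervals
    (0-based half-open; strand is ignored, as validation sets are typically
    strandless region calls). Returns a per-peak flag table and a summary
    with the fraction of peaks supported by at least one source and upset
    counts per source combination.
    """
    trees: Dict[Tuple[str, str], IntervalTree] = {}
    for source, intervals in validation_sets.items():
        for chrom, start, end in intervals:
            if start >= end:
                raise ValueError(f"invalid interval {chrom}:{start}-{end}")
            trees.setdefault((source, chrom), IntervalTree()).addi(start, end)
    sources = sorted(validation_sets)
    rows = []
    upset: Counter = Counter()
    for p in peaks:
        flags = {
            s: bool(trees.get((s, p.chrom)) and trees[(s, p.chrom)].overlap(p.wide_start, p.wide_end))
            for s in sources
        }
        combo = tuple(s for s in sources if flags[s])
        upset[combo] += 1
        rows.append({"name": p.name, "chrom": p.chrom, "wide_start": p.wide_start,
                     "wide_end": p.wide_end, **flags, "supported": bool(combo)})
    table = pd.DataFrame(rows)
    n = len(peaks)
    summary = {
        "n_peaks": n,
        "fraction_supported": (table["supported"].mean() if n else float("nan")),
        "upset_counts": {"+".join(c) if c else "(none)": int(v) for c, v in sorted(upset.items())},
    }
    return table, summary
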