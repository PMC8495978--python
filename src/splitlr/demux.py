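"""Demultiplexing of combinatorially barcoded long reads.

Long reads carry the full Split-seq barcode block — three well barcodes
separated by two linker sequences, plus a UMI — at the 3' end of the cDNA.
Demultiplexing proceeds by

1. locating both linkers (semi-global alignment in a bounded window inferred
   from the layout geometry, on the read and its reverse complement);
2. reading the fixed-length barcode windows flanking the linker hits and the
   UMI distal to the round-3 barcode;
3. correcting each barcode to its round whitelist within an edit-distance
   budget (full Levenshtein: substitutions and indels, which are the dominant
   long-read error mode);
4. optionally filtering to barcode combinations observed in companion
   short-read data;
5. merging the oligo-dT and random-hexamer round-1 barcodes of each well
   into a single cell.

Every read ends up in exactly one status class, so class counts sum to the
input read count.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Set, Tuple

import edlib

from .layout import BarcodeLayout, Priming

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: slack (bp) added on each side of a linker's expected position when searching
LINKER_SEARCH_SLACK = 10


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class DemuxStatus(str, Enum):
    OK = "OK"
    NO_LINKERS = "NO_LINKERS"
    BC_UNCORRECTABLE = "BC_UNCORRECTABLE"
    BC_AMBIGUOUS = "BC_AMBIGUOUS"
    NOT_IN_ILLUMINA = "NOT_IN_ILLUMINA"


class Orientation(str, Enum):
    FORWARD = "FORWARD"
    REVERSE_COMPLEMENT = "REVERSE_COMPLEMENT"


@dataclass
class LinkerHits:
    """Placement of both linkers on the oriented read.

    Spans are 0-based half-open coordinates on the oriented read;
    ``spans[0]`` is linker 1 (5'-most), ``spans[1]`` is linker 2.
    """

    orientation: Orientation
    spans: List[Tuple[int, int]]
    edit_distances: List[int]

    @property
    def total_errors(self) -> int:
        return sum(self.edit_distances)


@dataclass
class DemuxRecord:
    read_id: str
    status: DemuxStatus
    raw_bc: Optional[Tuple[str, str, str]] = None  # (round1, round2, round3)
    corrected_bc: Optional[Tuple[Optional[str], Optional[str], Optional[str]]] = None
    umi: Optional[str] = None
    cell_id: Optional[str] = None
    priming: Priming = Priming.NA
    orientation: Optional[Orientation] = None
    trim_end: Optional[int] = None


def _search_linker(
    linker: str, read: str, expected_start: int, expected_end: int, max_errors: int
) -> Optional[Tuple[int, int, int]]:
    """Best placement of ``linker`` near its expected window, or None.

    Returns (start, end, edit_distance) with a half-open span on ``read``.
    """
    lo = max(0, expected_start - LINKER_SEARCH_SLACK - max_errors)
    hi = min(len(read), expected_end + LINKER_SEARCH_SLACK + max_errors)
    if hi - lo < len(linker) - max_errors:
        return None
    res = edlib.align(linker, read[lo:hi], mode="HW", task="locations", k=max_errors)
    if res["editDistance"] < 0:
        return None
    start, end = res["locations"][0]
    return lo + start, lo + end + 1, res["editDistance"]


def _locate_oriented(read: str, layout: BarcodeLayout) -> Optional[LinkerHits]:
    n = len(read)
    l1, l2 = layout.linkers
    len1 = layout.rounds[0].barcode_length
    len2 = layout.rounds[1].barcode_length
    # geometry anchored at the 3' end of the oriented read
    l2_end = n - len1
    l2_start = l2_end - len(l2)
    l1_end = l2_start - len2
    l1_start = l1_end - len(l1)
    hit1 = _search_linker(l1, read, l1_start, l1_end, layout.max_linker_errors)
    hit2 = _search_linker(l2, read, l2_start, l2_end, layout.max_linker_errors)
    if hit1 is None or hit2 is None:
        return None
    if hit1[1] > hit2[0]:  # overlapping or out of order
        return None
    return LinkerHits(
        orientation=Orientation.FORWARD,
        spans=[(hit1[0], hit1[1]), (hit2[0], hit2[1])],
        edit_distances=[hit1[2], hit2[2]],
    )


def locate_linkers(read_sequence: str, layout: BarcodeLayout) -> Optional[LinkerHits]:
    """Place both linkers on the read or its reverse complement.

    Tries both orientations and keeps the one with the smaller total edit
    distance (ties resolved toward FORWARD). Returns ``None`` when the
    linkers cannot be placed within ``layout.max_linker_errors`` each, in
    order and without overlap, in either orientation. Spans in the returned
    hits refer to the *oriented* read.
    """
    if not read_sequence:
        raise ValueError("empty read sequence")
    fwd = _locate_oriented(read_sequence, layout)
    rev = _locate_oriented(reverse_complement(read_sequence), layout)
    if rev is not None:
        rev = replace(rev, orientation=Orientation.REVERSE_COMPLEMENT)
    if fwd is None:
        return rev
    if rev is None or fwd.total_errors <= rev.total_errors:
        return fwd
    return rev


def extract_barcodes(
    oriented_read: str, hits: LinkerHits, layout: BarcodeLayout
) -> Optional[Tuple[Tuple[str, str, str], str, int]]:
    """Read the barcode windows flanking the linker hits.

    Returns ``((bc1, bc2, bc3), umi, trim_end)`` where barcode i is the raw
    round-i window, or ``None`` when the read is too short to contain all
    windows. Windows at the read boundary may be truncated by up to
    ``layout.max_edit_distance`` bases (a terminal deletion shortens the
    read; Levenshtein correction absorbs the missing bases). ``trim_end`` is
    the position separating the cDNA from the UMI/barcode block on the
    oriented read.
    """
    (l1s, l1e), (l2s, l2e) = hits.spans
    len1 = layout.rounds[0].barcode_length
    len2 = layout.rounds[1].barcode_length
    len3 = layout.rounds[2].barcode_length
    slack = layout.max_edit_distance
    umi_start = l1s - len3 - layout.umi_length
    if umi_start < -slack or l2e + len1 - slack > len(oriented_read):
        return None
    bc3 = oriented_read[max(0, l1s - len3) : l1s]
    bc2 = oriented_read[l1e : l1e + len2]
    bc1 = oriented_read[l2e : l2e + len1]
    umi = oriented_read[max(0, umi_start) : max(0, umi_start) + layout.umi_length]
    if min(len(bc1), len(bc2), len(bc3)) == 0:
        return None
    return (bc1, bc2, bc3), umi, max(0, umi_start)


def correct_barcode(
    raw: str, whitelist: Iterable[str], max_edit_distance: int
) -> Tuple[Optional[str], str]:
    """Correct a raw barcode to its whitelist by minimum Levenshtein distance.

    Returns ``(barcode, "OK")`` when a unique whitelist entry attains the
    minimum distance and that minimum is within budget; ``(None,
    "AMBIGUOUS")`` on a tie at the minimum; ``(None, "UNCORRECTABLE")`` when
    the minimum exceeds ``max_edit_distance``.
    """
    if not raw:
        raise ValueError("empty raw barcode")
    entries = sorted(whitelist)
    if not entries:
        raise ValueError("empty whitelist")
    best: Optional[str] = None
    best_d = None
    tied = False
    for wl in entries:
        d = edlib.align(raw, wl, mode="NW", task="distance")["editDistance"]
        if best_d is None or d < best_d:
            best, best_d, tied = wl, d, False
        elif d == best_d:
            tied = True
    assert best_d is not None
    if best_d > max_edit_distance:
        return None, "UNCORRECTABLE"
    if tied:
        return None, "AMBIGUOUS"
    return best, "OK"


def correct_barcode_windowed(
    segment: str, whitelist: Iterable[str], max_edit_distance: int
) -> Tuple[Optional[str], str]:
    """Correct a barcode by best infix match inside a padded window.

    Linker alignments can end a base or two off when errors fall on their
    boundaries, shifting the nominal fixed-length barcode window and
    inflating its apparent edit distance. Scoring each whitelist entry
    semi-globally against a slightly padded segment is insensitive to such
    shifts; the distance it finds is never larger than the fixed-window
    Levenshtein distance. Tie and budget semantics match
    :func:`correct_barcode`.
    """
    if not segment:
        raise ValueError("empty barcode segment")
    entries = sorted(whitelist)
    if not entries:
        raise ValueError("empty whitelist")
    best: Optional[str] = None
    best_d = None
    tied = False
    for wl in entries:
        d = edlib.align(wl, segment, mode="HW", task="distance")["editDistance"]
        if best_d is None or d < best_d:
            best, best_d, tied = wl, d, False
        elif d == best_d:
            tied = True
    assert best_d is not None
    if best_d > max_edit_distance:
        return None, "UNCORRECTABLE"
    if tied:
        return None, "AMBIGUOUS"
    return best, "OK"


def assign_priming(corrected_round1_bc: str, layout: BarcodeLayout) -> Priming:
    """Priming strategy encoded by the round-1 barcode (deterministic lookup)."""
    try:
        return layout.priming_map[corrected_round1_bc]
    except KeyError:
        raise KeyError(f"round-1 barcode {corrected_round1_bc!r} not in priming map") from None


def assign_cell(
    record: DemuxRecord,
    illumina_combos: Optional[Set[Tuple[str, str, str]]],
) -> DemuxRecord:
    """Filter on barcode combinations seen in companion short-read data.

    ``illumina_combos`` is a set of corrected (round1, round2, round3)
    triples; ``None`` disables the filter. On success the record receives
    status OK and a cell id joined from its corrected barcodes.
    """
    assert record.corrected_bc is not None and all(record.corrected_bc)
    triple = record.corrected_bc
    if illumina_combos is not None and tuple(triple) not in illumina_combos:
        return replace(record, status=DemuxStatus.NOT_IN_ILLUMINA)
    return replace(record, status=DemuxStatus.OK, cell_id="_".join(triple))  # type: ignore[arg-type]


def merge_priming_pairs(
    records: Sequence[DemuxRecord], layout: BarcodeLayout
) -> List[DemuxRecord]:
    """Collapse the two round-1 barcodes of each well into one cell.

    The round-1 barcode component of ``cell_id`` is replaced by its well id;
    the per-read priming label is retained so merged cells can still be
    stratified by priming strategy.
    """
    out = []
    for rec in records:
        if rec.status is DemuxStatus.OK:
            bc1, bc2, bc3 = rec.corrected_bc  # type: ignore[misc]
            well = layout.well_pair_map[bc1]
            rec = replace(rec, cell_id=f"{well}_{bc2}_{bc3}")
        out.append(rec)
    return out


def demux_read(
    read_id: str,
    sequence: str,
    layout: BarcodeLayout,
    illumina_combos: Optional[Set[Tuple[str, str, str]]] = None,
) -> DemuxRecord:
    """Demultiplex a single read; always returns a record with a status."""
    sequence = sequence.upper()
    hits = locate_linkers(sequence, layout)
    if hits is None:
        return DemuxRecord(read_id=read_id, status=DemuxStatus.NO_LINKERS)
    oriented = (
        sequence
        if hits.orientation is Orientation.FORWARD
        else reverse_complement(sequence)
    )
    extracted = extract_barcodes(oriented, hits, layout)
    if extracted is None:
        return DemuxRecord(
            read_id=read_id, status=DemuxStatus.NO_LINKERS, orientation=hits.orientation
        )
    raw_bc, umi, trim_end = extracted
    (l1s, l1e), (l2s, l2e) = hits.spans
    pad = layout.max_edit_distance
    len1, len2, len3 = (r.barcode_length for r in layout.rounds)
    segments = (
        oriented[max(0, l2e - pad) : l2e + len1 + pad],
        oriented[max(0, l1e - pad) : l1e + len2 + pad],
        oriented[max(0, l1s - len3 - pad) : l1s + pad],
    )
    corrected = []
    reasons = []
    for seg, rnd in zip(segments, layout.rounds):
        bc, reason = correct_barcode_windowed(
            seg, rnd.whitelist.values(), layout.max_edit_distance
        )
        corrected.append(bc)
        reasons.append(reason)
    record = DemuxRecord(
        read_id=read_id,
        status=DemuxStatus.OK,
        raw_bc=raw_bc,
        corrected_bc=tuple(corrected),
        umi=umi,
        orientation=hits.orientation,
        trim_end=trim_end,
    )
    if "AMBIGUOUS" in reasons:
        return replace(record, status=DemuxStatus.BC_AMBIGUOUS)
    if "UNCORRECTABLE" in reasons:
        return replace(record, status=DemuxStatus.BC_UNCORRECTABLE)
    record = replace(record, priming=assign_priming(corrected[0], layout))
    return assign_cell(record, illumina_combos)


def demux_reads(
    reads: Iterable[Tuple[str, str]],
    layout: BarcodeLayout,
    illumina_combos: Optional[Set[Tuple[str, str, str]]] = None,
    merge_wells: bool = True,
) -> List[DemuxRecord]:
    """Demultiplex an iterable of ``(read_id, sequence)`` pairs."""
    records = [demux_read(rid, seq, layout, illumina_combos) for rid, seq in reads]
    if merge_wells:
        records = merge_priming_pairs(records, layout)
    return records


def status_counts(records: Sequence[DemuxRecord]) -> Dict[str, int]:
    counts: Dict[str, int] = {s.value: 0 for s in DemuxStatus}
    for rec in records:
        counts[rec.status.value] += 1
    return counts


def trimmed_read(
    sequence: str, quality: Optional[str], record: DemuxRecord
) -> Tuple[str, Optional[str], str]:
    """Oriented, barcode-trimmed read plus its annotated name suffix.

    The suffix carries cell, UMI and priming in the form
    ``cell:<id>;umi:<seq>;pr:<dT|hex>`` for downstream tools.
    """
    assert record.status is DemuxStatus.OK and record.trim_end is not None
    if record.orientation is Orientation.REVERSE_COMPLEMENT:
        sequence = reverse_complement(sequence)
        quality = quality[::-1] if quality is not None else None
    pr = "dT" if record.priming is Priming.OLIGO_DT else "hex"
    suffix = f"cell:{record.cell_id};umi:{record.umi};pr:{pr}"
    return sequence[: record.trim_end], (
        quality[: record.trim_end] if quality is not None else None
    ), suffix
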