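"""Readers and writers for the pipeline's text formats.

All genomic coordinates are 0-based half-open (BED convention). The
read-annotation table is an 11-column TSV mirroring a per-read transcript
annotation export (one row per aligned long read with its cell, gene,
transcript, novelty class and genomic 5'/3' end coordinates).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Set, Tuple

import pandas as pd
from Bio import SeqIO

from .end_calling import EndPeak, Novelty

ANNOT_COLUMNS = [
    "read_id",
    "cell_id",
    "chrom",
    "strand",
    "five_prime_pos",
    "three_prime_pos",
    "gene_id",
    "transcript_id",
    "novelty",
    "priming",
    "dataset",
]

_VALID_NOVELTY = {n.value for n in Novelty}


def read_fastq(path) -> Iterator[Tuple[str, str, str]]:
    """Yield (read_id, sequence, phred33-quality) from a FASTQ file."""
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        yield rec.id, str(rec.seq), qual


def write_fastq(path, reads: Iterable[Tuple[str, str, str]]) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_annotation_table(path) -> Tuple[pd.DataFrame, List[Tuple[int, str]]]:
    """Load and validate a read-annotation TSV.

    Returns the validated frame and a list of (line_number, reason) for
    rejected rows. A missing required column is a hard error.
    """
    # keep_default_na: "NA" is a legitimate priming label, not a missing value
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, keep_default_na=False)
    missing = [c for c in ANNOT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table missing required column(s): {missing}")
    rejected: List[Tuple[int, str]] = []
    keep = []
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # header is line 1
        if row.strand not in ("+", "-"):
            rejected.append((line_no, f"bad strand {row.strand!r}"))
            continue
        try:
            five, three = int(row.five_prime_pos), int(row.three_prime_pos)
        except (TypeError, ValueError):
            rejected.append((line_no, "non-integer coordinate"))
            continue
        if five < 0 or three < 0:
            rejected.append((line_no, "negative coordinate"))
            continue
        if row.novelty not in _VALID_NOVELTY:
            rejected.append((line_no, f"unknown novelty {row.novelty!r}"))
            continue
        keep.append(i)
    out = df.iloc[keep].reset_index(drop=True)
    out["five_prime_pos"] = out["five_prime_pos"].astype(int)
    out["three_prime_pos"] = out["three_prime_pos"].astype(int)
    return out, rejected


def write_annotation_table(df: pd.DataFrame, path) -> None:
    df[ANNOT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_bed(path) -> List[Tuple]:
    """Read BED3+ intervals as tuples (chrom, start, end, *rest), validated
    and stably sorted by (chrom, start, end, name)."""
    rows: List[Tuple] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"line {line_no}: BED needs >= 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start < 0:
                raise ValueError(f"line {line_no}: negative start {start}")
            if start >= end:
                raise ValueError(f"line {line_no}: start {start} >= end {end}")
            rows.append((chrom, start, end, *parts[3:]))
    rows.sort(key=lambda r: (r[0], r[1], r[2], r[3] if len(r) > 3 else ""))
    return rows


def write_bed(rows: Iterable[Sequence], path) -> None:
    rows = sorted(rows, key=lambda r: (r[0], r[1], r[2], str(r[3]) if len(r) > 3 else ""))
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")


def peaks_to_bed(peaks: Sequence[EndPeak], path) -> None:
    """Write peaks as BED6+3: chrom, wide_start, wide_end, name, read_count,
    strand, narrow_start, narrow_end, summit."""
    write_bed(
        [
            (
                p.chrom, p.wide_start, p.wide_end, p.name or ".", p.read_count,
                p.strand, p.narrow_start, p.narrow_end, p.summit,
            )
            for p in peaks
        ],
        path,
    )


def bed_to_peaks(path, end_type: str = "TSS") -> List[EndPeak]:
    peaks = []
    for row in read_bed(path):
        chrom, ws, we, name, count, strand, ns, ne, summit = row[:9]
        gene = name.rsplit("_", 1)[0] if name != "." else None
        peaks.append(
            EndPeak(
                chrom=chrom, strand=strand, wide_start=int(ws), wide_end=int(we),
                narrow_start=int(ns), narrow_end=int(ne), summit=int(summit),
                read_count=int(count), end_type=end_type, gene_id=gene,
                name=None if name == "." else name,
            )
        )
    return peaks


def write_matrix(counts: pd.DataFrame, out_dir, prefix: str = "matrix") -> None:
    """Write a feature x cell matrix as MatrixMarket triplets plus row and
    column name files."""
    from scipy import io as spio
    from scipy import sparse

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(out_dir / f"{prefix}.mtx"), sparse.csr_matrix(counts.values))
    (out_dir / f"{prefix}.rows.txt").write_text("\n".join(map(str, counts.index)) + "\n")
    (out_dir / f"{prefix}.cols.txt").write_text("\n".join(map(str, counts.columns)) + "\n")


def read_matrix(out_dir, prefix: str = "matrix") -> pd.DataFrame:
    from scipy import io as spio

    out_dir = Path(out_dir)
    mat = spio.mmread(str(out_dir / f"{prefix}.mtx")).toarray()
    rows = (out_dir / f"{prefix}.rows.txt").read_text().splitlines()
    cols = (out_dir / f"{prefix}.cols.txt").read_text().splitlines()
    return pd.DataFrame(mat, index=rows, columns=cols)


def read_illumina_combos(path) -> Set[Tuple[str, str, str]]:
    """One corrected barcode triple per line (tab or underscore separated)."""
    combos: Set[Tuple[str, str, str]] = set()
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split("_")
            if len(parts) != 3:
                raise ValueError(f"line {line_no}: expected 3 barcodes, got {len(parts)}")
            combos.add(tuple(parts))  # type: ignore[arg-type]
    return combos


def demux_report(records, path) -> None:
    """Per-read demultiplexing report TSV."""
    rows = []
    for r in records:
        raw = r.raw_bc or ("", "", "")
        cor = r.corrected_bc or ("", "", "")
        rows.append(
            {
                "read_id": r.read_id,
                "status": r.status.value,
                "raw_bc1": raw[0], "raw_bc2": raw[1], "raw_bc3": raw[2],
                "bc1": cor[0] or "", "bc2": cor[1] or "", "bc3": cor[2] or "",
                "umi": r.umi or "",
                "cell_id": r.cell_id or "",
                "priming": r.priming.value,
                "orientation": r.orientation.value if r.orientation else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
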