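"""Per-cell quantification of TSS usage and feature-level filters.

TSS expression is quantified by expanding each read's 5' position by a fixed
pad (default +/- 25 bp), intersecting the expanded interval with the wide
extents of the filtered TSS peaks (>= 1 bp overlap) and counting reads per
TSS per cell. By default the read's gene must match the peak's gene, which
prevents cross-gene bleed at overlapping loci; the gate can be disabled to
reproduce a plain positional intersection. Assignment is conservative: every
read is either assigned to exactly one TSS or tallied as unassigned, so
column sums plus unassigned reproduce the input read count per cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .end_calling import EndPeak, Novelty


@dataclass
class FeatureCountMatrix:
    """Integer feature-by-cell count matrix with a feature-kind tag."""

    counts: pd.DataFrame  # features x cells
    feature_kind: str  # "tss" | "transcript" | "gene" | "tes"
    feature_genes: Optional[pd.Series] = None  # feature -> gene

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.feature_genes is not None:
            missing = self.counts.index.difference(self.feature_genes.index)
            if len(missing):
                raise ValueError(f"feature_genes missing entries, e.g. {list(missing[:3])}")


def expand_read_starts(annotations: pd.DataFrame, pad: int = 25) -> pd.DataFrame:
    """Expanded [start - pad, start + pad + 1) interval per read, clipped at 0."""
    starts = annotations["five_prime_pos"].astype(int)
    out = annotations.copy()
    out["interval_start"] = np.maximum(0, starts - pad)
    out["interval_end"] = starts + pad + 1
    return out


def quantify_tss(
    annotations: pd.DataFrame,
    peaks: Sequence[EndPeak],
    pad: int = 25,
    gene_gate: bool = True,
) -> Tuple[FeatureCountMatrix, pd.Series]:
    """Count reads per named TSS peak per cell.

    A read supports a peak when its expanded 5' interval overlaps the peak's
    wide extent by >= 1 bp on the same chromosome and strand (and, with the
    gene gate, the same gene). A read overlapping several candidate peaks is
    assigned to the peak containing its unexpanded start, else the nearest
    one, with ties resolved upstream (smaller start coordinate).

    Returns the TSS x cell matrix and the per-cell unassigned-read tally;
    assigned + unassigned equals input reads per cell.
    """
    trees: Dict[Tuple[str, str], IntervalTree] = {}
    peak_gene: Dict[str, Optional[str]] = {}
    for p in peaks:
        if p.name is None:
            raise ValueError("peaks must be named before quantification")
        trees.setdefault((p.chrom, p.strand), IntervalTree()).addi(
            p.wide_start, p.wide_end, p
        )
        peak_gene[p.name] = p.gene_id

    expanded = expand_read_starts(annotations, pad=pad)
    cells = sorted(expanded["cell_id"].astype(str).unique())
    cell_idx = {c: j for j, c in enumerate(cells)}
    peak_names = sorted(peak_gene)
    peak_idx = {n: i for i, n in enumerate(peak_names)}
    mat = np.zeros((len(peak_names), len(cells)), dtype=int)
    unassigned = np.zeros(len(cells), dtype=int)

    for chrom, strand, cell, gene, start, istart, iend in zip(
        expanded["chrom"], expanded["strand"], expanded["cell_id"].astype(str),
        expanded["gene_id"], expanded["five_prime_pos"].astype(int),
        expanded["interval_start"], expanded["interval_end"],
    ):
        j = cell_idx[cell]
        tree = trees.get((chrom, strand))
        hits = list(tree.overlap(istart, iend)) if tree is not None else []
        if gene_gate:
            hits = [h for h in hits if h.data.gene_id == gene]
        if not hits:
            unassigned[j] += 1
            continue

        def rank(iv):
            p: EndPeak = iv.data
            inside = p.wide_start <= start < p.wide_end
            dist = 0 if inside else min(abs(start - p.wide_start), abs(start - (p.wide_end - 1)))
            return (dist, p.wide_start, p.name)

        chosen: EndPeak = min(hits, key=rank).data
        mat[peak_idx[chosen.name], j] += 1

    counts = pd.DataFrame(mat, index=peak_names, columns=cells)
    genes = pd.Series({n: peak_gene[n] for n in peak_names})
    return (
        FeatureCountMatrix(counts=counts, feature_kind="tss", feature_genes=genes),
        pd.Series(unassigned, index=cells, name="unassigned"),
    )


def filter_cells_by_reads(matrix: FeatureCountMatrix, min_reads: int = 500) -> FeatureCountMatrix:
    """Keep cells with a total read count of at least ``min_reads``."""
    keep = matrix.counts.columns[matrix.counts.sum(axis=0) >= min_reads]
    return FeatureCountMatrix(
        counts=matrix.counts[keep], feature_kind=matrix.feature_kind,
        feature_genes=matrix.feature_genes,
    )


def filter_novel_transcripts_sc(
    counts: pd.DataFrame, novelty: Mapping[str, str], min_cells: int = 4
) -> List[str]:
    """Reproducibility filter for single-cell novel transcript models.

    A novel transcript is retained only when detected (count >= 1) in at
    least ``min_cells`` cells; known transcripts are exempt.
    """
    detected = (counts >= 1).sum(axis=1)
    kept = [
        t
        for t in counts.index
        if novelty.get(t, Novelty.KNOWN.value) == Novelty.KNOWN.value
        or detected[t] >= min_cells
    ]
    return kept


def filter_novel_transcripts_bulk(
    counts: pd.DataFrame,
    novelty: Mapping[str, str],
    min_count: int = 5,
    min_datasets: int = 2,
    frac_a: Optional[Mapping[str, float]] = None,
    max_frac_a: float = 0.5,
) -> List[str]:
    """Bulk reproducibility filter: a novel transcript needs >= ``min_count``
    copies in >= ``min_datasets`` replicates, and — when genomic-A metadata
    is available — no internal-priming evidence (fraction A <= max_frac_a)."""
    strong = (counts >= min_count).sum(axis=1)
    kept = []
    for t in counts.index:
        if novelty.get(t, Novelty.KNOWN.value) == Novelty.KNOWN.value:
            kept.append(t)
            continue
        if strong[t] < min_datasets:
            continue
        if frac_a is not None and t in frac_a and frac_a[t] > max_frac_a:
            continue
        kept.append(t)
    return kept


def complexity_profile(matrix: FeatureCountMatrix) -> pd.DataFrame:
    """Per-cell feature complexity: total reads, genes detected, and genes
    expressing >= 2 distinct features of this kind."""
    if matrix.feature_genes is None:
        raise ValueError("complexity profiling needs a feature -> gene map")
    detected = matrix.counts >= 1
    genes = matrix.feature_genes.reindex(matrix.counts.index)
    per_gene = detected.groupby(genes).sum()  # gene x cell: n features detected
    return pd.DataFrame(
        {
            "total_reads": matrix.counts.sum(axis=0),
            "genes_detected": (per_gene >= 1).sum(axis=0),
            "genes_multi_feature": (per_gene >= 2).sum(axis=0),
            "feature_kind": matrix.feature_kind,
        }
    )


def detection_overlap(feature_sets: Mapping[str, Set[str]]) -> Dict[Tuple[str, ...], int]:
    """Exact upset combination counts over named feature sets.

    Each feature present in any set is counted once, under the tuple of set
    names (sorted) that contain it.
    """
    names = sorted(feature_sets)
    combos: Dict[Tuple[str, ...], int] = {}
    universe = set().union(*feature_sets.values()) if feature_sets else set()
    for f in universe:
        combo = tuple(n for n in names if f in feature_sets[n])
        combos[combo] = combos.get(combo, 0) + 1
    return combos


def detection_support_rate(
    query_by_category: Mapping[str, Set[str]], reference: Set[str]
) -> Dict[str, float]:
    """Per-category support rate: |query ∩ reference| / |query|.

    Used e.g. to ask what fraction of single-cell novel transcript models of
    each novelty class is also detected in bulk data.
    """
    return {
        cat: (len(q & reference) / len(q) if q else float("nan"))
        for cat, q in query_by_category.items()
    }
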