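"""Seed-controlled synthetic inputs for every pipeline stage.

Four generators emulate the data the pipeline consumes, each a pure function
of its parameters and seed (repeated calls are bit-identical) and each
emitting a complete ground-truth record per read or feature:

* barcoded long reads with configurable substitution and indel error rates;
* read-annotation tables with reads jittered around planted TSS/TES
  architectures;
* per-condition feature count matrices with planted usage switches;
* accessibility matrices coupled to an expression matrix at a target
  Pearson correlation.

The default synthetic barcode whitelists use 16-bp barcodes with minimum
pairwise Levenshtein distance >= 7, so correction at edit distance <= 3 is
provably unambiguous; a "hard mode" (smaller minimum distance) exercises the
ambiguous-correction path. Real Split-seq kits use shorter (8-bp) barcodes
whose whitelists cannot reach that separation; the synthetic layout trades
that realism for a provable round-trip guarantee.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import edlib
import numpy as np
import pandas as pd

from .demux import reverse_complement
from .layout import BarcodeLayout, BarcodeRound, Priming

BASES = np.array(list("ACGT"))

#: fixed synthetic linker ("spacer") sequences, realistic Split-seq lengths
DEFAULT_LINKER1 = "ATCCACGTGCTTGAGAGGCCAGAGCATTCG"  # 30 bp
DEFAULT_LINKER2 = "GTGGCCGATGTTTCGCATCGGC"  # 22 bp


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(BASES, size=length))


def make_whitelist(
    n: int,
    length: int = 16,
    min_distance: int = 7,
    rng=0,
    max_attempts: int = 200_000,
) -> List[str]:
    """Greedy rejection sampling of barcodes with a pairwise Levenshtein floor."""
    rng = _rng(rng)
    accepted: List[str] = []
    attempts = 0
    while len(accepted) < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not build {n} barcodes of length {length} at distance {min_distance}"
            )
        cand = random_sequence(length, rng)
        if all(
            edlib.align(cand, b, mode="NW", task="distance")["editDistance"] >= min_distance
            for b in accepted
        ):
            accepted.append(cand)
    return accepted


def make_synthetic_layout(
    seed=0,
    n_wells_round1: int = 24,
    n_barcodes_round23: int = 48,
    barcode_length: int = 16,
    min_distance: int = 7,
    umi_length: int = 10,
    max_edit_distance: int = 3,
    max_linker_errors: int = 2,
) -> BarcodeLayout:
    """Three-round synthetic barcode layout.

    Round 1 holds two barcodes per well (oligo-dT and random hexamer);
    rounds 2 and 3 hold one barcode per well.
    """
    rng = _rng(seed)
    r1_bcs = make_whitelist(2 * n_wells_round1, barcode_length, min_distance, rng)
    r2_bcs = make_whitelist(n_barcodes_round23, barcode_length, min_distance, rng)
    r3_bcs = make_whitelist(n_barcodes_round23, barcode_length, min_distance, rng)
    r1_whitelist: Dict[str, str] = {}
    priming_map: Dict[str, Priming] = {}
    well_pair_map: Dict[str, str] = {}
    for w in range(n_wells_round1):
        well = f"w{w + 1:02d}"
        dt, hexamer = r1_bcs[2 * w], r1_bcs[2 * w + 1]
        r1_whitelist[f"{well}_dT"] = dt
        r1_whitelist[f"{well}_hex"] = hexamer
        priming_map[dt] = Priming.OLIGO_DT
        priming_map[hexamer] = Priming.RANDOM_HEXAMER
        well_pair_map[dt] = well
        well_pair_map[hexamer] = well
    rounds = [
        BarcodeRound(whitelist=r1_whitelist, barcode_length=barcode_length),
        BarcodeRound(
            whitelist={f"r2_{i + 1:02d}": b for i, b in enumerate(r2_bcs)},
            barcode_length=barcode_length,
        ),
        BarcodeRound(
            whitelist={f"r3_{i + 1:02d}": b for i, b in enumerate(r3_bcs)},
            barcode_length=barcode_length,
        ),
    ]
    return BarcodeLayout(
        rounds=rounds,
        linkers=[DEFAULT_LINKER1, DEFAULT_LINKER2],
        umi_length=umi_length,
        priming_map=priming_map,
        well_pair_map=well_pair_map,
        max_edit_distance=max_edit_distance,
        max_linker_errors=max_linker_errors,
    )


def mutate_sequence(
    seq: str, substitution_rate: float, indel_rate: float, rng: np.random.Generator
) -> str:
    """Apply iid per-base substitutions and indels (half insertions before a
    base, half deletions of a base)."""
    n = len(seq)
    if n == 0 or (substitution_rate == 0 and indel_rate == 0):
        return seq
    res = list(seq)
    sub_mask = rng.random(n) < substitution_rate
    indel_draw = rng.random(n)
    for i in np.nonzero(sub_mask)[0]:
        choices = [b for b in "ACGT" if b != res[i]]
        res[i] = choices[rng.integers(len(choices))]
    del_mask = indel_draw < indel_rate / 2
    ins_mask = (indel_draw >= indel_rate / 2) & (indel_draw < indel_rate)
    for i in np.nonzero(ins_mask)[0]:
        res[i] = str(BASES[rng.integers(4)]) + res[i]
    for i in np.nonzero(del_mask)[0]:
        res[i] = ""
    return "".join(res)


def simulate_barcoded_reads(
    layout: Optional[BarcodeLayout] = None,
    n_reads: int = 10_000,
    n_cells: int = 96,
    substitution_rate: float = 0.01,
    indel_rate: float = 0.002,
    cdna_length: Tuple[int, int] = (100, 300),
    revcomp_fraction: float = 0.5,
    seed=0,
) -> Tuple[List[Tuple[str, str, str]], pd.DataFrame, BarcodeLayout]:
    """Synthesize barcoded long reads with ground truth.

    Each read is ``cDNA | UMI | bc3 | linker1 | bc2 | linker2 | bc1`` on the
    forward strand, reverse-complemented with probability
    ``revcomp_fraction``, then corrupted base-by-base. Returns
    ``(reads, truth, layout)`` with reads as (id, sequence, quality) and one
    truth row per read.
    """
    rng = _rng(seed)
    if layout is None:
        layout = make_synthetic_layout(seed=rng.integers(2**31))
    wells = sorted(layout.well_pair_map.values())
    by_well: Dict[str, Dict[Priming, str]] = {w: {} for w in wells}
    for bc, well in layout.well_pair_map.items():
        by_well[well][layout.priming_map[bc]] = bc
    r2 = sorted(layout.rounds[1].whitelist.values())
    r3 = sorted(layout.rounds[2].whitelist.values())

    cell_keys = set()
    while len(cell_keys) < n_cells:
        cell_keys.add(
            (wells[rng.integers(len(wells))], r2[rng.integers(len(r2))], r3[rng.integers(len(r3))])
        )
    cell_list = sorted(cell_keys)

    l1, l2 = layout.linkers
    reads: List[Tuple[str, str, str]] = []
    truth_rows = []
    for i in range(n_reads):
        well, bc2, bc3 = cell_list[rng.integers(len(cell_list))]
        priming = Priming.OLIGO_DT if rng.random() < 0.5 else Priming.RANDOM_HEXAMER
        bc1 = by_well[well][priming]
        umi = random_sequence(layout.umi_length, rng)
        cdna = random_sequence(int(rng.integers(cdna_length[0], cdna_length[1] + 1)), rng)
        clean = cdna + umi + bc3 + l1 + bc2 + l2 + bc1
        seq = mutate_sequence(clean, substitution_rate, indel_rate, rng)
        orientation = "FORWARD"
        if rng.random() < revcomp_fraction:
            seq = reverse_complement(seq)
            orientation = "REVERSE_COMPLEMENT"
        read_id = f"read_{i:06d}"
        reads.append((read_id, seq, "I" * len(seq)))
        truth_rows.append(
            {
                "read_id": read_id,
                "cell_id": f"{well}_{bc2}_{bc3}",
                "bc1": bc1,
                "bc2": bc2,
                "bc3": bc3,
                "umi": umi,
                "priming": priming.value,
                "orientation": orientation,
            }
        )
    return reads, pd.DataFrame(truth_rows), layout


@dataclass
class GeneModel:
    """Planted end architecture of one gene.

    TSS/TES positions are genomic coordinates; usage vectors sum to 1.
    On the + strand TSSs sit 5' (left) of TESs; on the - strand the layout
    mirrors.
    """

    gene_id: str
    chrom: str
    strand: str
    tss_positions: List[int]
    tss_usage: List[float]
    tes_positions: List[int]
    tes_usage: List[float]
    n_reads: int = 100
    jitter_sd: float = 5.0

    def __post_init__(self) -> None:
        for usage in (self.tss_usage, self.tes_usage):
            if abs(sum(usage) - 1.0) > 1e-9 or any(u < 0 for u in usage):
                raise ValueError("usage vectors must be non-negative and sum to 1")


def random_gene_models(
    n_genes: int = 20,
    seed=0,
    max_tss: int = 4,
    max_tes: int = 2,
    min_separation: int = 200,
    reads_per_gene: Tuple[int, int] = (50, 500),
    jitter_sd: float = 5.0,
    gene_span: int = 50_000,
) -> List[GeneModel]:
    """Draw non-overlapping gene models with 1..max_tss planted TSSs spaced
    at least ``min_separation`` apart (and TESs likewise)."""
    rng = _rng(seed)
    models = []
    for g in range(n_genes):
        chrom = f"chr{g % 4 + 1}"
        strand = "+" if g % 2 == 0 else "-"
        offset = 100_000 + (g // 4) * (gene_span * 2)
        n_tss = int(rng.integers(1, max_tss + 1))
        n_tes = int(rng.integers(1, max_tes + 1))
        tss = sorted(
            offset + min_separation * k + int(rng.integers(0, min_separation // 2))
            for k in range(n_tss)
        )
        tes_base = offset + gene_span // 2
        tes = sorted(
            tes_base + min_separation * k + int(rng.integers(0, min_separation // 2))
            for k in range(n_tes)
        )
        if strand == "-":  # mirror: TSSs at high coordinates
            tss, tes = tes, tss
            n_tss, n_tes = n_tes, n_tss
        usage_tss = rng.dirichlet(np.full(len(tss), 5.0))
        usage_tes = rng.dirichlet(np.full(len(tes), 5.0))
        models.append(
            GeneModel(
                gene_id=f"gene{g + 1:03d}",
                chrom=chrom,
                strand=strand,
                tss_positions=(sorted(tss, reverse=True) if strand == "-" else tss),
                tss_usage=list(usage_tss / usage_tss.sum()),
                tes_positions=(sorted(tes, reverse=True) if strand == "-" else tes),
                tes_usage=list(usage_tes / usage_tes.sum()),
                n_reads=int(rng.integers(reads_per_gene[0], reads_per_gene[1] + 1)),
                jitter_sd=jitter_sd,
            )
        )
    return models


def simulate_end_annotations(
    models: Sequence[GeneModel],
    n_cells: int = 24,
    noise_fraction: float = 0.0,
    seed=0,
    dataset: str = "sim",
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Read-annotation table with 5'/3' ends jittered around planted sites.

    Signal reads are labeled KNOWN; a ``noise_fraction`` of reads per gene is
    emitted as GENOMIC reads with uniform 5' positions across the gene span.
    Returns (annotations, truth) where truth records each read's planted
    TSS/TES index and noise flag.
    """
    rng = _rng(seed)
    cells = [f"cell{j + 1:03d}" for j in range(n_cells)]
    ann_rows, truth_rows = [], []
    counter = 0
    for m in models:
        span_lo = min(min(m.tss_positions), min(m.tes_positions))
        span_hi = max(max(m.tss_positions), max(m.tes_positions))
        for _ in range(m.n_reads):
            read_id = f"r{counter:07d}"
            counter += 1
            cell = cells[rng.integers(len(cells))]
            is_noise = rng.random() < noise_fraction
            if is_noise:
                five = int(rng.integers(span_lo, span_hi + 1))
                three = int(rng.integers(span_lo, span_hi + 1))
                if (m.strand == "+") == (five > three):
                    five, three = three, five
                novelty, tss_idx, tes_idx = "GENOMIC", -1, -1
            else:
                tss_idx = int(rng.choice(len(m.tss_positions), p=m.tss_usage))
                tes_idx = int(rng.choice(len(m.tes_positions), p=m.tes_usage))
                five = m.tss_positions[tss_idx] + int(round(rng.normal(0, m.jitter_sd)))
                three = m.tes_positions[tes_idx] + int(round(rng.normal(0, m.jitter_sd)))
                if m.strand == "+":
                    three = max(three, five)
                else:
                    five = max(five, three)
                novelty = "KNOWN"
            ann_rows.append(
                {
                    "read_id": read_id,
                    "cell_id": cell,
                    "chrom": m.chrom,
                    "strand": m.strand,
                    "five_prime_pos": five,
                    "three_prime_pos": three,
                    "gene_id": m.gene_id,
                    "transcript_id": f"{m.gene_id}_t{tss_idx}_{tes_idx}",
                    "novelty": novelty,
                    "priming": "NA",
                    "dataset": dataset,
                }
            )
            truth_rows.append(
                {
                    "read_id": read_id,
                    "gene_id": m.gene_id,
                    "tss_index": tss_idx,
                    "tes_index": tes_idx,
                    "tss_position": m.tss_positions[tss_idx] if tss_idx >= 0 else -1,
                    "tes_position": m.tes_positions[tes_idx] if tes_idx >= 0 else -1,
                    "is_noise": is_noise,
                }
            )
    return pd.DataFrame(ann_rows), pd.DataFrame(truth_rows)


def true_delta_pi(pi_a: Sequence[float], pi_b: Sequence[float]) -> float:
    """Planted effect size: summed |percent usage change| over the top-two
    features by combined usage."""
    pa = 100 * np.asarray(pi_a, dtype=float)
    pb = 100 * np.asarray(pi_b, dtype=float)
    order = np.argsort(-(pa + pb), kind="stable")[:2]
    return float(np.abs(pa[order] - pb[order]).sum())


def simulate_usage_counts(
    n_null_genes: int = 100,
    n_features: int = 5,
    reads_per_condition: int = 50,
    switch_spec: Optional[Mapping[str, Tuple[Sequence[float], Sequence[float]]]] = None,
    n_cells_per_group: int = 50,
    seed=0,
) -> Tuple[pd.DataFrame, Dict[str, str], Dict[str, str], pd.DataFrame]:
    """Feature x cell count matrix with planted usage switches.

    Null genes draw reads from one shared multinomial usage vector (uniform
    over features) in both conditions; ``switch_spec`` maps gene id ->
    (pi_A, pi_B) for planted switches. Reads are spread uniformly over the
    cells of each group. Returns (matrix, feature_genes, cell_groups, truth).
    """
    rng = _rng(seed)
    cells_a = [f"A_cell{j:03d}" for j in range(n_cells_per_group)]
    cells_b = [f"B_cell{j:03d}" for j in range(n_cells_per_group)]
    cell_groups = {**{c: "A" for c in cells_a}, **{c: "B" for c in cells_b}}
    specs: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for g in range(n_null_genes):
        pi = np.full(n_features, 1.0 / n_features)
        specs[f"null{g + 1:04d}"] = (pi, pi)
    for gene, (pa, pb) in (switch_spec or {}).items():
        specs[gene] = (np.asarray(pa, dtype=float), np.asarray(pb, dtype=float))
    feature_rows = []
    feature_genes: Dict[str, str] = {}
    data: Dict[str, np.ndarray] = {}
    truth_rows = []
    all_cells = cells_a + cells_b
    for gene in sorted(specs):
        pa, pb = specs[gene]
        if abs(pa.sum() - 1) > 1e-9 or abs(pb.sum() - 1) > 1e-9:
            raise ValueError(f"usage vectors for {gene} must sum to 1")
        names = [f"{gene}_iso{i + 1}" for i in range(len(pa))]
        counts_a = rng.multinomial(reads_per_condition, pa)
        counts_b = rng.multinomial(reads_per_condition, pb)
        block = np.zeros((len(names), len(all_cells)), dtype=int)
        for i in range(len(names)):
            if counts_a[i]:
                block[i, : len(cells_a)] = rng.multinomial(
                    counts_a[i], np.full(len(cells_a), 1 / len(cells_a))
                )
            if counts_b[i]:
                block[i, len(cells_a):] = rng.multinomial(
                    counts_b[i], np.full(len(cells_b), 1 / len(cells_b))
                )
        for i, name in enumerate(names):
            data[name] = block[i]
            feature_genes[name] = gene
            feature_rows.append(name)
        is_switch = bool(switch_spec and gene in switch_spec)
        truth_rows.append(
            {"gene_id": gene, "is_switch": is_switch, "true_dpi": true_delta_pi(pa, pb)}
        )
    matrix = pd.DataFrame(
        np.vstack([data[f] for f in feature_rows]), index=feature_rows, columns=all_cells
    )
    return matrix, feature_genes, cell_groups, pd.DataFrame(truth_rows)


def simulate_accessibility(
    expr: pd.DataFrame,
    target_r: float = 0.8,
    baseline: float = 1000.0,
    seed=0,
) -> pd.DataFrame:
    """Accessibility matrix coupled to expression at a target Pearson r.

    ``acc = baseline + sign(r) * (expr - mean) + noise`` with the noise
    variance solved so the population correlation with ``expr`` equals
    ``target_r``; values are truncated at 0, which biases the realized
    correlation only when the baseline is small relative to the spread.
    """
    if not -1 <= target_r <= 1:
        raise ValueError("target_r must lie in [-1, 1]")
    rng = _rng(seed)
    x = expr.to_numpy(dtype=float)
    sd = float(x.std())
    if sd == 0:
        raise ValueError("expression matrix has zero variance")
    centered = np.sign(target_r) * (x - x.mean()) if target_r != 0 else np.zeros_like(x)
    if target_r == 0:
        noise_sd = sd
    elif abs(target_r) == 1:
        noise_sd = 0.0
    else:
        noise_sd = sd * np.sqrt(1 / target_r**2 - 1)
    noise = rng.normal(0, noise_sd, size=x.shape) if noise_sd > 0 else 0.0
    acc = np.maximum(0.0, baseline + centered + noise)
    return pd.DataFrame(acc, index=expr.index, columns=expr.columns)
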