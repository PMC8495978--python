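"""End-to-end pipeline runner with provenance manifest.

Chains the stages on simulated inputs — barcoded-read simulation and
demultiplexing, end-architecture simulation and TSS/TES calling, per-cell
TSS quantification, differential TSS usage testing between two synthetic
groups, and accessibility integration — writing each stage's outputs plus a
manifest of parameters and content checksums. Under a fixed seed the whole
run is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import __version__
from .atac import integrate
from .demux import demux_reads, status_counts
from .differential import UsageTestConfig, run_usage_tests
from .end_calling import EndCallConfig, call_ends
from .io import (
    demux_report,
    peaks_to_bed,
    sha256_file,
    write_annotation_table,
    write_fastq,
    write_json,
    write_matrix,
)
from .quantification import quantify_tss
from .simulate import (
    make_synthetic_layout,
    random_gene_models,
    simulate_accessibility,
    simulate_barcoded_reads,
    simulate_end_annotations,
    simulate_usage_counts,
)


@dataclass
class PipelineConfig:
    seed: int = 0
    n_reads: int = 2000
    n_cells: int = 48
    substitution_rate: float = 0.01
    indel_rate: float = 0.002
    n_genes: int = 20
    noise_fraction: float = 0.05
    n_null_genes: int = 50
    target_r: float = 0.8


def run_pipeline(out_dir, config: PipelineConfig = PipelineConfig()) -> dict:
    """Run every stage on simulated data; returns the manifest dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    seeds = {k: int(rng.integers(2**31)) for k in ("reads", "ends", "counts", "acc")}
    manifest: dict = {
        "version": __version__,
        "config": asdict(config),
        "stage_seeds": seeds,
        "stages": {},
    }

    # stage 1: simulate + demux barcoded reads
    layout = make_synthetic_layout(seed=seeds["reads"])
    reads, truth, layout = simulate_barcoded_reads(
        layout=layout,
        n_reads=config.n_reads,
        n_cells=config.n_cells,
        substitution_rate=config.substitution_rate,
        indel_rate=config.indel_rate,
        seed=seeds["reads"],
    )
    write_fastq(out / "reads.fastq", reads)
    records = demux_reads([(r[0], r[1]) for r in reads], layout)
    demux_report(records, out / "demux_report.tsv")
    manifest["stages"]["demux"] = {
        "n_reads": len(reads),
        "status_counts": status_counts(records),
        "outputs": _checksums(out, ["reads.fastq", "demux_report.tsv"]),
    }

    # stage 2: simulate end architectures, call TSS and TES peaks
    models = random_gene_models(n_genes=config.n_genes, seed=seeds["ends"])
    annotations, _ = simulate_end_annotations(
        models, noise_fraction=config.noise_fraction, seed=seeds["ends"]
    )
    write_annotation_table(annotations, out / "reads_annot.tsv")
    tss_peaks = call_ends(annotations, EndCallConfig.tss_single_cell())
    tes_peaks = call_ends(annotations, EndCallConfig.tes())
    peaks_to_bed(tss_peaks, out / "tss.bed")
    peaks_to_bed(tes_peaks, out / "tes.bed")
    manifest["stages"]["call_ends"] = {
        "n_annotated_reads": len(annotations),
        "n_tss": len(tss_peaks),
        "n_tes": len(tes_peaks),
        "outputs": _checksums(out, ["reads_annot.tsv", "tss.bed", "tes.bed"]),
    }

    # stage 3: quantify TSS per cell
    matrix, unassigned = quantify_tss(annotations, tss_peaks)
    write_matrix(matrix.counts, out, prefix="tss_counts")
    manifest["stages"]["quantify"] = {
        "n_tss": matrix.counts.shape[0],
        "n_cells": matrix.counts.shape[1],
        "assigned_reads": int(matrix.counts.values.sum()),
        "unassigned_reads": int(unassigned.sum()),
        "outputs": _checksums(
            out, ["tss_counts.mtx", "tss_counts.rows.txt", "tss_counts.cols.txt"]
        ),
    }

    # stage 4: differential usage between two simulated groups
    counts, feature_genes, cell_groups, _ = simulate_usage_counts(
        n_null_genes=config.n_null_genes,
        switch_spec={"switch01": ([0.8, 0.2], [0.2, 0.8])},
        reads_per_condition=200,
        seed=seeds["counts"],
    )
    results = run_usage_tests(counts, feature_genes, cell_groups, ("A", "B"), UsageTestConfig())
    results.to_csv(out / "usage_tests.tsv", sep="\t")
    manifest["stages"]["usage_tests"] = {
        "n_genes": len(results),
        "n_testable": int(results["testable"].sum()),
        "n_significant": int(results["significant"].sum()),
        "outputs": _checksums(out, ["usage_tests.tsv"]),
    }

    # stage 5: accessibility integration
    expr_cells = matrix.counts
    groups = {
        c: ("G1" if i < expr_cells.shape[1] // 2 else "G2")
        for i, c in enumerate(expr_cells.columns)
    }
    acc = simulate_accessibility(expr_cells, target_r=config.target_r, seed=seeds["acc"])
    table, summary = integrate(
        expr_cells, acc, groups, groups, [("G1", "G2")],
        tss_genes=matrix.feature_genes.to_dict(),
    )
    table.to_csv(out / "integration.tsv", sep="\t", index=False)
    write_json(summary, out / "integration_summary.json")
    manifest["stages"]["integrate"] = {
        "n_tss": int(table["tss_name"].nunique()),
        "outputs": _checksums(out, ["integration.tsv", "integration_summary.json"]),
    }

    write_json(manifest, out / "manifest.json")
    return manifest


def _checksums(out: Path, names) -> Dict[str, str]:
    return {n: sha256_file(out / n) for n in names}
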