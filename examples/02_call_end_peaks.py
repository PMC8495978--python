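"""Call TSS peaks from long-read 5' ends around a planted architecture.

Plants a gene with a major and a minor TSS 400 bp apart, simulates reads
whose starts jitter around them, and calls peaks with the 50-bp window.
"""

from splitlr import EndCallConfig, call_ends
from splitlr.simulate import GeneModel, simulate_end_annotations

gene = GeneModel(
    gene_id="Tnnt2", chrom="chr1", strand="+",
    tss_positions=[100_000, 100_400], tss_usage=[0.8, 0.2],
    tes_positions=[115_000], tes_usage=[1.0],
    n_reads=300, jitter_sd=5.0,
)
annotations, truth = simulate_end_annotations([gene], noise_fraction=0.1, seed=3)

peaks = call_ends(annotations, EndCallConfig.tss_single_cell())
for p in peaks:
    print(f"{p.name}: summit {p.chrom}:{p.summit} ({p.strand}), "
          f"wide [{p.wide_start}, {p.wide_end}), {p.read_count} reads")
# Both planted TSSs come back as <gene>_1 and <gene>_2 (numbered by
# coordinate), summits within a few bp of the planted sites; the GENOMIC
# noise reads are excluded by the novelty filter before calling.
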