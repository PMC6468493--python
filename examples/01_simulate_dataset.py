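"""Generate a synthetic DIvA-style dataset with known ground truth.

Builds a two-chromosome toy genome with 40 AsiSI sites planted inside
genes (half flagged as cut in vivo), then writes the genome, gene
annotation, mNET-seq alignments, ChIP tracks, qPCR Ct table and the
truth sidecar to ./example_output/.
"""

from pathlib import Path

from divanet import simulate, sites

out = Path("example_output")
out.mkdir(exist_ok=True)

genome, truth, genes = simulate.simulate_genome(
    n_chrom=2, length_bp=200_000, n_sites=40, n_genes=48, seed=42
)
simulate.write_genome_fasta(genome, out / "genome.fa")
sites.write_bed6(genes, out / "genes.bed")
truth.to_json(out / "truth.json")

records, header = simulate.simulate_mnet(genome, truth, genes, induced=True, seed=43)
simulate.write_sam(records, header, out / "mnet_induced.sam")

treatment, control = simulate.simulate_chip(truth, depth=50, seed=44)
treatment.to_bedgraph(out / "chip_treatment.bedgraph")
control.to_bedgraph(out / "chip_control.bedgraph")

amplicons = {f"acDS-{i}": i for i, cut in enumerate(truth.cut_flags) if cut}
ct = simulate.simulate_ct(truth, amplicons, replicates=3, seed=45)
ct.to_csv(out / "ct_table.csv", index=False)

n_cut = sum(truth.cut_flags)
print(f"genome: {sum(truth.chrom_lengths.values()):,} bp over {len(genome)} chromosomes")
print(f"planted sites: {truth.n_sites} ({n_cut} cut at fraction {max(truth.cut_fraction)})")
print(f"mNET-seq pairs: {len(records) // 2:,}")
# Every downstream example reads these files; the truth sidecar is what
# lets the pipeline's answers be checked against what was simulated.
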