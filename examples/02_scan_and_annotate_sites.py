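"""Find AsiSI recognition sites in a genome and annotate them as genic.

The 8-bp motif GCGATCGC is its own reverse complement, so a forward-
strand scan reports each cuttable position exactly once.  Run
01_simulate_dataset.py first.
"""

from divanet import sites

found = sites.scan_sites("example_output/genome.fa")
annotated = sites.annotate_sites(found, "example_output/genes.bed")

n_genic = sum(s.genic for s in annotated)
print(f"sites found: {len(found)}")
print(f"genic: {n_genic}, intergenic: {len(found) - n_genic}")
for s in annotated[:3]:
    host = f"{s.gene_id} ({s.gene_strand})" if s.genic else "intergenic"
    print(f"  {s.chrom}:{s.start}-{s.end}  {host}")
# Each genic site carries its host gene's strand, which later orients
# the sense/antisense frame of the metagene profiles.
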