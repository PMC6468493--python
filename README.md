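# divanet

Analysis of nascent RNA polymerase II transcription at sequence-specific
DNA double-strand breaks (DSBs), for labs using the DIvA system: the
AsiSI-ER restriction endonuclease, activated by 4-hydroxytamoxifen,
cleaves its 8-bp recognition motif `GCGATCGC` genome-wide, and mNET-seq
reads out the position of transcribing RNAPII at single-nucleotide
resolution around those breaks.

The package implements the complete computational chain:

1. **Site discovery** — scan a genome for the AsiSI motif (palindromic,
   so one forward scan reports every cuttable position once) and
   annotate each site as genic/intergenic with its host gene's strand.
2. **3′-end profiling** — convert paired-end mNET-seq alignments into
   strand-specific single-nucleotide RNAPII profiles: keep only proper
   pairs with FLAGs (99, 147) or (83, 163), take the 3′-most aligned
   base of read 2 as the polymerase position and the strand of read 1
   as the transcript strand.
3. **Cut/uncut classification** — score each site by the γH2A.X/H2A.X
   log2 ratio, log2((T+p)/(C+p)) over CPM-normalized coverage in a
   ±1 kb window, and select the top-*N* genic sites as the "cut" set
   and the bottom-*N* as the "uncut" negative control.
4. **Metagene statistics** — average sense/antisense 3′-end signal
   across a site set in a gene-oriented frame (offset 0 = site 5′ end),
   smooth with a 5-nt forward rolling average
   (smoothed[x] = mean over [x, x+4]), and summarize each site by the
   ratio of proximal ([0, 500)) to distal ([1500, 2000)) signal.
5. **%DSB by qPCR** — double-normalized ΔΔCt: target Ct minus
   housekeeping Ct within condition, then minus the untreated baseline;
   fold = 2^(−ΔΔCt), %DSB = (1 − fold) × 100. Cutting a fraction *f* of
   templates shifts the treated Ct by −log2(1−f), so the chain recovers
   100·*f* exactly in the noise-free limit.
6. **Synthetic data** — a generator that plants AsiSI sites in toy
   genomes, simulates mNET-seq pairs (background gene-body transcription
   plus break-induced bidirectional transcription decaying geometrically
   from cut sites), ChIP tracks with boxcar enrichment, and Ct tables —
   all with known ground truth, so every stage is testable end to end.

## Worked example

```bash
cd examples
python 01_simulate_dataset.py     # writes example_output/
python 04_classify_cut_sites.py
python 05_metagene_profiles.py
python 06_quantify_dsb_qpcr.py
```

prints (seed 42):

```
planted sites: 40 (20 cut at fraction 0.8)
selected 20 cut + 20 uncut; accuracy vs planted truth: 100%
  cut: 20 sites, smoothed sense peak 0.82, proximal/distal median 128.00 (IQR 59.71-145.25)
uncut: 20 sites, smoothed sense peak 0.04, proximal/distal median 1.71 (IQR 1.00-3.00)
target amplicons: mean 79.4% DSB (simulated cut fraction 0.8 -> expect ~80%)
no-DSB control locus: -4.2% DSB (expect ~0%)
```

The γH2A.X classifier recovers the 20 planted cut sites perfectly; the
proximal/distal ratio (median 128 at cut vs 1.7 at uncut sites) shows
nascent transcription concentrated at breaks; and the ΔΔCt chain reads
the simulated 80% cut fraction back from the Ct table to within noise.

The same stages are scriptable from the shell:

```bash
divanet simulate --outdir sim --seed 1
divanet scan-sites sim/genome.fa --genes-bed sim/genes.bed --out sites.tsv
divanet extract-3p sim/mnet.sam --out-prefix mnet
divanet dsb-qpcr sim/ct_table.csv --out dsb.csv
divanet run-all --config config.yaml
```

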