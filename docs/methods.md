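# Methods

## The measurement problem

In the DIvA system the AsiSI-ER endonuclease introduces double-strand
breaks (DSBs) at a defined set of genomic positions — every occurrence
of the palindromic 8-mer `GCGATCGC` — but only a minority of those
positions are cleaved efficiently in vivo. Three observables describe
what happens at a break: phosphorylated H2A.X (γH2A.X) spreading in
chromatin around cut sites, nascent RNAPII transcription detected by
mNET-seq at single-nucleotide resolution, and loss of intact template
measurable by qPCR. This package turns each observable into a
statistic and validates the whole chain on simulations with known
ground truth.

## Models and procedures

### Site discovery

The motif equals its own reverse complement, so a forward-strand scan
reports each cuttable position exactly once; windows containing `N`
never match. A site is *genic* when it overlaps a gene body by at
least 1 bp; with several overlapping genes the larger overlap wins and
exact ties go to the alphabetically first gene id (deterministic and
logged). An optional `promoter_extension` widens genes upstream
(strand-aware) so promoter-proximal sites can be treated as genic;
the default is 0 because gene-body overlap is the conservative
reading of "genic". Coordinates are 0-based half-open throughout
(BED convention); offset 0 in all downstream frames is the site's 5′
end in host-gene orientation.

### 3′-end profiling

Only FLAG combinations (99, 147) and (83, 163) — proper pairs, both
mates primary — are accepted; the predicate is exact, so secondary,
supplementary, singleton and discordant records all fall out of one
membership test. The RNAPII position is the 3′-most *aligned* base of
read 2, computed from the reference span (CIGAR reference-consuming
operations; soft clips excluded): leftmost base when read 2 maps
reverse, rightmost when forward. The transcript strand is read 1's
strand. Because library chemistries differ in read-1 orientation, a
`flip_strand` switch mirrors the assignment; the default follows the
convention above. MAPQ is not filtered by default (`min_mapq=0`), and
no deduplication is performed. Pairing is by query name with a
first-two-records buffer, so streams need not be sorted; orphans and
cross-reference pairs are counted, not silently dropped.

### Cut/uncut classification

Both ChIP tracks are scaled to counts-per-million (total bin mass
1e6), then each site scores log2((T+p)/(C+p)) with T, C the mean bin
value over `[start − w, end + w)`. Defaults w = 1000 bp and p = 1 CPM:
the window matches the scale of γH2A.X spreading in the simulation,
and a pseudocount of 1 is the convention of the coverage-comparison
tools this statistic mirrors. Both are exposed as parameters. The
cut set is the n highest-scoring genic sites and the uncut set the n
lowest, ties broken by (chrom, start) so reruns are byte-identical;
n defaults to 94 (the size used for human data) but is free, and the
synthetic pipeline uses n = 20.

CPM normalization has a compositional consequence worth knowing: when
enriched windows hold a non-negligible share of the treatment library
(as in a small, site-dense toy genome), all scores shift down by a
common offset and the absolute score no longer equals
log2(enrichment). Ranking — and therefore classification — is
unaffected, which is why parameter-recovery tests assert labels, and
the absolute-score test uses a single cut site in a 1 Mb genome where
the offset is negligible.

### Metagene statistics

Signal around each site is collected on offsets [−F, +F] (default
F = 2000) in a gene-oriented frame: for a '+' host gene,
offset = pos − start and sense = '+' counts; for a '−' host gene,
offset = (end − 1) − pos and sense = '−' counts. This lets sites of
mixed orientation average coherently; a reference-orientation mode
exists for unannotated or intergenic sites. Sites whose window leaves
the chromosome are dropped (logged), not zero-padded, to avoid edge
bias. Matrices hold raw counts; when two libraries are compared they
should first be scaled to equal accepted-pair totals (the pipeline
compares cut vs uncut within one library, where no scaling is
needed).

The across-site mean profile is optionally smoothed with a forward
rolling average: smoothed[x] = mean(raw[x .. x+window−1]), window 5 by
default, with a shrinking window at the right edge so the last point
equals the raw value. The per-site summary statistic is
(Σ proximal + p) / (Σ distal + p) with proximal = offsets [0, 500),
distal = [1500, 2000), p = 1: both windows are 500 nt, downstream of
the site in the gene-oriented frame. The one-sided (downstream) choice
is an assumption — the windows are parameters, and a symmetric caller
can pass mirrored windows — and the pseudocount guards empty distal
windows. Medians and quartiles are reported across sites.

### ΔΔCt quantitation

ΔCt(amplicon, condition, rep) = Ct − mean housekeeping Ct in the same
condition. With two housekeeping genes the default reference is the
mean of the per-gene condition means (equivalent to averaging the two
per-housekeeping ΔCt values); a single housekeeping gene can be
selected explicitly for transparency. ΔΔCt subtracts the untreated
ΔCt, paired by replicate index when the replicate sets match and
against the untreated mean otherwise; fold = 2^(−ΔΔCt), averaged over
replicates with SEM, and %DSB = (1 − fold) × 100, reported unclamped
(negative values mean signal gain). Any additional condition
(e.g. drug preincubation before induction) is normalized against the
same untreated baseline. Algebraically, a cut fraction f shifts the
treated Ct by −log2(1−f), so the noise-free chain returns exactly
100·f; adding a constant to every Ct of one condition cancels in the
within-condition normalization (housekeeping invariance).

## The synthetic-data generator

The generator emulates the statistical structure of the experiment,
not its molecular detail:

- **Genome**: uniform random A/C/G/T chromosomes; genes are
  non-overlapping fixed-length (3 kb) intervals with random strand,
  packed with at least a 2 kb flank to each chromosome end; one motif
  is planted per host gene. Spontaneous motif occurrences are
  destroyed by a single-base substitution (at a base outside any
  planted window) and the genome re-scanned until clean, so the
  planted set is the exact census. Half the genic sites are flagged
  cut (cut fraction 0.8 by default — an efficiently restricted site);
  optional intergenic sites are never cut.
- **mNET-seq**: background transcription is Poisson over gene bodies
  (5 pairs/kb) on the gene strand; each cut site adds
  Poisson(200 × cut fraction) pairs per strand at a truncated-geometric
  distance (mean 250 bp, cap 2 kb, matching a signal extent of
  ≤1 kb) downstream on '+' and upstream on '−' — bidirectional
  transcription pointing away from the break. Pairs are written as
  valid SAM with fixed 50-bp reads, 150-bp inserts, no indels or
  clips, flags 99/147 or 83/163, so the 3′-end rule has a closed-form
  oracle.
- **ChIP**: control is flat Poisson (depth per 50-bp bin); treatment
  adds a boxcar of half-width 2 kb and amplitude (enrichment − 1) ×
  depth around cut sites only, enrichment 8 by default (a strong
  γH2A.X focus).
- **qPCR**: each amplicon draws one baseline Ct uniform in [18, 26];
  non-untreated conditions add −log2(1−f) at target amplicons and 0 at
  housekeeping/control amplicons, plus Gaussian noise (σ = 0.1
  cycles). f = 1 is rejected (infinite shift).

What the simulation does *not* model — sequencing error, fragment-size
variation, PCR duplicates, mappability, splice junctions, chromatin
covariates, amplification-efficiency differences between primers —
bounds what passing tests show: they demonstrate that the statistics
recover planted structure under the declared noise models, not that
real libraries are free of the artefacts above.

## Numerical and design choices

- All randomness flows through `numpy.random.default_rng(seed)`;
  identical seeds give byte-identical outputs, and the pipeline writes
  no timestamps, so reruns are checksum-stable.
- Tie-breaks (classification ranks, cut/uncut membership, gene
  assignment) are lexicographic by coordinate or id — never
  insertion-order or hash-order dependent.
- Tracks are dense numpy bins (default 50 bp) rather than interval
  trees: the package targets desk-scale validation genomes, where
  dense arrays are simpler and faster; window means weight bins by bp
  overlap, and the last (ragged) bin of a chromosome is handled
  explicitly in bedGraph round trips.
- Problem sizes in tests and the acceptance script (two 200-kb
  chromosomes, 40 sites, ~10⁴ read pairs, 20 classification seeds,
  200 Monte-Carlo qPCR trials) were chosen so the full validation
  suite completes in seconds while keeping every statistical check
  comfortably powered.

## Known limitations

- The genic count for a real genome depends on the annotation release
  supplied; the package reports counts per annotation and hard-codes
  nothing.
- The classifier assumes a single ChIP replicate per arm; replicate-
  aware differential binding is out of scope.
- `select_cut_uncut` guarantees disjoint sets, which with heavy score
  ties means "bottom n of the remainder" rather than "bottom n
  overall"; with continuous scores the two coincide.
- The qPCR module does not calibrate amplification efficiency
  (standard curves) or perform melt-curve QC; it assumes the ideal
  doubling implied by the 2^(−ΔΔCt) transform.
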