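"""Metagene profiles of nascent transcription around cut vs uncut sites.

Averages the 3'-end signal across each site set in a gene-oriented
frame (offset 0 = site 5' end), smooths with a 5-nt forward rolling
average, and computes the per-site proximal ([0,500)) over distal
([1500,2000)) ratio.  Run 01_simulate_dataset.py first.
"""

from divanet import metagene, profile3p, sites
from divanet.simulate import SimTruth

truth = SimTruth.from_json("example_output/truth.json")
annotated = sites.annotate_sites(
    sites.scan_sites("example_output/genome.fa"), "example_output/genes.bed"
)
profile = profile3p.build_profile("example_output/mnet_induced.sam")

flag = dict(zip(truth.site_positions, truth.cut_flags))
cut = [s for s in annotated if flag[(s.chrom, s.start)]]
uncut = [s for s in annotated if not flag[(s.chrom, s.start)]]

for label, site_set in (("cut", cut), ("uncut", uncut)):
    mat = metagene.site_matrix(profile, site_set, flank=2000)
    prof = metagene.rolling_smooth(metagene.average_profile(mat))
    table, summary = metagene.proximal_distal_stat(mat)
    peak = prof.mean_sense.max()
    print(
        f"{label:>5}: {mat.n_sites} sites, smoothed sense peak {peak:.2f}, "
        f"proximal/distal median {summary['median']:.2f} "
        f"(IQR {summary['q1']:.2f}-{summary['q3']:.2f})"
    )
# Break-induced bidirectional transcription concentrates signal near the
# site: the cut-site median ratio far exceeds the uncut-site median.
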