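"""Synthetic DIvA-style data with known ground truth.

Generates toy genomes with planted AsiSI sites inside non-overlapping
genes, paired-end mNET-seq-like alignments whose 3'-of-read-2 positions
encode background gene-body transcription plus break-induced bidirectional
transcription decaying with distance from cut sites, gammaH2A.X-style
treatment/control ChIP tracks with boxcar enrichment around cut sites,
and qPCR Ct tables in which cutting a fraction ``f`` of templates shifts
the treated Ct by ``-log2(1-f)`` cycles.

Every generator is a pure function of its seed: identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .sites import MOTIF
from .tracks import CoverageTrack

__all__ = [
    "SimTruth",
    "simulate_genome",
    "simulate_mnet",
    "simulate_chip",
    "simulate_ct",
    "sam_header",
    "write_genome_fasta",
    "write_sam",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMP = str.maketrans("ACGT", "TGCA")

#: margin kept free of sites/genes at each chromosome end (bp)
DEFAULT_FLANK = 2000


@dataclass
class SimTruth:
    """Ground truth of one simulated experiment.

    ``site_positions`` are 0-based starts of the planted 8-bp motif;
    ``cut_flags``/``cut_fraction`` give, per site, whether the nuclease
    cuts it in vivo and the fraction of templates cut.  Rate parameters
    are carried here so that every downstream simulator draws from the
    same declared conditions.
    """

    seed: int
    chrom_lengths: dict[str, int]
    site_positions: list[tuple[str, int]]
    cut_flags: list[bool]
    cut_fraction: list[float]
    induction_rate: float = 200.0
    decay_length: float = 250.0
    background_rate: float = 5.0
    chip_enrichment: float = 8.0
    chip_spread: int = 2000
    ct_noise_sd: float = 0.1
    flank: int = DEFAULT_FLANK
    read_length: int = 50
    insert_size: int = 150
    site_genic: list[bool] = field(default_factory=list)

    def __post_init__(self):
        n = len(self.site_positions)
        if not (len(self.cut_flags) == len(self.cut_fraction) == n):
            raise ValueError("per-site truth vectors must have equal length")
        if not self.site_genic:
            self.site_genic = [True] * n
        for (chrom, start), f, cut in zip(
            self.site_positions, self.cut_fraction, self.cut_flags
        ):
            length = self.chrom_lengths[chrom]
            if start < self.flank or start + len(MOTIF) > length - self.flank:
                raise ValueError(
                    f"site {chrom}:{start} violates the {self.flank} bp flank margin"
                )
            if not 0.0 <= f <= 1.0:
                raise ValueError("cut_fraction must lie in [0, 1]")
            if not cut and f != 0.0:
                raise ValueError("uncut sites must have cut_fraction 0")
        positions = sorted(self.site_positions)
        for (c1, s1), (c2, s2) in zip(positions, positions[1:]):
            if c1 == c2 and s2 < s1 + len(MOTIF):
                raise ValueError("planted sites overlap")

    @property
    def n_sites(self) -> int:
        return len(self.site_positions)

    def to_json(self, path=None):
        d = asdict(self)
        d["site_positions"] = [list(p) for p in self.site_positions]
        text = json.dumps(d, indent=2, sort_keys=True)
        if path is None:
            return text
        Path(path).write_text(text)
        return None

    @classmethod
    def from_json(cls, source) -> "SimTruth":
        text = str(source)
        try:
            p = Path(text)
            if p.exists():
                text = p.read_text()
        except OSError:
            pass
        d = json.loads(text)
        d["site_positions"] = [tuple(p) for p in d["site_positions"]]
        return cls(**d)


# ----------------------------------------------------------------- genome


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _find_all(seq: str, motif: str) -> list[int]:
    out = []
    pos = seq.find(motif)
    while pos != -1:
        out.append(pos)
        pos = seq.find(motif, pos + 1)
    return out


def simulate_genome(
    n_chrom: int = 1,
    length_bp: int = 100_000,
    n_sites: int = 10,
    n_genes: int = 12,
    seed: int = 0,
    *,
    flank: int = DEFAULT_FLANK,
    gene_length: int = 3000,
    frac_cut: float = 0.5,
    cut_fraction: float | Sequence[float] = 0.8,
    n_intergenic: int = 0,
    induction_rate: float = 200.0,
    decay_length: float = 250.0,
    background_rate: float = 5.0,
    chip_enrichment: float = 8.0,
    chip_spread: int = 2000,
    ct_noise_sd: float = 0.1,
) -> tuple[dict[str, str], SimTruth, pd.DataFrame]:
    """Generate a random genome with planted AsiSI sites inside genes.

    Chromosomes (``chr1`` ...) are uniform random A/C/G/T of ``length_bp``
    each.  ``n_genes`` non-overlapping genes of ``gene_length`` bp with
    random strand are packed per chromosome (round-robin), each staying
    ``flank`` bp clear of the chromosome ends; the first ``n_sites`` genes
    (in shuffled order) each receive one planted motif.  ``n_intergenic``
    additional sites are planted between genes and are never cut.
    Spontaneous motif occurrences are destroyed by single-base
    substitution and the genome re-scanned until the planted set is the
    exact census.

    Returns ``(genome, truth, genes)`` where ``genome`` maps chrom ->
    sequence and ``genes`` is a BED6-style DataFrame.

    ``round(frac_cut * n_sites)`` genic sites are flagged cut, each with
    the given ``cut_fraction`` (scalar, or one value per cut site).
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    if n_chrom * length_bp < n_sites * 4000:
        raise ValueError(
            f"packing infeasible: {n_sites} sites need >= {n_sites * 4000} bp, "
            f"genome has {n_chrom * length_bp}"
        )
    if n_genes < n_sites:
        raise ValueError("need n_genes >= n_sites (one host gene per genic site)")

    rng = np.random.default_rng(seed)
    chrom_names = [f"chr{i + 1}" for i in range(n_chrom)]
    chrom_lengths = {c: length_bp for c in chrom_names}

    # pack genes: distribute counts round-robin, then place each
    # chromosome's genes by splitting the leftover bp into random gaps
    per_chrom = [n_genes // n_chrom + (1 if i < n_genes % n_chrom else 0)
                 for i in range(n_chrom)]
    genes: list[tuple[str, int, int, str, int, str]] = []
    gi = 0
    for chrom, g in zip(chrom_names, per_chrom):
        usable = length_bp - 2 * flank
        leftover = usable - g * gene_length
        if g > 0 and leftover < 0:
            raise ValueError(
                f"packing infeasible: {g} genes of {gene_length} bp do not fit "
                f"in {usable} usable bp on {chrom}"
            )
        gaps = rng.multinomial(leftover, [1.0 / (g + 1)] * (g + 1)) if g else []
        pos = flank
        for k in range(g):
            pos += int(gaps[k])
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append((chrom, pos, pos + gene_length, f"gene{gi:03d}", 0, strand))
            pos += gene_length
            gi += 1
    gene_df = pd.DataFrame(
        genes, columns=["chrom", "start", "end", "name", "score", "strand"]
    )

    # plant one site per host gene, clear of the gene edges
    host_order = rng.permutation(len(genes))[:n_sites]
    site_positions: list[tuple[str, int]] = []
    site_genic: list[bool] = []
    margin = 100  # keep the motif away from gene edges
    for idx in host_order:
        chrom, gs, ge = genes[idx][0], genes[idx][1], genes[idx][2]
        start = int(rng.integers(gs + margin, ge - margin - len(MOTIF)))
        site_positions.append((chrom, start))
        site_genic.append(True)

    # optional intergenic sites, planted in gaps between genes
    for _ in range(n_intergenic):
        placed = False
        for _attempt in range(200):
            chrom = chrom_names[int(rng.integers(0, n_chrom))]
            start = int(rng.integers(flank, length_bp - flank - len(MOTIF)))
            in_gene = any(
                g[0] == chrom and g[1] - margin < start < g[2] + margin
                for g in genes
            )
            near_site = any(
                c == chrom and abs(s - start) < 2 * len(MOTIF)
                for c, s in site_positions
            )
            if not in_gene and not near_site:
                site_positions.append((chrom, start))
                site_genic.append(False)
                placed = True
                break
        if not placed:
            raise ValueError("packing infeasible: cannot place intergenic site")

    # cut flags over genic sites only; intergenic sites are never cut
    genic_idx = [i for i, g in enumerate(site_genic) if g]
    n_cut = int(round(frac_cut * len(genic_idx)))
    cut_idx = set(
        int(i) for i in rng.choice(genic_idx, size=n_cut, replace=False)
    )
    cut_flags = [i in cut_idx for i in range(len(site_positions))]
    if np.isscalar(cut_fraction):
        fractions = [float(cut_fraction) if c else 0.0 for c in cut_flags]
    else:
        fvals = list(cut_fraction)
        if len(fvals) != n_cut:
            raise ValueError("cut_fraction sequence must have one value per cut site")
        it = iter(fvals)
        fractions = [float(next(it)) if c else 0.0 for c in cut_flags]

    # build sequences, plant motifs, destroy spontaneous occurrences
    arrays = {c: _random_sequence(rng, length_bp) for c in chrom_names}
    motif_arr = np.frombuffer(MOTIF.encode(), dtype="S1")
    for chrom, start in site_positions:
        arrays[chrom][start : start + len(MOTIF)] = motif_arr
    planted = {c: {s for cc, s in site_positions if cc == c} for c in chrom_names}
    for chrom in chrom_names:
        protected = planted[chrom]
        for _sweep in range(50):
            seq = arrays[chrom].tobytes().decode()
            spurious = [p for p in _find_all(seq, MOTIF) if p not in protected]
            if not spurious:
                break
            for p in spurious:
                # mutate one base of the occurrence lying outside any
                # planted window, so planted sites stay intact
                offsets = [
                    o
                    for o in range(len(MOTIF))
                    if not any(q <= p + o < q + len(MOTIF) for q in protected)
                ]
                o = int(rng.choice(offsets))
                old = arrays[chrom][p + o]
                choices = _BASES[_BASES != old]
                arrays[chrom][p + o] = choices[int(rng.integers(0, len(choices)))]
        else:
            raise RuntimeError("could not eliminate spontaneous motif occurrences")

    genome = {c: arrays[c].tobytes().decode() for c in chrom_names}
    truth = SimTruth(
        seed=seed,
        chrom_lengths=chrom_lengths,
        site_positions=site_positions,
        cut_flags=cut_flags,
        cut_fraction=fractions,
        induction_rate=induction_rate,
        decay_length=decay_length,
        background_rate=background_rate,
        chip_enrichment=chip_enrichment,
        chip_spread=chip_spread,
        ct_noise_sd=ct_noise_sd,
        flank=flank,
        site_genic=site_genic,
    )
    return genome, truth, gene_df


# ------------------------------------------------------------------- mNET


def sam_header(truth: SimTruth) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [
                {"SN": c, "LN": int(l)} for c, l in truth.chrom_lengths.items()
            ],
        }
    )


def _make_pair(
    header: pysam.AlignmentHeader,
    genome: Mapping[str, str],
    qname: str,
    chrom: str,
    pos3p: int,
    strand: str,
    read_length: int,
    insert_size: int,
) -> tuple[pysam.AlignedSegment, pysam.AlignedSegment] | None:
    """Build a proper pair whose 3'-of-read-2 signal is (chrom, pos3p, strand).

    Strand '+' uses flags (99, 147): read 1 forward at the fragment's left
    end, read 2 reverse at its right end, so read 2's leftmost base is the
    signal.  Strand '-' uses (83, 163) mirrored.  Returns None when the
    fragment would leave the chromosome.
    """
    L = len(genome[chrom])
    gap = insert_size - 2 * read_length
    if strand == "+":
        frag_start = pos3p - read_length - gap
        r1_start, r2_start = frag_start, pos3p
    else:
        r2_start = pos3p - read_length + 1
        frag_start = r2_start
        r1_start = r2_start + read_length + gap
    frag_end = frag_start + insert_size
    if frag_start < 0 or frag_end > L:
        return None

    tid = header.get_tid(chrom)
    r1 = pysam.AlignedSegment(header)
    r2 = pysam.AlignedSegment(header)
    for r, start, flag in (
        (r1, r1_start, 99 if strand == "+" else 83),
        (r2, r2_start, 147 if strand == "+" else 163),
    ):
        r.query_name = qname
        r.flag = flag
        r.reference_id = tid
        r.reference_start = start
        r.mapping_quality = 60
        r.cigarstring = f"{read_length}M"
        r.query_sequence = genome[chrom][start : start + read_length]
        r.query_qualities = pysam.qualitystring_to_array("I" * read_length)
    r1.next_reference_id = tid
    r2.next_reference_id = tid
    r1.next_reference_start = r2.reference_start
    r2.next_reference_start = r1.reference_start
    sign = 1 if strand == "+" else -1
    r1.template_length = sign * insert_size
    r2.template_length = -sign * insert_size
    return r1, r2


def _truncated_geometric(
    rng: np.random.Generator, n: int, scale: float, truncate: int
) -> np.ndarray:
    """Geometric offsets (support >= 1) with mean ``scale``, resampled above ``truncate``."""
    p = 1.0 / scale
    out = rng.geometric(p, size=n)
    bad = out > truncate
    while bad.any():
        out[bad] = rng.geometric(p, size=int(bad.sum()))
        bad = out > truncate
    return out


def simulate_mnet(
    genome: Mapping[str, str],
    truth: SimTruth,
    genes: pd.DataFrame,
    induced: bool,
    seed: int,
    *,
    decay_truncate: int = 2000,
) -> tuple[list[pysam.AlignedSegment], pysam.AlignmentHeader]:
    """Simulate mNET-seq proper pairs (flags 99/147 and 83/163 only).

    Background transcription emits ``Poisson(background_rate * kb)`` pairs
    per gene with 3'-of-read-2 positions uniform over the gene body, on
    the gene's strand.  When ``induced``, each cut site additionally
    emits ``Poisson(induction_rate * cut_fraction)`` pairs per strand,
    placed at a truncated-geometric distance (mean ``decay_length``, cap
    ``decay_truncate``) downstream of the site start on '+' and upstream
    on '-' — bidirectional transcription pointing away from the break.

    Returns the records (name-grouped, mates adjacent) and their header.
    """
    rng = np.random.default_rng(seed)
    header = sam_header(truth)
    signals: list[tuple[str, int, str]] = []

    for row in genes.itertuples(index=False):
        kb = (row.end - row.start) / 1000.0
        n = rng.poisson(truth.background_rate * kb)
        if n:
            positions = rng.integers(row.start, row.end, size=n)
            signals.extend((row.chrom, int(p), row.strand) for p in positions)

    if induced:
        for (chrom, start), cut, f in zip(
            truth.site_positions, truth.cut_flags, truth.cut_fraction
        ):
            if not cut or f <= 0:
                continue
            for strand in ("+", "-"):
                n = rng.poisson(truth.induction_rate * f)
                if not n:
                    continue
                offsets = _truncated_geometric(
                    rng, n, truth.decay_length, decay_truncate
                )
                if strand == "+":
                    positions = start + offsets
                else:
                    positions = start - offsets
                signals.extend((chrom, int(p), strand) for p in positions)

    records: list[pysam.AlignedSegment] = []
    for i, (chrom, pos, strand) in enumerate(signals):
        pair = _make_pair(
            header,
            genome,
            f"sim{i:07d}",
            chrom,
            pos,
            strand,
            truth.read_length,
            truth.insert_size,
        )
        if pair is not None:
            records.extend(pair)
    return records, header


def write_sam(records: Iterable[pysam.AlignedSegment], header, path) -> None:
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for rec in records:
            fh.write(rec)


def write_genome_fasta(genome: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# -------------------------------------------------------------------- ChIP


def simulate_chip(
    truth: SimTruth,
    depth: int,
    seed: int,
    *,
    binsize: int = 50,
) -> tuple[CoverageTrack, CoverageTrack]:
    """Simulate gammaH2A.X-style treatment and H2A.X control tracks.

    The control is flat Poisson noise with mean ``depth`` per bin.  The
    treatment adds a boxcar of half-width ``chip_spread`` and amplitude
    ``(chip_enrichment - 1) * depth`` around each *cut* site, so the
    expected treatment/control ratio inside the window is
    ``chip_enrichment`` and 1 elsewhere (including uncut sites).
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    rng = np.random.default_rng(seed)
    control = CoverageTrack(binsize=binsize, chrom_lengths=dict(truth.chrom_lengths))
    treatment = CoverageTrack(binsize=binsize, chrom_lengths=dict(truth.chrom_lengths))
    lam = {
        c: np.full((length + binsize - 1) // binsize, float(depth))
        for c, length in truth.chrom_lengths.items()
    }
    for (chrom, start), cut in zip(truth.site_positions, truth.cut_flags):
        if not cut:
            continue
        lo = max(0, start - truth.chip_spread) // binsize
        hi = min(
            truth.chrom_lengths[chrom], start + len(MOTIF) + truth.chip_spread
        )
        hi = (hi + binsize - 1) // binsize
        lam[chrom][lo:hi] += (truth.chip_enrichment - 1.0) * depth
    for chrom, length in truth.chrom_lengths.items():
        nbins = (length + binsize - 1) // binsize
        control.values[chrom] = rng.poisson(float(depth), size=nbins).astype(float)
        treatment.values[chrom] = rng.poisson(lam[chrom]).astype(float)
    return treatment, control


# -------------------------------------------------------------------- qPCR


def simulate_ct(
    truth: SimTruth,
    amplicon_map: Mapping[str, int | None],
    replicates: int = 3,
    seed: int = 0,
    *,
    housekeeping: Sequence[str] = ("ACTB", "GAPDH"),
    control_loci: Sequence[str] = ("noDSB",),
    conditions: Sequence[str] = ("untreated", "treated"),
) -> pd.DataFrame:
    """Simulate a qPCR Ct table for DSB quantitation.

    ``amplicon_map`` maps target amplicon ids to the index of the site
    they span (in ``truth.site_positions``).  For a site cut in fraction
    ``f`` of templates, every non-untreated condition loses fraction
    ``f`` of amplifiable template, shifting its Ct by ``-log2(1-f)``
    cycles; housekeeping and control-locus amplicons shift by 0.  Each
    amplicon's baseline Ct is drawn once, uniform in [18, 26]; Gaussian
    noise of sd ``truth.ct_noise_sd`` cycles is added per measurement.

    Returns a tidy DataFrame with columns
    (amplicon_id, role, condition, replicate, ct).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    plan: list[tuple[str, str, float]] = []  # (amplicon, role, f)
    for amp, site_idx in amplicon_map.items():
        f = 0.0
        if site_idx is not None:
            f = truth.cut_fraction[site_idx]
        if f >= 1.0:
            raise ValueError(
                f"cut fraction 1 at amplicon {amp!r}: Ct shift is infinite"
            )
        plan.append((amp, "target", f))
    plan.extend((amp, "control_locus", 0.0) for amp in control_loci)
    plan.extend((amp, "housekeeping", 0.0) for amp in housekeeping)

    rows = []
    for amp, role, f in plan:
        baseline = float(rng.uniform(18.0, 26.0))
        shift = -np.log2(1.0 - f)
        for condition in conditions:
            for rep in range(1, replicates + 1):
                ct = baseline + (shift if condition != "untreated" else 0.0)
                ct += float(rng.normal(0.0, truth.ct_noise_sd)) if truth.ct_noise_sd else 0.0
                rows.append(
                    {
                        "amplicon_id": amp,
                        "role": role,
                        "condition": condition,
                        "replicate": rep,
                        "ct": ct,
                    }
                )
    return pd.DataFrame(rows)
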