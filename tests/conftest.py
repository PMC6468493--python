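"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's own code paths: the
motif oracle tests every 8-mer window by string comparison, and the
3'-end oracle re-derives pair signals from raw SAM text fields.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict

import pytest
from hypothesis import settings

from divanet import simulate

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

MOTIF = "GCGATCGC"


# ------------------------------------------------------------------ oracles


def brute_force_scan(genome: dict[str, str]) -> list[tuple[str, int]]:
    """Test every 8-bp window against the motif, one window at a time."""
    hits = []
    for chrom in sorted(genome):
        seq = genome[chrom].upper()
        for i in range(len(seq) - len(MOTIF) + 1):
            if seq[i : i + len(MOTIF)] == MOTIF:
                hits.append((chrom, i))
    return hits


_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def _aligned_span(pos1: int, cigar: str) -> tuple[int, int]:
    """0-based [start, end) of the aligned reference span from SAM fields."""
    start = pos1 - 1
    ref_len = sum(
        int(n) for n, op in _CIGAR_RE.findall(cigar) if op in "MDN=X"
    )
    return start, start + ref_len


def brute_force_profile(sam_text: str) -> dict[tuple[str, str], Counter]:
    """Re-derive per-position 3'-end counts from raw SAM text.

    Groups records by QNAME, keeps only flag pairs (99,147)/(83,163),
    takes the 3'-most aligned base of read 2 and the strand of read 1.
    """
    groups: dict[str, list[tuple[int, str, int, str]]] = defaultdict(list)
    for line in sam_text.splitlines():
        if not line or line.startswith("@"):
            continue
        f = line.split("\t")
        groups[f[0]].append((int(f[1]), f[2], int(f[3]), f[5]))
    counts: dict[tuple[str, str], Counter] = defaultdict(Counter)
    for recs in groups.values():
        if len(recs) != 2:
            continue
        r1 = next((r for r in recs if r[0] & 0x40), None)
        r2 = next((r for r in recs if r[0] & 0x80), None)
        if r1 is None or r2 is None:
            continue
        if (r1[0], r2[0]) not in {(99, 147), (83, 163)}:
            continue
        start, end = _aligned_span(r2[2], r2[3])
        pos = start if (r2[0] & 0x10) else end - 1
        strand = "-" if (r1[0] & 0x10) else "+"
        counts[(r1[1], strand)][pos] += 1
    return {k: v for k, v in counts.items() if v}


def sam_to_text(records, header) -> str:
    return str(header) + "".join(r.to_string() + "\n" for r in records)


# ----------------------------------------------------------------- fixtures


@pytest.fixture(scope="session")
def small_sim():
    """Two-chromosome genome with 40 genic sites, half of them cut."""
    genome, truth, genes = simulate.simulate_genome(
        n_chrom=2, length_bp=200_000, n_sites=40, n_genes=48, seed=11
    )
    return genome, truth, genes


@pytest.fixture(scope="session")
def induced_profile(small_sim):
    """3'-end profile of an induced mNET-seq simulation on small_sim."""
    from divanet import profile3p

    genome, truth, genes = small_sim
    records, header = simulate.simulate_mnet(genome, truth, genes, induced=True, seed=12)
    return profile3p.build_profile(records)


@pytest.fixture(scope="session")
def annotated_sites(small_sim):
    from divanet import sites as sites_mod

    genome, _truth, genes = small_sim
    return sites_mod.annotate_sites(sites_mod.scan_sites(genome), genes)
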