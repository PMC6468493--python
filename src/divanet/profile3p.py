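"""Strand-specific single-nucleotide 3'-end profiles from mNET-seq pairs.

In mNET-seq the 3'-most nucleotide of the nascent RNA marks the position
of the transcribing RNA polymerase II.  After paired-end alignment this
position is recovered as the 3'-most aligned base of read 2, and the
transcript strand as the strand of read 1.  Only properly paired primary
alignments are used, i.e. the FLAG combinations (99, 147) and (83, 163).
"""

from __future__ import annotations

import io
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pysam

logger = logging.getLogger(__name__)

#: FLAG pairs accepted for profiling: (read1, read2) both proper-pair
#: primary alignments.  0x63/0x93 = 99/147 (read 1 forward), 0x53/0xA3 =
#: 83/163 (read 1 reverse).
ACCEPTED_FLAG_PAIRS = frozenset({(0x63, 0x93), (0x53, 0xA3)})

__all__ = [
    "ACCEPTED_FLAG_PAIRS",
    "StrandProfile",
    "accept_pair",
    "pair_signal",
    "build_profile",
    "export_bedgraph",
    "import_bedgraph",
]


@dataclass
class StrandProfile:
    """Sparse per-(chrom, strand) single-nucleotide 3'-end counts.

    ``counts`` maps ``(chrom, strand)`` to a Counter of 0-based position
    -> number of accepted pairs whose RNAPII position falls there.
    """

    counts: dict[tuple[str, str], Counter] = field(default_factory=dict)
    n_pairs_seen: int = 0
    n_pairs_accepted: int = 0
    n_orphans: int = 0
    n_cross_reference: int = 0

    def add(self, chrom: str, position: int, strand: str, count: int = 1) -> None:
        self.counts.setdefault((chrom, strand), Counter())[position] += count

    def total(self) -> int:
        return sum(sum(c.values()) for c in self.counts.values())

    def get(self, chrom: str, position: int, strand: str) -> int:
        return self.counts.get((chrom, strand), Counter()).get(position, 0)


def accept_pair(flag_read1: int, flag_read2: int) -> bool:
    """True iff the pair's FLAGs are one of the two accepted combinations.

    Everything else — unmapped, non-proper, secondary, supplementary,
    singleton, wrong orientation — is rejected.
    """
    return (flag_read1, flag_read2) in ACCEPTED_FLAG_PAIRS


def pair_signal(
    read1: pysam.AlignedSegment, read2: pysam.AlignedSegment
) -> tuple[str, int, str]:
    """RNAPII position and strand for one accepted pair.

    Position is the reference coordinate of the 3'-most *aligned* base of
    read 2 (CIGAR-aware; soft clips excluded): the rightmost aligned base
    when read 2 maps forward, the leftmost when it maps reverse.  Strand
    is read 1's strand.
    """
    if read1.reference_name != read2.reference_name:
        raise ValueError("mates aligned to different references")
    if read2.is_reverse:
        position = read2.reference_start
    else:
        position = read2.reference_end - 1
    strand = "-" if read1.is_reverse else "+"
    return read2.reference_name, position, strand


def _iter_records(alignments):
    """Yield AlignedSegments from a path, AlignmentFile or iterable."""
    if isinstance(alignments, (str, Path)):
        with pysam.AlignmentFile(str(alignments), check_sq=False) as fh:
            yield from fh
        return
    if isinstance(alignments, pysam.AlignmentFile):
        yield from alignments
        return
    yield from alignments


def build_profile(
    alignments,
    *,
    min_mapq: int = 0,
    flip_strand: bool = False,
) -> StrandProfile:
    """Build a 3'-end profile from an alignment stream.

    Records are paired by query name (first two records sharing a name
    form the pair), so the stream need not be sorted.  No deduplication
    is performed.  Pairs failing :func:`accept_pair`, mapped below
    ``min_mapq``, or split across references are counted and skipped;
    mates left unpaired at end of stream are counted as orphans.

    ``flip_strand`` swaps '+'/'-' on every signal, for library preps
    whose read-1 orientation is antisense to the transcript.
    """
    profile = StrandProfile()
    pending: dict[str, pysam.AlignedSegment] = {}
    for rec in _iter_records(alignments):
        mate = pending.pop(rec.query_name, None)
        if mate is None:
            pending[rec.query_name] = rec
            continue
        profile.n_pairs_seen += 1
        if rec.flag & 0x40:  # rec is read 1
            r1, r2 = rec, mate
        else:
            r1, r2 = mate, rec
        if not accept_pair(r1.flag, r2.flag):
            continue
        if r1.mapping_quality < min_mapq or r2.mapping_quality < min_mapq:
            continue
        if r1.reference_name != r2.reference_name:
            profile.n_cross_reference += 1
            logger.warning("pair %s spans references; skipped", r1.query_name)
            continue
        chrom, pos, strand = pair_signal(r1, r2)
        if flip_strand:
            strand = "-" if strand == "+" else "+"
        profile.add(chrom, pos, strand)
        profile.n_pairs_accepted += 1
    profile.n_orphans = len(pending)
    if profile.n_orphans:
        logger.info("%d orphan mates at end of stream", profile.n_orphans)
    return profile


def export_bedgraph(
    profile: StrandProfile,
    strand: str,
    path_or_handle=None,
    *,
    negate_minus: bool = False,
):
    """Write one strand of a profile as single-bp bedGraph intervals.

    Lines are sorted by (chrom, position); minus-strand values can be
    negated for stacked browser display.  Returns the text when no
    path/handle is given.
    """
    if strand not in ("+", "-"):
        raise ValueError("strand must be '+' or '-'")
    sign = -1 if (negate_minus and strand == "-") else 1
    buf = io.StringIO()
    buf.write(f"track type=bedGraph name=mnet3p_{'plus' if strand == '+' else 'minus'}\n")
    for (chrom, s), counter in sorted(profile.counts.items()):
        if s != strand:
            continue
        for pos in sorted(counter):
            buf.write(f"{chrom}\t{pos}\t{pos + 1}\t{sign * counter[pos]}\n")
    text = buf.getvalue()
    if path_or_handle is None:
        return text
    if hasattr(path_or_handle, "write"):
        path_or_handle.write(text)
    else:
        with open(path_or_handle, "w") as fh:
            fh.write(text)
    return None


def import_bedgraph(plus_source, minus_source) -> StrandProfile:
    """Rebuild a StrandProfile from the two per-strand bedGraph outputs.

    Inverse of :func:`export_bedgraph` (with ``negate_minus=False``);
    ``n_pairs_seen``/``n_pairs_accepted`` are set to the recovered total.
    """
    profile = StrandProfile()
    for source, strand in ((plus_source, "+"), (minus_source, "-")):
        if source is None:
            continue
        if hasattr(source, "read"):
            text = source.read()
        else:
            try:
                with open(source) as fh:
                    text = fh.read()
            except (OSError, ValueError):
                text = source
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            chrom, s, _e, val = line.split("\t")[:4]
            profile.add(chrom, int(s), strand, int(val))
    n = profile.total()
    profile.n_pairs_seen = n
    profile.n_pairs_accepted = n
    return profile
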