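"""Damage scoring and cut/uncut site selection from ChIP tracks.

Each AsiSI site is scored by the log2 ratio of gammaH2A.X (treatment)
over H2A.X (control) coverage in a window around the site, after
counts-per-million normalization of both tracks — the same quantity
deepTools' ``bamCompare`` produces, computed here directly from tracks.
The top-N scoring genic sites form the "cut" set and the bottom-N the
"uncut" negative-control set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .sites import GenomeSite
from .tracks import CoverageTrack

logger = logging.getLogger(__name__)

__all__ = [
    "SiteScore",
    "normalize_cpm",
    "site_log2_score",
    "score_sites",
    "select_cut_uncut",
    "bam_to_track",
    "scores_to_frame",
]


@dataclass
class SiteScore:
    """Per-site damage score with rank (1 = highest) and label."""

    site_id: str
    chrom: str
    start: int
    genic: bool
    log2_ratio: float
    rank: int | None = None
    label: str = "unlabelled"


def normalize_cpm(track: CoverageTrack) -> CoverageTrack:
    """Scale a track to counts-per-million: total over all bins becomes 1e6."""
    total = track.total()
    if total <= 0:
        raise ValueError("cannot CPM-normalize a track with zero total signal")
    return track.scaled(1e6 / total)


def site_log2_score(
    site: GenomeSite,
    treatment: CoverageTrack,
    control: CoverageTrack,
    window_bp: int = 1000,
    pseudocount: float = 1.0,
) -> float:
    """log2((T + p) / (C + p)) over ``[start - window_bp, end + window_bp)``.

    ``T`` and ``C`` are mean CPM-normalized bin values over the window
    (clipped to the chromosome with a log message if truncated).
    """
    lo = site.start - window_bp
    hi = site.end + window_bp
    length = treatment.chrom_lengths.get(site.chrom)
    if lo < 0 or (length is not None and hi > length):
        logger.info("window for %s truncated to chromosome bounds", site.site_id)
    t = treatment.mean(site.chrom, lo, hi)
    c = control.mean(site.chrom, lo, hi)
    return float(np.log2((t + pseudocount) / (c + pseudocount)))


def score_sites(
    sites: Iterable[GenomeSite],
    treatment: CoverageTrack,
    control: CoverageTrack,
    window_bp: int = 1000,
    pseudocount: float = 1.0,
    *,
    assume_normalized: bool = False,
) -> list[SiteScore]:
    """Score every site; tracks are CPM-normalized here unless told otherwise.

    Ranks are assigned 1..n by descending score, ties broken by
    (chrom, start) ascending.
    """
    if not assume_normalized:
        treatment = normalize_cpm(treatment)
        control = normalize_cpm(control)
    scores = [
        SiteScore(
            site_id=s.site_id,
            chrom=s.chrom,
            start=s.start,
            genic=s.genic,
            log2_ratio=site_log2_score(s, treatment, control, window_bp, pseudocount),
        )
        for s in sites
    ]
    for rank, sc in enumerate(
        sorted(scores, key=lambda x: (-x.log2_ratio, x.chrom, x.start)), start=1
    ):
        sc.rank = rank
    return scores


def select_cut_uncut(
    scores: Sequence[SiteScore],
    n: int,
    genic_only: bool = True,
) -> tuple[list[str], list[str]]:
    """Pick the n highest-scoring sites as "cut" and n lowest as "uncut".

    Ties are broken by (chrom, start) ascending; the two sets are always
    disjoint.  Labels are written back into the SiteScore objects.
    Raises ``ValueError`` naming the shortfall when fewer than ``2n``
    eligible sites exist.
    """
    eligible = [s for s in scores if s.genic] if genic_only else list(scores)
    if len(eligible) < 2 * n:
        raise ValueError(
            f"need >= {2 * n} eligible sites for n={n}, have {len(eligible)} "
            f"(short by {2 * n - len(eligible)})"
        )
    for s in scores:
        s.label = "unlabelled"
    by_desc = sorted(eligible, key=lambda s: (-s.log2_ratio, s.chrom, s.start))
    cut = by_desc[:n]
    rest = by_desc[n:]
    uncut = sorted(rest, key=lambda s: (s.log2_ratio, s.chrom, s.start))[:n]
    for s in cut:
        s.label = "cut"
    for s in uncut:
        s.label = "uncut"
    return [s.site_id for s in cut], [s.site_id for s in uncut]


def scores_to_frame(scores: Iterable[SiteScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "site_id": s.site_id,
                "chrom": s.chrom,
                "start": s.start,
                "genic": s.genic,
                "log2_ratio": s.log2_ratio,
                "rank": s.rank,
                "label": s.label,
            }
            for s in scores
        ]
    )


def bam_to_track(
    alignments,
    chrom_lengths: dict[str, int],
    binsize: int = 50,
) -> CoverageTrack:
    """Count alignment start positions per bin (helper for BAM/SAM ChIP input)."""
    track = CoverageTrack(binsize=binsize, chrom_lengths=dict(chrom_lengths))
    for c, length in chrom_lengths.items():
        track.values[c] = np.zeros((length + binsize - 1) // binsize)
    if isinstance(alignments, (str,)):
        handle = pysam.AlignmentFile(alignments, check_sq=False)
        records = iter(handle)
    else:
        handle = None
        records = iter(alignments)
    for rec in records:
        if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
            continue
        chrom = rec.reference_name
        if chrom in track.values:
            track.values[chrom][rec.reference_start // binsize] += 1
    if handle is not None:
        handle.close()
    return track
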