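"""Metagene profiles of RNAPII 3'-end signal around AsiSI sites.

Signals are accumulated in a gene-oriented frame: offset 0 is the 5' end
of the site in the host gene's reading direction, positive offsets run
downstream, "sense" is the host gene's strand.  For a minus-strand host
gene the offset axis and the strand labels are therefore both flipped,
so sites of mixed orientation average coherently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .profile3p import StrandProfile
from .sites import GenomeSite

logger = logging.getLogger(__name__)

__all__ = [
    "MetageneMatrix",
    "MetageneProfile",
    "site_matrix",
    "average_profile",
    "rolling_smooth",
    "proximal_distal_stat",
]


@dataclass
class MetageneMatrix:
    """Per-site sense/antisense signal vectors on offsets [-flank, +flank]."""

    site_ids: list[str]
    flank: int
    sense: np.ndarray  # shape (n_sites, 2*flank + 1)
    antisense: np.ndarray

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.flank, self.flank + 1)

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    def window_sums(self, lo: int, hi: int) -> np.ndarray:
        """Per-site sense+antisense totals over offsets ``[lo, hi)``."""
        if lo < -self.flank or hi > self.flank + 1:
            raise ValueError(f"window [{lo},{hi}) outside [-{self.flank},{self.flank}]")
        i0, i1 = lo + self.flank, hi + self.flank
        return self.sense[:, i0:i1].sum(axis=1) + self.antisense[:, i0:i1].sum(axis=1)


@dataclass
class MetageneProfile:
    """Across-site mean of a MetageneMatrix, optionally smoothed."""

    flank: int
    mean_sense: np.ndarray
    mean_antisense: np.ndarray
    n_sites: int
    smoothed: bool = False

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.flank, self.flank + 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "offset": self.offsets,
                "sense": self.mean_sense,
                "antisense": self.mean_antisense,
            }
        )


def site_matrix(
    profile: StrandProfile,
    sites: list[GenomeSite],
    flank: int = 2000,
    *,
    orientation: str = "gene",
    chrom_lengths: dict[str, int] | None = None,
) -> MetageneMatrix:
    """Collect per-site signal vectors around site 5' ends.

    In ``gene`` orientation every site must carry a host-gene strand; for
    a '+' gene ``offset = pos - site.start`` and sense is the '+' profile,
    for a '-' gene ``offset = (site.end - 1) - pos`` and sense is the '-'
    profile.  ``reference`` orientation treats every site as '+'.

    Sites whose window leaves the chromosome (requires ``chrom_lengths``)
    are dropped with a log message rather than zero-padded.
    """
    if not sites:
        raise ValueError("empty site list")
    if orientation not in ("gene", "reference"):
        raise ValueError("orientation must be 'gene' or 'reference'")

    kept: list[GenomeSite] = []
    for s in sites:
        if orientation == "gene" and s.gene_strand not in ("+", "-"):
            raise ValueError(
                f"site {s.site_id} has no host-gene strand; annotate sites "
                "or use orientation='reference'"
            )
        if chrom_lengths is not None:
            length = chrom_lengths[s.chrom]
            if s.start - flank < 0 or s.end - 1 + flank >= length:
                logger.info("site %s window exceeds %s bounds; dropped", s.site_id, s.chrom)
                continue
        kept.append(s)
    if not kept:
        raise ValueError("all sites dropped (windows exceed chromosome bounds)")

    width = 2 * flank + 1
    sense = np.zeros((len(kept), width))
    antisense = np.zeros((len(kept), width))
    for i, s in enumerate(kept):
        strand = s.gene_strand if orientation == "gene" else "+"
        plus = profile.counts.get((s.chrom, "+"), {})
        minus = profile.counts.get((s.chrom, "-"), {})
        if strand == "+":
            sense_src, anti_src = plus, minus
            anchor, step = s.start, 1
        else:
            sense_src, anti_src = minus, plus
            anchor, step = s.end - 1, -1
        for j, off in enumerate(range(-flank, flank + 1)):
            pos = anchor + step * off
            v = sense_src.get(pos, 0)
            if v:
                sense[i, j] = v
            v = anti_src.get(pos, 0)
            if v:
                antisense[i, j] = v
    return MetageneMatrix(
        site_ids=[s.site_id for s in kept], flank=flank, sense=sense, antisense=antisense
    )


def average_profile(matrix: MetageneMatrix) -> MetageneProfile:
    """Per-offset arithmetic mean across sites, sense and antisense separately."""
    if matrix.n_sites == 0:
        raise ValueError("empty matrix")
    return MetageneProfile(
        flank=matrix.flank,
        mean_sense=matrix.sense.mean(axis=0),
        mean_antisense=matrix.antisense.mean(axis=0),
        n_sites=matrix.n_sites,
        smoothed=False,
    )


def _forward_rolling(v: np.ndarray, window: int) -> np.ndarray:
    """mean(v[x .. x+window-1]) with a shrinking window at the right edge."""
    n = len(v)
    cs = np.concatenate(([0.0], np.cumsum(v)))
    idx = np.arange(n)
    hi = np.minimum(idx + window, n)
    return (cs[hi] - cs[idx]) / (hi - idx)


def rolling_smooth(profile: MetageneProfile, window: int = 5) -> MetageneProfile:
    """Forward rolling average: smoothed[x] = mean over offsets [x, x+window-1].

    At the right edge, where fewer than ``window`` positions remain, the
    mean is over the positions available (the last point is unchanged).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    return MetageneProfile(
        flank=profile.flank,
        mean_sense=_forward_rolling(profile.mean_sense, window),
        mean_antisense=_forward_rolling(profile.mean_antisense, window),
        n_sites=profile.n_sites,
        smoothed=True,
    )


def proximal_distal_stat(
    matrix: MetageneMatrix,
    proximal: tuple[int, int] = (0, 500),
    distal: tuple[int, int] = (1500, 2000),
    pseudocount: float = 1.0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-site ratio of site-proximal to downstream signal, with summary.

    For each site, ``ratio = (sum of sense+antisense over the proximal
    offset window + p) / (same over the distal window + p)``; windows are
    half-open in gene-oriented offsets.  Returns the per-site table and a
    summary dict with the median and quartiles across sites.
    """
    prox = matrix.window_sums(*proximal)
    dist = matrix.window_sums(*distal)
    ratio = (prox + pseudocount) / (dist + pseudocount)
    table = pd.DataFrame(
        {
            "site_id": matrix.site_ids,
            "proximal_sum": prox,
            "distal_sum": dist,
            "ratio": ratio,
        }
    )
    q1, med, q3 = (float(np.percentile(ratio, q)) for q in (25, 50, 75))
    return table, {"median": med, "q1": q1, "q3": q3, "n_sites": matrix.n_sites}
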