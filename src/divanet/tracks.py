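"""Binned genome coverage tracks with bedGraph I/O.

A :class:`CoverageTrack` holds one non-negative value per fixed-width bin
per chromosome.  Tracks are the common currency between the ChIP simulator
and the damage-score classifier; they deliberately stay dense (numpy arrays)
because the synthetic genomes this package operates on are small.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

__all__ = ["CoverageTrack"]


@dataclass
class CoverageTrack:
    """Per-chromosome binned coverage values.

    Parameters
    ----------
    binsize
        Width of each bin in bp.  The last bin of a chromosome may cover
        fewer than ``binsize`` bases.
    values
        Mapping chromosome -> float array of per-bin values.
    chrom_lengths
        Mapping chromosome -> length in bp.  Required so that bedGraph
        output can clip the final bin.
    """

    binsize: int
    values: dict[str, np.ndarray] = field(default_factory=dict)
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def total(self) -> float:
        """Sum of all bin values across all chromosomes."""
        return float(sum(v.sum() for v in self.values.values()))

    def copy(self) -> "CoverageTrack":
        return CoverageTrack(
            binsize=self.binsize,
            values={c: v.copy() for c, v in self.values.items()},
            chrom_lengths=dict(self.chrom_lengths),
        )

    def scaled(self, factor: float) -> "CoverageTrack":
        out = self.copy()
        for c in out.values:
            out.values[c] = out.values[c] * factor
        return out

    def mean(self, chrom: str, start: int, end: int) -> float:
        """Mean bin value over ``[start, end)``, weighted by bp overlap.

        The window is clipped to the chromosome; a fully out-of-range
        window raises ``ValueError``.
        """
        if chrom not in self.values:
            raise ValueError(f"chromosome {chrom!r} not in track")
        length = self.chrom_lengths.get(chrom, len(self.values[chrom]) * self.binsize)
        start = max(0, start)
        end = min(end, length)
        if end <= start:
            raise ValueError(f"window [{start},{end}) is empty after clipping")
        v = self.values[chrom]
        total = 0.0
        span = 0
        b0 = start // self.binsize
        b1 = (end - 1) // self.binsize
        for b in range(b0, b1 + 1):
            lo = max(start, b * self.binsize)
            hi = min(end, (b + 1) * self.binsize, length)
            w = hi - lo
            total += float(v[b]) * w
            span += w
        return total / span

    # ------------------------------------------------------------------ I/O

    def to_bedgraph(self, path_or_handle=None, *, include_zero: bool = False):
        """Write the track as bedGraph (0-based half-open intervals).

        Adjacent bins with equal value are merged into one interval.
        Returns the text when no path/handle is given.
        """
        buf = io.StringIO()
        buf.write("track type=bedGraph\n")
        for chrom in sorted(self.values):
            v = self.values[chrom]
            length = self.chrom_lengths.get(chrom, len(v) * self.binsize)
            run_start = 0
            run_val = v[0] if len(v) else 0.0
            for b in range(1, len(v) + 1):
                val = v[b] if b < len(v) else None
                if val is None or val != run_val:
                    if include_zero or run_val != 0:
                        s = run_start * self.binsize
                        e = min(b * self.binsize, length)
                        buf.write(f"{chrom}\t{s}\t{e}\t{run_val:g}\n")
                    run_start = b
                    run_val = val
        text = buf.getvalue()
        if path_or_handle is None:
            return text
        if hasattr(path_or_handle, "write"):
            path_or_handle.write(text)
        else:
            with open(path_or_handle, "w") as fh:
                fh.write(text)
        return None

    @classmethod
    def from_bedgraph(
        cls,
        source,
        binsize: int,
        chrom_lengths: dict[str, int],
    ) -> "CoverageTrack":
        """Read a bedGraph file/text into a binned track.

        Interval values are distributed over the bins they overlap in
        proportion to the bp overlapped, so reading back a track written
        by :meth:`to_bedgraph` with the same ``binsize`` is lossless.
        """
        if hasattr(source, "read"):
            text = source.read()
        else:
            try:
                with open(source) as fh:
                    text = fh.read()
            except (OSError, ValueError):
                text = source
        values = {
            c: np.zeros((length + binsize - 1) // binsize)
            for c, length in chrom_lengths.items()
        }
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            chrom, s, e, val = line.split("\t")[:4]
            s, e, val = int(s), int(e), float(val)
            if chrom not in values:
                raise ValueError(f"bedGraph chromosome {chrom!r} not in chrom_lengths")
            v = values[chrom]
            length = chrom_lengths[chrom]
            b0, b1 = s // binsize, (e - 1) // binsize
            for b in range(b0, b1 + 1):
                lo = max(s, b * binsize)
                hi = min(e, (b + 1) * binsize)
                # last bin of a chromosome may be narrower than binsize
                width = min((b + 1) * binsize, length) - b * binsize
                v[b] += val * (hi - lo) / width
        return cls(binsize=binsize, values=values, chrom_lengths=dict(chrom_lengths))
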