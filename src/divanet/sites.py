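"""AsiSI recognition-site discovery and genic annotation.

The AsiSI endonuclease cuts at the 8-bp motif ``GCGATCGC``.  The motif is
its own reverse complement, so scanning the forward strand alone reports
every cuttable position exactly once.  Each site is annotated as genic or
intergenic by overlap with gene bodies; genic sites carry the host gene's
identifier and strand, which later orients the metagene frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

MOTIF = "GCGATCGC"

__all__ = [
    "MOTIF",
    "GenomeSite",
    "scan_sites",
    "annotate_sites",
    "read_bed6",
    "write_bed6",
    "sites_to_bed",
    "sites_to_frame",
]


@dataclass(frozen=True)
class GenomeSite:
    """One AsiSI recognition-site occurrence (0-based, half-open)."""

    site_id: str
    chrom: str
    start: int
    end: int
    genic: bool = False
    gene_id: str | None = None
    gene_strand: str | None = None

    def __post_init__(self):
        if self.end - self.start != len(MOTIF):
            raise ValueError(f"site must span {len(MOTIF)} bp")
        if self.genic != (self.gene_id is not None and self.gene_strand is not None):
            raise ValueError("genic flag inconsistent with gene_id/gene_strand")


def _iter_sequences(genome) -> Iterator[tuple[str, str]]:
    """Yield ``(chrom, sequence)`` from a dict, a pyfaidx.Fasta or a FASTA path."""
    if isinstance(genome, Mapping):
        for chrom, seq in genome.items():
            yield chrom, str(seq)
        return
    if isinstance(genome, (str, Path)):
        import pyfaidx

        fa = pyfaidx.Fasta(str(genome))
        for chrom in fa.keys():
            yield chrom, str(fa[chrom][:])
        return
    # duck-typed pyfaidx.Fasta or similar keyed container
    for chrom in genome.keys():
        yield chrom, str(genome[chrom][:])


def scan_sites(genome) -> list[GenomeSite]:
    """Locate every occurrence of the AsiSI motif in a genome.

    Parameters
    ----------
    genome
        Mapping chrom -> sequence, a FASTA path, or a pyfaidx.Fasta.
        Sequences may be any case; windows containing ``N`` never match.

    Returns
    -------
    list of :class:`GenomeSite`, sorted by (chrom, start).  Because the
    motif is palindromic, no separate reverse-strand scan is needed.
    """
    hits: list[tuple[str, int]] = []
    n_seqs = 0
    for chrom, seq in _iter_sequences(genome):
        n_seqs += 1
        s = seq.upper()
        pos = s.find(MOTIF)
        while pos != -1:
            hits.append((chrom, pos))
            pos = s.find(MOTIF, pos + 1)  # overlap-tolerant scan
    if n_seqs == 0:
        raise ValueError("genome source contains no sequences")
    hits.sort()
    return [
        GenomeSite(
            site_id=f"AsiSI_{chrom}_{start}",
            chrom=chrom,
            start=start,
            end=start + len(MOTIF),
        )
        for chrom, start in hits
    ]


def _as_gene_frame(genes) -> pd.DataFrame:
    """Coerce a BED6 path / DataFrame / iterable of tuples to a DataFrame."""
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    if isinstance(genes, pd.DataFrame):
        df = genes.copy()
    elif isinstance(genes, (str, Path)):
        df = read_bed6(genes)
    else:
        df = pd.DataFrame(list(genes), columns=cols)
    missing = set(cols) - set(df.columns)
    if missing:
        raise ValueError(f"gene annotation missing columns: {sorted(missing)}")
    return df


def annotate_sites(
    sites: Iterable[GenomeSite],
    genes,
    promoter_extension: int = 0,
) -> list[GenomeSite]:
    """Label each site genic/intergenic by overlap with gene bodies.

    A site is genic iff it overlaps at least one gene interval by >= 1 bp.
    When a site overlaps several genes, the gene with the larger overlap
    wins; exact ties go to the alphabetically first gene_id (logged).

    ``promoter_extension`` extends each gene upstream (strand-aware) by
    the given number of bp before testing overlap, so that
    promoter-proximal sites can optionally count as genic.
    """
    gdf = _as_gene_frame(genes)
    by_chrom: dict[str, list[tuple[int, int, str, str]]] = {}
    for row in gdf.itertuples(index=False):
        s, e = int(row.start), int(row.end)
        if promoter_extension:
            if row.strand == "+":
                s = max(0, s - promoter_extension)
            else:
                e = e + promoter_extension
        by_chrom.setdefault(row.chrom, []).append((s, e, str(row.name), str(row.strand)))

    out: list[GenomeSite] = []
    for site in sites:
        best: tuple[int, str, str] | None = None  # (overlap, gene_id, strand)
        tied = False
        for gs, ge, gid, gstrand in by_chrom.get(site.chrom, ()):
            ov = min(site.end, ge) - max(site.start, gs)
            if ov <= 0:
                continue
            if best is None or ov > best[0] or (ov == best[0] and gid < best[1]):
                tied = best is not None and ov == best[0]
                best = (ov, gid, gstrand)
            elif ov == best[0]:
                tied = True
        if best is None:
            out.append(
                replace(site, genic=False, gene_id=None, gene_strand=None)
            )
        else:
            if tied:
                logger.warning(
                    "site %s overlaps multiple genes equally; assigned %s",
                    site.site_id,
                    best[1],
                )
            out.append(
                replace(site, genic=True, gene_id=best[1], gene_strand=best[2])
            )
    return out


# --------------------------------------------------------------------- I/O


def read_bed6(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    return df


def write_bed6(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def sites_to_frame(sites: Iterable[GenomeSite]) -> pd.DataFrame:
    """Site list as a table (one row per site, annotation included)."""
    return pd.DataFrame(
        [
            {
                "site_id": s.site_id,
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "genic": s.genic,
                "gene_id": s.gene_id,
                "gene_strand": s.gene_strand,
            }
            for s in sites
        ]
    )


def sites_to_bed(sites: Iterable[GenomeSite], path) -> None:
    """Write sites as BED6 (name = site_id, score = 0, strand = '+')."""
    df = pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "name": s.site_id,
                "score": 0,
                "strand": "+",
            }
            for s in sites
        ]
    )
    write_bed6(df, path)
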