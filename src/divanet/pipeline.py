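"""End-to-end orchestration: scan -> annotate -> profile -> classify ->
metagene -> stats (+ optional qPCR), with a reproducible run manifest.

All stage outputs are plain text (BED/bedGraph/TSV/CSV/JSON) and contain
no timestamps, so rerunning with identical inputs and config reproduces
byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import classify, metagene, profile3p, qpcr, sites

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run.

    Serializes to/from a single YAML file; the effective config is
    written alongside the outputs of every run.
    """

    genome_fasta: str
    genes_bed: str
    alignments: str
    treatment_track: str
    control_track: str
    outdir: str
    ct_table: str | None = None
    # parameters
    flank: int = 2000
    score_window_bp: int = 1000
    score_pseudocount: float = 1.0
    n_cut: int = 94
    proximal: tuple[int, int] = (0, 500)
    distal: tuple[int, int] = (1500, 2000)
    stat_pseudocount: float = 1.0
    track_binsize: int = 50
    promoter_extension: int = 0
    min_mapq: int = 0
    flip_strand: bool = False
    seed: int = 0

    REQUIRED = ("genome_fasta", "genes_bed", "alignments",
                "treatment_track", "control_track", "outdir")

    def validate(self) -> "RunConfig":
        for name in self.REQUIRED:
            if not getattr(self, name):
                raise ValueError(f"config field {name!r} is required")
        for name in ("genome_fasta", "genes_bed", "alignments",
                     "treatment_track", "control_track"):
            if not Path(getattr(self, name)).exists():
                raise ValueError(f"config field {name!r}: no such file "
                                 f"{getattr(self, name)!r}")
        return self

    def to_yaml(self, path=None):
        d = dataclasses.asdict(self)
        d["proximal"] = list(self.proximal)
        d["distal"] = list(self.distal)
        text = yaml.safe_dump(d, sort_keys=True)
        if path is None:
            return text
        Path(path).write_text(text)
        return None

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        text = str(source)
        try:
            p = Path(text)
            if p.exists():
                text = p.read_text()
        except OSError:
            pass
        d = yaml.safe_load(text)
        for key in ("proximal", "distal"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest.

    Stages: scan, annotate, profile, classify, metagene, stats.  Any
    stage failure aborts with the stage name and cause.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    manifest: dict = {
        "inputs": {
            name: {"path": getattr(config, name), "sha256": _sha256(getattr(config, name))}
            for name in ("genome_fasta", "genes_bed", "alignments",
                         "treatment_track", "control_track")
        },
        "parameters": {"seed": config.seed, "n_cut": config.n_cut,
                       "flank": config.flank,
                       "score_window_bp": config.score_window_bp},
        "stages": [],
        "outputs": {},
    }
    if config.ct_table:
        manifest["inputs"]["ct_table"] = {
            "path": config.ct_table, "sha256": _sha256(config.ct_table)
        }

    stage = "scan"
    try:
        import pyfaidx

        fa = pyfaidx.Fasta(config.genome_fasta)
        chrom_lengths = {name: len(fa[name]) for name in fa.keys()}
        site_list = sites.scan_sites(config.genome_fasta)
        sites.sites_to_bed(site_list, outdir / "sites.bed")
        manifest["stages"].append(stage)
        manifest["outputs"]["sites"] = str(outdir / "sites.bed")

        stage = "annotate"
        annotated = sites.annotate_sites(
            site_list, config.genes_bed, promoter_extension=config.promoter_extension
        )
        sites.sites_to_frame(annotated).to_csv(
            outdir / "sites_annotated.tsv", sep="\t", index=False
        )
        manifest["stages"].append(stage)
        manifest["outputs"]["sites_annotated"] = str(outdir / "sites_annotated.tsv")

        stage = "profile"
        profile = profile3p.build_profile(
            config.alignments, min_mapq=config.min_mapq, flip_strand=config.flip_strand
        )
        profile3p.export_bedgraph(profile, "+", outdir / "profile_plus.bedgraph")
        profile3p.export_bedgraph(profile, "-", outdir / "profile_minus.bedgraph")
        manifest["stages"].append(stage)
        manifest["outputs"]["profile"] = {
            "plus": str(outdir / "profile_plus.bedgraph"),
            "minus": str(outdir / "profile_minus.bedgraph"),
            "n_pairs_seen": profile.n_pairs_seen,
            "n_pairs_accepted": profile.n_pairs_accepted,
        }

        stage = "classify"
        from .tracks import CoverageTrack

        treatment = CoverageTrack.from_bedgraph(
            config.treatment_track, config.track_binsize, chrom_lengths
        )
        control = CoverageTrack.from_bedgraph(
            config.control_track, config.track_binsize, chrom_lengths
        )
        scores = classify.score_sites(
            annotated, treatment, control,
            window_bp=config.score_window_bp, pseudocount=config.score_pseudocount,
        )
        cut_ids, uncut_ids = classify.select_cut_uncut(scores, config.n_cut)
        classify.scores_to_frame(scores).to_csv(
            outdir / "scores.tsv", sep="\t", index=False
        )
        by_id = {s.site_id: s for s in annotated}
        for label, ids in (("cut", cut_ids), ("uncut", uncut_ids)):
            sites.sites_to_bed([by_id[i] for i in ids], outdir / f"{label}.bed")
        manifest["stages"].append(stage)
        manifest["outputs"]["scores"] = str(outdir / "scores.tsv")

        stage = "metagene"
        profiles = {}
        matrices = {}
        for label, ids in (("cut", cut_ids), ("uncut", uncut_ids)):
            mat = metagene.site_matrix(
                profile, [by_id[i] for i in ids], flank=config.flank,
                chrom_lengths=chrom_lengths,
            )
            matrices[label] = mat
            prof = metagene.rolling_smooth(metagene.average_profile(mat))
            profiles[label] = prof
            prof.to_frame().to_csv(
                outdir / f"metagene_{label}.tsv", sep="\t", index=False
            )
        manifest["stages"].append(stage)
        manifest["outputs"]["metagene"] = {
            label: str(outdir / f"metagene_{label}.tsv") for label in profiles
        }

        stage = "stats"
        summaries = {}
        tables = []
        for label, mat in matrices.items():
            table, summary = metagene.proximal_distal_stat(
                mat, config.proximal, config.distal, config.stat_pseudocount
            )
            table.insert(0, "label", label)
            tables.append(table)
            summaries[label] = summary
        pd.concat(tables, ignore_index=True).to_csv(
            outdir / "stats.tsv", sep="\t", index=False
        )
        (outdir / "stats_summary.json").write_text(
            json.dumps(summaries, indent=2, sort_keys=True)
        )
        manifest["stages"].append(stage)
        manifest["outputs"]["stats"] = str(outdir / "stats.tsv")
        manifest["summaries"] = summaries

        if config.ct_table:
            stage = "dsb_qpcr"
            table = pd.read_csv(config.ct_table)
            estimates = qpcr.quantify_dsb(table)
            estimates.to_csv(outdir / "dsb_estimates.csv", index=False)
            manifest["stages"].append(stage)
            manifest["outputs"]["dsb_estimates"] = str(outdir / "dsb_estimates.csv")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
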