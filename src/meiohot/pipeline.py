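"""Shared readers/writers, the run manifest and the end-to-end driver.

All interval interfaces are 0-based half-open (BED native); bedGraph is the
canonical coverage interchange.  ``run_pipeline`` chains synthetic-data
generation with the analysis stages and records a manifest (config
snapshot, seed, stage list, output checksums, version) so deterministic
stages reproduce byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .coverage import CoverageTrack, read_bedgraph, write_bedgraph
from .intervals import read_intervals, sort_intervals, write_bed
from .simulate import (SimulationConfig, simulate_genome_and_coverage,
                       simulate_protein_family)

__all__ = ["read_intervals", "read_coverage", "write_bed", "write_bedgraph",
           "read_fasta", "write_fasta", "read_taxonomy", "RunManifest",
           "run_pipeline"]

log = logging.getLogger("meiohot")


def read_coverage(path, chrom_lengths=None, strand=".") -> CoverageTrack:
    """bedGraph -> dense per-base track; gaps fill 0."""
    return read_bedgraph(path, chrom_lengths=chrom_lengths, strand=strand)


def write_fasta(records: dict[str, str], path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    SeqIO.write([SeqRecord(Seq(s), id=name, description="")
                 for name, s in records.items()], str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_taxonomy(path) -> pd.DataFrame:
    """Taxonomy TSV with columns species, genus, family, order, clade, phylum."""
    df = pd.read_csv(path, sep="\t")
    missing = {"species", "clade"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing taxonomy columns {sorted(missing)}")
    return df


@dataclasses.dataclass
class RunManifest:
    config: dict
    seed: int
    stages: list[str]
    outputs: dict[str, str]   # relative path -> sha256
    version: str = __version__

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def read(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


ALL_STAGES = ("protein", "genome", "chip", "dsb", "cpg")


def run_pipeline(config: SimulationConfig, outdir,
                 stages: tuple[str, ...] = ALL_STAGES) -> RunManifest:
    """Generate synthetic inputs and run the requested analysis stages.

    Stage order is fixed; downstream stages that need an upstream stage's
    in-memory outputs raise a clear error if it was not requested.
    """
    from . import chip, cpg, dsb, orthology

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = tuple(stages)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    t0 = time.time()
    outputs: list[Path] = []
    tracks = intervals = truth = None

    if "protein" in stages:
        log.info("stage protein: n_clades=%d species_per_clade=%d rate=%g",
                 config.n_clades, config.species_per_clade, config.substitution_rate)
        aln, ptruth = simulate_protein_family(config)
        res = orthology.profile_and_call(aln)
        prof_df = res["profile"].to_frame()
        prof_df["jsd_z"] = orthology.jsd_conservation(res["profile"])
        prof_df.to_csv(outdir / "conservation_profile.tsv", sep="\t", index=False)
        res["calls"].to_csv(outdir / "orthologue_calls.tsv", sep="\t", index=False)
        write_fasta({"reference": aln.reference}, outdir / "reference.fasta")
        write_fasta({s.species_id: s.residues for s in aln.sequences.values()},
                    outdir / "alignment.fasta")
        pd.DataFrame([{"species": t.species_id, **t.ranks}
                      for t in aln.taxa.values()]).to_csv(
            outdir / "taxonomy.tsv", sep="\t", index=False)
        outputs += [outdir / f for f in ("conservation_profile.tsv",
                                         "orthologue_calls.tsv",
                                         "reference.fasta", "alignment.fasta",
                                         "taxonomy.tsv")]

    if "genome" in stages:
        log.info("stage genome: %s, n_hotspots=%d mode=%s",
                 config.chrom_lengths, config.n_hotspots, config.mode)
        tracks, intervals, truth = simulate_genome_and_coverage(config)
        for name, track in tracks.items():
            write_bedgraph(track, outdir / f"{name}.bedGraph")
            outputs.append(outdir / f"{name}.bedGraph")
        for name, df in intervals.items():
            write_bed(sort_intervals(df), outdir / f"{name}.bed")
            outputs.append(outdir / f"{name}.bed")
        write_fasta(truth.genome, outdir / "genome.fasta")
        truth.methylation.to_csv(outdir / "methylation.tsv", sep="\t", index=False)
        truth.hotspots.to_csv(outdir / "hotspot_truth.tsv", sep="\t", index=False)
        outputs += [outdir / "genome.fasta", outdir / "methylation.tsv",
                    outdir / "hotspot_truth.tsv"]

    def need_genome(stage):
        if truth is None:
            raise RuntimeError(f"stage '{stage}' requires stage 'genome' output")

    if "chip" in stages:
        need_genome("chip")
        log.info("stage chip: pthresh=1e-6 peakminsep=250")
        calls = chip.force_call(tracks["zcwpw1"], tracks["input"],
                                intervals["hotspots"])
        calls.to_csv(outdir / "force_calls.tsv", sep="\t", index=False)
        peaks = chip.call_peaks(tracks["zcwpw1"], tracks["input"])
        peaks = chip.dedup_nearby(chip.filter_peaks(peaks))
        peaks.peaks.to_csv(outdir / "peaks.tsv", sep="\t", index=False)
        prof = chip.aggregate_profile(tracks["zcwpw1"], tracks["input"],
                                      intervals["hotspots"])
        prof.to_csv(outdir / "zcwpw1_profile.tsv", sep="\t", index=False)
        outputs += [outdir / "force_calls.tsv", outdir / "peaks.tsv",
                    outdir / "zcwpw1_profile.tsv"]

    if "dsb" in stages:
        need_genome("dsb")
        log.info("stage dsb: persistence_exponent=%g", config.persistence_exponent)
        table = dsb.scale_by_autosomal_mean(
            truth.hotspots, ["spo11", "dmc1_wt", "dmc1_ko"])
        lin_wt = dsb.linearity_assessment(table["spo11"], table["dmc1_wt"])
        lin_ko = dsb.linearity_assessment(table["spo11"], table["dmc1_ko"])
        ratio = dsb.ko_wt_ratio_model(table, "h3k4me3")
        summary = {
            "linearity_wt": {"exponent": lin_wt.exponent, "ci": lin_wt.exponent_ci},
            "linearity_ko": {"exponent": lin_ko.exponent, "ci": lin_ko.exponent_ci},
            "ratio_model": {"r": ratio.r, "fold_range": ratio.fold_range},
        }
        with open(outdir / "dsb_models.json", "w") as fh:
            json.dump(summary, fh, indent=1)
        binned = dsb.bin_with_ci(table["spo11"], table["dmc1_wt"],
                                 min(20, len(table) // 3))
        binned.to_csv(outdir / "dmc1_vs_spo11_binned.tsv", sep="\t", index=False)
        outputs += [outdir / "dsb_models.json", outdir / "dmc1_vs_spo11_binned.tsv"]

    if "cpg" in stages:
        need_genome("cpg")
        log.info("stage cpg: %d methylation records", len(truth.methylation))
        classified = cpg.classify_methylation(truth.methylation)
        classified.to_csv(outdir / "methylation_classes.tsv", sep="\t", index=False)
        alus = cpg.filter_alu_like(truth.repeats)
        alus["cpg_count"] = cpg.count_cpgs_in_intervals(alus, truth.genome)
        alus.to_csv(outdir / "alu_cpgs.tsv", sep="\t", index=False)
        outputs += [outdir / "methylation_classes.tsv", outdir / "alu_cpgs.tsv"]

    manifest = RunManifest(
        config=json.loads(config.to_json()), seed=config.seed,
        stages=list(stages),
        outputs={str(p.relative_to(outdir)): _sha256(p) for p in outputs})
    manifest.write(outdir / "manifest.json")
    log.info("pipeline complete in %.1f s (%d outputs)", time.time() - t0, len(outputs))
    return manifest
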