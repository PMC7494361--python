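"""Synthetic data with the statistical structure the analyses assume.

Two generators cover the pipeline's inputs:

* :func:`simulate_protein_family` — a reference protein, clade-structured
  true orthologues (reference plus per-position substitutions, never at the
  designated conserved positions), shuffled-profile decoys, and optional
  truncation; emulates the alignment + taxonomy inputs of the conservation
  analysis.
* :func:`simulate_genome_and_coverage` — small genomes with motif-defined
  hotspots, promoters carrying a PRDM9-independent H3K4me3 mark, Alu-like
  CpG-rich repeats with methylation states, Poisson background coverage,
  IP tracks with multiplicative enrichment at true sites, and
  strand-specific DMC1 coverage generated as SPO11 frequency x persistence.
  Persistence decreases with H3K4me3 in "WT" mode — hotspots more strongly
  bound by PRDM9 (on the homologue) resolve their DSBs faster — and is
  constant in "KO" mode, emulating loss of the reader protein.

Every stochastic draw flows from one seeded generator; the same seed gives
byte-identical outputs, and a :class:`SimulatedTruth` record maps every
emitted signal feature to its generative values.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coverage import CoverageTrack
from .orthology import (AMINO_ACIDS, GAP, NOT_ALIGNED, AlignedSequence,
                        AlignmentSet, TaxonRecord)

__all__ = ["SimulationConfig", "SimulatedTruth", "simulate_protein_family",
           "simulate_genome_and_coverage", "simulate_hotspot_table"]

#: kernel for enrichment around a site: triangular, unit peak
def _kernel(width: int) -> np.ndarray:
    half = width // 2
    return 1.0 - np.abs(np.arange(-half, half + 1)) / (half + 1)


@dataclass
class SimulationConfig:
    """All tunable study conditions for the synthetic generators.

    Protein-family block: ``n_clades`` x ``species_per_clade`` species,
    reference length ``ref_length``; ``n_conserved`` designated invariant
    positions (or give ``conserved_positions`` explicitly);
    ``substitution_rate`` is the per-position substitution probability in
    true orthologues; a ``decoy_fraction`` of species are drawn from a
    shuffled profile; ``truncation_prob`` sequences keep only a contiguous
    aligned span.

    Genome block: per-chromosome lengths, feature counts, Poisson background
    rate (fragments per base), multiplicative ``enrichment_scale`` at true
    sites with a triangular kernel of ``kernel_width`` bp, and the DMC1
    generative model DMC1 = SPO11 x persistence with
    persistence = (1 + H3K4me3)^(-persistence_exponent) in WT mode and 1 in
    KO mode, with multiplicative log-normal sampling noise ``dmc1_noise_sd``.
    """

    seed: int = 0
    # protein family
    n_clades: int = 5
    species_per_clade: int = 20
    ref_length: int = 450
    n_conserved: int = 20
    conserved_positions: list[int] | None = None
    substitution_rate: float = 0.05
    decoy_fraction: float = 0.20
    truncation_prob: float = 0.10
    implant_motifs: bool = True
    # genome & coverage
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"1": 150_000, "2": 150_000, "3": 150_000})
    n_hotspots: int = 60
    n_promoters: int = 30
    n_repeats: int = 80
    background_rate: float = 1.0
    enrichment_scale: float = 4.0
    kernel_width: int = 1000
    motif: str = "CCTCCCTAGCCAC"
    persistence_exponent: float = 1.0
    mode: str = "WT"
    spo11_log_sd: float = 0.8
    h3k4me3_log_sd: float = 0.4
    h3k4me3_mean: float = 3.0
    dmc1_noise_sd: float = 0.15
    repeat_meth_prob: float = 0.8
    high_copy_prob: float = 0.05

    def __post_init__(self):
        for name in ("n_clades", "species_per_clade", "ref_length",
                     "n_conserved", "n_hotspots", "n_promoters", "n_repeats"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("substitution_rate", "decoy_fraction", "truncation_prob",
                     "repeat_meth_prob", "high_copy_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.mode not in ("WT", "KO"):
            raise ValueError("mode must be 'WT' or 'KO'")
        if any(v <= 0 for v in self.chrom_lengths.values()):
            raise ValueError("chrom_lengths must be positive")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


@dataclass
class SimulatedTruth:
    """Generative record sufficient to recompute every downstream quantity."""

    config: SimulationConfig
    # protein family
    conserved_positions: dict[int, str] = field(default_factory=dict)
    orthologue_status: dict[str, bool] = field(default_factory=dict)
    # genome
    hotspots: pd.DataFrame | None = None     # per-hotspot generative values
    promoters: pd.DataFrame | None = None
    repeats: pd.DataFrame | None = None
    methylation: pd.DataFrame | None = None
    genome: dict[str, str] | None = None


def simulate_protein_family(config: SimulationConfig,
                            ) -> tuple[AlignmentSet, SimulatedTruth]:
    """Clade-structured protein family around a random reference.

    True orthologues are the reference with independent per-position
    substitutions (never at designated conserved positions); decoys are
    drawn from the reference's shuffled profile, so they share composition
    but not positions.  Truncated sequences keep one contiguous aligned
    span covering 60-90% of the reference.
    """
    if config.ref_length == 0:
        raise ValueError("zero-length reference")
    if config.n_clades < 2 or config.species_per_clade < 1:
        raise ValueError("need >= 2 clades with >= 1 species each")
    rng = np.random.default_rng(config.seed)
    aa = np.array(list(AMINO_ACIDS))
    ref = rng.choice(aa, size=config.ref_length)
    # implant the screening motifs; their residues are always conserved, so
    # shuffled decoys (which almost never contain them) fail the screen
    motif_pos: list[int] = []
    if config.implant_motifs and config.ref_length >= 40:
        for motif, offset in (("KWR", config.ref_length // 8),
                              ("PWWP", config.ref_length // 4)):
            ref[offset:offset + len(motif)] = list(motif)
            motif_pos += list(range(offset, offset + len(motif)))
    reference = "".join(ref)
    if config.conserved_positions is not None:
        pos = sorted(set(int(p) for p in config.conserved_positions) | set(motif_pos))
    else:
        extra = max(config.n_conserved - len(motif_pos), 0)
        candidates = np.setdiff1d(np.arange(config.ref_length), motif_pos)
        pos = sorted(set(motif_pos)
                     | set(int(p) for p in rng.choice(candidates, size=extra,
                                                      replace=False)))
    conserved = {p: reference[p] for p in pos}
    sequences: dict[str, AlignedSequence] = {}
    taxa: dict[str, TaxonRecord] = {}
    status: dict[str, bool] = {}
    ref_arr = np.array(list(reference))
    for ci in range(config.n_clades):
        clade = f"clade{ci:02d}"
        for si in range(config.species_per_clade):
            sid = f"{clade}_sp{si:02d}"
            is_decoy = rng.random() < config.decoy_fraction
            if is_decoy:
                seq = ref_arr[rng.permutation(config.ref_length)]
            else:
                seq = ref_arr.copy()
                sub = rng.random(config.ref_length) < config.substitution_rate
                for p in conserved:
                    sub[p] = False
                for p in np.flatnonzero(sub):
                    choices = [c for c in AMINO_ACIDS if c != reference[p]]
                    seq[p] = choices[rng.integers(len(choices))]
            residues = "".join(seq)
            if rng.random() < config.truncation_prob:
                frac = rng.uniform(0.6, 0.9)
                span = int(frac * config.ref_length)
                start = rng.integers(0, config.ref_length - span + 1)
                residues = (NOT_ALIGNED * start + residues[start:start + span]
                            + NOT_ALIGNED * (config.ref_length - start - span))
            sequences[sid] = AlignedSequence(sid, residues,
                                             seq_length=config.ref_length)
            taxa[sid] = TaxonRecord(sid, ranks={
                "genus": f"{clade}_g{si // 2}", "family": f"{clade}_f{si // 5}",
                "order": f"{clade}_o0", "clade": clade, "phylum": f"ph{ci % 2}",
            }, clade_label=clade)
            status[sid] = not is_decoy
    aln = AlignmentSet(reference, sequences, taxa)
    truth = SimulatedTruth(config, conserved_positions=conserved,
                           orthologue_status=status)
    return aln, truth


def simulate_hotspot_table(config: SimulationConfig,
                           rng: np.random.Generator) -> pd.DataFrame:
    """Per-hotspot generative values under the DMC1 = SPO11 x persistence
    model.

    SPO11 (DSB frequency) is log-normal; H3K4me3 tracks SPO11 with
    log-normal noise (both are driven by PRDM9 binding); persistence is
    (1 + H3K4me3)^(-b) for the WT genotype and 1 for the KO.  Observed DMC1
    per genotype carries multiplicative log-normal sampling noise.  The X
    chromosome is not modelled (all rows autosomal).
    """
    n = config.n_hotspots
    spo11 = rng.lognormal(0.0, config.spo11_log_sd, size=n)
    h3k4me3 = spo11 * rng.lognormal(0.0, config.h3k4me3_log_sd, size=n)
    h3k4me3 *= config.h3k4me3_mean / h3k4me3.mean()
    persistence_wt = (1.0 + h3k4me3) ** (-config.persistence_exponent)
    persistence_ko = np.ones(n)
    dmc1_wt = spo11 * persistence_wt * rng.lognormal(0.0, config.dmc1_noise_sd, size=n)
    dmc1_ko = spo11 * persistence_ko * rng.lognormal(0.0, config.dmc1_noise_sd, size=n)
    return pd.DataFrame({
        "spo11": spo11, "h3k4me3": h3k4me3,
        "persistence_wt": persistence_wt, "persistence_ko": persistence_ko,
        "dmc1_wt": dmc1_wt, "dmc1_ko": dmc1_ko, "is_x": False,
    })


def _place_features(rng, chrom_lengths, n, width, min_sep):
    """Uniform non-overlapping placements; error when infeasible."""
    total = sum(chrom_lengths.values())
    if n * (width + min_sep) > total:
        raise ValueError("requested features exceed chromosome length")
    chroms = list(chrom_lengths)
    probs = np.array([chrom_lengths[c] for c in chroms], float)
    probs /= probs.sum()
    placed = {c: [] for c in chroms}
    count, tries = 0, 0
    while count < n:
        tries += 1
        if tries > 200 * n:
            raise ValueError("could not place features at requested density")
        c = chroms[rng.choice(len(chroms), p=probs)]
        p = int(rng.integers(0, chrom_lengths[c] - width))
        if all(abs(p - q) >= width + min_sep for q in placed[c]):
            placed[c].append(p)
            count += 1
    rows = [(c, p, p + width) for c in chroms for p in sorted(placed[c])]
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def simulate_genome_and_coverage(config: SimulationConfig,
                                 ) -> tuple[dict[str, CoverageTrack],
                                            dict[str, pd.DataFrame],
                                            SimulatedTruth]:
    """Genomes, interval sets and IP/input coverage with truth records.

    Returns ``(tracks, intervals, truth)``.  Tracks: ``input`` (Poisson
    background), ``zcwpw1``, ``h3k4me3``, ``prdm9`` (multiplicative
    enrichment at their true sites), and stranded ``dmc1_plus`` /
    ``dmc1_minus`` for the configured genotype mode.  Intervals: hotspots
    (motif-centred, stranded), promoters, Alu-like repeats.  The truth
    carries the per-hotspot generative table (both genotypes), the repeat
    methylation table and the genome sequences.
    """
    rng = np.random.default_rng(config.seed)
    # genome sequence: ACGT background, CpG-poor enough for repeat contrast
    genome_arr = {c: rng.choice(np.array(list("ACGT")), size=length,
                                p=[0.3, 0.2, 0.2, 0.3])
                  for c, length in config.chrom_lengths.items()}

    hotspots = _place_features(rng, config.chrom_lengths, config.n_hotspots,
                               len(config.motif), config.kernel_width)
    hot_table = simulate_hotspot_table(config, rng)
    hot_table.insert(0, "chrom", hotspots["chrom"].to_numpy())
    centers = ((hotspots["start"] + hotspots["end"]) // 2).to_numpy()
    hot_table.insert(1, "pos", centers)
    hot_table["strand"] = np.where(rng.random(len(hotspots)) < 0.5, "+", "-")
    hot_table["id"] = [f"hs{i:04d}" for i in range(len(hotspots))]
    # write the motif into the genome at each hotspot
    for c, s, strand in zip(hotspots["chrom"], hotspots["start"], hot_table["strand"]):
        seq = config.motif if strand == "+" else config.motif[::-1].translate(
            str.maketrans("ACGT", "TGCA"))
        genome_arr[c][s:s + len(seq)] = list(seq)

    promoters = _place_features(rng, config.chrom_lengths, config.n_promoters,
                                500, config.kernel_width)
    promoters["h3k4me3"] = rng.lognormal(np.log(config.h3k4me3_mean), 0.5,
                                         size=len(promoters))
    repeat_widths = rng.integers(250, 351, size=config.n_repeats)
    repeats = _place_features(rng, config.chrom_lengths, config.n_repeats,
                              350, 100)
    repeats["end"] = repeats["start"] + repeat_widths
    repeats["name"] = "AluY"
    # CpGs: write CG dinucleotides into repeats, with methylation states
    meth_rows = []
    for _, rep in repeats.iterrows():
        n_cpg = int(rng.integers(3, 15))
        cpg_pos = np.sort(rng.choice(
            np.arange(rep.start + 2, rep.end - 2, 2), size=n_cpg, replace=False))
        methylated = rng.random() < config.repeat_meth_prob
        for p in cpg_pos:
            genome_arr[rep.chrom][p] = "C"
            genome_arr[rep.chrom][p + 1] = "G"
        for p in cpg_pos:
            depth = max(int(rng.poisson(20)), 1)
            ratio = rng.beta(9, 1) if methylated else rng.beta(1, 9)
            meth = rng.binomial(depth, ratio)
            copy_number = 2.0 if rng.random() < config.high_copy_prob else 1.0
            for strand in "+-":
                meth_rows.append((rep.chrom, int(p), strand, meth, depth - meth,
                                  copy_number, "CpG"))
    methylation = pd.DataFrame(meth_rows, columns=[
        "chrom", "pos", "strand", "meth_reads", "unmeth_reads",
        "copy_number", "context"])
    genome = {c: "".join(a) for c, a in genome_arr.items()}

    # coverage emission
    kern = _kernel(config.kernel_width)
    half = len(kern) // 2

    def emit(rates: dict[str, np.ndarray], strand=".") -> CoverageTrack:
        return CoverageTrack({c: rng.poisson(r).astype(float)
                              for c, r in rates.items()}, strand=strand)

    def base_rates():
        return {c: np.full(n, config.background_rate)
                for c, n in config.chrom_lengths.items()}

    def add_site(rates, chrom, center, amplitude, shift=0):
        arr = rates[chrom]
        lo = center - half + shift
        for k, v in enumerate(kern):
            p = lo + k
            if 0 <= p < len(arr):
                arr[p] += config.background_rate * amplitude * v

    input_rates = base_rates()
    zc_rates, h3_rates, pr_rates = base_rates(), base_rates(), base_rates()
    rel = hot_table["spo11"] / hot_table["spo11"].mean()
    for i, row in hot_table.iterrows():
        amp = config.enrichment_scale * rel[i]
        add_site(zc_rates, row.chrom, row.pos, amp)
        add_site(pr_rates, row.chrom, row.pos, amp)
        add_site(h3_rates, row.chrom, row.pos,
                 config.enrichment_scale * row.h3k4me3 / config.h3k4me3_mean)
    for _, row in promoters.iterrows():
        center = (row.start + row.end) // 2
        add_site(h3_rates, row.chrom, center,
                 config.enrichment_scale * row.h3k4me3 / config.h3k4me3_mean)
    # weak CpG-driven binding of the reader at repeats
    for _, rep in repeats.iterrows():
        center = (rep.start + rep.end) // 2
        add_site(zc_rates, rep.chrom, center, 0.5)

    dmc1_col = "dmc1_wt" if config.mode == "WT" else "dmc1_ko"
    dmc1_plus, dmc1_minus = base_rates(), base_rates()
    drel = hot_table[dmc1_col] / hot_table[dmc1_col].mean()
    for i, row in hot_table.iterrows():
        amp = config.enrichment_scale * drel[i]
        add_site(dmc1_plus, row.chrom, row.pos, amp, shift=half // 2)
        add_site(dmc1_minus, row.chrom, row.pos, amp, shift=-half // 2)

    tracks = {
        "input": emit(input_rates),
        "zcwpw1": emit(zc_rates),
        "h3k4me3": emit(h3_rates),
        "prdm9": emit(pr_rates),
        "dmc1_plus": emit(dmc1_plus, strand="+"),
        "dmc1_minus": emit(dmc1_minus, strand="-"),
    }
    hot_intervals = hot_table[["chrom"]].copy()
    hot_intervals["start"] = hot_table["pos"] - half
    hot_intervals["end"] = hot_table["pos"] + half
    hot_intervals["center"] = hot_table["pos"]
    hot_intervals["strand"] = hot_table["strand"]
    intervals = {"hotspots": hot_intervals, "promoters": promoters,
                 "repeats": repeats}
    truth = SimulatedTruth(config, hotspots=hot_table, promoters=promoters,
                           repeats=repeats, methylation=methylation,
                           genome=genome)
    return tracks, intervals, truth
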