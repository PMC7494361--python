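# meiohot

Analyses of meiotic recombination-hotspot regulation: clade-weighted protein
conservation and orthologue calling, hotspot-centric ChIP-seq enrichment,
CpG/methylation-dependent binding, and DMC1-persistence modelling — plus a
synthetic-data simulator so that every stage runs and is validated at desk
scale with no external downloads.

## The scientific problem

In most mammals the zinc-finger protein PRDM9 positions meiotic
double-strand breaks (DSBs): it binds a sequence motif and writes H3K4me3
and H3K36me3 on the flanking nucleosomes, and DSBs concentrate at these
*hotspots*. A reader protein (ZCWPW1-like, with CW and PWWP domains
recognising those two marks) is recruited to PRDM9-bound sites and is needed
for efficient DSB repair and homologue pairing. Two complementary lines of
computational evidence support this picture, and this package implements
both:

1. **Comparative genomics.** Orthologues of the reader are detected across
   species by a conservation-profile procedure: sequences aligned to a
   reference are weighted so each major clade contributes equally, the
   weighted probability of each of the 20 amino acids (or a gap, with a
   pseudocount ε = 10⁻⁵) is computed per position, and candidate sequences
   are accepted if they match ≥ 90% of the perfectly conserved residues to
   which they align, while aligning to ≥ 50% of them. Per-position
   conservation is summarised by entropy in bits (H = −Σ p log₂ p, so 1 bit
   ≡ two equiprobable residues) and by a Jensen–Shannon divergence score
   normalised to mean 0, sd 1. Co-occurrence of the reader and writer across
   taxa is tested with odds ratios and Fisher's exact test.

2. **Hotspot epigenomics.** ChIP fragment coverage is compared against input
   with a "force-called" enrichment estimate per window,

       β̂ = max(0, (r/C_r) / (g/C_g) − 1),

   where r, g are IP and input counts and C_r, C_g the library totals —
   coverage attributable to signal, relative to background, so any β̂ > 0 is
   enriched. Significance is the exact conditional binomial test for two
   Poisson rates (with a mid-p correction). On top of this sit a single-base
   peak caller with greedy minimum-separation suppression, the standard peak
   filters (promoter proximity, input-coverage bounds, 4 kb double-counting
   removal), aggregate profiles and heatmap matrices, CpG counting and
   bisulfite methylation classification, and the DMC1 persistence analyses:
   DMC1 ChIP-SSDS signal at a hotspot is the product of DSB frequency
   (measured by SPO11 oligos) and how long DMC1 persists on the resected
   DNA, so a sub-linear log-log relationship of DMC1 on SPO11 (exponent
   b < 1) indicates faster repair at strongly bound hotspots, and the
   per-hotspot KO:WT DMC1 ratio modelled against H3K4me3 quantifies how
   repair delay in a reader-knockout grows with writer binding.

The simulator generates protein families with designated conserved
positions and shuffled-profile decoys, and genomes with motif-defined
hotspots, promoters, CpG-rich Alu-like repeats with methylation states,
Poisson background coverage, multiplicative enrichment at true sites, and
strand-specific DMC1 coverage built as SPO11 × persistence, where
persistence decreases with H3K4me3 in "WT" mode and is constant in "KO"
mode. Every generated feature carries a truth record, so downstream results
can be checked against brute force.

## Worked example

```python
from meiohot.simulate import SimulationConfig, simulate_genome_and_coverage
from meiohot import chip, dsb

cfg = SimulationConfig(seed=1)                      # WT genome, 60 hotspots
tracks, intervals, truth = simulate_genome_and_coverage(cfg)

calls = chip.force_call(tracks["zcwpw1"], tracks["input"], intervals["hotspots"])
tab = dsb.scale_by_autosomal_mean(truth.hotspots, ["spo11", "dmc1_wt", "dmc1_ko"])
print(dsb.linearity_assessment(tab.spo11, tab.dmc1_wt).summary())
print(dsb.linearity_assessment(tab.spo11, tab.dmc1_ko).summary())
print(dsb.ko_wt_ratio_model(tab, "h3k4me3").summary())
```

prints

```
log-log regression, n=60
  exponent b = 0.382 (95% CI 0.298-0.466) -> sublinear
  RSS power 5.194 vs slope-1 24.63
  zero offset 0
log-log regression, n=60
  exponent b = 0.968 (95% CI 0.918-1.018) -> linear
  RSS power 1.816 vs slope-1 1.868
  zero offset 0
KO:WT DMC1 ratio ~ s(h3k4me3), n=60 (0 excluded)
  r (fitted vs observed) = 0.958
  fold-range top/bottom decile = 7.72
```

Read: in the WT-style genotype DMC1 grows sub-linearly with SPO11
(b ≈ 0.38, CI below 1 — hot hotspots shed DMC1 faster), while the
KO-style genotype is consistent with strict linearity (CI covers 1).
The KO:WT ratio tracks H3K4me3 tightly (r ≈ 0.96) and spans a ~8-fold
range from the most weakly to the most strongly marked hotspots.

The same stages run from the shell:

```bash
meiohot run --seed 1 --outdir out/          # full synthetic pipeline
meiohot dsb linearity --hotspots out/hotspot_truth.tsv --dmc1-col dmc1_wt
meiohot orthology cooccur --table 10 1 1 10
```

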