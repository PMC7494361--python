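# Methods

This note documents the models and procedures implemented in `meiohot`, the
choices made where the design was genuinely open, and what the synthetic
data do and do not establish.

## Conservation profiling and orthologue calling

**Clade weighting.** Given a taxonomy, each sequence in a clade of size
n_c receives weight 1/n_c, so every clade's weights sum to exactly 1 and an
over-represented clade (e.g. placental mammals in public databases) cannot
dominate the position frequencies. Duplicating sequences within a clade is
provably neutral, which the tests assert.

**Position frequencies.** Per reference position, the weighted probability
of each of the 20 amino acids or a gap is computed over the sequences that
align at that position (a gap inside a sequence's aligned span is the 21st
symbol; positions outside the span do not contribute). A pseudocount
ε = 10⁻⁵ is added once per symbol after weighting and the vector
renormalised — enough to exclude zero weights, small enough not to distort
anything at the data sizes involved.

**Entropy.** H = −Σ p log₂ p in bits, chosen so that the conservation
threshold H < 1 has the direct reading "one residue present in more than
half the (weighted) species": a column with two equiprobable residues sits
exactly at 1 bit. The acceptance script recomputes this anchor value.

**Conserved sets and the orthologue rule.** The *perfect* set contains
positions where every contributing sequence shows the same amino acid
(pseudocount ignored; gap-only or mixed columns excluded); the *low-entropy*
set has H < 1. A candidate is accepted as an orthologue iff it matches
≥ 90% of the perfect-set positions to which it aligns and aligns to ≥ 50%
of them; both thresholds are inclusive ("at least"), and both the
span-based and gap-excluded denominators are reported because incomplete
sequencing and genuine gaps are different failure modes. A candidate with
no aligned conserved position is rejected with reason "no alignment" rather
than raising a division error.

**Initial screen.** 'Clear' orthologues must contain perfect matches to the
CW/PWWP domain patterns (KWR, PWWP) and show reciprocal alignment coverage
≥ 39% in both directions, which excludes paralogues sharing only a short
homologous region (a ~19% overlap needs more than double that coverage to
pass). The conservation profile is built from the clear set only, then all
candidates are called against it.

**JSD conservation score.** Per position, the gap-excluded, renormalised
amino-acid vector is compared with a background distribution (uniform by
default) by Jensen–Shannon divergence (base 2), then z-normalised across
positions to mean 0, sd 1. No sequence-window smoothing is applied
(window = 0); smoothing is a presentation choice and the unsmoothed score
is the more conservative default.

**Co-occurrence.** The 2×2 table operation reports the sample odds ratio
(with the Haldane–Anscombe 0.5 correction when a cell is zero, flagged as
such), the conditional-MLE odds ratio underlying Fisher's exact test, and
the two-sided Fisher p-value, verified in the tests against exhaustive
hypergeometric enumeration. The exact construction of the published
SET-mutation × reader-absence table depends on species tables distributed
as separate supplementary material; `build_cooccurrence_table` documents
one plausible construction (boolean exposure × boolean outcome per
species), and the tests that assert the published values (odds ratio 285,
78% of 167 at species/family rank) fail with an explanatory message when
the tables are not present. They are deliberately not skipped: the absence
of the inputs is a reportable condition, not a pass.

**Alignments are inputs.** Pairwise alignment normally comes from a search
tool; `align_to_reference` (Biopython local alignment, BLOSUM62, gap open
11 / extend 1) exists only so synthetic fixtures can be built end to end.

## Force-called enrichment and peak calling

For a window with IP count r, input count g and library totals C_r, C_g,
the enrichment estimate is β̂ = max(0, (r/C_r)/(g/C_g) − 1): coverage due
to signal *after subtracting coverage due to background*, relative to
background. A value below 1 therefore does not imply depletion; any value
above 0 is enriched. β̂ is truncated at 0 because the quantity is a signal
fraction.

**The p-value is the exact conditional test for two Poisson rates**: given
the total r + g, under the null r ~ Binomial(r + g, C_r/(C_r + C_g)). A
plug-in Poisson test that treats g·C_r/C_g as a known mean is
anti-conservative whenever the input library is itself a noisy count of
depth comparable to the IP — exactly the regime of matched IP/input
designs — whereas the conditional test is calibrated by construction. A
mid-p correction (half the probability mass of the observed count) removes
the super-uniformity of the discrete tail; the test suite verifies
Kolmogorov–Smirnov uniformity of null p-values at α = 0.01 on 10⁴
kilobase windows. The likelihood statistic kept per call is the one-sided
Poisson log-likelihood ratio against the background mean, used only for
ranking (the "top five by likelihood" filter).

**Peak calling** is single-base: at every base the IP and input coverage
are summed over a centred window (default 101 bp, matching fragment scale),
tested as above, and bases with p < pthresh (default 10⁻⁶) are retained
greedily by significance with neighbours suppressed within peakminsep
(default 250 bp). Ties break to the leftmost base for determinism. This is
a deliberately simple single-sample model with the same semantics as the
replicate-aware caller used on the real data; replicate combining is out of
scope.

**Filters.** Peaks are removed when their center lies strictly within
2.5 kb of a promoter-type mark (distance boundaries are read exclusively:
"within 2.5 kb" ⇒ < 2500), when input coverage is ≤ 5 or above its 99.9th
percentile, and (flag-controlled) the top five peaks by likelihood. The
4 kb double-counting rule removes *both* members of any pair of peaks
whose centers fall within 4 kb, chains transitively — a rule chosen to
guarantee that profile averages never count the same fragment twice.

**Profiles and heatmaps.** Aggregate profiles are the ratio of
total-coverage-normalised mean IP to mean input across centred (optionally
stranded) regions, with minus-strand regions reversed and off-chromosome
positions contributing 0. Heatmap matrices scale normalised coverage by
10¹⁰, tile at 5 bp, add a pseudocount of 1 to both IP and input, take the
per-region ratio, threshold at the 0.01–0.99 quantiles and order rows by
mean IP coverage of the central 200 bp. Random control placements are
uniform with the same 4 kb minimum separation and a fixed default seed
(72346) for reproducibility.

**Binned curves.** Equal-count binning is rank-based (bin sizes differ by
at most one). Smooths are penalized B-spline GAMs (statsmodels `GLMGam`,
basis dimension 10, penalty weight chosen by the built-in criterion, with
a fallback to a fixed penalty when selection fails); logistic family for
overlap probabilities, Gaussian for enrichment-vs-enrichment curves on
log(x + 0.1). This differs from an R mgcv cubic-regression-spline/GCV fit
in basis details but not in the fitted shapes at these data sizes.

## CpG and methylation analyses

CpGs are counted as forward-strand CG dinucleotides — CG is its own
reverse complement, so each genomic site is counted once; N never matches.
Alu-like repeats are filtered to widths in [250, 350] bp (canonical
full-length Alu/B1). Methylation records are processed in a fixed order:
non-CpG contexts dropped, the two strands of a site summed, copy number
> 1.5 removed, zero-coverage sites dropped, then strict thresholds applied
(ratio > 0.75 methylated, < 0.25 unmethylated, otherwise ambiguous), which
makes the classification a partition of the retained sites. Window
analyses tile autosomes with non-overlapping 300 bp windows (stride
configurable); windows overlapping a repeat or CpG island by ≥ 10 bp are
excluded from model fits, while peak overlap for the response variable is
≥ 1 bp.

## DMC1 persistence analyses

DMC1 SSDS signal at a hotspot reflects DSB frequency × DMC1 persistence;
persistence itself is never observed, so the module reports observable
consequences only (the simulator carries the generative persistence):

* **Scaling**: enrichment columns are divided by their autosomal mean
  (X rows scaled by the same factor), making scaled autosomal means exactly
  1 and the operation idempotent.
* **Linearity**: OLS of log DMC1 on log SPO11; zeros are offset by the
  smallest positive observed value (recorded in the result). The exponent's
  95% CI classifies the relationship: entirely below 1 → sublinear
  (faster repair at hotter hotspots), covering 1 → linear. An RSS
  comparison against the slope-fixed-at-1 model is reported alongside.
* **KO:WT ratio model**: per-hotspot DMC1_KO/DMC1_WT (autosomes only;
  non-positive WT rows excluded with a count) smoothed on the predictor by
  a Gaussian GAM. r is the Pearson correlation of fitted vs observed
  ratios — the study's r could also be read as a deviance-based quantity,
  but fitted-vs-observed Pearson is the interpretation adopted and
  documented here. The fold-range is the mean fitted ratio in the top
  decile of the predictor divided by that in the bottom decile.
* **Profile normalisation**: per strand-sample combination, the mean
  per-offset coverage over that sample's regions on offsets
  [−5000, +2000] has the mean over [−5000, −3000] subtracted (so the
  background window averages exactly 0) and is divided by the summed
  coverage of that combination across *all* samples' region sets, making
  profiles comparable across genotypes and invariant to per-track scaling.
* **Stratification**: low (< 50th percentile of the mark), high (> 75th),
  medium otherwise; when all mark values are identical every region falls
  in "medium". The half-maximum width summary (offset range where the
  profile exceeds half its maximum) is descriptive, not an acceptance
  surface.
* **Status prediction**: DMC1 peaks are width-filtered (< 3 kb) and
  trimmed to ≤ 800 bp about their midpoint; binding sites with input ≤ 5,
  input > 200 or enrichment > 10 are removed; a logistic model (binomial
  GLM, logit link) is trained on all autosomes except chromosomes 1, 3, 5
  and evaluated there by AUROC and average precision.

Bin CIs are mean ± 1.96 SE (normal approximation) — figure-legend-style
95% intervals without a distributional claim. CI-boundary classifications
carry a 10⁻⁹ numerical slack so exact algebraic fits classify correctly.

## The synthetic-data generator

Defaults define the study conditions end to end:

* **Protein families**: 5 clades × 20 species (100 sequences), reference
  length 450, 20 designated conserved positions (including implanted KWR
  and PWWP motifs, so the initial screen functions as on real data), 5%
  per-position substitution in true orthologues, 20% shuffled-profile
  decoys, 10% truncation to a contiguous span covering 60–90% of the
  reference. At 5% substitution across ~80 true orthologues some
  unconserved positions remain invariant by chance (expected ~0.95⁸⁰ per
  position), so the recovery oracle is the brute-force invariant set over
  the screened sequences — which must contain every designated position —
  rather than the designated set alone.
* **Genomes**: 3 chromosomes × 150 kb, 60 motif-defined hotspots, 30
  promoters, 80 Alu-like repeats (each with 3–14 CpGs, 80% of repeats
  methylated, 5% high-copy), Poisson background at 1 fragment/base —
  typical deep-coverage ChIP density — and multiplicative enrichment 4 at
  true sites under a 1 kb triangular kernel. Chosen so that force-calling
  has realistic counts (~10³ per kb) while 100 replicate simulations run
  in under a minute.
* **DMC1 model**: SPO11 log-normal (sd 0.8 on the log scale); H3K4me3
  proportional to SPO11 with log-normal noise (sd 0.4), scaled to mean 3;
  persistence (1 + H3K4me3)^(−b) with b = 1 in WT mode and 1 in KO mode;
  observed DMC1 carries multiplicative log-normal sampling noise
  (sd 0.15). These values give a WT exponent visibly below 1 and a
  KO-to-WT ratio fold-range of roughly an order of magnitude across
  H3K4me3 deciles, the qualitative regime of the real data.

What the simulator does **not** emulate: read-level artefacts (FASTQ,
mapping, duplicates, mappability), fragment-length distributions, GC bias
beyond an optional smooth trend, chromatin contact structure, and the
X-chromosome's distinct repair pathway (X rows are synthesised only to
test the scaling contract). Passing tests therefore establish the
correctness and calibration of the *procedures*, not the biological
conclusions on real libraries.

## Problem sizes and determinism

The test suite validates calibration on 10⁴ kilobase windows over a 10 Mb
null genome, orthologue recovery over seeds 1–20, and persistence-model
classification over 100 seeded genome replicates; these sizes keep the
whole suite around one to two minutes while leaving Monte-Carlo error well
inside the asserted margins. All stochastic draws flow from explicit
`numpy` generators seeded per simulation; re-running any stage with the
same configuration reproduces byte-identical outputs, which the pipeline
manifest (config snapshot, seed, output checksums) makes checkable.

## Known limitations

* The enrichment model is single-sample; replicate-aware likelihoods and
  fragment-model refinements of full peak callers are out of scope.
* The conditional binomial p-value conditions on the window total, so
  extremely shallow windows (r + g near 0) carry almost no evidence and
  are flagged uninformative rather than tested.
* The KO-linear classification inherits the nominal 95% coverage of the
  exponent CI: over many replicates roughly 1 in 20 exactly-linear
  simulations will produce a CI that misses 1, which is the expected
  behaviour of a calibrated interval, not a defect.
* The published species-level summaries (78% of 167; odds ratio 285)
  require supplementary tables not distributed here; the operations that
  compute them are fully implemented and tested on synthetic taxonomies.
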