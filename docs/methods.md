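# Methods

`protqtl` dissects the genetics of a quantitative seed-composition trait
(percent seed protein) in breeding germplasm using three complementary
tracks — a QTL genome scan in a biparental recombinant-inbred-line (RIL)
population, bulked-segregant analysis (BSA) across several sister
populations, and a pedigree rare-allele retention scan over a diversity
panel — together with the simulators needed to generate data with the same
statistical structure. This note records the models, the defaults and the
design choices behind each piece.

## Simulation model

### RIL populations

A RIL population of `n_lines` is produced by strict single-seed descent
from the F1 of two fully homozygous parents: each line is advanced one
random seed per generation to its derived generation *k* (F5 by default),
so residual heterozygosity per marker is (1/2)^(k−1) (6.25% at F5).
Meiosis uses the Haldane mapping function (no crossover interference):
the per-interval recombination fraction is r(d) = (1 − e^(−2d/100))/2 for a
map distance d in cM. Crossovers are realized as independent Bernoulli(r)
origin switches per adjacent marker interval, which is equivalent in law,
at the marker positions, to drawing Poisson(L/100) crossovers with uniform
positions. No selection is applied during inbreeding, and residual
heterozygotes are retained rather than forced homozygous.

Genotypes are coded by parental origin: A (parent-1 homozygote), H
(heterozygote), B (parent-2 homozygote); additive dosage is −1/0/+1. By the
package's convention the B parent carries the trait-raising alleles in the
bundled models.

### Phenotypes

Per plot, trait = mean + Σᵢ aᵢ·xᵢ + Σᵢⱼ wᵢⱼ·xᵢxⱼ + trial + residual, with
balanced trials (every line in every trial) and the line value taken as the
arithmetic mean over trials — identical to least-square means under
balance. Because trial effects shift every line equally in a balanced
design, between-line variance is residual²/n_trials plus the genetic
variance.

When a model carries target variance fractions, effects are *solved* rather
than supplied: with σ²_eff = residual²/n_trials and total genetic fraction
F, the line-mean variance is V = σ²_eff/(1 − F) and each effect is
aᵢ = √(fᵢ·V)/sd(xᵢ) using the empirical dosage standard deviation of the
simulated population (likewise for interaction products). This makes each
locus's marginal share of line-mean variance equal its target in
expectation, which is what the recovery studies check. Targets summing
above 1 are rejected — they are not a realizable architecture.

Defaults: population mean 44% protein (midparent of high ≈ 48% and low
≈ 40% parents), residual SD 1.5% per plot, trial-effect SD 1.0%, three
trials. Oil is generated as a negatively correlated companion trait
(slope −0.6 on protein, matching the protein/oil trade-off typical of
high/low protein soybean parents) and yield as uncorrelated noise; both
exist to exercise the file formats, not to model seed biology.

### The canonical five-locus protein architecture

The bundled model places additive loci mid-chromosome on Gm20, Gm15, Gm01
and Gm16 and a fifth locus on Gm05 that acts purely through its interaction
with the Gm20 locus. The published single-locus variance shares for this
kind of architecture (60:23:14:13 plus 1 for the interaction) sum to 1.11
and therefore cannot all be simultaneous marginal truths; the model keeps
them as *relative weights* and scales them so the joint model explains 70%
of line-mean variance — the reported joint total. The resulting simulated
truths are 37.8/14.5/8.8/8.2% additive plus 0.6% interaction. Consequence:
in the joint architecture the minor loci's marginal R² recover their
*scaled* contributions (≈9–10%), not the raw printed shares; the
single-locus and two-locus studies, which are individually feasible, use
the unscaled 60% and 23% directly.

### Diversity panel and pedigree descent

The panel simulates inbred cultivars: per SNP an alt-allele frequency is
drawn from a configurable MAF distribution (default Uniform(0.01, 0.5)),
each line is homozygous with that probability, with small heterozygosity
(1%) and missingness (2%) overlays. A designated donor line is made
homozygous for a minor allele at a chosen number of SNPs whose expected
panel frequency equals `rare_frequency` (default 1/300, i.e. the donor is
usually the sole carrier among 300 lines).

Pedigree descent is modeled at the level the retention scan observes, not
meiosis-by-meiosis: each derivative cultivar carries the donor genotype at
every SNP inside the designated retained blocks (selection for the trait)
and, outside them, inherits donor vs recurrent-parent genotype per
independently segregating region (10 Mb windows) with a configurable
retention probability (default 0.125, the neutral expectation for a
BC2-derived line). What this does *not* emulate: linkage drag gradients at
block edges, pedigree-correlated retention among derivatives that share
intermediate ancestors, residual heterozygosity in derived cultivars, and
GBS-style call-rate structure. Passing the recovery tests therefore shows
the filters are correct and calibrated under clean Mendelian structure, not
that real-panel artifacts (paralogs, imputation errors) are handled.

## QTL genome scan

The scan is Haley–Knott-style regression of line means on expected additive
dosage over a cM grid (default step 1 cM, grid always includes the marker
positions), with the likelihood-ratio-type statistic

    TS(position) = n · ln(RSS₀ / RSS₁) = −n · ln(1 − r²)  (no cofactors).

The statistic's absolute scale is immaterial because significance comes
from permutations. Genotype probabilities at grid points condition on the
nearest informative flanking markers under the two-state Markov chain for
selfed RILs at fixation: the per-meiosis r maps to the line-level
R = 2r/(1 + 2r) (Haldane–Waddington), heterozygous calls are treated as
missing for conditioning (the standard `riself` convention), and a fully
uninformative line falls back to the prior ((1−h)/2, h, (1−h)/2) with h the
generation heterozygosity. The chain is an approximation in two respects:
finite-generation RILs are slightly less recombined than the fixation
limit, and the multi-locus genotype process of selfed RILs is not exactly
Markov; the three-locus exact-enumeration test bounds the resulting dosage
error (well under 0.02 at a 20 cM bracket near fixation).

Modes: SIM (no cofactors) and sCIM with fixed marker cofactors — by default
one marker per ~30 cM bin, chosen by strongest marginal association,
excluded within ±20 cM of the test position; collinear cofactors are
dropped with a warning. sCIM with an empty cofactor set is SIM, point by
point.

The permutation threshold permutes line means against genotype rows,
records each permutation's genome-wide maximum TS, and returns the k-th
order statistic with k = max(1, ⌈(1−α)·n_perm⌉) (so α = 1 returns the
minimum of the null maxima). 10,000 permutations is the reference setting;
the calibration study uses 1,000 for speed, which changes only the
threshold's Monte-Carlo jitter, not its level.

Peaks are local maxima above the threshold, one per chromosome unless the
profile dips below the threshold between maxima; a shoulder peak is also
reported when separated from an accepted peak by a dip of ≥25% of the lower
peak. Variance explained at a position is the R² of line means on the
expected dosage there (identical to the squared Pearson correlation).

The anchored re-scan fixes a declared QTL's dosage in the model and, at
each grid point outside a ±20 cM exclusion window around the anchor, tests
the added additive term and the anchor×test interaction term separately
(TS of nested model comparisons). Note that the anchored additive TS is on
the anchor-adjusted scale: with a large anchored QTL it exceeds the
unanchored TS at a second locus even when effects are orthogonal, because
the residual base is smaller; the equivalence that *does* hold (and is
tested) is with a scan of anchor-residualized phenotypes.

## Bulked-segregant analysis

Bulks are the top and bottom `tail_fraction` (default 10%, minimum 8 lines)
of line means, ties at the boundary broken by line name for determinism.
Bulk genotyping is modeled on lines pooled in silico: allele counts with
heterozygotes contributing half, not pooled-DNA signal intensities. Per
marker and population the frequency of the high-parent allele is estimated
in each bulk and the marker is classified:

* **positive** — Δf = f_high − f_low ≥ 0.4 and Fisher's exact test on the
  2N allele counts has p ≤ 0.05;
* **fixed_high / fixed_low** — both bulks ≥ 0.95 (resp. ≤ 0.05) for the
  high-parent allele: no contrast, but consistent with a locus already
  driven to fixation by prior selection;
* **uninformative** otherwise.

All three thresholds are exposed. Positive calls are merged across
populations into loci by single-linkage clustering along each chromosome
(gap ≤ 10 cM by default); each locus reports per-population status and a
support count of positives plus high-allele fixations, reflecting the
interpretation that fixation in a high × high cross corroborates rather
than contradicts a locus. Populations can be excluded from locus discovery
(the high × high cross) while still reporting their allele status at loci
found elsewhere.

## Rare-allele retention scan

Four steps over a diversity panel, all coordinates 1-based inclusive bp
(BED export converts to 0-based half-open):

1. **Rare-allele screen.** SNPs where the focal line is homozygous for an
   allele with panel frequency ≤ 0.02 (frequency over non-missing allele
   calls, hets as half; heterozygous/missing focal calls skipped). The
   focal line's own descendants are excluded from the frequency denominator:
   with seven derivatives counted, any fully retained allele would sit at
   ≥ 8/307 ≈ 2.6% and the screen could never fire — within-family retention
   is the signal under test, not evidence the allele is common. The 2%
   default is deliberately wider than the 0.05–1.1% range the retained
   alleles themselves occupy, and is configurable.
2. **Contrast filter.** Keep SNPs whose focal allele is absent (homozygous
   other) from the recurrent parent; by default the additional low-protein
   comparator lines must also lack it (a flag demotes them to annotation
   only, since either reading of the published procedure is defensible). A
   missing comparator call is non-informative: the SNP is kept and flagged.
3. **Retention filter.** Retention ratio ρ = carriers / informative
   derivatives, where a carrier is homozygous for the focal allele and
   informative excludes missing and (by default) heterozygous calls;
   keep ρ ≥ 0.66 (or 1.0 for the strict scan) with ≥ 4 informative
   derivatives. Counting hets as carriers is a flag.
4. **Blocks.** Single-linkage clustering along each chromosome: consecutive
   surviving SNPs ≤ 500 kb apart join one block; clusters below 2 SNPs are
   reported separately as singletons. Block span runs from first to last
   member SNP. Anchor markers and known regions (QTL, BSA loci, meta-QTL
   tables) within the block or within 1 Mb of its edge are attached;
   unannotated blocks are flagged novel.

The end-to-end recovery study measures span overlap against each injected
block's *detectable extent* — the interval spanned by its rare SNPs — since
no method can recover donor sequence beyond the outermost distinguishing
marker.

## Numerical and reporting choices

* One seeded `numpy.random.Generator` per operation call; seeds recorded in
  output metadata and in the pipeline's provenance file.
* The scan clips r² away from 1 by 1e−12 before the log; zero-variance
  dosage columns score TS = 0; a constant phenotype yields an all-zero
  profile with a warning.
* Δf is compared to its threshold with a 1e−9 tolerance so that
  mathematically symmetric bulk configurations classify identically under
  label mirroring.
* BSA exact tests round half-counts to the 2N allele scale (a het
  contributes one allele of each kind), keeping Fisher's test exact on
  integers.
* Model loci must coincide with map markers (tolerance 1e−6 cM); the
  simulators refuse positions off the map rather than silently snapping.

## Study problem sizes

The replicated studies use a 20-chromosome map with 13 markers per 120 cM
chromosome (a sparser stand-in for a ~640-marker SSR/DArT map whose
skeleton is also bundled), 200 replicate populations of 100 lines for the
recovery studies, 500 null simulations with 1,000 permutations for
threshold calibration, and a 300-line × 20,000-SNP panel for the retention
study. These sizes put Monte-Carlo error comfortably inside the recovery
tolerances (±5 percentage points of variance explained; ±2 points of
type-I error) while keeping a full run in the minutes range on one CPU.

## Known limitations

* No multiple-QTL model selection, no EM interval mapping, no dominance or
  genotype×environment modeling (RILs carry little residual
  heterozygosity, so the additive dosage model loses little).
* Sequencing-based BSA (pooled reads, Δ-SNP-index smoothing) is out of
  scope; BSA here is marker-based on in-silico pools.
* The retention scan does no imputation, phasing or LD-based haplotype
  inference; blocks are purely physical-proximity clusters.
* The anchored scan tests one anchor at a time; epistasis among undeclared
  loci is not searched exhaustively.
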