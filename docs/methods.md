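# Methods

`callusmap` re-implements, as a tested pipeline on synthetic data, the
statistical genetics of a binary callus-morphology mapping study in maize:
an F2 population from the cross of a transformation-amenable line (A188)
and a recalcitrant elite line (B73) is phenotyped for Type I (compact,
slow-growing) versus Type II (friable, fast-growing) callus, phenotypic
extremes are genotyped by GBS and pooled into bulks, and the trait is
mapped three ways — a per-marker logistic test, binary-model interval
mapping, and bulk-segregant allele association.  This note documents the
models, the defaults and why, and what the synthetic experiments do and do
not establish.

## Synthetic study generator (`simdata`)

**Genome and meiosis.**  The default genome is ten chromosomes of 100–180
cM (maize-shaped at reduced physical scale, 1 Mb/cM, configurable).
Meiosis follows the Haldane model: crossover counts per gamete and
chromosome are Poisson(length in Morgans) with i.i.d. uniform positions and
no interference.  This matches the map-function convention of standard
interval mapping; no interference model is asserted for the real organism.

**Phenotype.**  Callus type is generated from an additive liability on the
log-odds scale: `eta = mu + sum_q beta_q (x_q - 1)` with `x_q` the
A188-allele dosage at QTL q, and `P(Type II) = logistic(eta)`.  The default
architecture places QTLs on chromosomes 2, 5, 6, 8 and 9 with the
chromosome-6 allele favorable from A188 (`beta > 0`) and B73 favorable
elsewhere, chromosome 5 strongest — the qualitative structure the mapping
stages are expected to recover.  Effect magnitudes (|beta| 0.8–1.1 per
allele copy, `mu = 0`) are the package's own defaults: the source study
does not report liability-scale effects, so they were fixed once at values
that make the architecture mappable in a ~118-individual extreme design.

**Selection of extremes.**  The study design selects the 100 most extreme
calli of each morphology from 2194 embryos.  The generator models this as
the tails of a noisy morphology score — liability plus N(0, 2) observation
noise — within each phenotype class (`selection="extreme"`,
`selection_noise_sd=2.0`).  The score noise represents imperfect visual
assessment of morphology; with it, joint variance explained by the five
QTLs lands near 70% and single-QTL LODs near 10–20.  Pure
random-within-class sampling is available (`selection="random"`) but
discards the extremeness information of the real design: under it each
QTL's marginal penetrance contrast is capped by the other QTLs acting as
liability noise, localization degrades to ±20–40 cM, and dominance
classification at peaks becomes unreliable — an instructive contrast, not
a default.

**GBS degradation.**  Per call, independently: missing with probability
0.2; surviving heterozygotes become a random homozygote with probability
0.05 (allelic dropout / undercalling); any surviving call is replaced by a
uniformly chosen different code with probability 0.02.  These defaults are
typical of reduced-representation genotyping after upstream filtering.

**Bulks.**  The selected extremes are split into two 50-callus bulks per
class.  Per SNP and bulk, depth is Poisson(200) and A188-allele reads are
Binomial(depth, f) with f the mean A188 allele frequency of the bulk
members — exactly the generative model the downstream association test
assumes.  Real RNA-seq features the generator does *not* model: expression-
weighted allele sampling, overdispersion between replicates, reference-
mapping bias, and allele-specific expression.  Calibration results below
therefore certify the statistics under their stated model, not robustness
to those artifacts.

A single seed fans out to per-stage substreams (`SeedSequence.spawn`), so
every stage is independently reproducible and the whole simulation is
bit-reproducible.

## Segment (bin) markers (`binmarkers`)

Per chromosome and individual: (1) a sliding plurality vote of width
`smooth_window` over the non-missing calls (ties keep the original call);
(2) run-length encoding into candidate segments; (3) candidates with fewer
than `min_snps_per_segment` supporting SNPs are absorbed — merged through
when both flanks agree, otherwise into the better-supported flank.
Boundaries sit at the bp midpoint between flanking SNPs; intervals are
0-based half-open internally, 1-based in TSV output.

Two presets serve different purposes:

* **mapping** (`smooth_window=5`, `min_snps_per_segment=3`, the default):
  robust to a few percent genotype error; the cost is that true segments
  shorter than the window (double crossovers within ~0.5 cM at the default
  SNP density) are smoothed away.
* **QC** (`smooth_window=1`, `min_snps_per_segment=2`): used for the
  excess-recombination screen.  The screen exists to catch individuals
  whose genotyping noise inflates apparent recombination; heavy smoothing
  would erase precisely that signal, leaving the filter blind.  With light
  smoothing, paired-call errors remain visible: at the default 2% error
  rate the count inflates mildly (a few events over the expectation), at
  5x that rate it inflates several-fold, and the 2x-expectation filter
  separates the two regimes cleanly.

The expectation used by the filter is `2 x map length in Morgans`: two
gametes per F2, each crossover producing at most one discernible genotype
transition.  Double crossovers between adjacent informative SNPs are
invisible by construction, so "discernible" counts transitions only.  The
filter multiplier (default 2.0) is deliberately generous for Poisson
spread and exposed as a parameter, since the source analysis does not
state its cutoff.

Harmonization takes the union of all retained individuals' segment
boundaries per chromosome as bin edges, assigns each individual its
covering segment's genotype per bin (NA where uncovered), removes
monomorphic bins (a bin useless for mapping, and required by the
container's invariant), and collapses adjacent bins with identical call
vectors.  A bin's representative position is its bp midpoint, with cM
interpolated from the genetic map.

## Logistic genome scan (`qtlscan`)

At each bin the default test is a likelihood-ratio test of
`y ~ genotype-as-factor` against intercept-only.  Because the factor model
saturates on the (at most three) genotype classes, its logistic MLE fitted
values are the class means and the deviance has a closed form in class-wise
binomial log-likelihoods; the scan and its permutation machinery use this
closed form directly (vectorized over markers and permutations), which is
what makes hundreds of fully-permuted null scans affordable.  Complete
separation leaves the deviance finite; coefficient summaries are computed
with a small ridge (1e-4) Newton fit and flagged when a class proportion
hits 0 or 1.  Additive 1-df dosage coding is available for comparison.

Significance is reported two ways, side by side: Benjamini–Hochberg FDR at
q = 0.01 over all tested bins, and a genome-wide permutation threshold —
the alpha-quantile of the per-permutation genome-wide minimum p (1000
shuffles by default; the threshold is the k-th smallest extremum with
k = floor(alpha x n_perm), giving exceedance probability k/(n_perm+1) ≈
alpha for the unpermuted scan).

## Binary-model interval mapping (`qtlscan`)

On a pseudomarker grid (1 cM step by default, marker positions included),
latent QTL genotype probabilities are computed per individual from the
flanking informative bin markers under the F2 Markov chain with Haldane
recombination fractions; a missing flank falls back to a one-sided
transition, and positions outside coverage to the 1:2:1 prior.  The three
penetrances `p_g = P(y=1 | g)` are then fit by EM — E-step: posterior
genotype weights under current penetrances; M-step: weighted phenotype
means; convergence at max |delta p| < 1e-6 or 100 sweeps — and
`LOD = log10 L(fitted)/L(null)` with the null penetrance equal to the
phenotype mean.  At a fully informative marker the genotype probabilities
are point masses, the EM solution is the class-mean fit, and the LOD
equals the logistic 2-df LRT / (2 ln 10) to numerical precision; this
equivalence is tested.  The EM is vectorized over grid positions and, for
permutation thresholds, over permutations (the permutation grid drops the
marker-position refinement, which leaves the null extremum distribution
essentially unchanged while halving the work).  Thresholds: the
permutation LOD (1 - alpha quantile of genome-wide maxima) and the
conventional fixed LOD 3, reported together.

**Peaks and annotation.**  Above-threshold runs are grouped per
chromosome; each run's maximum is a peak (ties to the smaller bp); peaks
closer than 30 cM merge keeping the stronger.  Support intervals are
1.5-LOD drops by default — the drop value is a design choice, the source
analysis names only "LOD support interval".  Each peak is annotated from
its nearest bin: the favorable allele is the parental allele of the
homozygote class with the higher Type II proportion, and the dominance
call places the heterozygote proportion on the segment between the
homozygote proportions — middle third: additive; outer thirds: dominant;
outside the segment (over/underdominance): partial.  A joint
factor-coded ridge-logistic fit of all peak bins (complete cases, no
epistasis) gives the joint LOD, converted to phenotypic variance explained
by `100 (1 - 10^(-2 LOD / n))`.

## Bulk-segregant association (`bsrseq`)

Record-level filters follow the stated rules with their printed boundary
semantics — biallelic, AF >= 0.2, QUAL >= 30.0, 100 <= DP < 10,000 — plus
parental concordance (the site must be a fixed homozygous A188/B73
difference matching the record's alleles); rejections are tallied by rule
and the filters commute.  The association test pools the replicate bulks
within each class by default (no replicate term is stated in the source
model) and computes the binomial-GLM likelihood-ratio (deviance) test of
the class effect on the A188-read proportion — algebraically the G-test on
the pooled 2x2 table, computed in closed form and verified against the
iterative statsmodels GLM.  A `replicate_term` variant fits the GLM with a
replicate nuisance factor.  No overdispersion correction is applied by
default, matching the plain binomial model.  Genome-wide significance is
`alpha / n_tests` (Bonferroni), with n_tests the testable SNPs.

## Integration (`integrate`)

Inbred-derivative profiling reuses the segment caller on a single line and
reports segments (including residual heterozygosity) and the breakpoint
count `sum(segments - 1)`; `allele_at_qtl` reads the covering segment at
each QTL peak and labels it favorable/unfavorable/het against the peak's
favorable allele.  Candidate genes are DEGs (consumed as input tables; no
differential-expression statistics are re-implemented) that overlap a QTL
support interval — any-overlap on half-open intervals by default, full
containment behind a flag — and are DE in both contrasts, concordantly by
default.  Expression matrices in reads-per-million are z-scored per gene
with the sample standard deviation; zero-variance genes become all-zero
rows with a flag rather than dividing by zero.

## Validation experiments and their scales

The `experiments` module (exercised by the test suite and
`scripts/acceptance.py`) runs: exact segmentation recovery on an
error-free 10 x 120 cM, 5 SNP/cM, n = 200 population; the QC drop-rate
contrast at 1x vs 5x genotype error (same scale); genome-wide type-I-error
calibration of both scans on 150–200 null datasets of n = 100 over a small
two-chromosome genome with 200-permutation thresholds each; EM/closed-form
LOD equivalence on 50 random fixtures; full-pipeline five-QTL recovery at
study scale (2194 embryos, 100+100 extremes, default GBS noise) over 12–20
replicates; binomial-deviance vs Pearson chi-square agreement on 1000
mild-effect tables at depth >= 100 plus familywise-error control on
10,000-SNP null genomes; and byte-identity of two runs of the demo
pipeline.  The reduced replicate counts keep each experiment in the
seconds-to-minutes range on one core.

What passing shows: the algorithms are correct under their own generative
assumptions and calibrated under the null.  What it does not show:
robustness to real-data features the generator omits (linked selection of
sub-genomic regions, non-Poisson crossover interference, RNA-seq
overdispersion and mapping bias, genotyping error that is clustered rather
than independent).

## Numerical choices and degenerate inputs

Penetrances are clipped to [1e-12, 1 - 1e-12] inside likelihoods; the EM
starts from the null penetrance, so its LOD is non-negative by monotone
ascent.  Monomorphic markers return missing test results with a reason;
constant phenotypes yield LOD 0 tracks; empty bulks, empty phenotype
classes, single-sample expression matrices, and duplicate gene ids raise
errors naming the offender.  Plateau peaks break ties toward the smaller
bp.  All randomized procedures take explicit generators or seeds; pipeline
outputs carry no timestamps and fixed float formatting so reruns are
byte-identical.

## Known limitations

Segment smoothing erases true double-crossover segments shorter than the
window; the bin-marker count therefore slightly undercounts tight double
recombinants.  The interval mapper conditions on called bin genotypes
without a residual genotype-error term (upstream smoothing is relied upon
instead).  Dominance classification at a peak uses the marker nearest the
peak, which attenuates toward the null when the peak is displaced from the
causal position.  The BSR test treats reads within a bulk as independent
Bernoulli draws; overdispersed data will be anticonservative unless the
replicate-term variant is used.
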