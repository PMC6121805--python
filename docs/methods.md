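# Methods

`shoreclines` implements a hybrid-zone analysis for a steep ecological
transition sampled along a one-dimensional shore transect: geographic
cline models fitted to per-individual allelic read depths, a
system-tailored individual-based neutral simulation that supplies the
null distribution of cline fit quality, a classification of SNPs as
non-neutral, and downstream characterization of where non-neutral SNPs
sit in the genome (clustering on a linkage map, high-LD blocks,
dispersal from LD at the cline center).

## Transect geometry

Snail coordinates are reduced to one dimension by fitting a
piecewise-linear path (11 segments by default) through the (x, y) cloud,
minimizing the mean squared orthogonal distance of points to the path.
Vertices are initialized at quantile centroids of points ordered along
the first principal axis and refined jointly by L-BFGS-B; the objective
is non-convex, so the result is a local optimum, and the refined path is
never accepted if it is worse than its initialization.  Each sample's 1D
position is the cumulative arc length from the northern (Crab) end to
its nearest point on the path; projection ties break to the smaller arc
length.  Habitat transitions are located by projecting survey points,
majority-smoothing the labels in a 5-point window, and placing each
transition at the midpoint between flanking survey points.

## Cline model family

Five models: a constant-frequency null; the sigmoid
`p(x) = p_C + (p_W - p_C) / (1 + exp(-4 (x - c) / w))`, whose maximum
slope is `(p_W - p_C)/w` so that `w` is the conventional cline width;
and left-, right-, and two-tailed stepped clines.  A tail replaces the
sigmoid outside the junction `c - delta_L` (mirrored on the right) by an
exponential that is continuous with the sigmoid at the junction and
whose log-slope there is `tau` times the sigmoid's.  With `tau = 1` and
`delta = 0` the tail is tangent to the sigmoid at the center (value and
log-slope agree) but is not identical away from it; the family reduces
*exactly* to the sigmoid when the junctions lie outside the data range
(large `delta`), and property tests assert those true reductions plus
numerical continuity at the junctions.  The two-tailed model fits
independent tails by default; `symmetric_tails` constrains
`(delta, tau)` to be shared (6 instead of 8 free parameters).

Cline slope is reported as `|p_W - p_C| / w` and is undefined for the
null model.

## Read-depth likelihood

Genotype calls are never required: for individual *i* at transect
position `x_i` with `ref_i` reference and `alt_i` alternative reads,

    L_i = sum_g HW(g; p(x_i)) * Binom(ref_i; ref_i + alt_i, mu_g),
    mu_g = eps + (g/2) (1 - 2 eps),

with `g` the reference-allele dosage, Hardy-Weinberg genotype priors at
the local expected frequency, and a symmetric per-read error
`eps = 0.01` by default.  Zero-depth individuals contribute nothing.
The binomial coefficients and the genotype-conditional read factors do
not depend on the cline parameters, so the fitter precomputes them once
per SNP; each objective evaluation then costs one logarithm per
individual.  The factored path is verified against the direct kernel to
1e-12 and against exhaustive genotype-mixture enumeration on small read
counts.

Fitting is bounded multi-start L-BFGS-B (numba gradient by central
differences): `p_C, p_W in [0, 1]`, center within the position range
+-50 m, width in [1, 500] m (the 1 m floor caps how steep a fitted cline
can be), `delta in [0, 100]` m, `tau in [0.01, 1]`.  The sigmoid starts
from a data-driven initial value (center at the steepest smoothed
binned-frequency gradient, end frequencies from the outer bins, width
from the interquartile span of positions) plus seeded jitters (3 starts
by default); tailed models start from the sigmoid solution with small
tails plus one jittered start, and a tailed model is never reported with
a worse likelihood than the sigmoid it nests.

Model selection uses AIC with a conservative complexity ladder: a SNP is
clinal iff `AIC(null) - min AIC(clinal) > 4` (strict), and a more
complex clinal model is selected only if it beats *every* simpler clinal
model by more than 4 (between the two equally complex one-tailed models
the lower AIC wins).  Quantitative traits use the same family with the
cline as the Gaussian mean and the residual SD profiled out (one extra
AIC parameter); morph indicators use a Bernoulli likelihood.

## var.ex

Fit quality per SNP is a depth-weighted R^2 on a 0-100 scale: with
`y_i = ref_i / depth_i` and weights `d_i = depth_i` (zero-depth
individuals excluded),

    var.ex = 100 * (1 - sum d_i (y_i - p(x_i))^2 / sum d_i (y_i - ybar)^2),

`ybar` the depth-weighted mean.  It can be negative for a bad fit, is
capped at 100, and is defined as 0 for the null model (a constant
explains no spatial variance).  Phenotype clines use unit weights.  A
weighted-regression oracle reproduces the value to 1e-9.

## SNP filters

Before fitting: (1) keep only SNPs within 1,000 bp of a mapped SNP on
the same contig (nearest entry wins; ties break to the lower cM);
(2) drop monomorphic/low-MAF SNPs (pooled read fraction < 0.01);
(3) drop SNPs rejecting an exact Hardy-Weinberg test (conditional
hypergeometric, two-sided) within either transect-end reference region
(outermost 30 m on each side) at p < 1e-6 -- a deliberately stringent,
Bonferroni-style threshold, configurable; (4) drop SNPs whose
allele frequencies differ between sexes (chi-square two-proportion test,
p < 1e-6).  Genotypes for (3) and (4) are maximum-likelihood calls from
the same read model.  Every exclusion is logged with its first failing
reason.

## Forward simulation

Diploid individuals live in a chain of 152 demes of 1 m, with the
habitat switching after deme 85.  Each generation: adults disperse by a
zero-mean Gaussian displacement (SD `sigma`, reflected at the chain
ends) and are re-binned to demes; within each deme, the next generation
of exactly N offspring is produced by drawing two distinct parents per
offspring with probability proportional to viability fitness in the
deme's habitat (soft selection / local regulation), with Mendelian
transmission per locus.  Selected loci (200) favour allele 1 in Wave
habitat and allele 0 in Crab habitat, with multiplicative fitness across
loci and additive within-locus effects; the per-locus coefficient
`s_loc = 1 - (1 - s_total)^(1/n_selected)` makes the fitness gap between
fully matched and fully mismatched multilocus homozygotes equal
`s_total = 0.7`.  Neutral loci are unlinked and unselected but share the
pedigree, so they feel the multilocus barrier.  Primary divergence
initializes every locus at frequency 0.5 everywhere; secondary contact
fixes selected loci for the locally favoured allele on each side.
Mutation is off by default (4,000 generations is short relative to
mutation input) but a per-allele flip rate is available.

Genotypes are stored as two allele bit-planes packed into 64-bit words,
so transmitting a gamete is a handful of masked word operations with one
random mask per word, and fitness reduces to popcounts over the
selected-locus mask.  The kernel uses its own xoshiro256++ generator
seeded via splitmix64: runs are bit-identical for a given (config, seed)
regardless of numpy/numba internals.  A full default run (152 demes x
100 individuals, 700 loci, 4,000 generations) takes tens of seconds,
which is what lets the test suite and the acceptance script re-derive
the null from scratch at full scale.

Calibration checks: single-deme neutral runs match the Wright-Fisher
drift variance `p0 q0 (1 - (1 - 1/2N)^t)`; the median selected-locus
cline center sits at the 85 m habitat boundary within +-3 m; widths of
the mean selected-locus cline decrease monotonically in `s_total`
(measured by an independent least-squares sigmoid fit).

## Sampling simulated transects

The final generation is sampled like the field study: each individual
gets a continuous position uniform within its deme, and 373 individuals
are drawn without replacement with probability proportional to a
piecewise density profile -- two intentional sampling gaps (25-35 m and
115-125 m) and a density trough (weight 0.25 on 88-94 m) mimicking the
gap in the snail distribution near the average cline center.  Read
depths are negative binomial (mean 20, dispersion 5; constants chosen
as typical of targeted capture data) and reference reads binomial with
the same `mu_g` error model the likelihood assumes.

## Neutrality classification

The null distribution is the var.ex of *clinal* neutral loci from the
simulation, analyzed with exactly the same fitting code as observed
data; the threshold is its empirical 0.99 quantile
(linear-interpolation definition, recorded in the output).  SNPs are
non_clinal, clinal_neutral, or non_neutral (clinal AND var.ex strictly
above the threshold).  The sensitivity sweep re-derives the threshold
for `sigma in {1.09, 1.70}`, `N in {50, 200}` and the secondary-contact
model; thresholds order as drift/dispersal intuition predicts (smaller N
or smaller sigma -> stronger neutral structure -> larger threshold).

## Differentiation and dispersal from LD

Per-SNP end differentiation uses ML genotype calls within the outermost
30 m on each side: `|delta p|` plus Hudson's two-population Fst estimator
(negative estimates truncated at 0).  Gametic D between SNP pairs is the
standard two-locus EM composite estimator on unphased dosages.

Dispersal is estimated from the cline-theory relation
`D ~ sigma^2 dp1 dp2 / (r w1 w2)` solved for sigma, with `r = 0.5` for
unlinked pairs and the median taken across pairs.  Two numerical points
matter.  First, per-locus widths from per-deme frequency profiles are
taken from long-lag central differences of an edge-corrected moving
average; raw adjacent-deme gradients are dominated by binomial sampling
noise (SD ~ sqrt(pq/2N) per deme) and make clines look several-fold
steeper than they are.  Second, D is measured among individuals within a
*narrow* window at the mean center (+-2 m by default) rather than within
one cline width: composite D over a window spanning appreciable
frequency change adds the spatial covariance of allele frequencies
(admixture LD) on top of the within-deme gametic LD the relation refers
to, and inflates sigma several-fold.

A known limitation, demonstrated by the round-trip experiment in
`scripts/acceptance.py`: under the simulated regime of ~200 concordant
selected clines with a strong total barrier (s = 0.7), within-deme D at
the center is elevated ~2-3x above the pairwise weak-LD prediction
(ancestry structure correlates *all* selected loci, not just the
measured pair), and the recovered sigma plateaus around 2-3 m whatever
the true sigma in {1.09, 1.46, 1.70}.  The estimator is therefore
reported as-is and its output should be read as an upper bound in
strong-barrier systems.

## Genomic architecture

SNPs are assigned the (LG, cM) of the nearest mapped SNP on the same
contig within 1,000 bp.  Clustering of non-neutral SNPs is tested by
permuting labels across all mapped SNPs: per-unit one-sided enrichment
of the non-neutral proportion at the linkage-group, map-position and
10-cM-window scales (windows anchored per LG), with add-one p-values
`(1 + #perm >= obs)/(1 + n_perm)` and Benjamini-Hochberg adjustment
across units; the within-contig scale tests, per bp-distance class, the
fraction of same-contig pairs in which both members are non-neutral
among pairs containing at least one.  Exhaustively enumerable cases
match the exact tail probability.

LD is the absolute Pearson correlation of genotype dosages (composite
LD), computed over all individuals or one cline-end group; decay
profiles are binned means per cM distance.

nnBlocks are detected by seed-and-extend: 5-cM windows (anchored at each
LG's first map position, making detection invariant to cM translation)
qualify when their non-neutral proportion is at least 5x the genome-wide
proportion and they hold >= 3 SNPs; qualifying windows merge, bridging
one non-qualifying window.  When dosages are available the candidate's
non-neutral members are then refined by LD coherence: members whose mean
|r| with the rest falls below 0.3 in both end groups are trimmed
(isolated false positives must not set boundaries), nearby non-neutral
SNPs within two windows that are in LD with the block are absorbed
(their window may have missed the enrichment cutoff by chance), and the
block is kept only if its members' mean |r| reaches 0.3 in at least one
end group.  Boundaries are the outermost surviving non-neutral map
positions.

## Synthetic study-like data

The generator emits every pipeline input with known truth: 600
individuals along a wiggly 11-segment path of 152 m (sampling gaps and
density trough as above), 373 genotyped; phenotypes from trait clines
plus noise; a 17-LG map with exact total length 1011.9 cM at 0.2 cM
resolution; 1,000 SNPs with 2% selected.  Neutral SNP frequencies follow
smoothed random-walk curves along the transect (autocorrelation scale
20 m, excursion SD 0.1) -- a cheap stand-in for isolation-by-distance
clines, which the forward simulator produces mechanistically.  Selected
SNPs are steep sigmoids (centers ~N(91.8, 2) m, widths 6-18 m); 75% of
them sit in three planted blocks (LGs 6, 14, 17; 14-25.5 cM long) and
are generated from a shared latent karyotype dosage per block with 95%
concordance, producing the correlated-dosage, concordant-steep-cline
signature of an inversion without simulating one.  Block members tile
the whole span (inversion-wide LD reaches the breakpoints), and
non-block selected SNPs are placed clear of the blocks (+-5 cM) so their
labels are consistent with their positions.  What passing tests on this
fixture do *not* show: robustness to the mechanistic spatial
autocorrelation, linked selection, or depth heterogeneity of real
capture data -- that is what the forward-simulated null is for.

## Problem sizes and reproducibility

The test suite and `scripts/acceptance.py` re-derive the default-scenario
null at full scale (4,000 generations, 500 neutral loci, 373 sampled
individuals); the sensitivity sweep uses 250 neutral loci per scenario;
parameter recovery uses 100 replicates; the dispersal round trip uses 10
replicate 1,000-generation runs (the selected-cline quasi-equilibrium is
reached well before that).  Every stochastic stage derives its seed from
the global seed and the stage name (SHA-256, below 2^31), so stages are
independently re-runnable and full runs are reproducible.

## Known limitations

* The polyline fit is a local optimum; pathological point clouds can
  need more segments or a better initialization.
* Cline width is weakly identified from read depths at moderate depth:
  at depth 30 with 373 individuals the ML width of a 10 m cline has an
  interquartile range of roughly 7-13 m even though the center is
  recovered to +-2 m.  Width-based downstream quantities inherit this
  noise.
* The LD-based dispersal estimator is biased upward and insensitive to
  the true sigma in strong-multilocus-barrier regimes (see above).
* The neutral null depends on unpublished details of the original
  simulation design (read-depth model, exact mating scheme, var.ex
  definition); the defaults here are stated explicitly so the derived
  thresholds are reproducible, but they are not guaranteed to coincide
  with the published threshold values.
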