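# Methods

This note documents the models, defaults and numerical choices behind
chromdyn, and what the synthetic-data experiments do and do not
demonstrate about real data.

## Gaussian-process dynamics test

Each feature's profile is a matrix of counts over replicates × time
points, sampled at 0, 20, 60, 120, 240 and 1440 minutes. Counts are
scaled to counts-per-million per sample (so whole-table rescaling cannot
change any call), transformed with log2(x + 1), and mean-centred per
profile. Time is mapped to log2(1 + minutes), which de-compresses the
4 h → 24 h gap; raw hours are available as an option.

Two zero-mean GP regressions are fitted to the stacked replicate
observations (n = replicates × time points; replicate averaging is
deliberately reserved for the correlation stage):

* dynamic: K = σ_f²·RBF(ℓ) + σ_n²·I, three hyperparameters;
* static: K = σ_n²·I, whose maximum-likelihood solution is closed form
  (σ̂² = mean of squared centred values).

The dynamic marginal likelihood is maximised by L-BFGS-B on
log-hyperparameters with six starts: two data-driven, one at the
"signal off" boundary seeded with the static solution, and three seeded
log-uniform draws. Bounds: noise variance 1e-4…1e4, lengthscale
0.1–10 × the time-axis span, signal variance 1e-12…1e4. The tiny signal
floor plus the boundary start guarantee the nesting property
LML_dynamic ≥ LML_static − 1e-6 on every input; with a 1e-4 floor that
property provably fails on near-constant profiles. A dense 20³
grid-search oracle is used in the tests to confirm the optimizer never
trails a brute-force search.

Model selection reports both rules: BIC = k ln n − 2 ln L̂ with k = 3 vs 1
(no mean parameter — data are pre-centred), and LR = 2(ln L̂_RBF −
ln L̂_static), clipped at zero, referred to χ²(1) at α = 0.05. The LR is a
boundary-null statistic (σ_f² = 0 sits on the parameter boundary and ℓ is
unidentified there), so the χ²(1) reference is conservative: on static
synthetic profiles the empirical false-positive rate is about 0.01–0.03
with two replicates and below 0.01 with three, because replicate pairs
observed at the same time point carry strong evidence against a shared
latent signal. No multiple-testing correction is applied across features;
the raw p < 0.05 rule is the documented behaviour.

## Temporal archetype clustering

Dynamic peaks are pre-filtered by the inclusive rule LR > 1 (more
inclusive than the χ² cut) and by exclusion of promoter-proximal
intervals; the promoter window is strand-aware, [TSS − 1000, TSS + 500]
on the gene's strand. Unknown strands are an error because the window
cannot be oriented.

Clustering uses a mixture of K Gaussian-process mean trajectories: each
cluster has a latent mean with an RBF prior (amplitude 1, lengthscale
0.3 × the time-axis span by default) and observations are
replicate-averaged normalised profiles with i.i.d. Gaussian noise. EM on
the penalised likelihood alternates responsibilities, mixing weights,
GP-posterior cluster means and a closed-form noise update; every step is
an exact coordinate maximisation, so the objective is non-decreasing (the
tests assert this from the iteration trace). Initialisation is k-means on
the profile vectors with a fixed seed; argmax assignment ties break to
the lowest cluster index. K defaults to 6, matching the number of broad
temporal patterns the stimulation response exhibits, but is a free
parameter; no automatic K selection is attempted.

## Linking accessibility, interactions and expression

Retention rules follow the printed inequalities: interactions need a
score strictly greater than 5 at one or more time points; genes need a
total of at least 10 counts in **every** replicate; bait-to-bait
interactions are registered twice with the roles swapped. Links join a
peak lying wholly inside an otherEnd fragment to every bait fragment that
otherEnd contacts, expanding to one link per gene on the bait (multi-gene
baits therefore multiply links; downstream prioritisation is per-gene).
Distance is measured midpoint-to-midpoint of the two fragments
(TSS-to-midpoint is available), stratified half-open into < 200 kb,
200–500 kb, 500 kb–1 Mb and 1–5 Mb; links at 5 Mb or more are dropped.

Correlations are Pearson coefficients of the normalised,
replicate-averaged six-point series. A zero-variance series makes the
coefficient undefined; such links are flagged and excluded from
enrichment rather than imputed. The background draws uniformly random
(peak, interaction, gene) triplets with no genomic restriction —
n_draws = max(10,000, observed links) by default — and each stratum is
compared with the null by a two-sided Wilcoxon rank-sum test. Whether the
published comparison was paired is not determinable; the unpaired
rank-sum is the documented choice. Fold changes across time are
log2((max + 1)/(min + 1)) on the count scale; a last-versus-first variant
exists behind an option.

## Fine-mapping

The Wakefield approximate Bayes factor uses prior effect variance
ω = 0.04 and V = se². All arithmetic runs in log space: at GWAS-scale
|z| the exponent exceeds double range, so posteriors are softmax of log
ABFs and only the reported ABF column may print as inf. Ranking ties
break by genomic position then rsid. The credible level defaults to 0.99
but is a parameter (bait-design work sometimes uses 0.95). The cumulative
rule uses a 1e-9 slack so exact posterior ties (e.g. 100 identical SNPs
at 0.01 each) attain the level at the intended rank.

## Prioritisation and compartments

LD expansion keeps SNPs with r² ≥ 0.8 to the lead (the ≥ convention;
configurable). SNP-in-peak overlap is half-open: a SNP at the start
coordinate is inside, at the end coordinate outside. Gene assignment
demands all three pairwise correlations of the link reach the threshold
(0.5 by default), signed; an absolute-value mode exists for users who
want anti-correlated regulation counted. Compartment membership labels
each SNP A or B per time point and classifies consistent-A,
consistent-B, switching, or unassigned. Reported percentages round half
away from zero to the printed precision (so 10.528% prints as 11%), and
genes-per-peak is distinct genes over distinct peaks at one decimal.

## Structure metrics

TAD/compartment consistency is the fraction of intervals in track A with
a 90% reciprocal-overlap partner in track B — asymmetric by construction
(the denominator is |A|) and documented as such. Compartment eigen-score
signs are arbitrary per sample, so each sample is oriented to correlate
non-negatively with the first before the r-versus-|Δt| line is fitted by
ordinary least squares. The SCC is the stratum-weighted Pearson
correlation over off-diagonal distances with weights N_d·sd_a,d·sd_b,d;
the 2D mean-filter smoothing of the original formulation is deliberately
omitted (no smoothing parameters are published for this setting), so
outputs are labelled "simplified SCC". Zero-variance strata are skipped.

## Synthetic-data generator

The generator emulates the *structure* of the study inputs, not their
biology: a single chromosome tiled by a homogeneous random
restriction-fragment partition (HindIII geometry is not modelled), genes
on distinct bait fragments, peaks inside non-bait fragments, each
peak-hosting fragment contacting one to three nearby baits within 5 Mb,
per-time TAD tracks with jittered ~1 Mb boundaries, drifting A/B
eigen-scores per 100 kb bin at the five structure time points (0, 20, 60,
240, 1440 min), and a SNP panel with exponential-decay LD (an
Ornstein-Uhlenbeck correlation squared elementwise, hence positive
semi-definite by construction).

Counts are negative binomial (dispersion size 10 by default, i.e. ~10%
extra-Poisson variance at high means) around an exponentiated latent
mean of ~100 counts; dynamic features draw the latent log2 trajectory
from an RBF GP on the transformed time axis and static features are
flat. Replicates are conditionally independent given the latent mean. A
configurable fraction of dynamic peaks shares its trajectory (plus 10%
jitter) with one interaction and that interaction's gene, planting true
correlated links; these concentrate at short range because interactions
prefer nearby baits, mirroring the short-range enrichment seen in real
activation data.

For detection experiments, "signal-to-noise ratio" is defined on the
realized signal: `amplitude_for_snr` solves for the GP amplitude whose
expected trajectory variance *across the sampled grid* (prior amplitude
× (1 − mean RBF correlation between grid points)) is the target multiple
of the delta-method log2-scale count noise at the baseline mean. Defining
SNR on the prior amplitude instead would overstate the nominal ratio by
~2.3× on this grid, because correlations between the six sampled points
absorb most of the prior variance.

GWAS loci place one causal variant with fixed effect (default β = 0.25,
se = 0.05) among 50 SNPs; non-causal means attenuate as r²·β and the
sampling noise is N(0, se²) **correlated according to the signed allelic
correlation r**, the standard behaviour of summary statistics estimated
from a single cohort. With independent noise, near-perfect proxies
out-jump the causal variant independently and credible-set coverage
collapses; LD-correlated noise restores the nominal behaviour.

What passing these experiments shows — and does not show — about real
data: the pipeline's rules, statistics and numerics behave as specified
under a generative model whose noise is i.i.d. NB given a smooth latent
trajectory. Real ATAC/CHi-C/RNA counts have batch structure, GC and
mappability biases, correlated replicates and non-stationary dynamics
that the generator omits; headline counts from the deposited data (tens
of thousands of links, thousands of credible SNPs) are not reproducible
at this scale and are only re-derived arithmetically from their printed
numerators and denominators.

## Problem sizes

Default experiment scales were chosen to keep any single check under a
minute on one core: 1000 static and 500 dynamic profiles for
calibration/power, 50 profiles against a 20³ grid oracle, 200 loci of 50
SNPs for coverage, 600 profiles for six-archetype recovery, ~650 links
for enrichment, 200×200 matrices for the SCC null.

## Known limitations

* The LR reference distribution is asymptotic and boundary-conservative;
  empirical type-I error sits below the nominal α/2 (see above), so the
  χ² rule errs toward missing weak dynamics rather than inventing them.
* CPM normalisation introduces small shared per-sample offsets; with few
  features these correlate calls across features within a run.
* The GP mixture uses a penalised-likelihood EM (cluster means as MAP
  trajectories), not a fully Bayesian mixture; responsibilities are
  conditionally independent across profiles.
* Fine-mapping assumes a single causal variant per locus and no
  LD-aware conditioning.
* The simplified SCC omits smoothing and is not numerically comparable
  to smoothed implementations, although its identity, symmetry and null
  behaviour match.
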