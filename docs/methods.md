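# Methods

## The mapping problem

In bulk segregant analysis (BSA), haploid F2 segregants from a cross between
two divergent parents (here called Oak and Wine) are pooled before and after
selection and sequenced as pools; loci whose allele frequency diverges
between selected and unselected pools affect the selected trait. Standard
two-bulk BSA averages each locus's effect over all genotypes at other loci,
so it cannot see epistasis. This package analyzes the four-bulk variant in
which one chromosome is fixed for a single parent in every segregant and the
experiment is done reciprocally in both fixed-chromosome "backgrounds":
loci whose selection response differs between backgrounds interact
epistatically with the fixed chromosome, and those interactions are
estimated with the same pooled-sequencing power as additive effects.

## Statistical model

At each smoothed position the Wine-allele odds are modeled by a binomial
GLM with a logit link:

    log(odds_Wine) = β0 + β1·selection + β2·background + β3·(selection × background)

with contrasts selection ∈ {0 = no stress, 1 = stress} and background
∈ {−0.5 = Wine, +0.5 = Oak}. β1 is the additive (selection) effect, β2 the
background main effect (expected ≈ 0 absent segregation or growth effects
of the fixed chromosome), and β3 the selection-by-background interaction —
epistasis with the fixed chromosome. Effects are summarized by z = β/se
with standard errors from the Fisher information at the MLE; the smoothed
(generally non-integer) read counts act as binomial weights with the
dispersion fixed at 1, which reproduces ordinary logistic-regression
z-scores.

Two implementation facts are worth recording. First, the four-cell design
with four coefficients is saturated, so the MLE has a closed form: fitted
cell probabilities equal the count-weighted empirical Wine fractions,
β = X⁻¹·logit(p_cell), and Cov(β) = X⁻¹W⁻¹X⁻ᵀ with W the binomial weights.
The scan is therefore vectorized over all positions at once; the test suite
checks it position-by-position against an independent IRLS fit
(statsmodels GLM). Second, replicates are pooled within each cell inside
the fit; by binomial sufficiency this equals treating each replicate as its
own observation, for both the estimates and the standard errors.
Separation or an empty cell (a zero-depth region) marks the position
non-converged; its z-scores are missing and it is excluded from peak
calling, with counts reported in the run manifest.

## Smoothing

Read counts are smoothed per (selection, background, replicate, chromosome,
allele) with a Gaussian-weighted rolling mean over windows of 200 SNPs in
SNP-index space. Windows never span chromosomes; at chromosome ends the
kernel is truncated and renormalized (no padding or reflection, which would
invent counts beyond the chromosome). The kernel standard deviation
defaults to window/6 (≈33 SNPs at the default window) so that ±3σ spans the
window and the weights effectively vanish at its edges; both window and σ
are configurable for sensitivity checks.

## Permutation null and FDR thresholds

The null distribution of each effect's z-scores is built exclusively from
unselected bulks, on the assumption that without selection no locus is
associated with the trait. Per permutation, the position labels of
(oak, wine) smoothed-count pairs are shuffled independently within each
(background, replicate) unselected series; the shuffled series are assigned
at random to pseudo-bulk slots replicating the original design (same
replicate counts per cell, with fresh shuffles filling the pseudo-selected
slots); the genome scan is rerun; and absolute z-scores are pooled per
effect. The fixed chromosomes are excluded before shuffling, as are any
chromosomes carrying engineered regions that do not segregate neutrally
(defaults I, VIII, III, V for the copper-resistance experiments).

The threshold at level α (default 0.05) is the empirical exceedance-ratio
construction standard in genome scans: the smallest observed |z| value t
such that

    (mean per-permutation count of null |z| ≥ t) / (observed count of |z| ≥ t) ≤ α,

or +∞ (no discoveries) when unattainable. A simpler (1 − α) null-quantile
rule is available behind `method="null_quantile"`. The default permutation
count is 1000; the desk-scale simulations in the tests and the acceptance
script use 100, which is ample for the 5% pooled-tail estimate at ~4,200
null positions per permutation.

## Peak calling

Within each chromosome the local slope of the |z| trace is estimated by
OLS in a centered sliding window of 700 SNPs (truncated at ends). Segment
boundaries sit at chromosome ends and at local minima — indices where the
slope changes strictly from negative (at the previous position) to
positive; exact-zero plateaus do not split segments, so flat noise is not
fragmented. The maximum |z| per segment (leftmost on ties) is called a
peak when it clears the effect's threshold, with the signed z reported.
All segment maxima above threshold are reported, ranked per chromosome by
|z|, so secondary "shoulder" peaks are retained; `top_k` can restrict
this. Peaks from two experiments are colocalized by greedy
nearest-neighbor matching per chromosome with a 1.5-kb tolerance.

## Sign vs magnitude epistasis

At each interaction peak the replicate-averaged Wine-allele frequency is
taken in the four cells. The within-background selection shifts
ΔAF_bg = AF(selected) − AF(unselected) decide the call: strictly opposite
signs (the selected allele-frequency lines cross between backgrounds) mean
sign epistasis; otherwise magnitude. A zero shift in one background is not
a reversal and classifies as magnitude — the conservative reading, since
sign epistasis requires a direction change. The call is supplemented by a
dominance scan (significant positions where |z_interaction| >
|z_selection|, which would indicate the interaction obscures the additive
effect) and by the bp distance to the nearest same-chromosome additive
peak with a 6-kb colocalization flag. Point estimates, not replicate
error bars, drive the crossing test; replicate-level frequencies are
reported alongside.

## Forward simulator

The simulator regenerates the entire experiment with known truth:

- **Genome.** 16 chromosomes of 60 kb with a SNP every 200 bp (grid mode;
  a binomial "uniform" mode is available) — the parents' ~1-in-200-bp
  divergence at desk scale — and 1 Morgan of genetic length per
  chromosome, linearly mapped to bp.
- **Meiosis.** Haldane model (no crossover interference): per segregant
  and chromosome, a Poisson(Morgan-length) crossover count with uniform
  breakpoints and a fair starting phase. The fixed chromosome is uniformly
  one parent's. Realized crossover counts are exposed for verification;
  two markers d Morgans apart recombine at (1 − e^(−2d))/2.
- **Selection.** Survival probability per segregant is
  link(μ + Σa_i·g_i + Σγ_j·b·g_j) with g the Wine-allele indicator and
  b = ±0.5 the background contrast, so a planted γ is exactly what the
  scan's interaction term estimates. The link is logistic by default.
  Survival is an independent Bernoulli draw per segregant — equivalent to
  a liability-threshold model with logistic noise.
- **Dose calibration.** The baseline μ is solved per background so the
  expected survival hits a 5% target (the experimental 1–10% design
  range), mirroring the per-cross stress-dose determination; planted
  effects therefore never push survival out of range.
- **Bulks.** Selected replicate bulks are independent survivor draws. Each
  unselected replicate is by default an independent random subsample of
  the pool matched in size to its paired selected bulk. This reflects the
  design — unselected cultures are deliberately seeded/grown to cell
  numbers comparable to the selected ones — and it is statistically
  load-bearing at desk scale: with ~500 survivors out of 10,000, the
  selected bulks carry sampling ("drift") noise far above sequencing
  noise, and a permutation null built from drift-free full-population
  unselected bulks would be anticonservative (in measurements, every null
  experiment produced spurious interaction calls; with drift-matched
  subsamples the null-experiment call rate is ≈ α). A "full" mode retains
  the whole pool.
- **Sequencing.** Per SNP and bulk replicate, total reads ~ Poisson(70)
  and Wine reads ~ Binomial(total, frequency); a constant-depth mode
  supports analytic checks.

Canonical planted architectures (used by the tests and the acceptance
script): one additive QTL with a = 2 on the survival logit; a magnitude
architecture with a = 1.5 and γ = 1.5 (selection slopes 2.25 and 0.75 —
same direction, different size); a sign architecture with a = 0 and γ = 3
(slopes ±1.5); and a power-gain pair with a major QTL (a = 3) on the
fixable chromosome plus a secondary QTL (a = 1).

### What the simulator does not emulate

Mapping error, repetitive-region artifacts and copy-number variation
(excluded upstream of the real pipeline), growth competition within bulks,
crossover interference, and chromosome-specific genetic maps. Desk-scale
sizes (300 SNPs/chromosome, 10⁴ segregants) are far below the real
experiment's marker density and bulk sizes, so passing tests demonstrate
the pipeline's correctness and calibration under the modeled noise
sources, not field performance on real libraries.

### A note on the power-gain scenario

Under the logistic link at low survival, survival odds are multiplicative
across loci, so the post-selection allele-frequency shift at one QTL is
independent of whether another QTL segregates: fixing a major-effect
chromosome then provably does not increase power at secondary loci (and
measurements confirm no gain). The classical "removing a major source of
variance sharpens selection at other loci" phenomenon requires a
thinner-tailed liability; the power-gain scenario therefore uses the
`liability="probit"` option (Gaussian liability, i.e. truncation
selection), under which the gain is real and consistent (~10% higher mean
|z| at the secondary QTL in the acceptance run). The logit link remains
the default everywhere else.

## Numerical choices and degenerate inputs

- Even smoothing windows are widened to the next odd value (warned) so the
  kernel has a center; chromosomes shorter than the window use a
  full-chromosome truncated kernel.
- Zero-depth positions flow through smoothing (neighbors fill in); a cell
  that is all-zero at a position flags the fit non-converged rather than
  crashing or propagating NaN silently.
- Peak ties break to the leftmost position; segment boundaries sit at the
  first position with positive slope (deterministic and order-free).
- All randomness flows through `numpy.random.Generator` seeded from the
  run configuration; identical config + seed reproduces every output byte.

## Desk-scale problem sizes

The acceptance script and heavy tests use 50 null experiments, 20
additive-recovery runs, 5 runs per epistasis architecture and 8 runs per
power-gain arm, each a full experiment at the sizes above with a
100-permutation null — chosen to give stable fractions at desk scale.
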