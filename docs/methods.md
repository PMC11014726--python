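# Methods

This note documents the models implemented in `teselect`, the reasoning
behind the main design choices, and what the synthetic experiments do and
do not establish.

## The age-adjusted site frequency spectrum

A classical folded SFS confounds purifying selection with changes in the
mutation supply: transposable elements (TEs) transpose in bursts, so an
excess of rare TE insertions can mean either selection against insertions
or simply a recent burst of activity.  The age-adjusted SFS removes this
confound by conditioning on allele age.  Given a focal set of variants
(TE insertion/absence polymorphisms) and a neutral reference set
(synonymous SNPs), each carrying a derived-allele frequency and an age in
generations:

1. focal sites are sorted by age and split into `B` bins containing equal
   numbers of sites (default `B = 5`; the first `n mod B` bins take the
   extra site);
2. neutral sites are randomly down-sampled, without replacement, to match
   the focal sites' number *and age distribution*;
3. per bin, **Δ frequency = mean(focal frequency) − mean(matched neutral
   frequency)**;
4. steps 2–3 are repeated `R = 100` times to quantify the down-sampling
   uncertainty of each bin's Δ.

Under neutral evolution of the focal class, focal and matched neutral
sites are exchangeable at every age, so Δ ≈ 0 in every bin regardless of
the age distribution — this is what makes the statistic robust to
transposition-rate changes and demography, both of which distort the age
distribution identically for the comparison because the matching absorbs
them.  Under purifying selection, focal alleles accumulate more slowly
than neutral alleles of the same age and Δ turns increasingly negative
with age; the oldest bin carries the strongest signal because only there
have selection and drift had time to separate the classes.

**Matching granularity.**  Matching only the per-bin counts over the
bins' age ranges is not sufficient: allele frequency rises with age
*within* a bin, so if the focal age density changes sharply inside a
bin's range (e.g. at the edge of an activity burst) a bin-level match is
biased even under neutrality.  The model therefore matches within fine
equal-count strata (about `match_stratum_size = 10` focal sites each)
nested inside the reporting bins.  When a stratum's neutral pool is too
small the shortfall is borrowed from the nearest-aged unused neutral
sites, and a warning summarises the borrowing per fit.

**Tests on Δ.**  The R resampled estimates measure only down-sampling
noise, not the sampling noise of the focal bin mean, and treating them as
independent observations (e.g. a signed-rank test of the R estimates
against zero) is badly anti-conservative: in our neutral simulations the
familywise false-positive rate of that construction approaches one.
`test_delta_below_zero` therefore offers three methods:

- `"normal"` (default): the mean Δ is referred to a normal null with
  **twice** the resampling variance.  Under the null the focal bin mean
  and one matched neutral mean are exchangeable draws from the same
  age-conditional distribution, so Var(Δ) ≈ 2 × the matched-resampling
  variance.  Empirically calibrated (slightly conservative) and able to
  reject at Bonferroni-corrected α = 0.01 with R = 100.
- `"quantile"`: p = (#{Δ ≥ 0} + 1)/(R + 1); assumption-free but
  granularity-limited (p ≥ 1/101 at R = 100).
- `"wilcoxon"`: the literal signed-rank construction, retained for
  comparability; do not use it for inference.

The oldest-vs-others comparison (`test_oldest_vs_others`) is a one-sided
rank-sum of the oldest bin's Δ estimates against each other bin,
Bonferroni-corrected over the `B − 1` comparisons.  In the simulation
screen the estimates entering this test are **per-replicate mean Δs**, so
the unit of variation is the simulation ensemble (20 independent
replicates), not the resampling noise; this is what "running each cell 20
times to assess the variation" demands, and it is approximately
calibrated under exchangeability.  Pooling all resampling estimates
instead (available as `screen_unit="pooled_estimates"`) is far more
powerful but anti-conservative for the same reason as the signed-rank
variant.

## Forward Wright–Fisher simulator

`teselect.wf` simulates a diploid population of size `N` with partial
self-fertilisation: each offspring derives from one fitness-weighted
parent by selfing with probability σ, otherwise from two fitness-weighted
parents by random outcrossing.  Two mutation streams enter each
generation (Poisson, rate 2·N·U per stream): *neutral markers* (the
synonymous-SNP stand-in) and *focal* mutations, of which a fraction `r`
is neutral and the rest carry selection coefficient `s = S/Ne` with
genotype fitnesses 1, 1 + h·s, 1 + s (codominance, h = 0.5, matching the
expectation that dominance matters little when selfing keeps most loci
homozygous).  Every mutation records its origin generation; at the
sampling generation `sample_size` diploids are drawn without replacement
and segregating mutations are reported with sample frequency and true
age.

**Per-locus engine.**  The simulated regime is deliberately the
high-recombination limit ("a high recombination rate … to minimize the
effects of linked selection"): population-scaled recombination across the
fragment is ≫ 1 and fitness is multiplicative across loci.  In that limit
loci evolve as exchangeable single-locus processes, so the engine applies
the exact marginal genotype-count recursion per mutation — state
(n_hom, n_het), fitness-weighted selfing/outcrossing mixture, two
binomial draws per generation — independently across mutations.  This is
what makes a 700-run acceptance grid tractable on one CPU.  The per-bp
recombination rate is carried in the configuration (and transformed by
`rescale_config`) as metadata; positions are assigned to sampled
mutations at reporting time, uniformly without collision, since they do
not enter the dynamics.  Identity disequilibrium and linked-selection
interference are therefore absent; consequences are listed under
*Limitations*.

**Sampling tiers.**  Binomial updates use exact inversion when n·p < 12,
numpy's exact sampler in intermediate regimes, and a continuity-corrected
normal approximation (matched mean and variance, clamped) when
n·p·(1−p) > 36.  The approximation only touches common alleles, where the
CDF error is far below drift noise.

**Validation.**  The acceptance suite recomputes three closed-form
oracles: the equilibrium inbreeding coefficient F = σ/(2−σ) at σ = 0.7,
the neutral fixation probability 1/(2N) over ≥ 10⁴ introduced mutations,
and the Kimura–Ohta mean age of neutral alleles at frequency x,
t̄(x) = −4·Ne·x·ln(x)/(1−x) (with Ne the census size at σ = 0).  The
selfing-adjusted effective size used elsewhere is Ne = N(2−σ)/2.

**Desk-scale default configuration.**  N = 1,000 diploids, L = 100 kb —
a λ = 10 rescaling of an N = 10,000 / 1 Mb population (rescaling
preserves S = Ne·s, θ = 4·N·U and the population-scaled recombination
rate; `rescale_config` implements the transformation with a guard at
N/λ < 50).  Selfing rate 0.7; h = 0.5; 20 replicates per scenario;
sample of 50 diploids; run length 10·N generations of mutation influx
(≈ 3.8 × the coalescent timescale 4·Ne under selfing), after which the
sampled age distribution is effectively stationary.  The mutation-stream
rates are not published for the original runs; we set
U_focal = 0.018 and U_neutral = 0.020 per gamete over the fragment so
that the *analysis-facing* quantities mirror the real-data analysis: a
pooled focal set of ~600–3,000 segregating sites per scenario across the
S grid (cf. 1,035–2,106 retrotransposons per clade) and a neutral pool of
~5,000–6,000 (cf. 10,000 matched SNPs).  The scaled-selection grid is
S ∈ {−5, −8, −10, −12, −15, −20, −50} and the neutral-ratio grid
r ∈ {0, 5, 10, 25, 50}%; S = −1 is treated as effectively neutral and
excluded from the r* majority vote (configurable).  `Ne` in `s = S/Ne`
is the census N by default (`ne_for_s="selfing_adjusted"` uses
N(2−σ)/2), matching how scaled coefficients are normally set in
forward-simulation scripts.

## Selection inference

**Neutral-ratio screen.**  For every grid cell (r, S), each replicate's
age-adjusted SFS is computed (5 bins, 100 resamples) and the cell is
flagged *reproduced* when the oldest bin's Δ is significantly below every
other bin (rank-sum on per-replicate means, Bonferroni, α = 0.01).  Cells
with fewer than two usable replicates are excluded as not-evaluated.  For
each S the largest r still reproducing the pattern is reported; **r\*** is
the smallest grid r at which the pattern fails for a strict majority of
the S values.  Observed data showing the pattern are then compatible only
with neutral ratios below r*.

**Selection-strength estimation.**  Stronger purifying selection removes
mutations faster, so the oldest surviving focal mutations are younger
under more negative S.  The estimator compares the 25/50/75% age
quantiles of the oldest age bin between observed data and the r = 0 grid
simulations (replicates pooled by default; per-replicate quantile
averaging behind `pooled_ages=False`).  Per quantile, the **relative age
difference** (sim − obs)/max_S|sim − obs| is computed — the normalisation
makes the measure invariant to any common rescaling of ages — and **S\***
is the grid value minimising its magnitude, with the consensus across
quantiles reported as a set when quantiles disagree.

## Synthetic data generator

Parametric mode draws sample allele counts from the expected frequency
spectrum (1/k for neutral sites; Wright's semidominant polymorphism
density with scaled coefficient 2S for selected classes) and ages given
frequency from a Gamma distribution (shape 2) around the Kimura–Ohta mean
t̄(x) for every class.  Selection enters through the spectrum tilt alone:
concentrating selected sites at low frequencies lowers their mean
frequency at any given age (negative Δ) and compresses their age
marginal (younger oldest sites as |S| grows).  The conditional age of a
deleterious allele at fixed frequency is in truth somewhat younger than
neutral (Maruyama's result); that refinement is deliberately omitted —
the Δ statistic conditions on age, where the tilt is the leading effect —
and quantitative selected age-frequency structure always comes from the
forward simulator (`dataset_from_simulation`).
Transposition bursts are produced by thinning focal origin times so their
density is multiplied inside burst windows; demographic change is
emulated as a monotone piecewise-linear age warp applied identically to
every class (it distorts the age marginal, which is exactly the nuisance
the statistic claims robustness to, while preserving age-conditional
structure).  Age-estimate error is multiplicative log-normal
(median-unbiased), reflecting the roughly multiplicative error of
IBD-length-based age estimators; its magnitude is a free parameter, not
an empirical claim.  The generator writes the same VCF + age-table +
clade-table formats the real-data reader consumes, with an ancestral
outgroup clade included so polarisation round-trips.

What passing synthetic tests do *not* show about real data: the generator
has no linkage, no population structure within clades, no TE-caller false
positives (false negatives only as an optional per-site drop), and
age-estimator error that is independent across sites, none of which hold
exactly in resequencing data.

## Real-data processing

The reader consumes a combined TE/SNP VCF, joins per-(variant, clade)
age estimates, applies the published cleaning rules (hard filters on QD,
FS, SOR, MQ, MQRankSum, ReadPosRankSum with all-strict inequalities and
missing annotations passing; heterozygous SNP calls set to missing; TE
calls treated as homozygous; multiallelic sites dropped; same-family TIPs
under 100 bp apart merged by single linkage keeping the leftmost
position), polarises against the ancestral outgroup clade (sites with a
polymorphic or missing outgroup are excluded), computes folded spectra
from minor allele frequencies, and classifies distance to the nearest
gene-body edge into ≤ 1 kb (including genic), 1–5 kb and > 5 kb with
left-inclusive boundaries.  The rank-sum annotation filters are
interpreted as symmetric bands (remove when |MQRankSum| > 2.5 or
|ReadPosRankSum| > 2.0).  An optional coverage filter restricts to
samples with mean mapping coverage ≥ 20×.

## Numerical and procedural choices

- B = 5 bins by default (the visual bin count of the published
  age-adjusted spectra), with a warning below 50 focal sites per bin.
- Equal-count binning breaks age ties by stable (age, variant id) order.
- Down-sampling is without replacement within each repetition; the
  borrow fallback is without replacement globally.
- The frequency-matched neutral resample (bias control for TE-specific
  frequency estimation error) is a separate mode, never composed with age
  matching in one analysis — applying both would force Δ toward 0 by
  construction.
- Non-synonymous / high-effect comparison sets larger than 10,000 sites
  per clade should be down-sampled to 10,000, mirroring the original
  analysis.
- All randomness flows from explicit seeds; grid cell and replicate seeds
  are derived deterministically from the master seed via
  `numpy.random.SeedSequence`, so any sub-grid reproduces its cells.
- Degenerate inputs: all-zero Δ estimates give p = 1; an all-equal
  simulated-vs-observed age grid gives relative age differences of 0; an
  empty oldest bin, an unpolarisable site table, or a neutral pool
  smaller than the focal set raise errors.

## Problem sizes

The bundled experiments are desk-scale by design: the full screen runs
5 × 7 × 20 = 700 forward replicates (about ten minutes on one CPU);
type-I control uses 100 generator seeds per scenario; sensitivity uses
three 20-replicate ensembles; parameter recovery uses a 20-replicate
reference grid and ten 2-replicate held-out datasets; the simulator
oracles use reduced populations (N = 100–400) where the closed forms are
sharpest.

## Limitations

- The per-locus engine omits identity disequilibrium between loci under
  selfing and any linked-selection interference; both are second-order in
  the high-recombination design point but real at low recombination.
- No back mutation or excision: like the statistic itself, the simulator
  is built for retrotransposon-like (copy-and-paste) dynamics; DNA
  transposons can be run through the same machinery but no excision
  correction is attempted.
- r* is a grid value, not a continuous estimate, and inherits the screen
  test's finite power: very strong selection with few segregating sites
  (S = −50) can fail the pattern test for lack of data rather than lack
  of signal.
- The parametric generator's selected class captures the spectrum tilt
  but not the age-given-frequency shift of deleterious alleles; use
  simulator output where selected ages matter.
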