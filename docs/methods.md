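# Methods

This note records the models implemented, the defaults and why, the
numerical choices, and what the synthetic data do and do not show about
real data.

## Sequence statistics

Haplotypes are defined by exact string identity over the alignment;
ambiguous symbols (`N`, `-`) stay part of the haplotype but are excluded
pairwise from every distance computation (pairwise deletion). Diversity
uses Nei's unbiased estimators; nucleotide diversity defaults to raw
(Hamming) site differences per bp, with the TN93 model available because
published tables do not always state which convention their software used.

The TN93 distance is computed from the transition proportions P1 (A↔G),
P2 (C↔T) and the transversion proportion Q, with base frequencies taken
empirically from the compared pair unless fixed in the `DistanceModel`.
The gamma-rates correction replaces each −ln e term by α(e^(−1/α) − 1);
the default shape α = 0.023 is the value fitted for the COI marker this
package is designed around. Distances are undefined (a `SaturationError`)
when a log/power argument is non-positive.

Φ_ST and the hierarchical AMOVA decompose sums of squared model distances
(Excoffier's framework). Permutation schemes: individuals between the two
populations for pairwise Φ_ST; whole populations among groups for F_CT;
individuals among populations within groups for F_SC; individuals among
all populations for F_ST. All permutation p-values use the conservative
(b+1)/(m+1) estimator, one-sided on statistic ≥ observed. Negative
variance-component estimates are retained and reported, as is standard.

**Mismatch/expansion.** The sudden-expansion expected curve is
F_i = F̂_i(θ1) + e^(−τ) Σ_j τ^j/j! [F̂_{i−j}(θ0) − F̂_{i−j}(θ1)] with
F̂_i(θ) = θ^i/(1+θ)^(i+1); (τ, θ0, θ1) are fitted by bounded least squares
from a small multistart grid (θ1 parametrized as θ0 + δ, δ ≥ 0, so the
order constraint is structural). Raggedness pads the histogram with a zero
class on *both* sides, R = x_0² + Σ(x_i − x_{i−1})² + x_d²; conventions in
the literature differ and this one is used consistently everywhere,
including the bootstrap. p(SSD) and p(R) come from a parametric bootstrap:
coalescent samples are simulated under the fitted expansion (present size
θ1/2, size θ0/2 before generation τ/2, per-sequence mutation rate 1),
refitted (seeded from the observed fit for speed), and compared one-sided.

**Neutrality tests.** Tajima's D uses the standard a1…e2 constants with
π̂ the mean pairwise difference count. Fu's Fs computes
S′ = P(K ≥ k_obs | θ = π̂) from the Ewens sampling formula via exact
unsigned Stirling numbers (integer recurrence; probabilities assembled in
log space), Fs = ln(S′/(1−S′)), with ±∞ sentinels at the boundaries.
Significance for both comes from coalescent simulation *conditional on n
and S*: Kingman genealogies with S mutations multinomially placed along
branches; p is the lower tail (the direction demographic expansion
pushes). The published workflow used 10,000 simulations; that is the
default, reducible everywhere for testing.

**Haplotype network.** Kruskal MST on Hamming distances with deterministic
tie-breaks by (distance, lower index pair); total weight is invariant to
input order, the edge set under ties is fixed by the ordering rule.

## Microsatellite statistics

He is the unbiased estimator 2n/(2n−1)(1 − Σp²); F_IS = 1 − Ho/He, whose
expectation is ≈0 under random mating precisely because unbiased He
estimates heterozygosity of two copies drawn without replacement. HWE and
linkage tests are permutation tests (gene copies into genotypes; one
locus's genotypes among individuals within populations, G statistic).
Because the underlying statistics are discrete, each test also reports a
randomized tie-smoothed p-value, (g + u(e+1))/(m+1) with u ~ U(0,1), which
is exactly uniform under the null; the plain conservative p is what
inference should use, the smoothed one is for calibration work.

Rarefied allelic richness follows the hypergeometric formula at g gene
copies, default g = 34 (17 diploids), matching the reporting convention of
the study design.

**Null alleles.** The EM estimator fits, per locus and population, a
segregating null allele under HWE with a blank class: apparent
homozygotes are apportioned between true homozygotes and visible/null
heterozygotes, blanks between null homozygotes and technical failures
(probability β). The ENA-corrected θ treats the null as an extra allelic
state: observed visible frequencies are rescaled by (1 − r), a null state
of frequency r with zero observed heterozygosity is appended, and the
Weir–Cockerham components are summed over the augmented allele set; with
r = 0 this reduces exactly to the uncorrected θ. Two distinct degradation
models ship with the generator: `apply_null_alleles` (independent per-copy
amplification failure — the Dempster-style masking model) and
`segregating_nulls` (existing allele lineages relabeled as heritable
nulls — the primer-site-mutation mechanism). Only the latter biases the
uncorrected θ appreciably, so the correction experiments use it; under
per-copy masking the uncorrected estimator is already nearly unbiased and
no correction can systematically improve it.

**Bottleneck test.** Per polymorphic locus, coalescent samples under the
two-phase model (fraction p_SMM = 0.7–0.9 single-step, multi-step geometric
with variance 10–30 mapped to its success probability by
q = (−1+√(1+4σ²))/(2σ²)) are retained when they reproduce the observed
allele count and sample size; θ is pre-calibrated by a short stochastic
search on the expected allele count. He excess across loci is tested by
the one-tailed Wilcoxon signed-rank, exact for ≤ 25 loci.

## Scenario inference (ABC)

Scenarios are rooted split histories (no migration, matching the modeled
introduction histories); msprime implements the splits as complete
backward lineage movements. Priors are independent uniforms: Ne 10⁴–10⁵
(sequences) or 10⁴–2·10⁵ (microsatellites), split times 10–10⁴
generations, sequence rate 10⁻⁸–10⁻⁶/site/gen, microsatellite rate
10⁻⁴–10⁻³/gen; inconsistent event orderings are rejected and redrawn.
Summary statistics: per population, haplotype number and mean pairwise
differences (sequences) or mean allele number and He (microsatellites);
per pair, Φ_ST/θ plus mean between-population differences or Goldstein's
dμ² on mean allele sizes. Undefined pairwise statistics on monomorphic
data are encoded 0 so vectors stay complete. The posterior retains the
closest 1% of standardized simulations by Euclidean distance and fits a
ridge-regularized multinomial logistic regression on
(simulated − observed) statistics with Epanechnikov weights, evaluated at
zero difference; the raw rejection frequencies are always reported
alongside, and are the fallback when the regression is degenerate. The
prior-predictive check uses nearest-neighbour distances so that a point
inside the cloud scores a low quantile and an exact member scores 0.

Published analyses ran 10⁶–4·10⁶ simulations per scenario; the package's
experiments use 10⁴ per scenario, which resolves well-separated scenario
contrasts while keeping a full scenario-recovery study within minutes.
With the full-width Ne and mutation-rate priors a sizable minority of
draws is genuinely uninformative (near-zero polymorphism), which caps
recovery rates near 80% regardless of the inference machinery.

## Larval dispersal

Tracking is 2-D; the stored field stands for the surface mixed layer in
which the larvae drift. Velocities are interpolated bilinearly in space
and linearly in time and integrated with RK4 at a 15-minute default step.
Coast handling is free-slip: a step that would land on a land cell is
retried along each axis separately, otherwise the particle holds position.
An optional horizontal eddy diffusivity adds a Gaussian random walk of
std √(2KΔt) per step for sub-grid turbulence the stored fields cannot
resolve; it defaults to 0 so pure-advection trajectories reproduce
analytic solutions exactly, and the seascape experiment uses K = 50 m²/s.
Each particle carries an independent uniform pelagic larval duration
(default 20–30 days) and is scored at exactly release + PLD ("end
position", not first contact). The default release design follows the
study conditions: 47,040 particles per locality over 10 habitat cells,
spawning June–August, eight years, with particles cycled evenly over
cells × release times; connectivity is computed per year and averaged.
Localities must be disjoint and no deeper than 100 m. Multi-generation
connectivity is the matrix power (all stepping-stone routes), and
min-symmetrization takes the elementwise minimum of the two directions.

## Seascape correlation

Mantel tests correlate the off-diagonal halves of two labeled symmetric
matrices, permuting one matrix's row/column order jointly, with the +1
correction so p never reaches 0. Defaults are one-tailed in the
hypothesized direction: positive for isolation-by-distance on linearized
differentiation vs distance, negative for differentiation vs minimum
multi-generation connectivity. Connectivity enters raw by default; a
log10 option exists because multi-generation transfer probabilities are
products along routes and span many decades. The end-to-end experiment
(`experiments.connectivity_vs_distance_experiment`) uses the log scale:
linearized Φ_ST is roughly hyperbolic in migration, and on the raw scale
that nonlinearity, not the biology, dominates the Pearson correlation.

## What the synthetic data emulate — and what they do not

The generators reproduce the statistical structure the analyses assume:
coalescent genealogies with population splits, TN93+Γ mutation (per-site
gamma multipliers drawn once per simulation, default shape 0.5),
geometric-step GSM microsatellites (default 80% single steps, reflecting
bounds at ancestral ± 40 repeats), HWE-consistent null-allele masking,
and divergence-free flow fields built from a discrete stream function
(an oscillating double gyre whose circulation reverses over its period,
plus low-wavenumber eddy modes, half of them steady) — so the
centred-difference divergence vanishes identically at interior nodes.
The synthetic shipping-distance matrix is along-coast separation plus
seeded per-locality port detours, mimicking routes that run via the
nearest major port. The end-to-end experiment generates gene flow with an
equilibrium island-type coalescent whose migration rates are proportional
to the simulated minimum connectivity (plus a 10⁻⁶ background so the
metapopulation stays connected); that migration model exists only for
this experiment — the scenario simulators remain migration-free.

Not emulated: recombination, selection, real bathymetry or tides,
vertical larval behaviour, mortality, sequencing error, allele-size
homoplasy constraints beyond the reflecting bounds. Passing tests
demonstrate internal statistical correctness and the qualitative
relationships among the methods, not agreement with any particular
empirical dataset.

## Problem sizes

Default analysis settings follow the published workflow (10,000
permutations/simulations, 1,000 Mantel permutations, 47,040 particles per
locality over eight years). The test suite and the bundled experiments
run the same code at reduced sizes chosen to keep full runs in the
minutes range: hundreds of permutations, 10⁴ ABC simulations per
scenario, hundreds of particles per locality over one compressed year —
each reduction is a sample-size choice, the estimators are unchanged.
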