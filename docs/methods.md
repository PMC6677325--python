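# Methods

## Model overview

`dsdrift` simulates the origin of hybrid incompatibilities between
allopatric lineages whose *organismal* phenotype — a sharp anterior step of
gene expression in a one-dimensional embryo — is held by stabilising
selection while the *molecular* machinery underneath is free to drift
(developmental system drift).

The genotype **G** of one lineage is six binary strings plus one real
number:

| field | length | role |
|---|---|---|
| `g_r`, `g_m` | 10 | DNA-binding faces of polymerase R and morphogen M |
| `g_R`, `g_M` | 5 | protein–protein faces of R and M |
| `g_P`, `g_B` | 10 | promoter and morphogen binding site (cis-region) |
| `alpha` | — | morphogen gradient steepness (> 0, units 1/L) |

Protein–DNA binding energy is `eps_pd` = 2 kT per mismatch between a
protein's DNA face and a site. Protein–protein stabilisation is
`eps_pp` = −1 kT per matching contact between one face and the
*centre-reversed* other face; the reversal encodes the chirality of real
protein interfaces and keeps homodimers from being trivially optimal.
The morphogen profile is the steady state of a reaction–diffusion equation
with reflecting boundaries, `[M](x) = [M0] cosh(alpha (x − L)) / sinh(alpha L)`,
approximately exponential for `alpha·L ≫ 1`.

Expression `T(x)` is the equilibrium probability that R occupies the
promoter, from the 9-state partition function over the occupants (empty, R,
M) of the promoter–B-site pair (a two-site, 3-state Potts construction).
Chemical potentials are `ln` concentration; protein–protein binding off DNA
is ignored in the partition sum (it is weak relative to DNA binding).

Patterning quality is the anterior-minus-posterior contrast

    W = (∫₀^{L/2} T − ∫_{L/2}^{L} T) / ((L/2) · max T) ∈ [−1, 1],

and log fitness is `F = kappa_F ln W`, truncated to −∞ (inviable) whenever
`F ≤ F*` or `W ≤ 0`. With the defaults `kappa_F = 1e-3`, `F* = −1.6e-3`
the viability boundary sits at `W = e^{−1.6} ≈ 0.2019`.

## Evolution

Origin–fixation kinetic Monte Carlo (monomorphic regime,
`ell_G·mu0·N ≪ 1`): at each step all one-step mutants are proposed — one
channel per binary site (50) plus 10 channels carrying independent Gaussian
perturbations of `alpha` (sd 0.5, redrawn every step, proposals driving
`alpha ≤ 0` rejected), so the mutational target is `ell_G = 60` effective
base pairs. Each channel's substitution rate is Kimura's

    k = mu0 · N · (1 − e^{−2 δF}) / (1 − e^{−2N δF}),

evaluated with the stable form `mu0·φ(2δF)/φ(2NδF)`, `φ(u) = (1−e^{−u})/u`
with a series below |u| < 1e-6. The next event and waiting time follow
the Gillespie algorithm (`dt = −ln u / K`). `mu0` defaults to `1/60`, so
one time unit is one expected genome-wide mutation and reported times are
divergence times `mu·t` directly. Experiments are labelled by
`2N·kappa_F`; `kappa_F` stays fixed and `N` varies.

**Equilibration from random genomes.** A uniformly random genome has
essentially no anterior bias (`W ≈ 0`), i.e. it is inviable, yet the
equilibration protocol starts from one. While the lineage is inviable,
rates are therefore computed from the *un-truncated* score
`kappa_F · ln(max(W, 1e-12))`, which gives hill-climbing-with-drift
dynamics toward the viable region; the moment `F > F*` the truncated
fitness takes over and inviable mutants get rate 0, so a viable lineage
never fixes an inviable state. Adaptation typically completes within a few
hundred substitutions (fastest at large `2N·kappa_F`). Ancestors are drawn
from one long run (default 100 000 substitutions; scaled-down experiments
use 10 000–20 000, comfortably past the observed adaptation transient) and
successive draws are separated by 100 substitutions.

With `kappa_F = 0` selection is off and `F ≡ 0` for every genotype
(`N_e` must then be given explicitly); the per-channel substitution rate is
exactly `mu0`.

## Hybrids and divergence

The genome partitions into four fully linked loci — R = (`g_R`,`g_r`),
M = (`g_M`,`g_m`), C = (`g_P`,`g_B`), A = `alpha` — reassorting freely in
hybrids. Two lineages evolve from a common ancestor on independent RNG
streams to the same horizon; the divergence-time axis is the per-lineage
elapsed `mu·t`. The 14 non-parental four-locus combinations are evaluated
after every substitution in either lineage (patterns are exact step
functions of time; no grid error), and a hybrid is incompatible when its
truncated `F` is −∞. Hybrids are recombinant haploid genotypes;
heterozygosity, diploid crosses and within-locus recombination are out of
scope.

## DMI decomposition

A fundamental n-way DMI is an allele assignment over n ∈ {2,3,4} loci, not
all from one parent; its footprint on the Boolean 4-cube of hybrids is a
face (4 hybrids), edge (2) or point (1). There are 50 candidates
(12 / 24 / 14 by order). A pattern is explained by any set of candidates
whose footprints lie inside and jointly exhaust the incompatible set; the
decomposition enumerates **all** covers of minimum cardinality by
branch-and-bound (branch on the lowest uncovered hybrid, iterative
deepening on size; a cover always exists because every incompatible point
is itself a 4-way candidate), averages the per-order counts uniformly over
minimum covers in exact rational arithmetic (so the worked six-hybrid
example yields n2 = 4/3, n3 = 2/3 exactly), and reports the per-type
spectrum (fraction of minimum covers containing each candidate).
Decompositions are memoised over the 2^14 possible patterns. The search is
validated against an exhaustive subset oracle for every pattern with up to
six incompatible hybrids.

Note one non-monotonicity: adding an incompatible hybrid can *decrease* the
minimum cover size (three corners of a face need two DMIs; the fourth
completes the face and one pairwise DMI suffices). The only one-sided bound
is that the size never grows by more than 1.

The random null model flags each hybrid independently with probability p
and decomposes; for small p this is dominated by isolated points, giving
mean n4 > n3 > n2 — the reverse of the evolved patterns, where whole faces
go incompatible and pairwise DMIs dominate.

## Growth-law fits

Replicate-averaged DMI counts I(t) are fitted with two laws:

* power law `I(t) = I0 · t/(T+t) · (1 − exp(−(t/tau)^(gamma−1)))`
  — grows as `t^gamma` for `t ≪ tau, T`, saturates at `I0`;
* sub-diffusion `I(t) = A · erfc(K*/√(4 (mu t)^beta))` — the first-passage
  curve of fractional Brownian hybrid traits a distance `K*` effective
  substitutions from the inviability boundary; `beta = 1` is normal
  diffusion.

Both groupings are reconstructions anchored to their stated limits; the
erfc amplitude A is left free to absorb prefactor ambiguity, and `K*`,
`beta`, `gamma` are the comparable quantities. Fits are weighted nonlinear
least squares on log ordinates (strictly positive points only; relative
weights from the replicate SEM, floored at 2%), multi-started from a
moment-based guess plus seven lognormally jittered copies with a fixed
seed, parameter tolerance 1e-12. Standard errors come from the
Gauss–Newton covariance; failed optimisations return a results object with
`success=False` rather than raising. Model choice uses small-sample
corrected AIC with an explicit "ambiguous" tie band.

## Numerical and design choices

* Embryo discretisation: 100 uniform midpoint cells on [0, 1], midpoint
  quadrature for W; doubling the resolution changes W by < 1e-3 (tested).
* Concentrations are not part of the published parameter set; defaults
  `conc_R = 1` (mu_R = 0) and `conc_M0 = 10` put an intermediate-affinity
  promoter (2–4 mismatches) near half occupancy with cooperative boosting,
  which is the patterning mechanism this map is known to evolve. Both are
  configuration fields; quantitative results that depend on them are
  treated as qualitative.
* `eps_pp` is stored with the stabilising (negative) sign.
* `W ≤ 0` maps to F = −∞ outright (strictly worse than the boundary).
* Ẽ is symmetric in its two species by construction (Hamming distance to a
  reversed string is exchange-symmetric).
* Time increment uses `dt = −ln(u)/K` (positive).
* Exact rationals for decomposition counts; floats only at I/O.
* One root seed expands to per-stage/per-lineage/per-replicate streams via
  `numpy` `SeedSequence.spawn`; artifact headers log the spawned seeds.

## What the simulations do and do not show

The synthetic ensembles are the study conditions themselves (the model *is*
the data-generating process): binary alphabets, a single enhancer with two
sites, one organismal trait, no recombination within loci, no polymorphism.
Passing tests show the implementation reproduces the model's internal
predictions — the drift-load ordering of ancestor fitness, the
population-size ordering of DMI accumulation, quadratic early growth of
total DMIs at weak selection, pairwise dominance against the
high-order-dominated random null — not that real genomes behave this way.

Scaled-down problem sizes used by the test suite (chosen once, as package
defaults for desk-scale verification): equilibration burn-ins of
10 000–20 000 substitutions, 40–120 replicate pairs per condition, horizons
of 30–100 mu·t. The full published-scale protocol (100 000-substitution
burn-ins, long horizons at `2N·kappa_F` up to 100 for the sub-diffusive
regime) runs through the same API and CLI; the quantitative sub-diffusion
table additionally depends on the unpublished concentration/discretisation
choices above and is therefore not asserted by the desk-scale suite.

## Known limitations

* The sub-diffusive regime (`2N·kappa_F ≥ 50`) needs long horizons to leave
  the zero-DMI floor; the desk-scale suite only checks its orderings and
  the fit machinery on synthetic curves.
* SEs of the four-parameter power law are strongly correlated; treat
  per-parameter SEs as approximate (the recovery tests use absolute error
  bands).
* `lru_cache` memoisation of decompositions assumes L = 4 scale; for
  larger L the candidate enumeration grows as 3^L and the cache keys as
  2^(2^L), so the generalised code paths are exercised only for small L.
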