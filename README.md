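# dsdrift

Speciation through developmental system drift: a biophysical
genotype-phenotype map for spatial gene-expression patterning, evolved by
origin-fixation kinetic Monte Carlo under stabilising selection, with exact
decomposition of hybrid incompatibilities into fundamental
Dobzhansky-Muller incompatibilities (DMIs) and fits of their growth laws.

## The problem

Closely related species often conserve a body-plan phenotype while the
molecular wiring underneath diverges cryptically ("developmental system
drift"). When two such allopatric lineages hybridise, alleles that never
co-occurred can be incompatible — a DMI — even though each lineage stayed
perfectly fit. `dsdrift` is for evolutionary geneticists and biophysicists
who want a mechanistic, simulable model of this process: how fast do
incompatibilities accumulate, which molecular interactions break first, and
do pairwise or higher-order incompatibilities dominate?

## The model

One lineage's genome is six binary strings plus a real number
(`ell_G` = 60 effective base pairs): DNA-binding and protein-protein faces
of a polymerase R and a morphogen M, a promoter P and a morphogen site B,
and the morphogen gradient steepness α. Binding energies are Hamming
distances (ε_pd = 2 kT per protein-DNA mismatch; ε_pp = −1 kT per
protein-protein contact against the centre-reversed partner face), the
morphogen profile is [M](x) = [M0]·cosh(α(x−L))/sinh(αL), and expression
T(x) is the promoter-occupancy probability of R from a two-site, 3-state
partition function. The organismal trait

    W = (∫ anterior T − ∫ posterior T) / ((L/2)·max T)

feeds a truncated log fitness F = κ_F ln W, with F = −∞ (inviable) below
F\* = −1.6×10⁻³; at κ_F = 10⁻³ the viability boundary sits at W ≈ 0.202.
Evolution is origin-fixation: all 60 one-step mutants get Kimura rates
k = μ₀N(1−e^(−2δF))/(1−e^(−2NδF)) and a Gillespie clock picks the next
substitution. Two lineages split from an equilibrated common ancestor; the
14 four-locus hybrids between them are re-evaluated after every
substitution, and an incompatibility pattern is decomposed — exactly, by
enumerating *all* minimum covers on the Boolean 4-cube — into fundamental
2-/3-/4-way DMIs (50 candidates: 12/24/14 by order). Replicate-averaged
DMI counts I(t) are fitted with a saturating power law
I₀·t/(T+t)·(1−exp(−(t/τ)^(γ−1))) (drift-dominated regime) or a
sub-diffusive first-passage law A·erfc(K\*/√(4(μt)^β)).

See `docs/methods.md` for assumptions, parameter defaults and numerical
choices.

## Worked example

The package ships the printed six-hybrid incompatibility pattern as a
fixture; its decomposition is the canonical worked example:

```sh
$ dsdrift decompose --pattern fig4b
mu_t=0 incompatible=6 n_total=2 n2=4/3 n3=2/3 n4=0 covers=3
  cover: I_Ra + I_Ca
  cover: I_Ra + I_rCa
  cover: I_Ca + I_Rca
```

Three different pairs of fundamental DMIs explain the pattern; averaging
uniformly over them gives 4/3 pairwise and 2/3 three-way DMIs, total 2 —
the minimum number able to explain the observed hybrid inviabilities.

A small divergence experiment from the library (weak selection,
2Nκ_F = 1):

```python
import numpy as np
from dsdrift import ModelParams, EvoParams
from dsdrift.speciation import replicate_ensemble
from dsdrift.fitting import aggregate
from dsdrift.gpmap import fitness

params = ModelParams()                        # kappa_F = 1e-3, F* = -1.6e-3
evo = EvoParams(two_N_kappa=1.0, rng_seed=0)  # weak selection, N = 500

runs = replicate_ensemble(params, evo, n_replicates=50, t_max=60.0,
                          n_burn=10_000, n_gap=100, seed=0)
F_anc = np.array([fitness(r.ancestor, params) for r in runs])
print(f"mean ancestor log-fitness: {F_anc.mean():.2e} "
      f"(boundary F* = {params.F_star:.1e})")

series = aggregate(runs, grid=np.geomspace(0.5, 60.0, 30))
print(f"at mu*t = 60: I_total = {series.mean['total'][-1]:.2f} "
      f"(n2 = {series.mean['2'][-1]:.2f}, n3 = {series.mean['3'][-1]:.2f}, "
      f"n4 = {series.mean['4'][-1]:.2f})")
```

prints

```
mean ancestor log-fitness: -1.19e-03 (boundary F* = -1.6e-03)
at mu*t = 60: I_total = 2.40 (n2 = 1.74, n3 = 0.53, n4 = 0.13)
```

The drift-dominated ancestors sit close to the inviability boundary
(−1.19×10⁻³ vs F\* = −1.6×10⁻³), so incompatibilities appear after only a
handful of substitutions, and pairwise DMIs dominate the decomposition
(n2 > n3 > n4) — the opposite of the random-pattern null
(`dsdrift null --p 0.05 --reps 10000 --seed 1`), where isolated hybrids
make 4-way DMIs most common. Fitting the replicate-averaged total count
with the saturating power law (`dsdrift fit`, or
`fitting.fit_power_law`) at this population size gives a short-time
exponent γ close to 2. The statsmodels-style results object reports
estimates, standard errors and a `summary()` table.

The CLI subcommands `equilibrate`, `diverge`, `decompose`, `fit`, `null`
and `fixtures` chain the same pipeline from the shell, writing plain-text
artifacts whose `#`-JSON headers embed the resolved configuration and
seeds.

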