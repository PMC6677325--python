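"""Allopatric divergence and four-locus hybrid construction.

After equilibration, a common ancestor is split into two lineages that
evolve independently under the same fitness function.  The genome decomposes
into four fully linked loci with free reassortment between them:

  R locus: polymerase sequences (g_R, g_r)
  M locus: morphogen sequences (g_M, g_m)
  C locus: cis-regulatory sites (g_P, g_B)
  A locus: morphogen gradient steepness alpha

A hybrid is one of the 2^4 - 2 = 14 non-parental combinations of the four
loci, written as a 4-letter label (e.g. ``rMCa``: R and alpha from lineage
1, M and C from lineage 2; lower case = lineage 1, upper case = lineage 2).
A hybrid is incompatible (a DMI) when its truncated log fitness is -inf,
i.e. its patterning score falls below the viability boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .evolution import EvoParams, Trajectory, evolve, equilibrate_and_sample_ancestors
from .gpmap import Genome, ModelParams, log_fitness

__all__ = [
    "LOCI",
    "N_HYBRIDS",
    "HybridPattern",
    "DivergenceRun",
    "label_to_string",
    "string_to_label",
    "swap_lineages_label",
    "swap_lineages_mask",
    "make_hybrid",
    "evaluate_hybrids",
    "run_divergence_experiment",
    "replicate_ensemble",
]

#: locus order; bit 3 = R, bit 2 = M, bit 1 = C, bit 0 = A.  Bit value 1
#: means the allele comes from lineage 2 (upper-case letter).
LOCI = ("R", "M", "C", "A")
N_LOCI = 4
N_HYBRIDS = 2 ** N_LOCI - 2  # 14
_PARENT1 = 0
_PARENT2 = 2 ** N_LOCI - 1


def label_to_string(label: int) -> str:
    """4-letter hybrid label; lower case = lineage 1, upper = lineage 2."""
    if not 0 <= label < 2 ** N_LOCI:
        raise ValueError("label out of range")
    out = []
    for i, locus in enumerate(LOCI):
        bit = (label >> (N_LOCI - 1 - i)) & 1
        out.append(locus.upper() if bit else locus.lower())
    return "".join(out)


def string_to_label(s: str) -> int:
    if len(s) != N_LOCI or [c.upper() for c in s] != list(LOCI):
        raise ValueError(f"bad hybrid label {s!r}; expected e.g. 'rMCa'")
    label = 0
    for c in s:
        label = (label << 1) | int(c.isupper())
    return label


def swap_lineages_label(label: int) -> int:
    """Exchanging parent 1 and parent 2 maps a label to its case swap."""
    return label ^ _PARENT2


def swap_lineages_mask(mask: int) -> int:
    """Apply the lineage swap to a whole incompatibility mask."""
    out = 0
    for h in range(2 ** N_LOCI):
        if mask >> h & 1:
            out |= 1 << swap_lineages_label(h)
    return out


@dataclass(frozen=True)
class HybridPattern:
    """Boolean incompatibility assignment over the 14 hybrids at one time.

    ``mask`` has bit h set iff the hybrid whose 4-bit label is h is
    incompatible; bits 0 (all-lineage-1) and 15 (all-lineage-2) are the
    parental genotypes and always clear.
    """

    divergence_time: float
    mask: int

    def __post_init__(self) -> None:
        if self.mask & ((1 << _PARENT1) | (1 << _PARENT2)):
            raise ValueError("parental genotypes cannot be flagged")
        if not 0 <= self.mask < 2 ** (2 ** N_LOCI):
            raise ValueError("mask out of range")

    @property
    def flags(self) -> np.ndarray:
        """Boolean vector over hybrid labels 1..14."""
        return np.array([bool(self.mask >> h & 1) for h in range(1, 15)])

    @property
    def n_incompatible(self) -> int:
        return int(self.mask.bit_count())

    @property
    def incompatible_labels(self) -> tuple:
        return tuple(label_to_string(h) for h in range(1, 15) if self.mask >> h & 1)

    @classmethod
    def from_labels(cls, labels, divergence_time: float = 0.0) -> "HybridPattern":
        mask = 0
        for lab in labels:
            h = string_to_label(lab) if isinstance(lab, str) else int(lab)
            if h in (_PARENT1, _PARENT2):
                raise ValueError("parental genotypes cannot be flagged")
            mask |= 1 << h
        return cls(divergence_time, mask)

    def to_line(self) -> str:
        bits = "".join(str(self.mask >> h & 1) for h in range(1, 15))
        return f"{self.divergence_time:.10g}\t{bits}"

    @classmethod
    def from_line(cls, line: str) -> "HybridPattern":
        t_str, bits = line.split()
        if len(bits) != N_HYBRIDS or set(bits) - {"0", "1"}:
            raise ValueError("pattern field must be 14 characters of 0/1")
        mask = 0
        for i, c in enumerate(bits):
            mask |= int(c) << (i + 1)
        return cls(float(t_str), mask)


def make_hybrid(parent1: Genome, parent2: Genome, label) -> Genome:
    """Reassort the four loci between the parents according to ``label``."""
    if isinstance(label, str):
        label = string_to_label(label)
    if not 0 <= label < 2 ** N_LOCI:
        raise ValueError("label out of range")
    pR, pM, pC, pA = (
        parent2 if label >> (N_LOCI - 1 - i) & 1 else parent1
        for i in range(N_LOCI)
    )
    return Genome(g_R=pR.g_R.copy(), g_r=pR.g_r.copy(),
                  g_M=pM.g_M.copy(), g_m=pM.g_m.copy(),
                  g_P=pC.g_P.copy(), g_B=pC.g_B.copy(),
                  alpha=pA.alpha)


def _hybrid_fitnesses(parent1: Genome, parent2: Genome,
                      params: ModelParams) -> np.ndarray:
    """F of the 14 hybrids (index = label - 1), via the jitted W kernel."""
    kargs = _kernels.kernel_args(params)
    F = np.empty(N_HYBRIDS)
    for h in range(1, 2 ** N_LOCI - 1):
        hyb = make_hybrid(parent1, parent2, h)
        W = _kernels.w_of_bits(hyb.bits, hyb.alpha, *kargs)
        F[h - 1] = log_fitness(W, params)
    return F


def evaluate_hybrids(parent1: Genome, parent2: Genome, params: ModelParams,
                     divergence_time: float = 0.0):
    """Fitness of all 14 hybrids and the resulting incompatibility pattern.

    A hybrid is flagged incompatible iff its truncated log fitness is -inf.
    Returns (HybridPattern, F array indexed by label-1).
    """
    F = _hybrid_fitnesses(parent1, parent2, params)
    mask = 0
    for h in range(1, 15):
        if np.isneginf(F[h - 1]):
            mask |= 1 << h
    return HybridPattern(divergence_time, mask), F


@dataclass
class DivergenceRun:
    """Two lineages from one ancestor plus the hybrid time series.

    ``times`` is the union of both lineages' substitution times (plus t=0);
    ``masks[i]``/``F[i]`` give the incompatibility pattern and the 14 hybrid
    fitnesses immediately after ``times[i]``.  Patterns are step functions
    of divergence time (they only change at substitutions).
    """

    ancestor: Genome
    params: ModelParams
    evo: EvoParams
    t_max: float
    times: np.ndarray
    masks: np.ndarray
    F: np.ndarray
    traj1: Trajectory | None = None
    traj2: Trajectory | None = None
    seeds: tuple = ()

    def mask_at(self, t) -> np.ndarray:
        """Pattern mask in force at divergence time(s) t (step function)."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right") - 1
        idx = np.clip(idx, 0, len(self.times) - 1)
        return self.masks[idx]

    def patterns(self):
        return [HybridPattern(float(t), int(m))
                for t, m in zip(self.times, self.masks)]


def run_divergence_experiment(ancestor: Genome, params: ModelParams,
                              evo: EvoParams, t_max: float,
                              seeds: tuple = (0, 1)) -> DivergenceRun:
    """Evolve two lineages from ``ancestor`` and track the 14 hybrids.

    Both lineages run to the same horizon ``t_max`` on independent RNG
    streams; hybrids are re-evaluated after every substitution in either
    lineage (the pattern is constant in between).
    """
    rngs = [np.random.default_rng(s) for s in seeds]
    trajs = [evolve(ancestor, params, evo, t_max=t_max, rng=r) for r in rngs]

    # merge the two event streams, replaying each lineage's genotype
    merged = sorted(
        [(ev.time, li, ev) for li, tr in enumerate(trajs) for ev in tr.events]
    )
    n_bits = params.n_binary_sites
    bits = [ancestor.bits, ancestor.bits]
    alphas = [ancestor.alpha, ancestor.alpha]

    times = [0.0]
    pat0, F0 = evaluate_hybrids(ancestor, ancestor, params)
    masks = [pat0.mask]
    Fs = [F0]
    for t, li, ev in merged:
        if ev.channel < n_bits:
            bits[li][ev.channel] = int(ev.new)
        else:
            alphas[li] = float(ev.new)
        g1 = Genome.from_bits(bits[0], alphas[0], params)
        g2 = Genome.from_bits(bits[1], alphas[1], params)
        pat, F = evaluate_hybrids(g1, g2, params, divergence_time=t)
        times.append(t)
        masks.append(pat.mask)
        Fs.append(F)

    return DivergenceRun(
        ancestor=ancestor.copy(), params=params, evo=evo, t_max=t_max,
        times=np.array(times), masks=np.array(masks, dtype=np.int64),
        F=np.array(Fs), traj1=trajs[0], traj2=trajs[1], seeds=tuple(seeds))


def replicate_ensemble(params: ModelParams, evo: EvoParams,
                       n_replicates: int, t_max: float,
                       n_burn: int = 100_000, n_gap: int = 100,
                       seed: int | None = None,
                       ancestors: list | None = None) -> list:
    """Independent divergence runs, one per equilibrium ancestor draw.

    Ancestors come from a single long equilibration run sampled every
    ``n_gap`` substitutions (successive draws from the same reference
    equilibrium).  Per-replicate lineage seeds are spawned from ``seed``
    (default: evo.rng_seed) and recorded on each run.
    """
    root = np.random.SeedSequence(evo.rng_seed if seed is None else seed)
    eq_ss, *rep_ss = root.spawn(n_replicates + 1)
    if ancestors is None:
        ancestors = equilibrate_and_sample_ancestors(
            params, evo, n_burn=n_burn, n_gap=n_gap, n_samples=n_replicates,
            rng=np.random.default_rng(eq_ss))
    if len(ancestors) != n_replicates:
        raise ValueError("need one ancestor per replicate")
    runs = []
    for anc, ss in zip(ancestors, rep_ss):
        s1, s2 = ss.spawn(2)
        run = run_divergence_experiment(anc, params, evo, t_max, seeds=(s1, s2))
        run.seeds = tuple(int(s.generate_state(1)[0]) for s in (s1, s2))
        runs.append(run)
    return runs
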