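"""Exact parsimonious decomposition of hybrid incompatibility patterns.

The 2^L - 2 hybrids between two lineages with L fully linked loci sit on a
Boolean L-cube (L = 4 here).  A *fundamental* n-way DMI is an allele
assignment over n of the loci, not all drawn from one parent; every hybrid
that carries the assignment is inviable, so the DMI's footprint is a
(L - n)-dimensional subcube: for L = 4 a face (n = 2, four hybrids), an edge
(n = 3, two hybrids) or a point (n = 4).  There are
sum_n (2^n - 2) C(L, n) = 3^L + 1 - 2^(L+1) fundamental DMIs (50 for L = 4:
12 pairwise, 24 three-way, 14 four-way).

An observed pattern of incompatible hybrids is explained by any *cover*: a
set of fundamental DMIs whose footprints lie inside and jointly exhaust the
incompatible set.  The decomposition enumerates every cover of minimum
cardinality, treats them as a priori equally likely, and reports the average
number of 2-/3-/4-way DMIs over minimum covers (exact rationals, e.g.
n2 = 4/3) plus the per-type spectrum (fraction of minimum covers containing
each fundamental DMI).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from itertools import combinations

import numpy as np

__all__ = [
    "FundamentalDMI",
    "DecompositionResult",
    "DMITimeSeries",
    "NullSummary",
    "ELL_PRIME",
    "enumerate_fundamental_dmis",
    "max_fundamental_dmis",
    "admissible_dmis",
    "minimum_covers",
    "decompose",
    "decompose_timeseries",
    "random_pattern_null",
]


def _locus_letters(L: int) -> tuple:
    if L == 4:
        return ("r", "m", "c", "a")
    return tuple(f"x{i}" for i in range(L))


@dataclass(frozen=True)
class FundamentalDMI:
    """An n-locus allele assignment (n >= 2, not all from one parent).

    ``loci_mask`` has bit (L-1-i) set iff locus i participates; ``alleles``
    (a submask of loci_mask) has the bit set iff that locus carries the
    lineage-2 allele.  The footprint on the hybrid cube is every genotype
    label h with (h & loci_mask) == alleles.
    """

    loci_mask: int
    alleles: int
    L: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.loci_mask < 2 ** self.L:
            raise ValueError("loci_mask out of range")
        if self.alleles & ~self.loci_mask:
            raise ValueError("alleles must be a submask of loci_mask")
        if self.order < 2:
            raise ValueError("a DMI involves at least 2 loci")
        if self.alleles in (0, self.loci_mask):
            raise ValueError("alleles cannot all come from one parent")

    @property
    def order(self) -> int:
        """Number of participating loci (2 = face, 3 = edge, 4 = point)."""
        return self.loci_mask.bit_count()

    @property
    def subspace_mask(self) -> int:
        """Bitmask over the 2^L genotype labels in the footprint."""
        mask = 0
        for h in range(2 ** self.L):
            if h & self.loci_mask == self.alleles:
                mask |= 1 << h
        return mask

    @property
    def name(self) -> str:
        letters = _locus_letters(self.L)
        out = []
        for i in range(self.L):
            bit = self.L - 1 - i
            if self.loci_mask >> bit & 1:
                c = letters[i]
                out.append(c.upper() if self.alleles >> bit & 1 else c.lower())
        return "I_" + "".join(out)

    @classmethod
    def from_name(cls, name: str, L: int = 4) -> "FundamentalDMI":
        s = name.removeprefix("I_")
        letters = _locus_letters(L)
        loci_mask = alleles = 0
        for c in s:
            try:
                i = letters.index(c.lower())
            except ValueError:
                raise ValueError(f"unknown locus letter {c!r}") from None
            bit = L - 1 - i
            loci_mask |= 1 << bit
            if c.isupper():
                alleles |= 1 << bit
        return cls(loci_mask, alleles, L)


def max_fundamental_dmis(L: int) -> int:
    """3^L + 1 - 2^(L+1): the number of fundamental DMI candidates."""
    return 3 ** L + 1 - 2 ** (L + 1)


@lru_cache(maxsize=None)
def enumerate_fundamental_dmis(L: int = 4) -> tuple:
    """All fundamental DMIs for L loci, in a canonical deterministic order."""
    if L < 2:
        raise ValueError("need at least 2 loci")
    out = []
    for n in range(2, L + 1):
        for loci in combinations(range(L), n):
            loci_mask = sum(1 << (L - 1 - i) for i in loci)
            for h in range(2 ** L):
                a = h & loci_mask
                if a != 0 and a != loci_mask and (h & ~loci_mask) == 0:
                    out.append(FundamentalDMI(loci_mask, a, L))
    # the subset loop above visits each allele submask once per h with equal
    # projection; dedupe while preserving order
    seen, uniq = set(), []
    for d in out:
        key = (d.loci_mask, d.alleles)
        if key not in seen:
            seen.add(key)
            uniq.append(d)
    assert len(uniq) == max_fundamental_dmis(L)
    return tuple(uniq)


def _as_mask(pattern, L: int = 4) -> int:
    """Accept a HybridPattern, an integer mask, or an iterable of labels."""
    from .speciation import HybridPattern, string_to_label
    if isinstance(pattern, HybridPattern):
        return pattern.mask
    if isinstance(pattern, (int, np.integer)):
        mask = int(pattern)
    else:
        mask = 0
        for lab in pattern:
            h = string_to_label(lab) if isinstance(lab, str) else int(lab)
            mask |= 1 << h
    if mask & (1 | 1 << (2 ** L - 1)):
        raise ValueError("parental genotypes cannot be flagged")
    if not 0 <= mask < 2 ** (2 ** L):
        raise ValueError("mask out of range")
    return mask


def admissible_dmis(pattern, L: int = 4) -> list:
    """Fundamental DMIs whose entire footprint is inside the incompatible set."""
    mask = _as_mask(pattern, L)
    return [d for d in enumerate_fundamental_dmis(L)
            if d.subspace_mask & ~mask == 0]


@lru_cache(maxsize=None)
def _min_cover_indices(mask: int, L: int) -> tuple:
    """All minimum covers as tuples of candidate indices (canonical order).

    Branch-and-bound over admissible candidates: branch on the lowest
    uncovered hybrid, iterative deepening on cover size.  Every incompatible
    point is itself an admissible point DMI, so a cover always exists.
    """
    cands = enumerate_fundamental_dmis(L)
    subs = [d.subspace_mask for d in cands]
    adm = [i for i in range(len(cands)) if subs[i] & ~mask == 0]
    if mask == 0:
        return ((),)
    covering = {}
    for h in range(2 ** L):
        if mask >> h & 1:
            covering[h] = [i for i in adm if subs[i] >> h & 1]
    max_foot = max(s.bit_count() for s in (subs[i] for i in adm))
    lower = -(-mask.bit_count() // max_foot)
    for limit in range(max(lower, 1), mask.bit_count() + 1):
        found: set = set()

        def dfs(uncov: int, chosen: tuple) -> None:
            if uncov == 0:
                found.add(frozenset(chosen))
                return
            if len(chosen) == limit:
                return
            h = (uncov & -uncov).bit_length() - 1
            for i in covering[h]:
                dfs(uncov & ~subs[i], chosen + (i,))

        dfs(mask, ())
        if found:
            return tuple(sorted(tuple(sorted(f)) for f in found))
    raise AssertionError("unreachable: point DMIs always cover the pattern")


def minimum_covers(pattern, L: int = 4) -> list:
    """Every cover of minimum cardinality, each a tuple of FundamentalDMI."""
    mask = _as_mask(pattern, L)
    cands = enumerate_fundamental_dmis(L)
    return [tuple(cands[i] for i in cover)
            for cover in _min_cover_indices(mask, L)]


@dataclass(frozen=True)
class DecompositionResult:
    """Minimum-cover statistics of one incompatibility pattern.

    Counts are exact rationals: the per-order totals averaged uniformly over
    all minimum covers, so n2 + n3 + n4 equals the minimum cover size
    exactly.  ``spectrum`` maps each fundamental DMI name to the fraction of
    minimum covers that contain it; ``covers`` lists the minimum covers by
    name.
    """

    pattern_mask: int
    L: int
    n_total: int
    counts: dict
    spectrum: dict
    covers: tuple
    n_minimum_covers: int

    @property
    def n2(self) -> Fraction:
        return self.counts.get(2, Fraction(0))

    @property
    def n3(self) -> Fraction:
        return self.counts.get(3, Fraction(0))

    @property
    def n4(self) -> Fraction:
        return self.counts.get(4, Fraction(0))


@lru_cache(maxsize=None)
def _decompose_mask(mask: int, L: int) -> DecompositionResult:
    cands = enumerate_fundamental_dmis(L)
    covers_idx = _min_cover_indices(mask, L)
    n_covers = len(covers_idx)
    n_total = len(covers_idx[0]) if covers_idx else 0
    counts: dict = {n: Fraction(0) for n in range(2, L + 1)}
    appear: dict = {}
    for cover in covers_idx:
        for i in cover:
            counts[cands[i].order] += Fraction(1, n_covers)
            appear[i] = appear.get(i, 0) + 1
    spectrum = {cands[i].name: Fraction(k, n_covers)
                for i, k in sorted(appear.items())}
    covers = tuple(tuple(cands[i].name for i in cover) for cover in covers_idx)
    assert sum(counts.values()) == n_total
    return DecompositionResult(
        pattern_mask=mask, L=L, n_total=n_total, counts=counts,
        spectrum=spectrum, covers=covers, n_minimum_covers=n_covers)


def decompose(pattern, L: int = 4) -> DecompositionResult:
    """Average the 2-/3-/4-way DMI counts over all minimum covers."""
    return _decompose_mask(_as_mask(pattern, L), L)


# ---------------------------------------------------------------------------
# Time series and the random-pattern null model
# ---------------------------------------------------------------------------

#: base pairs per pairwise interaction, used to rescale divergence time in
#: the pairwise DMI spectra (protein-protein faces for rm; a DNA-binding
#: face against the regulatory region for rc and mc)
ELL_PRIME = {"rm": 5.0, "rc": 10.0, "mc": 10.0}


@dataclass
class DMITimeSeries:
    """Replicate-averaged DMI counts versus divergence time mu*t.

    ``mean``/``sem`` map the keys "total", "2", "3", "4" to arrays on the
    ``mu_t`` grid.  ``spectrum`` holds the replicate-mean fractional count
    per fundamental DMI name; ``pair_spectrum`` aggregates the pairwise
    types by unordered locus pair (e.g. "rm" = I_rM + I_Rm).
    """

    mu_t: np.ndarray
    n_replicates: int
    mean: dict
    sem: dict
    spectrum: dict | None = None
    pair_spectrum: dict | None = None

    def scaled_pair_time(self, pair: str) -> np.ndarray:
        """Divergence time rescaled by the pair's base-pair count ell'."""
        return ELL_PRIME[pair] * self.mu_t

    def to_frame(self):
        import pandas as pd
        data = {"mu_t": self.mu_t}
        for k in ("total", "2", "3", "4"):
            data[f"n{k}_mean"] = self.mean[k]
            data[f"n{k}_sem"] = self.sem[k]
        if self.pair_spectrum:
            for pair, arr in self.pair_spectrum.items():
                data[f"I_{pair}"] = arr
        return pd.DataFrame(data)


def decompose_timeseries(runs, grid=None, with_spectrum: bool = True,
                         L: int = 4) -> DMITimeSeries:
    """Decompose the pattern step functions of one or more divergence runs.

    ``grid`` defaults to 50 uniform times on (0, t_max].  Per time point the
    minimum-cover statistics of each run's pattern are averaged across
    replicates (decompositions are memoised by pattern, so repeated patterns
    cost nothing).
    """
    if not isinstance(runs, (list, tuple)):
        runs = [runs]
    if not runs:
        raise ValueError("empty ensemble")
    if grid is None:
        t_max = max(r.t_max for r in runs)
        grid = np.linspace(0.0, t_max, 51)[1:]
    grid = np.asarray(grid, dtype=float)
    n_rep = len(runs)
    keys = ("total", "2", "3", "4")
    per_run = {k: np.empty((n_rep, grid.size)) for k in keys}
    spec_sum: dict = {}
    pair_sum: dict = {}
    for j, run in enumerate(runs):
        masks = run.mask_at(grid)
        for i, m in enumerate(masks):
            res = _decompose_mask(int(m), L)
            per_run["total"][j, i] = res.n_total
            per_run["2"][j, i] = float(res.n2)
            per_run["3"][j, i] = float(res.n3)
            per_run["4"][j, i] = float(res.n4)
            if with_spectrum:
                for name, frac in res.spectrum.items():
                    arr = spec_sum.setdefault(name, np.zeros(grid.size))
                    arr[i] += float(frac)
    mean = {k: per_run[k].mean(axis=0) for k in keys}
    sem = {k: (per_run[k].std(axis=0, ddof=1) / np.sqrt(n_rep)
               if n_rep > 1 else np.zeros(grid.size)) for k in keys}
    spectrum = pair_spectrum = None
    if with_spectrum:
        spectrum = {name: arr / n_rep for name, arr in sorted(spec_sum.items())}
        for name, arr in spectrum.items():
            body = name.removeprefix("I_")
            if len(body) == 2:
                pair = body.lower()
                pair_sum.setdefault(pair, np.zeros(grid.size))
                pair_sum[pair] += arr
        pair_spectrum = dict(sorted(pair_sum.items()))
    return DMITimeSeries(mu_t=grid, n_replicates=n_rep, mean=mean, sem=sem,
                         spectrum=spectrum, pair_spectrum=pair_spectrum)


@dataclass(frozen=True)
class NullSummary:
    """Mean decomposition of random incompatibility patterns."""

    p_incompatible: float
    n_reps: int
    mean: dict
    sem: dict


def random_pattern_null(p_incompatible: float, n_reps: int,
                        rng: np.random.Generator | None = None,
                        L: int = 4) -> NullSummary:
    """Decompose patterns with each hybrid flagged independently with prob p.

    With small p this yields mostly isolated incompatible hybrids, so the
    mean counts order as n4 > n3 > n2 - the opposite of what the evolved
    patterns show.
    """
    if not 0 <= p_incompatible <= 1:
        raise ValueError("p_incompatible must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(0)
    n_hyb = 2 ** L - 2
    flags = rng.random((n_reps, n_hyb)) < p_incompatible
    weights = 1 << np.arange(1, n_hyb + 1)
    masks = flags @ weights
    keys = ("total", "2", "3", "4")
    vals = {k: np.empty(n_reps) for k in keys}
    for j, m in enumerate(masks):
        res = _decompose_mask(int(m), L)
        vals["total"][j] = res.n_total
        vals["2"][j] = float(res.n2)
        vals["3"][j] = float(res.n3)
        vals["4"][j] = float(res.n4)
    mean = {k: float(vals[k].mean()) for k in keys}
    sem = {k: float(vals[k].std(ddof=1) / np.sqrt(n_reps)) if n_reps > 1
           else 0.0 for k in keys}
    return NullSummary(p_incompatible=p_incompatible, n_reps=n_reps,
                       mean=mean, sem=sem)
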