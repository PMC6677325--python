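"""Origin-fixation kinetic Monte Carlo over the patterning genotype.

The population is represented by a single fixed genotype (monomorphic,
ell_G * mu0 * N << 1).  At each step every one-step mutant is proposed: one
channel per binary site (a bit flip) plus ``alpha_channels`` channels that
each carry an independently drawn Gaussian perturbation of the morphogen
steepness.  Each channel's substitution rate is the mutation supply mu0 * N
times Kimura's fixation probability, expressed through the fitness change
delta_F:

    k = mu0 * N * (1 - exp(-2 dF)) / (1 - exp(-2 N dF))

The next substitution and the waiting time are drawn with the Gillespie
algorithm (dt = -ln(u)/K, K the total rate), so substitution times are
Poisson for a fixed genotype.

Viability is truncated at F_star.  From a viable genotype, inviable mutants
have rate zero, so a lineage never fixes an inviable state.  Equilibration
from a random (typically inviable) genome uses a soft selection score
kappa_F * ln(max(W, 1e-12)) until viability is first reached; see
docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from numba import njit

from . import _kernels
from .gpmap import Genome, ModelParams, log_fitness

__all__ = [
    "EvoParams",
    "SubstitutionEvent",
    "Trajectory",
    "MutationChannel",
    "fixation_rate",
    "enumerate_mutation_channels",
    "gillespie_step",
    "evolve",
    "equilibrate_and_sample_ancestors",
    "fitness_histogram",
    "TabularLandscape",
    "tabular_rate_matrix",
    "tabular_stationary",
    "evolve_tabular",
]

#: floor applied to W inside the soft (pre-viability) selection score
SOFT_W_FLOOR = 1e-12


class AbsorbingStateError(RuntimeError):
    """Raised when every mutation channel has rate zero."""


@dataclass(frozen=True)
class EvoParams:
    """Parameters of the substitution process.

    ``two_N_kappa`` is the population-scaled selection strength 2 N_e kappa_F
    used to label experiments; N_e is derived from it (and kappa_F) unless
    given explicitly.  ``mu0`` is the per-base mutation rate and defaults to
    1/ell_G so that one time unit equals one expected genome-wide mutation
    (divergence times are then in mu*t units directly).
    """

    two_N_kappa: float = 1.0
    N_e: float | None = None
    mu0: float | None = None
    delta_alpha_sd: float = 0.5
    alpha_channels: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.N_e is not None and self.N_e < 1:
            raise ValueError("N_e must be >= 1")
        if self.N_e is None and not self.two_N_kappa > 0:
            raise ValueError("two_N_kappa must be > 0 when N_e is not given")
        if self.mu0 is not None and not self.mu0 > 0:
            raise ValueError("mu0 must be > 0")
        if not self.delta_alpha_sd > 0:
            raise ValueError("delta_alpha_sd must be > 0")
        if self.alpha_channels < 0:
            raise ValueError("alpha_channels must be >= 0")

    def resolve_N(self, params: ModelParams) -> float:
        if self.N_e is not None:
            return float(self.N_e)
        if params.kappa_F == 0:
            raise ValueError("kappa_F = 0 (neutral): give N_e explicitly")
        return self.two_N_kappa / (2.0 * params.kappa_F)

    def resolve_mu0(self, params: ModelParams) -> float:
        return self.mu0 if self.mu0 is not None else 1.0 / params.ell_genome

    def replace(self, **kwargs) -> "EvoParams":
        return replace(self, **kwargs)


def _phi(u: np.ndarray) -> np.ndarray:
    """(1 - exp(-u))/u, continuous at 0."""
    out = np.empty_like(u)
    small = np.abs(u) < 1e-6
    us = u[small]
    out[small] = 1.0 - us / 2.0 + us * us / 6.0
    ub = u[~small]
    out[~small] = -np.expm1(-ub) / ub
    return out


def fixation_rate(delta_F, N: float, mu0: float = 1.0):
    """Kimura origin-fixation rate mu0 N (1-e^{-2dF})/(1-e^{-2N dF}).

    Continuous at dF = 0 (value mu0), zero for an inviable mutant
    (dF = -inf) and mu0*N for a guaranteed sweep (dF = +inf).  Accepts
    scalars or arrays; NaN entries (rejected proposals) map to rate 0.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    d = np.asarray(delta_F, dtype=float)
    scalar = d.ndim == 0
    d = np.atleast_1d(d)
    out = np.zeros(d.shape, dtype=float)
    out[d == 0] = mu0
    out[np.isposinf(d)] = mu0 * N
    fin = np.isfinite(d) & (d != 0)
    # for strongly deleterious mutants the rate underflows; cut before exp overflow
    safe = fin & (2.0 * N * d > -600.0)
    ds = d[safe]
    # (1-e^{-2dF})/(1-e^{-2N dF}) = (1/N) * phi(2dF)/phi(2N dF)
    out[safe] = mu0 * _phi(2.0 * ds) / _phi(2.0 * N * ds)
    return float(out[0]) if scalar else out


@dataclass(frozen=True)
class SubstitutionEvent:
    """One accepted substitution on a lineage."""

    time: float
    channel: int
    site: str
    old: float
    new: float
    delta_F: float
    F_after: float


@dataclass
class Trajectory:
    """An ordered substitution history; replaying it reproduces ``final``."""

    initial: Genome
    events: list
    final: Genome
    params: ModelParams
    evo: EvoParams
    t0: float = 0.0
    t_end: float = 0.0

    def __len__(self) -> int:
        return len(self.events)

    def replay(self) -> Genome:
        g = self.initial.copy()
        bits = g.bits
        alpha = g.alpha
        n_bits = self.params.n_binary_sites
        for ev in self.events:
            if ev.channel < n_bits:
                bits[ev.channel] = int(ev.new)
            else:
                alpha = float(ev.new)
        return Genome.from_bits(bits, alpha, self.params)

    def fitness_series(self) -> np.ndarray:
        return np.array([ev.F_after for ev in self.events])

    def times(self) -> np.ndarray:
        return np.array([ev.time for ev in self.events])


def _site_label(channel: int, params: ModelParams) -> str:
    sizes = (("g_R", params.ell_pp), ("g_r", params.ell_pd),
             ("g_M", params.ell_pp), ("g_m", params.ell_pd),
             ("g_P", params.ell_pd), ("g_B", params.ell_pd))
    i = channel
    for name, n in sizes:
        if i < n:
            return f"{name}[{i}]"
        i -= n
    return "alpha"


def _log_fitness_vec(W: np.ndarray, params: ModelParams) -> np.ndarray:
    """Vectorised truncated log fitness; NaN inputs stay NaN."""
    W = np.asarray(W, dtype=float)
    if params.kappa_F == 0:
        return np.where(np.isnan(W), np.nan, 0.0)
    out = np.full(W.shape, -np.inf)
    pos = W > 0
    out[pos] = params.kappa_F * np.log(np.minimum(W[pos], 1.0))
    out[out <= params.F_star] = -np.inf
    out[np.isnan(W)] = np.nan
    return out


def _soft_score_vec(W: np.ndarray, params: ModelParams) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    out = params.kappa_F * np.log(np.clip(W, SOFT_W_FLOOR, 1.0))
    out[np.isnan(W)] = np.nan
    return out


def _sweep(bits: np.ndarray, alpha: float, props: np.ndarray,
           params: ModelParams):
    return _kernels.mutant_sweep(bits, alpha, props, *_kernels.kernel_args(params))


def _channel_rates(W0: float, Wm: np.ndarray, params: ModelParams,
                   N: float, mu0: float):
    """Per-channel rates given current and mutant W scores.

    Uses truncated fitness when the current state is viable, otherwise the
    soft (untruncated) score so that equilibration can climb out of the
    inviable region.  Returns (F0, F_mut, delta, rates).
    """
    F0 = log_fitness(W0, params)
    Fm = _log_fitness_vec(Wm, params)
    if np.isneginf(F0):
        s0 = float(_soft_score_vec(np.array([W0]), params)[0])
        delta = _soft_score_vec(Wm, params) - s0
    else:
        delta = Fm - F0
    rates = fixation_rate(delta, N, mu0)
    rates[np.isnan(Wm)] = 0.0
    return F0, Fm, delta, rates


@dataclass(frozen=True)
class MutationChannel:
    """One proposed one-step mutant and its substitution rate."""

    index: int
    site: str
    old: float
    new: float
    W: float
    F: float
    delta_F: float
    rate: float

    def apply(self, genome: Genome, params: ModelParams) -> Genome:
        bits = genome.bits
        if self.index < params.n_binary_sites:
            bits[self.index] = int(self.new)
            return Genome.from_bits(bits, genome.alpha, params)
        return Genome.from_bits(bits, float(self.new), params)


def enumerate_mutation_channels(genome: Genome, params: ModelParams,
                                evo: EvoParams,
                                rng: np.random.Generator) -> list:
    """All one-step mutation channels with their Kimura substitution rates.

    With defaults this is 50 bit flips plus 10 alpha channels, each alpha
    channel carrying a fresh Gaussian proposal (resampled every step).
    Proposals driving alpha <= 0 get rate 0.
    """
    genome.validate(params)
    N = evo.resolve_N(params)
    mu0 = evo.resolve_mu0(params)
    props = rng.normal(0.0, evo.delta_alpha_sd, evo.alpha_channels)
    bits = genome.bits
    W0, Wm = _sweep(bits, genome.alpha, props, params)
    _, Fm, delta, rates = _channel_rates(W0, Wm, params, N, mu0)
    n_bits = params.n_binary_sites
    channels = []
    for c in range(n_bits + evo.alpha_channels):
        if c < n_bits:
            old, new = int(bits[c]), int(bits[c] ^ 1)
        else:
            old, new = genome.alpha, genome.alpha + props[c - n_bits]
        channels.append(MutationChannel(
            index=c, site=_site_label(c, params), old=old, new=new,
            W=float(Wm[c]), F=float(Fm[c]), delta_F=float(delta[c]),
            rate=float(rates[c]),
        ))
    return channels


def gillespie_step(genome: Genome, channels: Sequence[MutationChannel],
                   rng: np.random.Generator, params: ModelParams,
                   t: float = 0.0):
    """Pick one channel with probability rate/K and advance the clock.

    Returns (event, new_genome, dt) with dt = -ln(u)/K exponentially
    distributed with mean 1/K.
    """
    rates = np.array([ch.rate for ch in channels])
    K = rates.sum()
    if K <= 0:
        raise AbsorbingStateError("all mutation channels have rate zero")
    c = int(np.searchsorted(np.cumsum(rates), rng.random() * K))
    c = min(c, len(channels) - 1)
    dt = -np.log(rng.random()) / K
    ch = channels[c]
    event = SubstitutionEvent(time=t + dt, channel=ch.index, site=ch.site,
                              old=ch.old, new=ch.new, delta_F=ch.delta_F,
                              F_after=ch.F)
    return event, ch.apply(genome, params), dt


def evolve(genome: Genome, params: ModelParams, evo: EvoParams,
           n_substitutions: int | None = None, t_max: float | None = None,
           *, rng: np.random.Generator | None = None,
           allow_inviable_start: bool = False, t0: float = 0.0) -> Trajectory:
    """Run the origin-fixation process from ``genome``.

    Stops after ``n_substitutions`` events or at time ``t_max``, whichever
    comes first (at least one must be given).  The input genome is not
    modified.  With a viable start the lineage fitness stays above F_star
    throughout.
    """
    if n_substitutions is None and t_max is None:
        raise ValueError("give n_substitutions and/or t_max")
    genome.validate(params)
    if rng is None:
        rng = np.random.default_rng(evo.rng_seed)
    N = evo.resolve_N(params)
    mu0 = evo.resolve_mu0(params)
    kargs = _kernels.kernel_args(params)
    n_bits = params.n_binary_sites

    initial = genome.copy()
    bits = genome.bits  # working copy
    alpha = genome.alpha
    events: list[SubstitutionEvent] = []
    t = t0

    W0, _ = _kernels.mutant_sweep(bits, alpha, np.empty(0), *kargs)
    if np.isneginf(log_fitness(W0, params)) and not allow_inviable_start:
        raise ValueError("starting genome is inviable (F = -inf); "
                         "use allow_inviable_start or equilibrate first")

    while n_substitutions is None or len(events) < n_substitutions:
        props = rng.normal(0.0, evo.delta_alpha_sd, evo.alpha_channels)
        W0, Wm = _kernels.mutant_sweep(bits, alpha, props, *kargs)
        _, Fm, delta, rates = _channel_rates(W0, Wm, params, N, mu0)
        K = rates.sum()
        if K <= 0:
            raise AbsorbingStateError("all mutation channels have rate zero")
        dt = -np.log(rng.random()) / K
        if t_max is not None and t + dt > t_max:
            t = t_max
            break
        c = int(np.searchsorted(np.cumsum(rates), rng.random() * K))
        c = min(c, rates.size - 1)
        t += dt
        if c < n_bits:
            old, new = int(bits[c]), int(bits[c] ^ 1)
            bits[c] ^= 1
        else:
            old, new = alpha, alpha + props[c - n_bits]
            alpha = new
        events.append(SubstitutionEvent(
            time=t, channel=c, site=_site_label(c, params), old=old, new=new,
            delta_F=float(delta[c]), F_after=float(Fm[c])))

    final = Genome.from_bits(bits, alpha, params)
    return Trajectory(initial=initial, events=events, final=final,
                      params=params, evo=evo, t0=t0, t_end=t)


def equilibrate_and_sample_ancestors(
        params: ModelParams, evo: EvoParams, n_burn: int = 100_000,
        n_gap: int = 100, n_samples: int = 1,
        *, rng: np.random.Generator | None = None,
        initial: Genome | None = None, return_burn: bool = False):
    """Draw ancestor genomes from the (approximate) equilibrium ensemble.

    One long run of ``n_burn`` substitutions from a random genome (soft
    selection while inviable), then ``n_samples`` genomes taken every
    ``n_gap`` substitutions.  Raises if the lineage has not reached
    viability by the end of the burn-in.
    """
    if rng is None:
        rng = np.random.default_rng(evo.rng_seed)
    g = initial.copy() if initial is not None else Genome.random(rng, params)
    burn = evolve(g, params, evo, n_substitutions=n_burn, rng=rng,
                  allow_inviable_start=True)
    g = burn.final
    from .gpmap import fitness as _fitness
    if np.isneginf(_fitness(g, params)):
        raise RuntimeError(
            f"lineage still inviable after {n_burn} substitutions; "
            "increase n_burn")
    samples = []
    for _ in range(n_samples):
        step = evolve(g, params, evo, n_substitutions=n_gap, rng=rng)
        g = step.final
        samples.append(g.copy())
    if return_burn:
        return samples, burn
    return samples


def fitness_histogram(trajectory: Trajectory, bins: int = 50,
                      range: tuple | None = None):
    """Relative frequencies of F after each substitution (finite by contract)."""
    if not trajectory.events:
        raise ValueError("empty trajectory")
    F = trajectory.fitness_series()
    counts, edges = np.histogram(F[np.isfinite(F)], bins=bins, range=range)
    return counts / len(F), edges


# ---------------------------------------------------------------------------
# Toy tabular landscapes (small exact chains used as simulation oracles)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TabularLandscape:
    """An explicit log-fitness table over all 2**n_sites bit genotypes."""

    log_fitness: tuple
    n_sites: int

    def __post_init__(self) -> None:
        if len(self.log_fitness) != 2 ** self.n_sites:
            raise ValueError("fitness table must have 2**n_sites entries")

    @property
    def F(self) -> np.ndarray:
        return np.asarray(self.log_fitness, dtype=float)


def tabular_rate_matrix(land: TabularLandscape, N: float,
                        mu0: float = 1.0) -> np.ndarray:
    """rates[s, b]: substitution rate from genotype s via flipping bit b."""
    n_states = 2 ** land.n_sites
    F = land.F
    rates = np.empty((n_states, land.n_sites))
    for s in range(n_states):
        for b in range(land.n_sites):
            rates[s, b] = fixation_rate(F[s ^ (1 << b)] - F[s], N, mu0)
    return rates


def tabular_stationary(land: TabularLandscape, N: float) -> np.ndarray:
    """Exact stationary law of the chain: pi(s) proportional to e^{2(N-1)F(s)}.

    Follows from detailed balance of the Kimura rates,
    k(dF)/k(-dF) = e^{2(N-1) dF}.
    """
    w = np.exp(2.0 * (N - 1.0) * (land.F - land.F.max()))
    return w / w.sum()


@njit(cache=True)
def _tabular_walk(cum_rates, K, u_site, u_time, s0, n_states):
    occupancy = np.zeros(n_states)
    visits = np.zeros(n_states, dtype=np.int64)
    s = s0
    visits[s] += 1
    for i in range(u_site.size):
        occupancy[s] += -np.log(u_time[i]) / K[s]
        r = u_site[i] * K[s]
        row = cum_rates[s]
        b = np.searchsorted(row, r)
        if b >= row.size:
            b = row.size - 1
        s = s ^ (1 << b)
        visits[s] += 1
    return occupancy, visits, s


def evolve_tabular(land: TabularLandscape, n_substitutions: int, N: float,
                   mu0: float = 1.0, rng: np.random.Generator | None = None,
                   state0: int = 0):
    """Kinetic Monte Carlo on a tabular landscape.

    Returns (occupancy_time, visit_counts, final_state); ``occupancy_time``
    are the total waiting times per genotype, whose normalised version
    converges to :func:`tabular_stationary`.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    rates = tabular_rate_matrix(land, N, mu0)
    K = rates.sum(axis=1)
    if np.any(K <= 0):
        raise AbsorbingStateError("tabular landscape has an absorbing state")
    cum = np.cumsum(rates, axis=1)
    u_site = rng.random(n_substitutions)
    u_time = rng.random(n_substitutions)
    return _tabular_walk(cum, K, u_site, u_time, state0, 2 ** land.n_sites)
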