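"""Biophysical genotype-phenotype-fitness map for anterior-posterior patterning.

The regulatory task is to convert a monotonically decaying morphogen gradient
``[M](x)`` across a one-dimensional embryo into a sharp step of a downstream
transcription factor ``T``, expressed only in the anterior half.  Two proteins,
the morphogen M and an RNA polymerase R, compete for two adjacent binding
sites in the cis-regulatory region of ``T``: the promoter P and a morphogen
site B.  Transcription is proportional to the equilibrium probability that R
occupies P, computed from a two-site, three-state (empty/R/M) partition
function with cooperative protein-protein contacts between the occupants.

Sequences are binary.  Protein-DNA binding energy is ``eps_pd`` (kT) per
mismatch between the protein's DNA-binding face and the site; protein-protein
stabilisation is ``eps_pp`` (kT, negative) per matching contact between one
face and the *centre-reversed* other face (a chirality convention that keeps
homodimers from being trivially optimal).  The morphogen gradient steepness
``alpha`` is a continuous trait.

Fitness of the patterning phenotype is ``F = kappa_F * ln(W)`` with a hard
viability truncation at ``F_star``; ``W`` in [-1, 1] rewards anterior and
penalises posterior expression, normalised so an ideal anterior-only step
gives W = 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np

__all__ = [
    "ModelParams",
    "Genome",
    "EnergySet",
    "ExpressionProfile",
    "hamming",
    "reverse_face",
    "protein_dna_energy",
    "protein_protein_energy",
    "binding_energies",
    "morphogen_profile",
    "occupancy_weights",
    "promoter_occupancy",
    "expression_profile",
    "cell_positions",
    "patterning_score",
    "log_fitness",
    "fitness",
    "viability_boundary",
]


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the genotype-phenotype-fitness map.

    Energies are in units of kT, lengths in effective base pairs, positions in
    units of the embryo length ``L``.

    Attributes
    ----------
    eps_pd : energy penalty per protein-DNA mismatch (> 0).
    eps_pp : energy per favourable protein-protein contact (<= 0).
    ell_pd, ell_pp : lengths of the DNA-binding and protein-protein faces.
    ell_alpha : effective base pairs assigned to the continuous trait alpha
        (mutational weight only; alpha itself is a single real number).
    L : embryo length (dimensionless).
    n_cells : number of uniform midpoint cells discretising [0, L] (even).
    conc_R : polymerase activity; its chemical potential is ln(conc_R) kT.
    conc_M0 : anterior morphogen concentration scale [M0].
    kappa_F : weight of the patterning trait in log fitness.  kappa_F = 0
        switches selection off entirely (F = 0 for every genotype).
    F_star : viability threshold; F <= F_star means inviable (F = -inf).
    """

    eps_pd: float = 2.0
    eps_pp: float = -1.0
    ell_pd: int = 10
    ell_pp: int = 5
    ell_alpha: int = 10
    L: float = 1.0
    n_cells: int = 100
    conc_R: float = 1.0
    conc_M0: float = 10.0
    kappa_F: float = 1e-3
    F_star: float = -1.6e-3

    def __post_init__(self) -> None:
        if self.eps_pd <= 0:
            raise ValueError("eps_pd (mismatch penalty) must be > 0")
        if self.eps_pp > 0:
            raise ValueError(
                "eps_pp is a stabilising contact energy and must be <= 0"
            )
        if self.kappa_F < 0:
            raise ValueError("kappa_F must be >= 0")
        if self.F_star >= 0:
            raise ValueError("F_star must be < 0")
        if self.conc_R <= 0 or self.conc_M0 <= 0:
            raise ValueError("concentrations conc_R, conc_M0 must be > 0")
        if self.L <= 0:
            raise ValueError("embryo length L must be > 0")
        if min(self.ell_pd, self.ell_pp, self.ell_alpha) < 1:
            raise ValueError("segment lengths must be >= 1")
        if self.n_cells < 2 or self.n_cells % 2:
            raise ValueError("n_cells must be even and >= 2 (anterior/posterior split)")

    @property
    def n_binary_sites(self) -> int:
        """Number of binary sites in the genome (4 pd + 2 pp segments)."""
        return 4 * self.ell_pd + 2 * self.ell_pp

    @property
    def ell_genome(self) -> int:
        """Total mutational length, including alpha's effective base pairs."""
        return self.n_binary_sites + self.ell_alpha

    def replace(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


def _as_bits(value, name: str = "sequence") -> np.ndarray:
    """Coerce a '0101' string or 0/1 iterable to a uint8 array."""
    if isinstance(value, str):
        arr = np.frombuffer(value.encode("ascii"), dtype=np.uint8) - ord("0")
    else:
        arr = np.asarray(value, dtype=np.uint8)
    if arr.ndim != 1 or not np.all((arr == 0) | (arr == 1)):
        raise ValueError(f"{name} must be a flat 0/1 sequence")
    return arr.astype(np.uint8)


# Segment order inside the packed bit vector; must match _kernels offsets.
_SEGMENTS = ("g_R", "g_r", "g_M", "g_m", "g_P", "g_B")


@dataclass
class Genome:
    """The evolving state of one lineage.

    ``g_R``/``g_M`` are the protein-protein faces (length ell_pp) of the
    polymerase and morphogen; ``g_r``/``g_m`` their DNA-binding faces
    (length ell_pd); ``g_P``/``g_B`` the promoter and morphogen binding
    sites; ``alpha`` the morphogen gradient steepness (> 0, units 1/L).
    """

    g_R: np.ndarray
    g_r: np.ndarray
    g_M: np.ndarray
    g_m: np.ndarray
    g_P: np.ndarray
    g_B: np.ndarray
    alpha: float

    def __post_init__(self) -> None:
        for name in _SEGMENTS:
            setattr(self, name, _as_bits(getattr(self, name), name))
        self.alpha = float(self.alpha)
        if not self.alpha > 0:
            raise ValueError("alpha must be > 0")

    def validate(self, params: ModelParams) -> None:
        for name in ("g_R", "g_M"):
            if getattr(self, name).size != params.ell_pp:
                raise ValueError(f"{name} must have length ell_pp={params.ell_pp}")
        for name in ("g_r", "g_m", "g_P", "g_B"):
            if getattr(self, name).size != params.ell_pd:
                raise ValueError(f"{name} must have length ell_pd={params.ell_pd}")

    @property
    def bits(self) -> np.ndarray:
        """All binary sites packed in segment order (copy)."""
        return np.concatenate([getattr(self, s) for s in _SEGMENTS])

    @classmethod
    def from_bits(cls, bits: np.ndarray, alpha: float, params: ModelParams) -> "Genome":
        sizes = [params.ell_pp, params.ell_pd, params.ell_pp,
                 params.ell_pd, params.ell_pd, params.ell_pd]
        if len(bits) != sum(sizes):
            raise ValueError("bit vector length does not match params")
        parts, i = {}, 0
        for name, n in zip(_SEGMENTS, sizes):
            parts[name] = np.asarray(bits[i:i + n], dtype=np.uint8).copy()
            i += n
        return cls(alpha=alpha, **parts)

    @classmethod
    def random(cls, rng: np.random.Generator, params: ModelParams,
               alpha: float | None = None) -> "Genome":
        """Uniform random bits; alpha ~ U(1, 15) unless given."""
        bits = rng.integers(0, 2, size=params.n_binary_sites, dtype=np.uint8)
        if alpha is None:
            alpha = float(rng.uniform(1.0, 15.0))
        return cls.from_bits(bits, alpha, params)

    def copy(self) -> "Genome":
        return Genome(*(getattr(self, s).copy() for s in _SEGMENTS), alpha=self.alpha)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Genome):
            return NotImplemented
        return self.alpha == other.alpha and all(
            np.array_equal(getattr(self, s), getattr(other, s)) for s in _SEGMENTS
        )

    def to_dict(self) -> dict:
        d = {s: "".join(map(str, getattr(self, s))) for s in _SEGMENTS}
        d["alpha"] = self.alpha
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Genome":
        return cls(**{s: d[s] for s in _SEGMENTS}, alpha=d["alpha"])

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "Genome":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class EnergySet:
    """All pairwise interaction energies derived from one genome (kT units).

    Protein-DNA energies are >= 0 (mismatch penalties); cooperative
    protein-protein energies are <= 0 and symmetric in the two species.
    """

    E_RP: float
    E_RB: float
    E_MP: float
    E_MB: float
    Etilde_RM: float
    Etilde_RR: float
    Etilde_MM: float


@dataclass
class ExpressionProfile:
    """Relative transcription-factor level per cell (promoter occupancy)."""

    x: np.ndarray
    T: np.ndarray

    def mirrored(self) -> "ExpressionProfile":
        return ExpressionProfile(self.x.copy(), self.T[::-1].copy())


def hamming(a, b) -> int:
    """Number of mismatching positions between two equal-length bit strings."""
    a, b = _as_bits(a, "a"), _as_bits(b, "b")
    if a.size != b.size:
        raise ValueError(f"length mismatch: {a.size} != {b.size}")
    return int(np.count_nonzero(a != b))


def reverse_face(a) -> np.ndarray:
    """A protein-protein face flipped about its centre (chirality convention)."""
    return _as_bits(a)[::-1].copy()


def protein_dna_energy(protein_face, site, params: ModelParams) -> float:
    """Binding energy of a protein's DNA face to a site: eps_pd per mismatch."""
    face, s = _as_bits(protein_face), _as_bits(site)
    if face.size != params.ell_pd or s.size != params.ell_pd:
        raise ValueError(f"protein-DNA faces must have length ell_pd={params.ell_pd}")
    return params.eps_pd * hamming(face, s)


def protein_protein_energy(face_a, face_b, params: ModelParams) -> float:
    """Cooperative stabilisation between two bound proteins.

    eps_pp (<= 0) per matching contact between ``face_a`` and the
    centre-reversed ``face_b``; symmetric under exchanging a and b.
    """
    a, b = _as_bits(face_a), _as_bits(face_b)
    if a.size != params.ell_pp or b.size != params.ell_pp:
        raise ValueError(f"protein faces must have length ell_pp={params.ell_pp}")
    return params.eps_pp * (params.ell_pp - hamming(a, reverse_face(b)))


def binding_energies(genome: Genome, params: ModelParams) -> EnergySet:
    """All seven interaction energies implied by a genome."""
    genome.validate(params)
    return EnergySet(
        E_RP=protein_dna_energy(genome.g_r, genome.g_P, params),
        E_RB=protein_dna_energy(genome.g_r, genome.g_B, params),
        E_MP=protein_dna_energy(genome.g_m, genome.g_P, params),
        E_MB=protein_dna_energy(genome.g_m, genome.g_B, params),
        Etilde_RM=protein_protein_energy(genome.g_R, genome.g_M, params),
        Etilde_RR=protein_protein_energy(genome.g_R, genome.g_R, params),
        Etilde_MM=protein_protein_energy(genome.g_M, genome.g_M, params),
    )


def morphogen_profile(x, alpha: float, params: ModelParams) -> np.ndarray | float:
    """Morphogen concentration [M](x) = [M0] cosh(alpha (x - L)) / sinh(alpha L).

    The steady state of a reaction-diffusion equation with a source at x = 0
    and reflecting boundaries; approximately [M0] e^{-alpha x} for alpha L >> 1.
    Strictly decreasing in x and positive everywhere.
    """
    if not alpha > 0:
        raise ValueError("alpha must be > 0")
    x = np.asarray(x, dtype=float)
    return params.conc_M0 * np.cosh(alpha * (x - params.L)) / np.sinh(alpha * params.L)


def occupancy_weights(energies: EnergySet, mu_R: float, mu_M: float) -> np.ndarray:
    """Boltzmann weights of the 9 occupancy states of the (P, B) site pair.

    Rows index the promoter occupant, columns the B-site occupant, in the
    order (empty, R, M).  The weight of state (sP, sB) is
    exp(-(E_{sP,P} + E_{sB,B} - mu_{sP} - mu_{sB} + Etilde_{sP,sB})), with
    empty-state energies and chemical potential equal to zero.
    """
    E_P = np.array([0.0, energies.E_RP, energies.E_MP])
    E_B = np.array([0.0, energies.E_RB, energies.E_MB])
    mu = np.array([0.0, mu_R, mu_M])
    Et = np.zeros((3, 3))
    Et[1, 1] = energies.Etilde_RR
    Et[2, 2] = energies.Etilde_MM
    Et[1, 2] = Et[2, 1] = energies.Etilde_RM
    expo = -(E_P[:, None] + E_B[None, :] - mu[:, None] - mu[None, :] + Et)
    return np.exp(expo)


def promoter_occupancy(energies: EnergySet, mu_R: float, mu_M: float) -> float:
    """Probability that the polymerase occupies the promoter.

    Sums the three states with R on P (B empty, B = M, B = R) over the full
    9-state partition function.  Strictly between 0 and 1 for finite inputs.
    """
    w = occupancy_weights(energies, mu_R, mu_M)
    return float(w[1, :].sum() / w.sum())


def cell_positions(params: ModelParams) -> np.ndarray:
    """Midpoints of n_cells uniform cells on [0, L]."""
    n = params.n_cells
    return (np.arange(n) + 0.5) * params.L / n


def expression_profile(genome: Genome, params: ModelParams) -> ExpressionProfile:
    """T(x): promoter occupancy by R at each cell, with mu_M(x) = ln [M](x)."""
    e = binding_energies(genome, params)
    x = cell_positions(params)
    mu_R = np.log(params.conc_R)
    mu_M = np.log(morphogen_profile(x, genome.alpha, params))
    T = np.array([promoter_occupancy(e, mu_R, m) for m in mu_M])
    return ExpressionProfile(x=x, T=T)


def patterning_score(profile: ExpressionProfile, params: ModelParams) -> float:
    """Anterior-minus-posterior expression contrast W in [-1, 1].

    W = (int_0^{L/2} T - int_{L/2}^L T) / ((L/2) max_x T), midpoint rule.
    An identically-zero profile (no expression at all) is assigned W = 0,
    which maps to inviability downstream.
    """
    T = np.asarray(profile.T, dtype=float)
    n = T.size
    if n < 2 or n % 2:
        raise ValueError("profile must have an even number of cells")
    Tmax = T.max()
    if Tmax <= 0:
        return 0.0
    dx = params.L / n
    half = n // 2
    return float((T[:half].sum() - T[half:].sum()) * dx / ((params.L / 2) * Tmax))


def viability_boundary(params: ModelParams) -> float:
    """The W value below which the organism is inviable: exp(F_star/kappa_F)."""
    if params.kappa_F == 0:
        return 0.0
    return float(np.exp(params.F_star / params.kappa_F))


def log_fitness(W: float, params: ModelParams) -> float:
    """Truncated log fitness: kappa_F ln W above F_star, else -inf.

    W <= 0 (no anterior bias at all) is inviable outright.  With kappa_F = 0
    selection is off and F = 0 for every genotype.
    """
    if W > 1 + 1e-9:
        raise ValueError("W cannot exceed 1")
    if params.kappa_F == 0:
        return 0.0
    if W <= 0:
        return -np.inf
    F = params.kappa_F * np.log(min(W, 1.0))
    return F if F > params.F_star else -np.inf


def fitness(genome: Genome, params: ModelParams) -> float:
    """Convenience: genome -> profile -> W -> truncated log fitness F."""
    W = patterning_score(expression_profile(genome, params), params)
    return log_fitness(W, params)
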