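"""Genotype-phenotype map: energies, occupancy, patterning score, fitness."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dsdrift import _kernels, gpmap
from dsdrift.gpmap import (
    ExpressionProfile, Genome, ModelParams, binding_energies, cell_positions,
    expression_profile, fitness, hamming, log_fitness, morphogen_profile,
    occupancy_weights, patterning_score, promoter_occupancy,
    protein_dna_energy, protein_protein_energy, reverse_face,
    viability_boundary,
)


@pytest.mark.parametrize("a, b, expected", [
    ("00000", "00000", 0),
    ("10101", "01010", 5),
    ("1100110011", "1100110000", 2),
])
def test_hamming_examples(a, b, expected):
    assert hamming(a, b) == expected
    assert hamming(b, a) == expected  # symmetric


def test_hamming_rejects_length_mismatch():
    with pytest.raises(ValueError):
        hamming("0101", "01")


class TestProteinDNA:
    def test_examples(self, params):
        assert protein_dna_energy("0" * 10, "0" * 10, params) == 0.0
        assert protein_dna_energy("0" * 10, "1" * 10, params) == 20.0
        assert protein_dna_energy("1110000000", "0000000000", params) == 6.0

    def test_lattice_values(self, params, rng):
        allowed = {params.eps_pd * k for k in range(params.ell_pd + 1)}
        for _ in range(50):
            a = rng.integers(0, 2, 10)
            b = rng.integers(0, 2, 10)
            assert protein_dna_energy(a, b, params) in allowed

    def test_length_check(self, params):
        with pytest.raises(ValueError):
            protein_dna_energy("01", "01", params)


class TestProteinProtein:
    def test_reverse_contact_geometry(self, params):
        a = "10010"
        b = "".join(reversed(a))  # a equals reverse(b): all 5 contacts made
        assert protein_protein_energy(a, b, params) == -5.0
        assert protein_protein_energy("00000", "00000"[::-1].replace("0", "1"),
                                      params) == 0.0

    def test_symmetric_in_partners(self, params, rng):
        for _ in range(20):
            a = rng.integers(0, 2, 5)
            b = rng.integers(0, 2, 5)
            assert protein_protein_energy(a, b, params) == \
                protein_protein_energy(b, a, params)

    def test_homodimer_not_automatically_maximal(self, params):
        # the chirality (centre reversal) means a face paired with itself is
        # only maximally stable if it is a palindrome
        face = "10000"
        e = protein_protein_energy(face, face, params)
        assert e == params.eps_pp * (5 - hamming(face, reverse_face(face)))
        assert e > params.eps_pp * params.ell_pp  # strictly weaker than -5
        palindrome = "10101"
        assert protein_protein_energy(palindrome, palindrome, params) == -5.0

    def test_lattice_values(self, params, rng):
        allowed = {params.eps_pp * k for k in range(params.ell_pp + 1)}
        for _ in range(50):
            e = protein_protein_energy(rng.integers(0, 2, 5),
                                       rng.integers(0, 2, 5), params)
            assert e in allowed


class TestMorphogenProfile:
    def test_endpoints(self, params):
        alpha = 3.0
        L = params.L
        M0 = params.conc_M0
        assert morphogen_profile(L, alpha, params) == \
            pytest.approx(M0 / np.sinh(alpha * L))
        assert morphogen_profile(0.0, alpha, params) == \
            pytest.approx(M0 / np.tanh(alpha * L))

    def test_strictly_decreasing_and_positive(self, params):
        x = np.linspace(0, params.L, 200)
        M = morphogen_profile(x, 7.0, params)
        assert np.all(M > 0)
        assert np.all(np.diff(M) < 0)

    def test_exponential_limit(self, params):
        # for alpha*L >> 1 the profile approaches M0 exp(-alpha x)
        alpha = 10.0
        # away from the far boundary, where the reflected mode ~e^{-2a(L-x)}
        # is below the tolerance
        x = np.linspace(0.05, 0.6, 20)
        M = morphogen_profile(x, alpha, params)
        approx = params.conc_M0 * np.exp(-alpha * x)
        assert np.allclose(M, approx, rtol=1e-3)

    def test_rejects_nonpositive_alpha(self, params):
        with pytest.raises(ValueError):
            morphogen_profile(0.5, 0.0, params)


class TestPromoterOccupancy:
    def _random_energies(self, rng, params):
        g = Genome.random(rng, params)
        return binding_energies(g, params)

    def test_nine_state_probabilities_sum_to_one(self, params, rng):
        for _ in range(30):
            e = self._random_energies(rng, params)
            w = occupancy_weights(e, rng.normal(), rng.normal())
            assert (w / w.sum()).sum() == pytest.approx(1.0, abs=1e-12)

    def test_matches_literal_enumeration(self, params, rng):
        # independent oracle: write the nine Boltzmann terms out longhand
        for _ in range(100):
            e = self._random_energies(rng, params)
            mu_R, mu_M = rng.normal(size=2)
            E = {"0": 0.0, "R": None, "M": None}
            EP = {"0": 0.0, "R": e.E_RP, "M": e.E_MP}
            EB = {"0": 0.0, "R": e.E_RB, "M": e.E_MB}
            mu = {"0": 0.0, "R": mu_R, "M": mu_M}
            Et = {("R", "M"): e.Etilde_RM, ("M", "R"): e.Etilde_RM,
                  ("R", "R"): e.Etilde_RR, ("M", "M"): e.Etilde_MM}
            Z = num = 0.0
            for sP in "0RM":
                for sB in "0RM":
                    w = np.exp(-(EP[sP] + EB[sB] - mu[sP] - mu[sB]
                                 + Et.get((sP, sB), 0.0)))
                    Z += w
                    if sP == "R":
                        num += w
            assert promoter_occupancy(e, mu_R, mu_M) == \
                pytest.approx(num / Z, rel=1e-14)

    def test_unbindable_promoter_empties(self, params, rng):
        strong = params.replace(eps_pd=200.0)
        g = Genome.random(rng, strong)
        g.g_r = 1 - g.g_P  # maximal mismatch everywhere
        g.g_m = 1 - g.g_P
        e = binding_energies(g, strong)
        assert promoter_occupancy(e, 0.0, 0.0) < 1e-200

    def test_reduces_to_two_state_without_morphogen(self):
        # mu_M -> -inf and no cooperativity: p = aR/(1+aR) with aR = e^{mu_R-E_RP}
        e = gpmap.EnergySet(E_RP=0.0, E_RB=20.0, E_MP=20.0, E_MB=0.0,
                            Etilde_RM=0.0, Etilde_RR=0.0, Etilde_MM=0.0)
        p = promoter_occupancy(e, 0.0, -1e9)
        aR, bR = 1.0, np.exp(-20.0)
        expected = (aR + aR * bR) / ((1 + aR) * (1 + bR))
        assert p == pytest.approx(expected, rel=1e-12)
        assert p == pytest.approx(0.5, rel=1e-6)

    @settings(max_examples=30, derandomize=True)
    @given(mu1=st.floats(-5, 5), dmu=st.floats(0.01, 5))
    def test_monotone_in_polymerase_potential(self, params, mu1, dmu):
        e = binding_energies(
            Genome.random(np.random.default_rng(7), params), params)
        assert promoter_occupancy(e, mu1 + dmu, 0.3) > \
            promoter_occupancy(e, mu1, 0.3)


class TestExpressionProfile:
    def test_no_morphogen_binding_gives_flat_profile(self, params):
        g = Genome(g_R="00000", g_r="0000000000", g_M="11111",
                   g_m="1111111111", g_P="0000000000", g_B="0000000000",
                   alpha=5.0)
        # g_m mismatches both sites maximally; residual M binding ~ e^{-20}
        prof = expression_profile(g, params)
        assert np.ptp(prof.T) < 1e-6

    def test_invariant_under_reversing_all_protein_faces(self, params, rng):
        g = Genome.random(rng, params)
        g2 = g.copy()
        g2.g_R = g.g_R[::-1].copy()
        g2.g_M = g.g_M[::-1].copy()
        assert np.allclose(expression_profile(g, params).T,
                           expression_profile(g2, params).T, rtol=1e-14)

    def test_evolved_genome_is_an_anterior_switch(self, params, evolved_genome):
        prof = expression_profile(evolved_genome, params)
        half = params.n_cells // 2
        assert prof.T[:half].mean() > 2 * prof.T[half:].mean()
        # transition (half-maximum crossing) lies in the middle of the embryo
        crossing = prof.x[np.argmin(np.abs(prof.T - prof.T.max() / 2))]
        assert 0.2 < crossing < 0.8

    def test_kernel_matches_reference(self, params, rng):
        for _ in range(20):
            g = Genome.random(rng, params)
            W_ref = patterning_score(expression_profile(g, params), params)
            W_fast = _kernels.w_of_bits(g.bits, g.alpha,
                                        *_kernels.kernel_args(params))
            assert W_fast == pytest.approx(W_ref, abs=1e-12)


class TestPatterningScore:
    def _profile(self, T, params):
        return ExpressionProfile(x=cell_positions(params), T=np.asarray(T))

    def test_ideal_step_scores_one(self, params):
        n = params.n_cells
        T = np.r_[np.full(n // 2, 0.8), np.zeros(n // 2)]
        W = patterning_score(self._profile(T, params), params)
        assert W == pytest.approx(1.0)
        assert log_fitness(W, params) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_profile_scores_zero(self, params):
        W = patterning_score(
            self._profile(np.full(params.n_cells, 0.5), params), params)
        assert W == 0.0
        assert log_fitness(W, params) == -np.inf

    def test_mirrored_step_scores_minus_one(self, params):
        n = params.n_cells
        T = np.r_[np.zeros(n // 2), np.full(n // 2, 0.8)]
        assert patterning_score(self._profile(T, params), params) == \
            pytest.approx(-1.0)

    def test_antisymmetric_under_mirror_and_bounded(self, params, rng):
        for _ in range(20):
            g = Genome.random(rng, params)
            prof = expression_profile(g, params)
            W = patterning_score(prof, params)
            assert abs(W) <= 1.0
            assert patterning_score(prof.mirrored(), params) == \
                pytest.approx(-W, abs=1e-14)

    def test_zero_profile_defined_as_zero(self, params):
        W = patterning_score(
            self._profile(np.zeros(params.n_cells), params), params)
        assert W == 0.0

    def test_resolution_independence(self, params, evolved_genome):
        W100 = patterning_score(expression_profile(evolved_genome, params),
                                params)
        fine = params.replace(n_cells=400)
        W400 = patterning_score(expression_profile(evolved_genome, fine), fine)
        assert abs(W100 - W400) < 1e-3


class TestLogFitness:
    def test_viability_boundary_location(self, params):
        Wb = viability_boundary(params)
        assert Wb == pytest.approx(np.exp(-1.6))
        assert round(Wb, 4) == 0.2019
        assert log_fitness(Wb * 0.999, params) == -np.inf
        assert np.isfinite(log_fitness(Wb * 1.001, params))

    def test_examples(self, params):
        assert log_fitness(1.0, params) == 0.0
        F = log_fitness(0.6, params)
        assert F == pytest.approx(params.kappa_F * np.log(0.6))
        assert F == pytest.approx(-5.108e-4, rel=1e-3)
        assert F > params.F_star

    def test_monotone_nondecreasing(self, params):
        W = np.linspace(-0.5, 1.0, 400)
        F = [log_fitness(w, params) for w in W]
        assert all(b >= a for a, b in zip(F, F[1:]))

    def test_neutral_mode(self, params):
        neutral = params.replace(kappa_F=0.0)
        assert log_fitness(0.9, neutral) == 0.0
        assert log_fitness(-0.3, neutral) == 0.0


class TestGenome:
    def test_serialization_round_trip(self, params, rng):
        g = Genome.random(rng, params)
        assert Genome.from_json(g.to_json()) == g

    def test_bits_round_trip(self, params, rng):
        g = Genome.random(rng, params)
        assert Genome.from_bits(g.bits, g.alpha, params) == g

    def test_rejects_bad_alpha(self):
        with pytest.raises(ValueError):
            Genome(g_R="00000", g_r="0" * 10, g_M="00000", g_m="0" * 10,
                   g_P="0" * 10, g_B="0" * 10, alpha=-1.0)

    def test_validate_lengths(self, params):
        g = Genome(g_R="000", g_r="0" * 10, g_M="00000", g_m="0" * 10,
                   g_P="0" * 10, g_B="0" * 10, alpha=1.0)
        with pytest.raises(ValueError):
            g.validate(params)


def test_model_params_validation():
    with pytest.raises(ValueError):
        ModelParams(eps_pp=1.0)
    with pytest.raises(ValueError):
        ModelParams(eps_pd=-2.0)
    with pytest.raises(ValueError):
        ModelParams(n_cells=99)
    with pytest.raises(ValueError):
        ModelParams(F_star=0.1)
    p = ModelParams()
    assert p.ell_genome == 60
    assert p.n_binary_sites == 50
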