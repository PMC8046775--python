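"""Choice measurement, collapse, decay timing and the strength read-out."""

import numpy as np
import pytest

from openpref.dynamics import (ModelParams, PreferenceScale, build_generator,
                               evolve, initial_state, validate_density)
from openpref.measurement import (choice_probabilities, choice_projectors,
                                  collapse, effective_duration,
                                  expected_strength, rating_distribution,
                                  rating_projector, strength_map)

from conftest import random_params


def diag_rho(pops):
    pops = np.asarray(pops, dtype=float)
    return np.diag(pops / pops.sum()).astype(complex)


class TestProjectors:
    @pytest.mark.parametrize("n", [3, 5, 21])
    def test_squares_sum_to_identity(self, n):
        PL, PR = choice_projectors(PreferenceScale(n))
        assert np.allclose(PL @ PL + PR @ PR, np.eye(n))

    def test_midpoint_carries_sqrt_half(self):
        PL, PR = choice_projectors(PreferenceScale(5))
        assert PL[2, 2] == PR[2, 2] == pytest.approx(np.sqrt(0.5))
        assert np.allclose(np.diag(PL), [1, 1, np.sqrt(0.5), 0, 0])

    def test_rating_projector_is_single_level(self):
        P = rating_projector(PreferenceScale(5), 4)
        assert P[3, 3] == 1.0 and P.sum() == 1.0
        with pytest.raises(ValueError):
            rating_projector(PreferenceScale(5), 6)


class TestChoiceProbabilities:
    def test_symmetric_state_is_even_odds(self):
        rho = diag_rho([1, 2, 5, 2, 1])
        pL, pR = choice_probabilities(rho, PreferenceScale(5))
        assert pL == pytest.approx(0.5) and pR == pytest.approx(0.5)

    def test_state_on_top_level_always_right(self):
        rho = diag_rho([0, 0, 0, 0, 1])
        pL, pR = choice_probabilities(rho, PreferenceScale(5))
        assert (pL, pR) == (0.0, 1.0)

    def test_midpoint_mass_splits_evenly(self):
        rho = diag_rho([0, 0, 1, 0, 0])
        pL, pR = choice_probabilities(rho, PreferenceScale(5))
        assert pL == pytest.approx(0.5) and pR == pytest.approx(0.5)

    def test_probabilities_sum_to_one_for_random_states(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            p = random_params(rng, n=7)
            rho = evolve(initial_state(p), build_generator(p), 3.0)
            pL, pR = choice_probabilities(rho, p.scale)
            assert pL + pR == pytest.approx(1.0, abs=1e-10)


class TestCollapse:
    def test_collapse_is_idempotent_off_the_midpoint(self):
        """The choice operators are projectors away from the midpoint level
        (where they carry sqrt(1/2) rather than 1), so repeated collapse is
        exactly idempotent for states without midpoint mass."""
        rng = np.random.default_rng(1)
        p = random_params(rng, n=5)
        rho = evolve(initial_state(p), build_generator(p), 2.0)
        rho = np.asarray(rho).copy()
        rho[2, :] = 0.0
        rho[:, 2] = 0.0
        rho /= np.real(np.trace(rho))
        once = collapse(rho, "R", p.scale)
        twice = collapse(once, "R", p.scale)
        assert np.abs(once - twice).max() < 1e-12

    def test_repeated_collapse_drains_midpoint_mass(self):
        """With midpoint support, each application of the sqrt(1/2)-weighted
        choice operator halves the midpoint population before renormalising,
        so repeated collapse converges rather than being idempotent."""
        rho = diag_rho([0.0, 0.0, 0.5, 0.25, 0.25])
        out = collapse(rho, "R", PreferenceScale(5))
        assert np.real(out[2, 2]) == pytest.approx(0.25 / 0.75)
        again = collapse(out, "R", PreferenceScale(5))
        assert np.real(again[2, 2]) < np.real(out[2, 2])

    def test_classical_state_renormalises_selected_half(self):
        # diagonal 3-level state (0.3, 0.4, 0.3); right collapse keeps the
        # top level plus half of the midpoint mass
        rho = diag_rho([0.3, 0.4, 0.3])
        out = collapse(rho, "R", PreferenceScale(3))
        expect = np.diag([0.0, 0.2, 0.3]) / 0.5
        assert np.allclose(out, expect)
        validate_density(out)

    def test_collapse_preserves_density_invariants(self):
        rng = np.random.default_rng(2)
        for _ in range(4):
            p = random_params(rng, n=9)
            rho = evolve(initial_state(p), build_generator(p), 4.0)
            for resp in ("L", "R"):
                validate_density(collapse(rho, resp, p.scale), tol=1e-8)

    def test_zero_probability_branch_raises(self):
        rho = diag_rho([0, 0, 0, 0, 1])
        with pytest.raises(ZeroDivisionError):
            collapse(rho, "L", PreferenceScale(5))

    def test_markov_pooled_collapse_equals_no_measurement(self):
        """Chapman-Kolmogorov: at alpha=1 the response-weighted mixture of
        collapsed branches evolves to the same level populations as the
        untouched state (classical measurement invariance)."""
        rng = np.random.default_rng(3)
        p = random_params(rng, n=7, alpha=1.0)
        gen = build_generator(p)
        rho1 = evolve(initial_state(p), gen, 5.0)
        pL, pR = choice_probabilities(rho1, p.scale)
        for t in (1.0, 10.0):
            pooled = pL * evolve(collapse(rho1, "L", p.scale), gen, t) \
                + pR * evolve(collapse(rho1, "R", p.scale), gen, t)
            plain = evolve(rho1, gen, t)
            assert np.abs(np.diag(pooled) - np.diag(plain)).max() < 1e-8

    def test_quantum_pooled_collapse_differs(self, exp1_params):
        """At alpha=0 with coherent dynamics, measuring the choice changes
        the pooled later populations (interference)."""
        p = exp1_params.replace(alpha=0.0)
        gen = build_generator(p)
        rho1 = evolve(initial_state(p), gen, 5.0)
        pL, pR = choice_probabilities(rho1, p.scale)
        t = 6.0
        pooled = pL * evolve(collapse(rho1, "L", p.scale), gen, t) \
            + pR * evolve(collapse(rho1, "R", p.scale), gen, t)
        plain = evolve(rho1, gen, t)
        assert np.abs(np.real(np.diag(pooled) - np.diag(plain))).max() > 1e-3


class TestEffectiveDuration:
    def test_no_decay_returns_raw_delay(self):
        assert effective_duration(17.0, 5.0, 0.0) == pytest.approx(12.0)

    def test_decay_factor_at_45s_delay(self):
        # 45 * exp(-0.014 * 45) = 23.97 s of effective evolution
        tau = effective_duration(50.0, 5.0, 0.014)
        assert tau == pytest.approx(45 * np.exp(-0.63), rel=1e-12)
        assert tau == pytest.approx(23.97, abs=0.01)

    def test_bounded_by_inverse_lambda_e(self):
        lam = 0.3
        taus = [effective_duration(5.0 + d, 5.0, lam)
                for d in np.linspace(0.01, 60, 200)]
        assert max(taus) <= 1.0 / (lam * np.e) + 1e-12

    def test_literal_convention_floors_at_zero(self):
        # strong decay: the printed rescaling puts the rating time before
        # the first response; the literal mode floors at zero
        assert effective_duration(25.0, 5.0, 0.458, "literal") == 0.0
        # mild decay: literal uses the absolute clock
        val = effective_duration(13.0, 5.0, 0.014, "literal")
        assert val == pytest.approx(13.0 * np.exp(-0.014 * 8.0) - 5.0)

    def test_reversed_times_rejected(self):
        with pytest.raises(ValueError):
            effective_duration(4.0, 5.0, 0.1)


class TestRatingAndStrength:
    def test_rating_distribution_examples(self):
        assert np.allclose(rating_distribution(diag_rho([0, 0, 1])), [0, 0, 1])
        assert np.allclose(rating_distribution(diag_rho([1, 1, 1])),
                           np.full(3, 1 / 3))

    def test_rating_distribution_normalised_for_evolved_states(self):
        rng = np.random.default_rng(4)
        p = random_params(rng, n=9)
        rho = evolve(initial_state(p), build_generator(p), 7.0)
        assert rating_distribution(rho).sum() == pytest.approx(1.0, abs=1e-10)

    def test_strength_of_midpoint_state_is_half_scale(self):
        smap = strength_map(PreferenceScale(21), 30.0)
        rho = np.zeros((21, 21), dtype=complex)
        rho[10, 10] = 1.0
        assert expected_strength(rho, smap) == pytest.approx(15.0)

    def test_strength_of_level_16_on_30_scale(self):
        smap = strength_map(PreferenceScale(21), 30.0)
        rho = np.zeros((21, 21), dtype=complex)
        rho[15, 15] = 1.0
        assert expected_strength(rho, smap) == \
            pytest.approx(30 / (1 + np.exp(-5)), rel=1e-12)
        assert expected_strength(rho, smap) == pytest.approx(29.80, abs=0.01)

    def test_uniform_state_gives_average_of_map(self):
        smap = strength_map(PreferenceScale(5), 10.0)
        rho = diag_rho(np.ones(5))
        assert expected_strength(rho, smap) == pytest.approx(smap.mean())

    def test_strength_map_shape(self):
        smap = strength_map(PreferenceScale(9), 10.0)
        assert smap[4] == pytest.approx(5.0)        # midpoint -> S_max / 2
        assert np.allclose(smap, smap[::-1])        # symmetric about mid
        assert (np.diff(smap[4:]) > 0).all()        # increasing outward
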