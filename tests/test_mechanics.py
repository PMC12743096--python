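"""Cell dynamics: forces, motility, contact guidance, proliferation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fibreguide import (CellPopulation, ModelParams, apply_contact_guidance,
                        attempt_divisions, count_close_neighbours,
                        division_probability, euler_step_positions,
                        guidance_weight, lj_force_magnitude,
                        min_image_displacement, net_pairwise_force,
                        random_motility_force, uniform_fibre_field,
                        packed_disc_cells)
from fibreguide.mechanics import _pairwise_forces

EQ_SPACING = 2.0 ** (1.0 / 6.0) * 12.0  # zero-force separation, um


def make_population(positions, L=360.0, **kw):
    return CellPopulation(positions, L, history_steps=300, **kw)


def empty_field(params):
    nx, ny = params.grid_shape
    return uniform_fibre_field(0.0, 0.0, 0.0, nx, ny, params.delta)


class TestMinImage:
    def test_wraparound_corner(self):
        np.testing.assert_allclose(
            min_image_displacement((1.0, 1.0), (359.0, 359.0), 360.0),
            (2.0, 2.0))

    def test_identical_points(self):
        np.testing.assert_allclose(
            min_image_displacement((5.0, 5.0), (5.0, 5.0), 360.0), (0.0, 0.0))

    def test_matches_brute_force_over_images(self, rng):
        """Oracle: the displacement of smallest norm over the 3x3 tiles."""
        L = 100.0
        for _ in range(50):
            xi, xj = rng.uniform(0, L, 2), rng.uniform(0, L, 2)
            got = min_image_displacement(xi, xj, L)
            cands = [xi - xj + L * np.array([a, b])
                     for a in (-1, 0, 1) for b in (-1, 0, 1)]
            best = min(cands, key=lambda c: np.hypot(*c))
            assert np.hypot(*got) == pytest.approx(np.hypot(*best), abs=1e-9)


class TestLJForce:
    def test_zero_at_potential_minimum(self, params):
        assert lj_force_magnitude(EQ_SPACING, params) == pytest.approx(
            0.0, abs=1e-12)

    def test_zero_beyond_cutoff(self, params):
        assert lj_force_magnitude(37.0, params) == 0.0

    def test_value_at_18um(self, params):
        # independent scalar evaluation: 24*0.1*12^6*(2*12^6/18^13 - 1/18^7)
        s6 = 12.0 ** 6
        expected = 24.0 * 0.1 * s6 * (2.0 * s6 / 18.0 ** 13 - 18.0 ** -7)
        assert expected == pytest.approx(-9.65e-3, rel=1e-3)  # adhesion
        assert lj_force_magnitude(18.0, params) == pytest.approx(expected)

    def test_cap_active_near_contact(self, params):
        assert lj_force_magnitude(1e-3, params) == params.F0 == 2.4

    def test_rejects_nonpositive_separation(self, params):
        with pytest.raises(ValueError):
            lj_force_magnitude(0.0, params)

    def test_cap_leaves_adhesion_untouched(self, params):
        r = np.linspace(EQ_SPACING + 1e-9, 36.0, 50)
        f = lj_force_magnitude(r, params)
        assert np.all(f <= 0.0)  # adhesive branch, unaffected by the cap


class TestNetPairwiseForce:
    def test_isolated_cell(self, params):
        pop = make_population([(50.0, 50.0)])
        np.testing.assert_allclose(net_pairwise_force(0, pop, params),
                                   (0.0, 0.0))

    def test_equilibrium_pair(self, params):
        pop = make_population([(100.0, 100.0), (100.0 + EQ_SPACING, 100.0)])
        for i in (0, 1):
            np.testing.assert_allclose(net_pairwise_force(i, pop, params),
                                       (0.0, 0.0), atol=1e-12)

    def test_matches_double_loop_oracle(self, params, rng):
        """Vectorised sum equals a direct O(N^2) pure-Python loop."""
        pos = rng.uniform(140, 220, (5, 2))
        pop = make_population(pos)
        for i in range(5):
            expected = np.zeros(2)
            for j in range(5):
                if j == i:
                    continue
                dvec = min_image_displacement(pos[i], pos[j], 360.0)
                r = np.hypot(*dvec)
                expected += lj_force_magnitude(r, params) * dvec / r
            np.testing.assert_allclose(net_pairwise_force(i, pop, params),
                                       expected, atol=1e-12)

    def test_newton_third_law(self, params, rng):
        pos = rng.uniform(150, 210, (6, 2))
        forces = _pairwise_forces(pos, params)
        np.testing.assert_allclose(forces.sum(axis=0), (0.0, 0.0), atol=1e-12)

    def test_coincident_pair_gets_capped_random_kick(self, params, rng):
        pos = np.array([(50.0, 50.0), (50.0, 50.0)])
        forces = _pairwise_forces(pos, params, rng)
        assert np.hypot(*forces[0]) == pytest.approx(params.F0)
        np.testing.assert_allclose(forces[0], -forces[1])


class TestRandomMotility:
    def test_zero_diffusion(self, rng):
        p = ModelParams(D=0.0)
        np.testing.assert_array_equal(random_motility_force(p, rng),
                                      (0.0, 0.0))

    def test_component_variance(self, rng):
        p = ModelParams(D=0.3, dt=1.0)
        draws = np.array([random_motility_force(p, rng)
                          for _ in range(20000)])
        var = draws.var(axis=0)
        se = 0.6 * np.sqrt(2.0 / 20000)  # s.e. of a normal variance estimate
        assert np.all(np.abs(var - 0.6) < 3 * se)


class TestGuidanceWeight:
    def test_endpoints_exact(self, params):
        assert guidance_weight(0.0, params) == 0.0
        assert guidance_weight(1.0, params) == 1.0

    def test_value_at_half_maximal_fraction(self, params):
        # direct evaluation: the normalising shift puts Lambda(0.4)
        # slightly below one half
        assert guidance_weight(0.4, params) == pytest.approx(
            0.4998353, abs=1e-6)

    def test_strictly_increasing(self, params):
        x = np.linspace(0.0, 1.0, 201)
        lam = guidance_weight(x, params)
        assert np.all(np.diff(lam) > 0.0)

    def test_rejects_out_of_range(self, params):
        with pytest.raises(ValueError):
            guidance_weight(1.2, params)


class TestContactGuidance:
    def test_isotropic_field_leaves_vector_unchanged(self, params):
        b = np.array([0.3, -0.8])
        out = apply_contact_guidance((0.4, 0.0, 0.4), 0.8, b, params)
        np.testing.assert_allclose(out, b, atol=1e-12)

    def test_empty_field_leaves_vector_unchanged(self, params):
        b = np.array([1.0, 2.0])
        out = apply_contact_guidance((0.0, 0.0, 0.0), 0.0, b, params)
        np.testing.assert_allclose(out, b, atol=1e-12)

    def test_rank1_projection_rescaled(self, params):
        # fully aligned vertical fibres at saturation: b at 45 degrees
        # projects onto the vertical and is rescaled to |b|
        omega = (0.0, 0.0, 1.0)
        b = np.array([1.0, 1.0])
        out = apply_contact_guidance(omega, 1.0, b, params)
        np.testing.assert_allclose(out, (0.0, np.hypot(1, 1)), atol=1e-12)

    def test_perpendicular_degenerate_case(self, params):
        omega = (0.0, 0.0, 1.0)  # vertical rank-1, saturated
        out = apply_contact_guidance(omega, 1.0, np.array([1.0, 0.0]), params)
        np.testing.assert_allclose(out, (0.0, 0.0))

    def test_zero_vector_maps_to_zero(self, params):
        out = apply_contact_guidance((0.5, 0.0, 0.3), 0.8,
                                     np.zeros(2), params)
        np.testing.assert_array_equal(out, (0.0, 0.0))

    def test_length_preserved_many(self, params, rng):
        from conftest import random_psd_tensors
        oxx, oxy, oyy = random_psd_tensors(rng, 10000)
        b = rng.normal(0, 1, (10000, 2))
        for i in range(0, 10000, 97):
            out = apply_contact_guidance((oxx[i], oxy[i], oyy[i]),
                                         oxx[i] + oyy[i], b[i], params)
            assert np.hypot(*out) == pytest.approx(np.hypot(*b[i]),
                                                   abs=1e-12)

    def test_length_preserved_vectorised(self, params, rng):
        from conftest import random_psd_tensors
        from fibreguide.mechanics import _apply_guidance_many
        n = 10000
        oxx, oxy, oyy = random_psd_tensors(rng, n)
        b = rng.normal(0, 1, (n, 2))
        out = _apply_guidance_many(oxx, oxy, oyy,
                                   np.clip(oxx + oyy, 0, 1), b, params)
        np.testing.assert_allclose(np.hypot(out[:, 0], out[:, 1]),
                                   np.hypot(b[:, 0], b[:, 1]), atol=1e-12)

    @pytest.mark.parametrize("a,total", [(0.8, 1.0), (0.5, 0.6), (1.0, 0.9)])
    def test_output_angle_symmetric_about_90(self, params, a, total):
        """Bidirectional fibres: the response to vertical fibres is
        mirror-symmetric about 90 degrees of input angle."""
        l1 = total / (2.0 - a)
        l2 = l1 * (1.0 - a)
        omega = (l2, 0.0, l1)  # vertical major orientation
        angles = np.linspace(1.0, 89.0, 45)

        def out_angle(deg):
            b = np.array([np.cos(np.radians(deg)), np.sin(np.radians(deg))])
            o = apply_contact_guidance(omega, total, b, params)
            return np.degrees(np.arctan2(o[1], o[0]))

        for ang in angles:
            assert out_angle(90 + ang) == pytest.approx(
                180 - out_angle(90 - ang), abs=1e-9)


class TestEulerStep:
    def test_single_cell_no_noise_no_field_stays_put(self):
        p = ModelParams(D=0.0)
        pop = make_population([(100.0, 100.0)])
        euler_step_positions(pop, empty_field(p), p, np.random.default_rng(0))
        np.testing.assert_array_equal(pop.positions[0], (100.0, 100.0))

    def test_overlapping_pair_separates(self):
        p = ModelParams(D=0.0)
        gap0 = 10.0  # below the zero-force separation: repulsive branch
        pop = make_population([(100.0, 100.0), (100.0 + gap0, 100.0)])
        euler_step_positions(pop, empty_field(p), p, np.random.default_rng(0))
        gap = np.hypot(*(pop.positions[1] - pop.positions[0]))
        assert gap > gap0

    def test_pair_centre_of_mass_fixed(self):
        """Newton-symmetric forces keep an interacting pair's centre of
        mass fixed when motility is off and no fibres are present."""
        p = ModelParams(D=0.0)
        pop = make_population([(100.0, 100.0), (110.0, 104.0)])
        com0 = pop.unwrapped.mean(axis=0)
        f = empty_field(p)
        g = np.random.default_rng(0)
        for _ in range(50):
            euler_step_positions(pop, f, p, g)
        np.testing.assert_allclose(pop.unwrapped.mean(axis=0), com0,
                                   atol=1e-9)

    def test_matches_reference_step(self, params, rng):
        """One engine step equals a per-cell reference computation."""
        from fibreguide.mechanics import _pairwise_forces
        pos = rng.uniform(140, 220, (8, 2))
        f = uniform_fibre_field(0.7, 0.6, 30.0, *params.grid_shape,
                                params.delta)
        pop = make_population(pos.copy())
        seed_rng = np.random.default_rng(777)
        xi = seed_rng.normal(0, np.sqrt(2 * params.D / params.dt), (8, 2))
        forces = _pairwise_forces(pos, params)
        expected = np.empty_like(pos)
        for i in range(8):
            omega = f.sample(pos[i])
            tf = min(max(omega[0] + omega[2], 0.0), 1.0)
            v = apply_contact_guidance(omega, tf, xi[i] + forces[i], params)
            expected[i] = pos[i] + params.dt * v
        pop2 = make_population(pos.copy())
        euler_step_positions(pop2, f, params, np.random.default_rng(777))
        np.testing.assert_allclose(pop2.unwrapped, expected, atol=1e-10)

    def test_wrapped_unwrapped_consistency(self, rng):
        p = ModelParams(D=2.0)
        pop = make_population(rng.uniform(0, 360, (20, 2)))
        f = empty_field(p)
        for _ in range(200):
            euler_step_positions(pop, f, p, rng)
        diff = (pop.unwrapped - pop.positions) / 360.0
        np.testing.assert_allclose(diff, np.round(diff), atol=1e-9)


class TestFreeDiffusion:
    def test_msd_slope_is_4D(self):
        """No fibres, no interactions, no division: MSD(t) = 4 D t."""
        from fibreguide import msd
        p = ModelParams(D=0.3, epsilon=0.0, Delta0=np.inf, m=10.0)
        rng = np.random.default_rng(2024)
        pop = CellPopulation(rng.uniform(0, 360, (500, 2)), 360.0,
                             history_steps=10)
        f = empty_field(p)
        hist = [pop.unwrapped.copy()]
        for _ in range(500):
            euler_step_positions(pop, f, p, rng)
            hist.append(pop.unwrapped.copy())
        curve = msd(np.stack(hist))
        t = np.arange(501) * p.dt
        slope = (t @ curve) / (t @ t)
        assert slope == pytest.approx(4 * p.D, rel=0.05)


class TestProliferation:
    def test_probability_values(self, params):
        assert division_probability(6, params) == 0.0
        assert division_probability(7, params) == 0.0
        assert division_probability(0, params) == pytest.approx(1.0 / 1440.0)

    @settings(derandomize=True, max_examples=30)
    @given(beta=st.integers(0, 12))
    def test_probability_nonincreasing(self, beta):
        p = ModelParams()
        assert division_probability(beta + 1, p) <= division_probability(
            beta, p)

    def test_hexagonal_neighbour_count(self, params):
        pos = packed_disc_cells(7, params.sigma, (180.0, 180.0))
        pop = make_population(pos)
        assert count_close_neighbours(0, pop, params) == 6  # centre cell

    def test_neighbour_count_matches_brute_force(self, params, rng):
        pos = rng.uniform(100, 260, (30, 2))
        pop = make_population(pos)
        rc = params.repulsion_range
        for i in range(30):
            expected = sum(
                1 for j in range(30) if j != i and
                np.hypot(*min_image_displacement(pos[i], pos[j], 360.0))
                <= rc + 1e-9)
            assert count_close_neighbours(i, pop, params) == expected

    def test_no_divisions_with_infinite_cycle(self, rng):
        p = ModelParams(Delta0=np.inf)
        pop = make_population([(50.0, 50.0)])
        attempt_divisions(pop, p, rng)
        assert pop.n == 1

    def test_isolated_cell_division_frequency(self):
        """Monte-Carlo: an isolated cell divides at rate dt/Delta0."""
        p = ModelParams()
        rng = np.random.default_rng(99)
        trials = 100_000
        pexp = 1.0 / 1440.0
        divisions = 0
        pop = make_population([(180.0, 180.0)])
        for _ in range(trials):
            attempt_divisions(pop, p, rng)
            if pop.n == 2:
                divisions += 1
                pop = make_population([(180.0, 180.0)])
        se = np.sqrt(pexp * (1 - pexp) / trials)
        assert abs(divisions / trials - pexp) < 3 * se

    def test_daughter_distance_and_history(self, params):
        rng = np.random.default_rng(0)
        pop = make_population([(180.0, 180.0)])
        while pop.n == 1:
            attempt_divisions(pop, params, rng)
        gap = np.hypot(*(pop.unwrapped[1] - pop.unwrapped[0]))
        assert gap == pytest.approx(params.sigma / 2.0)
        mem = pop.velocity_memory(params.m)
        assert mem.window_min[1] == 0.0  # newborn: empty averaging window

    def test_daughters_do_not_divide_in_birth_step(self):
        # certain division: every cell with beta < 6 divides this sweep
        p = ModelParams(Delta0=1.0, dt=1.0)
        pop = make_population([(100.0, 100.0)])
        attempt_divisions(pop, p, np.random.default_rng(1))
        assert pop.n == 2  # parent divided once; daughter waited
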