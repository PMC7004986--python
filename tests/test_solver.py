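"""Inverse-solver unit tests: propagation, energy, objective, small solves.

The heavier closed-form recovery experiments (translation action, phantom
discrimination) live in the acceptance suite; here every instance is small.
"""

import numpy as np
import pytest

from romtflow.grid import DiffusionSpec, ImageGrid, ScalarField, VectorField, implicit_diffuse
from romtflow.phantoms import center_of_mass, gaussian_blob
from romtflow.preprocess import DensitySeries
from romtflow.solver import (
    RomtConfig,
    forward_propagate,
    objective,
    objective_gradient,
    solve_pair,
    solve_series,
    transport_energy,
)

from conftest import random_density


def const_velocity(grid, vec):
    comps = np.zeros((3, *grid.dims))
    for c in range(3):
        comps[c] = vec[c]
    return VectorField(grid, comps)


class TestForwardPropagate:
    def test_identity_when_no_motion_no_diffusion(self, rng, grid6):
        mu0 = random_density(grid6, rng)
        cfg = RomtConfig(sigma2=0.0, n_steps=3)
        mus = forward_propagate(mu0, [VectorField.zeros(grid6)] * 3, cfg)
        assert len(mus) == 4
        for m in mus:
            assert np.allclose(m.values, mu0.values)

    def test_pure_diffusion_matches_repeated_implicit_steps(self, rng, grid6):
        mu0 = random_density(grid6, rng)
        cfg = RomtConfig(sigma2=0.3, n_steps=4)
        mus = forward_propagate(mu0, [VectorField.zeros(grid6)] * 4, cfg)
        expect = mu0
        for n in range(4):
            expect = implicit_diffuse(expect, DiffusionSpec(0.3), cfg.dt)
            assert np.allclose(mus[n + 1].values, expect.values, atol=1e-10)
        assert mus[-1].values.sum() == pytest.approx(mu0.values.sum(), rel=1e-10)

    def test_constant_velocity_displaces_blob_center(self):
        grid = ImageGrid((20, 12, 12))
        mu0 = gaussian_blob(grid, (6.0, 5.5, 5.5), sd=2.0)
        cfg = RomtConfig(sigma2=0.0, n_steps=4)
        v = const_velocity(grid, (3.0, 0.0, 0.0))
        mus = forward_propagate(mu0, [v] * 4, cfg)
        com = center_of_mass(mus[-1])
        assert np.allclose(com, [9.0, 5.5, 5.5], atol=0.25)


class TestEnergyAndObjective:
    def test_zero_velocity_zero_energy(self, rng, grid6):
        mus = [random_density(grid6, rng) for _ in range(3)]
        cfg = RomtConfig(n_steps=2)
        vs = [VectorField.zeros(grid6)] * 2
        assert transport_energy(mus, vs, cfg) == 0.0

    def test_single_cell_direct_evaluation(self):
        # 1/2 * dt * dx^3 * mu * |v|^2 with dt=1, dx=1, mu=2, v=(1,0,0)
        grid = ImageGrid((1, 1, 1))
        cfg = RomtConfig(n_steps=1)
        mus = [ScalarField(grid, np.array([[[2.0]]]))] * 2
        vs = [const_velocity(grid, (1.0, 0.0, 0.0))]
        assert transport_energy(mus, vs, cfg) == pytest.approx(1.0)

    def test_quadratic_in_velocity(self, rng, grid6):
        mus = [random_density(grid6, rng) for _ in range(3)]
        cfg = RomtConfig(n_steps=2)
        vs = [VectorField(grid6, rng.normal(size=(3, *grid6.dims))) for _ in range(2)]
        v2 = [VectorField(grid6, 2 * v.components) for v in vs]
        e1 = transport_energy(mus, vs, cfg)
        assert transport_energy(mus, v2, cfg) == pytest.approx(4 * e1, rel=1e-12)

    def test_negative_density_rejected(self, grid6):
        cfg = RomtConfig(n_steps=1)
        bad = ScalarField(grid6, np.full(grid6.dims, -1.0))
        with pytest.raises(ValueError):
            transport_energy([bad, bad], [VectorField.zeros(grid6)], cfg)

    def test_objective_zero_at_fixed_point(self, rng, grid6):
        mu = random_density(grid6, rng)
        cfg = RomtConfig(sigma2=0.0, n_steps=2)
        J, terms = objective([VectorField.zeros(grid6)] * 2, mu, mu, cfg)
        assert J == pytest.approx(0.0, abs=1e-12)

    def test_objective_misfit_only_when_static(self, rng, grid6):
        mu0 = random_density(grid6, rng)
        muf = random_density(grid6, rng)
        cfg = RomtConfig(sigma2=0.0, xi=7.0, psi=2.0, n_steps=2)
        J, terms = objective([VectorField.zeros(grid6)] * 2, mu0, muf, cfg)
        beta = cfg.xi * grid6.n_cells / cfg.psi
        expected = beta * float(((mu0.values - muf.values) ** 2).sum())
        assert terms["transport"] == 0.0
        assert J == pytest.approx(expected, rel=1e-12)

    def test_gradient_matches_finite_differences(self, rng, grid6):
        """Adjoint gradient vs central differences on a random small instance."""
        mu0 = random_density(grid6, rng, 0.1, 1.0)
        muf = random_density(grid6, rng, 0.1, 1.0)
        cfg = RomtConfig(sigma2=0.02, xi=1.0, n_steps=2)
        # offsets inside (0, 1/2) voxel keep positions away from stencil kinks
        vs = [
            VectorField(grid6, rng.uniform(0.05, 0.45, (3, *grid6.dims))
                        * rng.choice([-1.0, 1.0], (3, *grid6.dims)))
            for _ in range(2)
        ]
        J, _, grad = objective_gradient(vs, mu0, muf, cfg)
        h = 1e-6
        for n, c, i in [(0, 0, 17), (0, 2, 100), (1, 1, 55), (1, 0, 200)]:
            vp = [VectorField(grid6, v.components.copy()) for v in vs]
            vm = [VectorField(grid6, v.components.copy()) for v in vs]
            vp[n].components.reshape(3, -1)[c, i] += h
            vm[n].components.reshape(3, -1)[c, i] -= h
            fd = (objective(vp, mu0, muf, cfg)[0] - objective(vm, mu0, muf, cfg)[0]) / (2 * h)
            assert grad[n, c, i] == pytest.approx(fd, rel=1e-4)


class TestSolvePair:
    def test_identical_images_need_no_transport(self, rng):
        grid = ImageGrid((8, 8, 8))
        mu = gaussian_blob(grid, (3.5, 3.5, 3.5), sd=1.5)
        cfg = RomtConfig(sigma2=0.0, n_steps=3, max_gn_iters=10)
        sol = solve_pair(mu, mu, cfg)
        vmax = max(float(np.abs(v.components).max()) for v in sol.velocities)
        assert vmax < 1e-6
        assert sol.energy["transport"] < 1e-10

    def test_interpolant_mass_constant(self, rng):
        grid = ImageGrid((10, 10, 10))
        mu0 = gaussian_blob(grid, (4.0, 4.5, 4.5), sd=1.5)
        muf = gaussian_blob(grid, (5.5, 4.5, 4.5), sd=1.5)
        cfg = RomtConfig(sigma2=0.01, n_steps=3, max_gn_iters=6)
        sol = solve_pair(mu0, muf, cfg)
        masses = [m.values.sum() for m in sol.interpolants]
        assert np.allclose(masses, masses[0], rtol=1e-8)
        assert all(m.values.min() >= 0 for m in sol.interpolants)

    def test_objective_monotone_over_accepted_iterates(self):
        grid = ImageGrid((10, 10, 10))
        mu0 = gaussian_blob(grid, (4.0, 4.5, 4.5), sd=1.5)
        muf = gaussian_blob(grid, (6.0, 4.5, 4.5), sd=1.5)
        cfg = RomtConfig(sigma2=0.0, n_steps=3, max_gn_iters=8)
        sol = solve_pair(mu0, muf, cfg)
        objs = [h["objective"] for h in sol.convergence]
        assert all(b <= a + 1e-12 for a, b in zip(objs, objs[1:]))

    def test_deterministic_bitwise(self):
        grid = ImageGrid((8, 8, 8))
        mu0 = gaussian_blob(grid, (3.0, 3.5, 3.5), sd=1.2)
        muf = gaussian_blob(grid, (4.5, 3.5, 3.5), sd=1.2)
        cfg = RomtConfig(sigma2=0.005, n_steps=2, max_gn_iters=5)
        s1 = solve_pair(mu0, muf, cfg)
        s2 = solve_pair(mu0, muf, cfg)
        for a, b in zip(s1.velocities, s2.velocities):
            assert np.array_equal(a.components, b.components)
        assert s1.energy == s2.energy


class TestSolveSeries:
    def _series(self, frames, grid):
        return DensitySeries(
            frames=frames, times=np.arange(len(frames), dtype=float),
            baseline_count=1, units="normalized",
        )

    def test_static_series_yields_zero_velocity(self):
        grid = ImageGrid((8, 8, 8))
        mu = gaussian_blob(grid, (3.5, 3.5, 3.5), sd=1.5)
        cfg = RomtConfig(sigma2=0.0, n_steps=2, max_gn_iters=5)
        sols = solve_series(self._series([mu, mu, mu], grid), cfg)
        assert len(sols) == 2
        for sol in sols:
            vmax = max(float(np.abs(v.components).max()) for v in sol.velocities)
            assert vmax < 1e-6

    def test_translation_series_recovers_per_pair_shift(self):
        grid = ImageGrid((18, 10, 10))
        frames = [gaussian_blob(grid, (5.0 + 1.5 * k, 4.5, 4.5), sd=2.0) for k in range(3)]
        cfg = RomtConfig(sigma2=0.0, n_steps=4, max_gn_iters=15)
        sols = solve_series(self._series(frames, grid), cfg)
        for k, sol in enumerate(sols):
            com = center_of_mass(sol.interpolants[-1])
            target = center_of_mass(frames[k + 1])
            assert np.allclose(com, target, atol=0.3)

    def test_too_few_frames_rejected(self, grid6):
        mu = ScalarField(grid6, np.ones(grid6.dims))
        with pytest.raises(ValueError):
            solve_series(self._series([mu], grid6), RomtConfig())
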