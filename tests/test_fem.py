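import math
from dataclasses import replace

import numpy as np
import pytest

from biofilm_mech import LayerStack, solve_wrinkling, bilayer_wavelength
from biofilm_mech.fem import (
    FemConfig,
    build_mesh,
    dominant_surface_wavelength,
    minimize_energy,
    neo_hookean_energy_density,
    run_growth,
    strain_fields,
    total_energy,
)
from biofilm_mech.fem import _energy_and_gradient, _make_cache

from conftest import make_bilayer


@pytest.fixture(scope="module")
def small_config():
    return FemConfig(L=20.0, gf_over_gs=10.0, gr_over_gf=0.1, g_max=0.1, seed=0)


@pytest.fixture(scope="module")
def small_mesh(small_config):
    return build_mesh(small_config)


class TestMesh:
    def test_film_band_rows(self):
        cfg = FemConfig(L=20.0, hf=1.0, hr_over_hf=0.3, hs_over_hf=10.0,
                        elements_per_hf=4)
        mesh = build_mesh(cfg)
        film_nodes = mesh.coords[np.unique(mesh.triangles[mesh.labels == 0])]
        # film occupies X2 in [10.3, 11.3]
        assert film_nodes[:, 1].min() == pytest.approx(10.3)
        assert film_nodes[:, 1].max() == pytest.approx(11.3)
        # 4 uniform element rows through the film: corner-node levels at
        # 10.3 + k/4
        corner_levels = np.unique(np.round(film_nodes[:, 1], 9))
        for k in range(5):
            assert 10.3 + 0.25 * k in corner_levels

    def test_bottom_boundary_flagged(self, small_mesh):
        on_bottom = np.flatnonzero(small_mesh.coords[:, 1] == 0.0)
        assert set(on_bottom) == set(small_mesh.fixed_y)

    def test_area_conservation(self, small_mesh, small_config):
        _, areas = small_mesh.element_geometry()
        total = small_config.L * (small_config.hf * (1 + 0.3 + 10.0))
        assert areas.sum() == pytest.approx(total, rel=1e-10)

    def test_interfaces_conform(self, small_mesh):
        # residual band directly below film, substrate below that
        for label, lo, hi in [(0, 10.3, 11.3), (1, 10.0, 10.3), (2, 0.0, 10.0)]:
            nodes = small_mesh.coords[np.unique(small_mesh.triangles[small_mesh.labels == label])]
            assert nodes[:, 1].min() >= lo - 1e-12
            assert nodes[:, 1].max() <= hi + 1e-12


class TestEnergyDensity:
    def test_identity_is_stress_free(self):
        assert neo_hookean_energy_density(np.eye(2), 1.0, 9.0) == 0.0

    def test_isochoric_closed_form(self):
        s = 1.3
        psi = neo_hookean_energy_density(np.diag([s, 1 / s]), 2.0, 7.0)
        assert psi == pytest.approx(0.5 * 2.0 * (s**2 + s**-2 - 2), rel=1e-12)

    def test_hand_value(self):
        # I_C = 2.42, J = 1.21: 0.5(0.42 - 2 ln 1.21) + 4.5 (ln 1.21)^2
        expected = 0.5 * (0.42 - 2 * math.log(1.21)) + 4.5 * math.log(1.21) ** 2
        assert expected == pytest.approx(0.182892, abs=1e-6)
        psi = neo_hookean_energy_density(np.diag([1.1, 1.1]), 1.0, 9.0)
        assert psi == pytest.approx(expected, rel=1e-12)

    def test_inverted_configuration_rejected(self):
        with pytest.raises(ValueError, match="inverted"):
            neo_hookean_energy_density(np.diag([-1.0, 1.0]), 1.0, 9.0)


class TestTotalEnergy:
    def test_reference_state_zero(self, small_mesh, small_config):
        u = np.zeros((small_mesh.n_nodes, 2))
        assert total_energy(u, small_mesh, small_config, 0.0) == 0.0

    def test_flat_compressed_state_stores_energy_in_growing_layers(
            self, small_mesh, small_config):
        u = np.zeros((small_mesh.n_nodes, 2))
        assert total_energy(u, small_mesh, small_config, 0.02) > 0.0
        state = strain_fields(u, small_mesh, small_config, 0.02)
        # substrate does not grow: F_e = I there, strain energy localises
        # in film + residual
        assert np.all(state.von_mises[small_mesh.labels == 2] == 0.0)
        assert np.all(state.von_mises[small_mesh.labels != 2] > 0.0)

    def test_uniform_stretch_annihilates_growth_in_growing_layers(
            self, small_mesh, small_config):
        # x1 = (1+g) X1 makes F = F_g exactly, so F_e = I in film+residual
        g = 0.05
        u = np.column_stack([g * small_mesh.coords[:, 0],
                             np.zeros(small_mesh.n_nodes)])
        state = strain_fields(u, small_mesh, small_config, g)
        grow = small_mesh.labels != 2
        assert np.allclose(state.green_lagrange[grow], 0.0, atol=1e-12)
        assert np.all(state.von_mises[~grow] > 0.0)

    def test_gradient_matches_finite_differences(self, small_mesh, small_config, rng):
        cache = _make_cache(small_mesh, small_config)
        u = rng.normal(0.0, 1e-3, (small_mesh.n_nodes, 2))
        _, grad = _energy_and_gradient(u.ravel(), small_mesh, small_config, 0.05, cache)
        free = cache["free"]
        h = 1e-7
        for k in rng.choice(free, 10, replace=False):
            up, um = u.ravel().copy(), u.ravel().copy()
            up[k] += h
            um[k] -= h
            fd = (_energy_and_gradient(up, small_mesh, small_config, 0.05, cache)[0]
                  - _energy_and_gradient(um, small_mesh, small_config, 0.05, cache)[0]) / (2 * h)
            assert grad[k] == pytest.approx(fd, rel=1e-5)


class TestStrainFields:
    def _affine_state(self, mesh, config, M):
        u = mesh.coords @ (M - np.eye(2)).T
        return strain_fields(u, mesh, config, 0.0)

    def test_identity(self, small_mesh, small_config):
        state = self._affine_state(small_mesh, small_config, np.eye(2))
        assert np.allclose(state.green_lagrange, 0.0)
        assert np.allclose(state.von_mises, 0.0)

    def test_rotation_is_strain_free(self, small_mesh, small_config):
        c, s = math.cos(0.3), math.sin(0.3)
        state = self._affine_state(small_mesh, small_config,
                                   np.array([[c, -s], [s, c]]))
        assert np.allclose(state.green_lagrange, 0.0, atol=1e-12)

    def test_simple_shear_matches_formulas(self, small_mesh, small_config):
        gamma = 0.1
        M = np.array([[1.0, gamma], [0.0, 1.0]])
        state = self._affine_state(small_mesh, small_config, M)
        e_exact = 0.5 * (M.T @ M - np.eye(2))
        assert np.allclose(state.green_lagrange, e_exact[None], atol=1e-12)
        tr = np.trace(e_exact)
        dev_exact = e_exact - 0.5 * tr * np.eye(2)
        vm_exact = math.sqrt(2.0 / 3.0 * np.sum(dev_exact * dev_exact))
        assert np.allclose(state.von_mises, vm_exact, atol=1e-12)
        # deviator traceless
        assert np.max(np.abs(state.deviatoric[:, 0, 0] + state.deviatoric[:, 1, 1])) < 1e-12

    def test_equibiaxial_has_zero_deviator(self, small_mesh, small_config):
        state = self._affine_state(small_mesh, small_config, 1.07 * np.eye(2))
        assert np.allclose(state.deviatoric, 0.0, atol=1e-12)
        assert np.allclose(state.von_mises, 0.0, atol=1e-12)


class TestMinimizeEnergy:
    def test_reference_is_already_minimal(self, small_mesh, small_config):
        u = minimize_energy(np.zeros((small_mesh.n_nodes, 2)), small_mesh,
                            small_config, 0.0)
        assert np.max(np.abs(u)) < 1e-10

    def test_energy_never_increases(self, small_mesh, small_config, rng):
        cache = _make_cache(small_mesh, small_config)
        u0 = rng.normal(0, 1e-3, (small_mesh.n_nodes, 2))
        e0 = total_energy(u0, small_mesh, small_config, 0.02)
        u = minimize_energy(u0, small_mesh, small_config, 0.02, cache)
        assert total_energy(u, small_mesh, small_config, 0.02) <= e0

    def test_perturbations_do_not_lower_converged_energy(
            self, small_mesh, small_config, rng):
        u = minimize_energy(np.zeros((small_mesh.n_nodes, 2)), small_mesh,
                            small_config, 0.02)
        e = total_energy(u, small_mesh, small_config, 0.02)
        for _ in range(3):
            du = rng.normal(0, 1e-6, u.shape)
            du[small_mesh.fixed_x, 0] = 0.0
            du[small_mesh.fixed_y, 1] = 0.0
            assert total_energy(u + du, small_mesh, small_config, 0.02) >= e - 1e-10


class TestGrowthRuns:
    def test_zero_growth_no_onset(self):
        cfg = FemConfig(L=20.0, gf_over_gs=10.0, gr_over_gf=0.1, g_max=0.0)
        res = run_growth(cfg)
        assert res.no_onset
        assert res.g_series.size == 0

    def test_flat_branch_persists_without_perturbation(self):
        """With no symmetry-breaking perturbation the minimiser stays on the
        flat branch well past the theoretical onset strain."""
        stack = make_bilayer(10.0)
        stack = replace(stack, film=replace(stack.film, nu=0.45),
                        residual=replace(stack.residual, nu=0.45),
                        substrate=replace(stack.substrate, nu=0.45))
        eps_cr = solve_wrinkling(stack).eps_cr
        g_past = 1.3 * eps_cr / (1 - 1.3 * eps_cr)
        cfg = FemConfig.for_stack(stack, wavelengths=4.0, dg=0.02,
                                  g_max=round(g_past, 2),
                                  perturbation_amplitude=0.0, seed=3)
        res = run_growth(cfg)
        assert res.no_onset
        assert np.all(res.deflection_series < 0.01 * cfg.hf)

    def test_bilayer_like_onset_and_wavelength(self):
        """The growth simulation reproduces the stability theory: onset
        strain within 25% and dominant wrinkle wavelength within 20%
        (the quantitative form of theory-vs-simulation agreement)."""
        stack = make_bilayer(10.0)
        sol = solve_wrinkling(stack)
        cfg = FemConfig.for_stack(stack, wavelengths=10.0, g_max=0.25, seed=1)
        res = run_growth(cfg)
        assert res.onset_strain is not None
        assert res.onset_strain == pytest.approx(sol.eps_cr, rel=0.25)
        assert res.measured_wavelength == pytest.approx(sol.lambda_cr, rel=0.20)
        lam_closed = bilayer_wavelength(10.0, 1.0, 1.0)
        assert res.measured_wavelength == pytest.approx(lam_closed, rel=0.20)
        # deflection grows monotonically once the wrinkle is established
        post = res.deflection_series[res.deflection_series > 0.01]
        assert np.all(np.diff(post) > 0)

    def test_mesh_convergence_of_onset(self):
        """Onset growth changes by < 10% when the film row count doubles."""
        stack = make_bilayer(10.0)
        onsets = []
        for rows in (3, 6):
            cfg = FemConfig.for_stack(stack, wavelengths=5.0, g_max=0.22,
                                      seed=2, elements_per_hf=rows,
                                      elements_per_wavelength=10)
            onsets.append(run_growth(cfg).onset_g)
        assert onsets[0] is not None and onsets[1] is not None
        assert abs(onsets[1] - onsets[0]) / onsets[1] < 0.10


def test_dominant_wavelength_of_pure_mode():
    L = 40.0
    x = np.linspace(0, L, 161)
    u2 = 0.05 * np.sin(2 * np.pi * 8 * x / L)
    assert dominant_surface_wavelength(x, u2, L) == pytest.approx(5.0)
    assert dominant_surface_wavelength(x, np.zeros_like(x), L) is None
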