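"""Diffusion/decay solver: conservation, steady-state profile, uptake."""

import numpy as np
import pytest

from pkpdsim.microenv import Grid


def make_grid(extent=200.0, h=10.0, **kwargs):
    g = Grid((-extent / 2, extent / 2), (-extent / 2, extent / 2), h, **kwargs)
    return g


class TestDiffuseDecay:
    def test_uniform_field_unchanged_by_diffusion(self):
        g = make_grid()
        g.add_substrate("s", diffusion=1000.0, decay=0.0, initial=4.2)
        for _ in range(50):
            g.diffuse_decay_step(0.01)
        assert np.allclose(g.substrates["s"].conc, 4.2, rtol=1e-12)

    def test_mass_conserved_without_decay_or_dirichlet(self, rng):
        g = make_grid()
        g.add_substrate("s", diffusion=2000.0, decay=0.0)
        g.substrates["s"].conc[:] = rng.random((g.ny, g.nx))
        m0 = g.total_mass("s")
        for _ in range(200):
            g.diffuse_decay_step(0.05)
        assert abs(g.total_mass("s") - m0) / m0 < 1e-10

    def test_decay_without_diffusion_is_implicit_euler(self):
        g = make_grid()
        g.add_substrate("s", diffusion=0.0, decay=0.5, initial=1.0)
        g.diffuse_decay_step(0.1)
        assert np.allclose(g.substrates["s"].conc, 1.0 / 1.05, rtol=1e-14)

    def test_nonnegativity_preserved(self, rng):
        g = make_grid()
        g.add_substrate("s", diffusion=5000.0, decay=0.1, dirichlet_edges=["left"])
        g.substrates["s"].conc[:] = rng.random((g.ny, g.nx))
        g.update_dirichlet("s", 5.0)
        for _ in range(100):
            g.diffuse_decay_step(0.1)
            assert (g.substrates["s"].conc >= 0.0).all()

    def test_dirichlet_voxels_pinned_after_every_step(self):
        g = make_grid()
        g.add_substrate("s", diffusion=3000.0, decay=0.02, dirichlet_edges=["bottom"])
        g.update_dirichlet("s", 7.0, biot=0.5)
        for _ in range(20):
            g.diffuse_decay_step(0.1)
            assert np.allclose(g.substrates["s"].conc[0, :], 3.5, rtol=1e-14)

    def test_steady_state_matches_cosh_profile(self):
        # 1D column with a bottom Dirichlet boundary, linear decay elsewhere:
        # u(y) = u0 * cosh(sqrt(lam/D) * (L - y)) / cosh(sqrt(lam/D) * L)
        D, lam, u0 = 1.0e4, 0.02, 7.0
        g = Grid((0.0, 10.0), (-400.0, 400.0), 10.0)
        g.add_substrate("s", diffusion=D, decay=lam, dirichlet_edges=["bottom"])
        g.update_dirichlet("s", u0)
        for _ in range(5000):
            g.diffuse_decay_step(0.1)
        y = g.y_centers - g.y_centers[0]
        L = g.y_max - g.y_centers[0]
        ell = np.sqrt(lam / D)
        ref = u0 * np.cosh(ell * (L - y)) / np.cosh(ell * L)
        num = g.substrates["s"].conc[:, 0]
        assert np.abs((num - ref) / ref).max() < 0.01

    def test_x_then_y_splitting_keeps_symmetric_input_symmetric(self):
        g = make_grid(extent=100.0, h=10.0)
        g.add_substrate("s", diffusion=500.0, decay=0.0)
        g.substrates["s"].conc[g.ny // 2, g.nx // 2] = 100.0
        mid = g.substrates["s"].conc.copy()
        g.substrates["s"].conc[:] = (mid + mid[::-1, :] + mid[:, ::-1] + mid[::-1, ::-1]) / 4
        for _ in range(50):
            g.diffuse_decay_step(0.05)
        u = g.substrates["s"].conc
        assert np.allclose(u, u[::-1, :], rtol=1e-9)
        assert np.allclose(u, u[:, ::-1], rtol=1e-9)

    def test_invalid_voxel_size_rejected(self):
        with pytest.raises(ValueError):
            Grid((-100, 100), (-100, 100), 0.0)

    def test_no_mask_update_warns_once(self):
        g = make_grid()
        g.add_substrate("s", diffusion=100.0, decay=0.0)
        with pytest.warns(UserWarning):
            g.update_dirichlet("s", 1.0)
        g.update_dirichlet("s", 1.0)  # second call silent


class TestExchange:
    def test_zero_uptake_changes_nothing(self):
        g = make_grid()
        g.add_substrate("s", diffusion=0.0, decay=0.0, initial=2.0)
        taken, _ = g.exchange_with_cells(
            "s", np.array([[0.0, 0.0]]), np.array([0.0]), np.array([2500.0]), 0.01
        )
        assert taken[0] == 0.0
        assert np.allclose(g.substrates["s"].conc, 2.0)

    def test_uptake_conserves_mass(self, rng):
        g = make_grid()
        g.add_substrate("s", diffusion=1000.0, decay=0.0, initial=1.0)
        m0 = g.total_mass("s")
        pos = rng.uniform(-90, 90, (20, 2))
        rho = rng.uniform(0, 0.1, 20)
        vol = np.full(20, 2500.0)
        total = 0.0
        for _ in range(200):
            taken, _ = g.exchange_with_cells("s", pos, rho, vol, 0.01)
            total += taken.sum()
            g.diffuse_decay_step(0.01)
        assert abs(g.total_mass("s") + total - m0) / m0 < 1e-12

    def test_multiple_cells_in_one_voxel_share_by_weight(self):
        g = make_grid()
        g.add_substrate("s", diffusion=0.0, decay=0.0, initial=1.0)
        pos = np.array([[1.0, 1.0], [2.0, 2.0]])  # same voxel
        taken, _ = g.exchange_with_cells(
            "s", pos, np.array([0.02, 0.04]), np.array([2000.0, 2000.0]), 0.1
        )
        assert taken[1] == pytest.approx(2.0 * taken[0], rel=1e-12)

    def test_single_cell_uptake_matches_ode_oracle(self):
        from scipy.integrate import solve_ivp

        g = Grid((-10, 10), (-10, 10), 20.0)
        g.add_substrate("s", diffusion=0.0, decay=0.0, initial=2.0)
        rho, vol = 0.05, 3000.0
        k = rho * vol / g.voxel_volume
        for _ in range(1000):
            g.exchange_with_cells(
                "s", np.array([[0.0, 0.0]]), np.array([rho]), np.array([vol]), 0.001
            )
        ref = solve_ivp(
            lambda t, y: [-k * y[0]], (0, 1.0), [2.0], rtol=1e-12, atol=1e-14
        ).y[0, -1]
        assert g.substrates["s"].conc[0, 0] == pytest.approx(ref, rel=1e-6)

    def test_secretion_moves_toward_target(self):
        g = make_grid()
        g.add_substrate("s", diffusion=0.0, decay=0.0, initial=0.0)
        pos = np.array([[0.0, 0.0]])
        for _ in range(3000):
            g.exchange_with_cells(
                "s",
                pos,
                np.array([0.0]),
                np.array([2500.0]),
                0.1,
                secretion_rates=np.array([0.5]),
                secretion_targets=np.array([4.0]),
            )
        iy, ix = g.voxel_indices(pos)
        assert g.substrates["s"].conc[iy[0], ix[0]] == pytest.approx(4.0, rel=1e-3)

    def test_cell_outside_domain_is_error(self):
        g = make_grid()
        g.add_substrate("s", diffusion=0.0, decay=0.0)
        with pytest.raises(ValueError):
            g.exchange_with_cells(
                "s", np.array([[500.0, 0.0]]), np.array([0.1]), np.array([2500.0]), 0.01
            )


def test_second_order_spatial_convergence():
    """The steady Dirichlet/decay profile error shrinks ~4x when h halves.

    The time step is refined with h^2 so the O(dt) splitting bias and the
    O(h^2) spatial error scale together.
    """
    D, lam, u0 = 1.0e4, 0.05, 1.0
    errors = []
    for h, dt in ((20.0, 0.02), (10.0, 0.005)):
        g = Grid((0.0, h), (-400.0, 400.0), h)
        g.add_substrate("s", diffusion=D, decay=lam, dirichlet_edges=["bottom"])
        g.update_dirichlet("s", u0)
        for _ in range(int(200.0 / dt)):
            g.diffuse_decay_step(dt)
        y = g.y_centers - g.y_centers[0]
        L = g.y_max - g.y_centers[0]
        ell = np.sqrt(lam / D)
        ref = u0 * np.cosh(ell * (L - y)) / np.cosh(ell * L)
        errors.append(np.abs(g.substrates["s"].conc[:, 0] - ref).max())
    assert errors[1] < errors[0] / 2.5
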