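import numpy as np
import pytest

from atherosim import fem
from atherosim.geometry import GAMMA_I, GAMMA_M, build_channel_domain


def unit_mesh(h):
    return build_channel_domain(
        length=1.0, thickness=1.0, bump_amplitude=0.0, h=h, lumen_clearance=10.0
    )


def l2_error(mesh, u, exact):
    M = fem.mass_matrix(mesh)
    e = u - exact
    return float(np.sqrt(e @ (M @ e)))


class TestTransportSolve:
    def test_constant_field_is_steady_under_no_flux(self, unit_square):
        c = np.full(unit_square.n_nodes, 3.7)
        sys = fem.assemble_transport(unit_square, 0.5, dt=0.1, previous=c)
        out = fem.solve(sys)
        assert np.allclose(out, 3.7, rtol=1e-12)

    def test_robin_steady_state_is_exterior_value(self):
        # flux balance: with a Robin side, zero source and no transport,
        # the steady solution is uniformly X0 (locks the Robin placement)
        m = unit_mesh(0.1)
        x0 = 2.5
        prev = np.zeros(m.n_nodes)
        for _ in range(400):
            sys = fem.assemble_transport(
                m, 5.0, dt=1.0, previous=prev, robin=(GAMMA_I, 1.0, x0, 5.0)
            )
            prev = fem.solve(sys)
        assert np.allclose(prev, x0, rtol=1e-6)

    def test_manufactured_solution_second_order(self):
        # steady reaction-diffusion, periodic in x, no-flux in y
        D = 0.7
        errs, hs = [], (0.1, 0.05, 0.025)
        for h in hs:
            m = unit_mesh(h)
            x, y = m.points.T
            exact = np.cos(2 * np.pi * x) * np.cos(np.pi * y)
            src = (1.0 + D * 5.0 * np.pi**2) * exact
            sys = fem.assemble_transport(
                m, D, dt=None, previous=None, source=src, linear_rate=1.0
            )
            errs.append(l2_error(m, fem.solve(sys), exact))
        order = np.log2(errs[0] / errs[1]), np.log2(errs[1] / errs[2])
        assert min(order) >= 1.8

    def test_mass_conserved_without_sources(self, unit_square, rng):
        X = rng.random(unit_square.n_nodes)
        m0 = fem.integrate(unit_square, X)
        for _ in range(5):
            sys = fem.assemble_transport(unit_square, 0.3, dt=0.1, previous=X)
            X = fem.solve(sys)
        assert fem.integrate(unit_square, X) == pytest.approx(m0, rel=1e-12)

    def test_maximum_principle_for_pure_diffusion(self, unit_square, rng):
        X = rng.random(unit_square.n_nodes)
        lo, hi = X.min(), X.max()
        sys = fem.assemble_transport(unit_square, 0.3, dt=0.05, previous=X)
        out = fem.solve(sys)
        assert out.min() >= lo - 1e-9 and out.max() <= hi + 1e-9

    def test_negative_dt_rejected(self, unit_square):
        with pytest.raises(ValueError):
            fem.assemble_transport(unit_square, 1.0, dt=-0.1, previous=None)

    def test_negative_robin_coefficient_rejected(self, unit_square):
        with pytest.raises(ValueError, match="non-negative"):
            fem.assemble_transport(
                unit_square, 1.0, dt=0.1,
                previous=np.zeros(unit_square.n_nodes),
                robin=(GAMMA_I, -1.0, 0.0, 1.0),
            )


class TestSolver:
    def test_small_diffusion_system_matches_dense_solve(self, rng):
        m = unit_mesh(0.25)
        src = rng.random(m.n_nodes)
        sys = fem.assemble_transport(m, 1.0, dt=0.5, previous=src, source=src)
        sparse_x = fem.solve(sys)
        dense_red = np.linalg.solve(sys.A.toarray(), sys.b)
        dense_x = sys.expand @ dense_red + sys.fixed
        assert np.allclose(sparse_x, dense_x, atol=1e-9)

    def test_singular_all_neumann_poisson_raises(self):
        import scipy.sparse as sp

        m = unit_mesh(0.25)
        A = fem.stiffness_matrix(m, 1.0)  # unpinned Laplacian is singular
        b = np.zeros(m.n_nodes)
        b[0] = 1.0
        sys = fem.LinearSystem(
            A.tocsr(), b, sp.identity(m.n_nodes, format="csr"), np.zeros(m.n_nodes)
        )
        with pytest.raises(fem.SolverError):
            fem.solve(sys)


class TestPressureSolve:
    def test_constant_dirichlet_zero_source_gives_constant(self, annulus):
        gi = annulus.boundary_nodes[GAMMA_I]
        sys = fem.assemble_pressure(
            annulus, np.zeros(annulus.n_nodes), np.full(len(gi), 4.2)
        )
        sig = fem.solve(sys)
        assert np.allclose(sig, 4.2, atol=1e-9)
        assert np.abs(fem.gradient(annulus, sig)).max() < 1e-7

    def test_manufactured_poisson_second_order(self):
        errs, hs = [], (0.1, 0.05, 0.025)
        for h in hs:
            m = unit_mesh(h)
            x, y = m.points.T
            exact = np.cos(2 * np.pi * x) * np.cos(np.pi * y) + 2.0
            rhs = 5.0 * np.pi**2 * np.cos(2 * np.pi * x) * np.cos(np.pi * y)
            gi = m.boundary_nodes[GAMMA_I]
            sys = fem.assemble_pressure(m, rhs, exact[gi])
            errs.append(l2_error(m, fem.solve(sys), exact))
        order = np.log2(errs[0] / errs[1]), np.log2(errs[1] / errs[2])
        assert min(order) >= 1.8

    def test_positive_source_lifts_interior_above_boundary(self, annulus):
        gi = annulus.boundary_nodes[GAMMA_I]
        sys = fem.assemble_pressure(
            annulus, np.ones(annulus.n_nodes), np.zeros(len(gi))
        )
        sig = fem.solve(sys)
        interior = np.setdiff1d(np.arange(annulus.n_nodes), gi)
        assert sig[interior].min() > 0.0

    def test_missing_kappa_values_rejected(self, annulus):
        with pytest.raises(ValueError, match="one value per"):
            fem.assemble_pressure(annulus, np.zeros(annulus.n_nodes), np.zeros(3))


class TestGradient:
    def test_linear_field_gradient_exact(self, unit_square):
        x, y = unit_square.points.T
        g = fem.gradient(unit_square, 3.0 * x - 2.0 * y)
        assert np.allclose(g, [3.0, -2.0], atol=1e-13)

    def test_constant_field_gradient_zero(self, unit_square):
        g = fem.gradient(unit_square, np.full(unit_square.n_nodes, 5.0))
        assert np.abs(g).max() < 1e-12

    def test_quadratic_field_gradient_first_order(self):
        errs = []
        for h in (0.1, 0.05):
            m = unit_mesh(h)
            x, y = m.points.T
            g = fem.gradient(m, x**2 + y**2)
            cent = m.points[m.triangles].mean(axis=1)
            exact = 2.0 * cent
            errs.append(np.abs(g - exact).max())
        assert errs[1] < 0.75 * errs[0]


class TestIntegrateAndTransfer:
    def test_p1_quadrature_exact_for_nodal_linear(self, unit_square):
        x, y = unit_square.points.T
        val = fem.integrate(unit_square, 2.0 + x + 3.0 * y)
        assert val == pytest.approx(2.0 + 0.5 + 1.5, rel=1e-12)

    def test_transfer_preserves_linear_fields(self):
        m1 = unit_mesh(0.1)
        m2 = unit_mesh(0.07)
        x, y = m1.points.T
        out = fem.transfer_fields(m1, m2, {"f": 1.0 + 2.0 * x - y})
        x2, y2 = m2.points.T
        assert np.allclose(out["f"], 1.0 + 2.0 * x2 - y2, atol=1e-10)

    def test_transfer_never_produces_negatives_from_nonnegative(self, rng):
        m1 = unit_mesh(0.1)
        m2 = unit_mesh(0.06)
        out = fem.transfer_fields(m1, m2, {"f": rng.random(m1.n_nodes)})
        assert out["f"].min() >= 0.0
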