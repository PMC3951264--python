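import numpy as np
import pytest
from scipy.integrate import solve_ivp

from atherosim.cli_io import make_fixture
from atherosim.geometry import GAMMA_I, GAMMA_M
from atherosim.model import (
    CELL_SPECIES,
    SPECIES,
    FieldState,
    OvercrowdingError,
    boundary_coefficients,
    close_state,
    ecm_source,
    pressure_rhs,
    reaction_rhs,
)
from conftest import random_positive_state
from oracles import wellmixed_rhs


class TestReactionRhs:
    def test_no_radicals_means_no_oxidation(self, params, rng):
        st = random_positive_state(rng)
        st["r"] = 0.0
        rx = reaction_rhs(st, params)
        assert rx["L"] == 0.0
        assert rx["H"] == 0.0
        # ox-LDL gain vanishes; only the ingestion loss remains
        assert rx["Lox"] <= 0.0

    def test_oxidation_loss_is_bilinear_product(self, params):
        st = {k: 0.0 for k in SPECIES}
        st["L"] = 1e-3
        st["r"] = 1e-2
        rx = reaction_rhs(st, params)
        assert rx["L"] == pytest.approx(-params.k_L * 1e-3 * 1e-2, rel=1e-14)
        assert rx["L"] == pytest.approx(-2.35e-9, rel=1e-12)

    def test_agrees_with_independent_wellmixed_oracle(self, params, rng):
        # cross-implementation agreement at 100 random physiological states
        for _ in range(100):
            st = random_positive_state(rng)
            ours = reaction_rhs(st, params)
            ref = wellmixed_rhs(st, params)
            for name in SPECIES:
                assert ours[name] == pytest.approx(ref[name], rel=1e-12, abs=1e-300), name

    def test_all_zero_state_has_only_radical_source(self, params):
        st = {k: 0.0 for k in SPECIES}
        rx = reaction_rhs(st, params)
        assert rx["r"] == params.r0
        assert all(rx[k] == 0.0 for k in SPECIES if k != "r")

    def test_mmp_timp_binding_terms_share_the_product(self, params):
        st = {k: 0.0 for k in SPECIES}
        st["Q"] = 2e-9
        st["Qr"] = 3e-9
        rx = reaction_rhs(st, params)
        loss_Q = -(rx["Q"] + params.d_Q * st["Q"])
        loss_Qr = -(rx["Qr"] + params.d_Qr * st["Qr"])
        assert loss_Q == pytest.approx(params.k_QQr * st["Q"] * st["Qr"], rel=1e-14)
        assert loss_Qr == pytest.approx(params.k_QrQ * st["Q"] * st["Qr"], rel=1e-14)
        assert loss_Qr / loss_Q == pytest.approx(1.04e9 / 4.98e8, rel=1e-12)

    def test_negative_input_rejected(self, params):
        st = {k: 0.0 for k in SPECIES}
        st["M"] = -1.0
        with pytest.raises(ValueError, match="negative"):
            reaction_rhs(st, params)

    def test_ldl_decays_exponentially_at_fixed_radicals(self, params):
        # closed form L(t) = L0 exp(-k_L r t) against a stiff integrator
        r_fixed, L0, t_end = 5.0, 1.9e-3, 50.0
        sol = solve_ivp(
            lambda t, y: [-params.k_L * y[0] * r_fixed],
            (0.0, t_end),
            [L0],
            method="BDF",
            rtol=1e-10,
            atol=1e-16,
        )
        exact = L0 * np.exp(-params.k_L * r_fixed * t_end)
        assert sol.y[0, -1] == pytest.approx(exact, rel=1e-8)


class TestBoundaryCoefficients:
    @pytest.fixture()
    def state(self, params):
        mesh, state = make_fixture("flat-strip", h=2.5e-3, p=params)
        return state

    def test_monocyte_influx_baseline_without_oxldl(self, params, state):
        gi = state.mesh.boundary_nodes[GAMMA_I]
        state.fields["Lox"][:] = 0.0
        beta = boundary_coefficients(state, params)[GAMMA_I]["M"][0]
        expected = params.beta_M / (1.0 + params.H0 / params.K_MH)
        assert np.allclose(beta[gi], expected)

    def test_monocyte_influx_increases_with_oxldl(self, params, state):
        gi = state.mesh.boundary_nodes[GAMMA_I]
        b1 = boundary_coefficients(state, params)[GAMMA_I]["M"][0][gi]
        state.fields["Lox"] = 2.0 * state.fields["Lox"]
        b2 = boundary_coefficients(state, params)[GAMMA_I]["M"][0][gi]
        assert np.all(b2 > b1)

    def test_monocyte_influx_decreases_with_hdl(self, params, state):
        gi = state.mesh.boundary_nodes[GAMMA_I]
        b1 = boundary_coefficients(state, params)[GAMMA_I]["M"][0][gi]
        state.fields["H"] = 2.0 * state.fields["H"]
        b2 = boundary_coefficients(state, params)[GAMMA_I]["M"][0][gi]
        assert np.all(b2 < b1)

    def test_smc_influx_raised_by_chemoattractants(self, params, state):
        gm = state.mesh.boundary_nodes[GAMMA_M]
        b1 = boundary_coefficients(state, params)[GAMMA_M]["S"][0][gm]
        state.fields["G"] = 10.0 * state.fields["G"]
        b2 = boundary_coefficients(state, params)[GAMMA_M]["S"][0][gm]
        assert np.all(b2 > b1)

    def test_only_lipoproteins_and_cells_get_influx(self, params, state):
        data = boundary_coefficients(state, params)
        assert set(data[GAMMA_I]) == {"L", "H", "M", "T"}
        assert set(data[GAMMA_M]) == {"S"}


class TestClosure:
    def test_rho_is_exact_residual(self, params, rng):
        mesh, state = make_fixture("flat-strip", h=2.5e-3, p=params)
        close_state(state, params)
        total = state.cell_density() + state.rho
        assert np.abs(total - params.C_tot).max() < 1e-15

    def test_zero_cells_gives_unit_ecm(self, params):
        mesh, state = make_fixture("flat-strip", h=2.5e-3, p=params)
        for k in CELL_SPECIES:
            state.fields[k] = np.zeros(mesh.n_nodes)
        close_state(state, params)
        assert np.allclose(state.rho, 1.0)

    def test_uniform_cells_give_complementary_ecm(self, params):
        mesh, state = make_fixture("flat-strip", h=2.5e-3, p=params)
        for k in CELL_SPECIES:
            state.fields[k] = np.full(mesh.n_nodes, 0.075)
        close_state(state, params)
        assert np.allclose(state.rho, 0.7)

    def test_overcrowding_raises(self, params):
        mesh, state = make_fixture("flat-strip", h=2.5e-3, p=params)
        state.fields["M"] = np.full(mesh.n_nodes, 1.5)
        with pytest.raises(OvercrowdingError):
            close_state(state, params)

    def test_linear_pressure_gives_constant_velocity(self, params):
        mesh, state = make_fixture("flat-strip", h=2.5e-3, p=params)
        sigma = -4.0 * mesh.points[:, 0]
        close_state(state, params, sigma=sigma)
        assert np.allclose(state.velocity, [4.0, 0.0], atol=1e-10)


class TestPressureSources:
    def test_cell_source_sum_matches_recomputation(self, params, rng):
        # f equals the independently summed per-species sources
        mesh, state = make_fixture("flat-strip", h=2.5e-3, p=params)
        for _ in range(20):
            st = random_positive_state(rng, n=mesh.n_nodes)
            for k, v in st.items():
                state.fields[k] = v
            close_state(state, params)
            rhs = pressure_rhs(state, params)
            ref = sum(
                wellmixed_rhs({k: state.fields[k] for k in SPECIES}, params)[s]
                for s in CELL_SPECIES
            )
            assert np.allclose(rhs["f"], ref, rtol=1e-12)

    def test_ecm_source_positive_for_pure_remodeling(self, params):
        fields = {"rho": np.array([0.99]), "Q": np.array([1e-30])}
        g = ecm_source(fields, params)
        assert g[0] > 0.0
        assert g[0] == pytest.approx(
            params.lambda_rho * 0.99 * (1.0 - 0.99 / params.rho0), rel=1e-12
        )

    def test_mmp_attack_reduces_ecm_source(self, params):
        lo = ecm_source({"rho": np.array([0.99]), "Q": np.array([1e-12])}, params)
        hi = ecm_source({"rho": np.array([0.99]), "Q": np.array([1e-9])}, params)
        assert hi[0] < lo[0]
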