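"""Time integration of one (L0, H0) scenario and the plaque-weight observable.

One step advances the fourteen species with semi-implicit backward Euler
(diffusion, advection and each species' own linear loss implicit;
cross-species couplings explicit), enforces the density closure, solves the
Darcy pressure with the adhesion condition ``sigma = gamma_adh * kappa`` on
the free boundary, and periodically moves the boundary with
``V_n = -dsigma/dn`` followed by remeshing and field transfer.

The headline observable is the plaque weight ``W = int (M+T+S+F) dx`` per
unit vessel depth; a scenario records ``W(t)`` on a regular output cadence.
The solver is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import fem
from .freeboundary import DisplacementCapError, advance, normal_velocity
from .geometry import GAMMA_I, GAMMA_M, GeometryError, Mesh, boundary_curvature
from .model import (
    CELL_SPECIES,
    SPECIES,
    TRANSPORTED,
    FieldState,
    OvercrowdingError,
    boundary_coefficients,
    chemotaxis_terms,
    close_state,
    ecm_source,
    plaque_weight,
    pressure_rhs,
    reaction_rhs,
)
from .parameters import ParameterSet, default_parameters, mgdl_to_gcm3

__all__ = ["ScenarioResult", "run_scenario", "step", "solve_pressure", "plaque_weight"]


@dataclass
class ScenarioResult:
    """Plaque-weight time series and bookkeeping for one scenario."""

    times: np.ndarray  # days
    weights: np.ndarray  # g per unit depth
    state: FieldState
    events: list[str] = field(default_factory=list)
    completed: bool = True

    @property
    def w0(self) -> float:
        return float(self.weights[0])

    def relative_change(self, t: float | None = None) -> float:
        """(W(t) - W(0)) / W(0); t defaults to the end of the run."""
        w = self.weight_at(self.times[-1] if t is None else t)
        return (w - self.w0) / self.w0

    def weight_at(self, t: float) -> float:
        return float(np.interp(t, self.times, self.weights))


def solve_pressure(state: FieldState, p: ParameterSet) -> FieldState:
    """Solve the sigma equation on the current state and close it.

    ``-lap(sigma) = f + g`` plus the weak divergence sources (ECM diffusion
    and chemo/haptotaxis), with ``sigma = gamma_adh * kappa`` on Gamma_I.
    """
    close_state(state, p)  # refresh the residual foam density
    rhs = pressure_rhs(state, p)
    kappa = boundary_curvature(state.mesh, GAMMA_I)
    grad_srcs: list[tuple[np.ndarray | float, np.ndarray]] = []
    chemo = chemotaxis_terms(state, p)
    for terms in chemo.values():
        for coef, wname in terms:
            grad_srcs.append((coef, state[wname] if wname != "rho" else state.rho))
    sys = fem.assemble_pressure(state.mesh, rhs["total"], p.gamma_adh * kappa, grad_srcs)
    sigma = fem.solve(sys)
    return close_state(state, p, sigma=sigma)


def step(state: FieldState, p: ParameterSet, dt: float) -> tuple[FieldState, float]:
    """One semi-implicit backward-Euler step; returns (new state, clipped mass).

    Raises :class:`~atherosim.model.OvercrowdingError` when the closure
    fails; the caller halves dt.
    """
    if state.sigma is None:
        state = solve_pressure(state, p)
    mesh = state.mesh
    f = state.fields
    rx = reaction_rhs({k: f[k] for k in SPECIES}, p)
    # exact velocity divergence from the pressure equation: div u = f + g
    div_u = sum(rx[s] for s in CELL_SPECIES) + ecm_source(f, p)
    phi = f["Lox"] / (p.K_Lox + f["Lox"])
    rates: dict[str, np.ndarray | float] = {
        "L": p.k_L * f["r"],
        "H": p.k_H * f["r"],
        "Lox": p.lambda_ox * (f["M"] / (p.K_ing + f["M"])) / (p.K_Lox + f["Lox"]),
        "r": p.d_r + p.k_L * f["L"] + p.k_H * f["H"],
        "M": p.d_M + p.lambda_F * phi,
        "P": p.d_P,
        "T": p.d_T,
        "Ig": p.d_Ig,
        "S": p.d_S,
        "I12": p.d_I12,
        "G": p.d_G,
        "Q": p.d_Q + p.k_QQr * f["Qr"],
        "Qr": p.d_Qr + p.k_QrQ * f["Q"],
        "F": p.d_F,
    }
    robin_all = boundary_coefficients(state, p)
    robin_of = {}
    for tag, entries in robin_all.items():
        for name, data in entries.items():
            robin_of[name] = (tag, *data)
    chemo = chemotaxis_terms(state, p)

    advected = set(CELL_SPECIES)
    new_fields: dict[str, np.ndarray] = {}
    clipped = 0.0
    for name in SPECIES:
        rate = rates[name]
        source = rx[name] + np.asarray(rate) * f[name]
        diffusivity = FieldState.diffusivity(name, p)
        is_adv = name in advected
        # conservation form div(uX) = u.grad X + X div u, with div u implicit
        full_rate = np.asarray(rate) + div_u if is_adv else rate
        sys = fem.assemble_transport(
            mesh,
            diffusivity,
            dt=dt,
            previous=f[name],
            source=source,
            velocity=state.velocity if is_adv else None,
            robin=robin_of.get(name),
            linear_rate=full_rate,
            grad_sources=[(coef, f[w]) for coef, w in chemo.get(name, [])],
        )
        x = fem.solve(sys)
        neg = x < 0.0
        if np.any(neg):
            clipped += -fem.integrate(mesh, np.where(neg, x, 0.0))
            x = np.maximum(x, 0.0)
        new_fields[name] = x

    new_fields["rho"] = f["rho"]  # replaced by the closure below
    new_state = FieldState(mesh, new_fields, time=state.time + dt)
    new_state = solve_pressure(new_state, p)  # closure + sigma + velocity
    return new_state, clipped


def run_scenario(
    L0: float = 190.0,
    H0: float = 40.0,
    horizon: float = 300.0,
    p: ParameterSet | None = None,
    fixture: str = "small-plaque",
    h: float = 1.0e-3,
    dt: float = 0.5,
    output_every: float = 5.0,
    move_every: int = 10,
    max_halvings: int = 8,
    overrides: dict[str, float] | None = None,
) -> ScenarioResult:
    """Integrate the full model for blood lipid levels (L0, H0) in mg/dL.

    Starts from the named fixture (a small formed plaque by default),
    records W on the output cadence, moves the free boundary every
    ``move_every`` accepted steps, and halves dt on overcrowding or
    displacement-cap rejections (up to ``max_halvings``; a boundary
    collapse returns the partial result with ``completed=False``).
    """
    from .cli_io import make_fixture

    if L0 < 0 or H0 < 0 or horizon <= 0:
        raise ValueError("need L0, H0 >= 0 and a positive horizon")
    base = p or default_parameters()
    over = dict(overrides or {})
    over["L0"] = mgdl_to_gcm3(L0)
    over["H0"] = mgdl_to_gcm3(H0)
    params = base.replace(**over)

    mesh, state = make_fixture(fixture, h=h, p=params)
    state = solve_pressure(state, params)

    events: list[str] = []
    times = [0.0]
    weights = [plaque_weight(state)]
    next_out = output_every
    dt0 = dt
    halvings = 0
    successes = 0
    time_since_move = 0.0
    n_remesh = 0
    completed = True

    while state.time < horizon - 1e-9:
        dt_eff = min(dt, horizon - state.time)
        try:
            new_state, clipped = step(state, params, dt_eff)
        except OvercrowdingError as exc:
            halvings += 1
            events.append(f"t={state.time:.2f} overcrowding, dt -> {dt / 2:g} ({exc})")
            if halvings > max_halvings:
                events.append("aborted: dt underflow after repeated overcrowding")
                completed = False
                break
            dt /= 2.0
            successes = 0
            continue
        if clipped > 0:
            events.append(f"t={new_state.time:.2f} clipped negative mass {clipped:.3e}")
        state = new_state
        successes += 1
        time_since_move += dt_eff

        # Move the free boundary well before the accumulated displacement
        # reaches the stability cap, on the regular cadence, or at the
        # horizon; keep dt itself below the per-step displacement cap.
        motion = normal_velocity(state.mesh, state.sigma)
        cap = 0.2 * float(motion.local_edge.min())
        vmax = float(np.abs(motion.v_n).max())
        if successes >= 50 and dt < dt0 and vmax * 2.0 * dt <= 0.9 * cap:
            dt = min(2.0 * dt, dt0)
            successes = 0
            events.append(f"t={state.time:.2f} dt restored to {dt:g}")
        if vmax * dt > 0.9 * cap:
            halvings += 1
            events.append(
                f"t={state.time:.2f} boundary velocity {vmax:.2e} cm/d, dt -> {dt / 2:g}"
            )
            if halvings > max_halvings:
                events.append("aborted: dt underflow from boundary speed")
                completed = False
                break
            dt /= 2.0
            successes = 0
        due = (
            time_since_move >= move_every * dt0
            or vmax * (time_since_move + dt) > 0.5 * cap
            or state.time >= horizon - 1e-9
        )
        if due and time_since_move > 0.0:
            try:
                new_mesh = advance(state.mesh, motion, time_since_move)
            except DisplacementCapError as exc:
                events.append(f"t={state.time:.2f} {exc}")
                completed = False
                break
            except GeometryError as exc:
                events.append(f"t={state.time:.2f} boundary collapse: {exc}")
                completed = False
                break
            if new_mesh is not state.mesh:
                fields = fem.transfer_fields(
                    state.mesh, new_mesh, {k: state.fields[k] for k in SPECIES}
                )
                fields["rho"] = np.zeros(new_mesh.n_nodes)
                state = FieldState(new_mesh, fields, time=state.time)
                state = solve_pressure(state, params)
                n_remesh += 1
                if n_remesh % 20 == 1:
                    events.append(
                        f"t={state.time:.2f} remesh #{n_remesh} ({new_mesh.n_nodes} nodes)"
                    )
            time_since_move = 0.0

        if state.time >= next_out - 1e-9 or state.time >= horizon - 1e-9:
            times.append(state.time)
            weights.append(plaque_weight(state))
            while next_out <= state.time + 1e-9:
                next_out += output_every

    return ScenarioResult(np.array(times), np.array(weights), state, events, completed)
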