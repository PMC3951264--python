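"""Plaque model right-hand sides, boundary influxes, and the mass closure.

Fourteen species live in the evolving intima domain: the lipoproteins LDL
(L), HDL (H), oxidised LDL (Lox) and free radicals (r); the cytokines
MCP-1 (P), IFN-gamma (Ig), IL-12 (I12) and PDGF (G); the enzyme pair MMP
(Q) and TIMP (Qr); and the cells - macrophages (M), T cells (T), smooth
muscle cells (S) and foam cells (F).  Cells advect with the common Darcy
velocity u = -grad(sigma); the total density closure

    M + T + S + F + rho = C_tot (= 1 g/cm^3)

is enforced exactly by construction: all four cell species are integrated
and the ECM density is defined as the residual rho = C_tot - (M+T+S+F).
The ECM balance g (remodeling minus MMP attack) then enters only the
pressure equation -lap(sigma) = f + g, whose solution supplies the Darcy
velocity that keeps the residual rho consistent with its own transport
equation in the continuum limit (all cells and the ECM share one
diffusivity and one velocity).

The reaction network (all rates in g/cm^3/day):

    L:   -k_L L r
    H:   -k_H H r
    Lox:  k_L L r - lambda_ox M/(K_ing + M) phi,   phi = Lox/(K_Lox + Lox)
    r:    r0 - d_r r - k_L L r - k_H H r
    M:    lambda_MIg M Ig/(K_Ig_act + Ig) - lambda_F M phi - d_M M
          - div(chi_P M grad P)            [recruitment by MCP-1]
    P:    lambda_P phi - d_P P
    T:    lambda_TI12 I12 hill(M) hdl(H) - d_T T,   hill(M) = M/(K_M + M)
    Ig:   lambda_IgT T - d_Ig Ig
    S:    -div(chi_P S grad P) - div(chi_G S grad G) - div(chi_rho S grad rho)
          - d_S S
    I12:  (lambda_I12M hill(M) (1 + Ig/(K_Ig_I12 + Ig))
           + lambda_I12F F/(K_F + F)) hdl(H) - d_I12 I12
    G:    lambda_GM M + lambda_GF F + lambda_GS S - d_G G
    Q:    lambda_QS S - k_QQr Q Qr - d_Q Q
    Qr:   lambda_QrS S + lambda_QrM M - k_QrQ Q Qr - d_Qr Qr
    F:    lambda_F M phi - d_F F

with hill(M) = M/(K_M + M) the MHC-II/antigen-presentation saturation and
hdl(H) = 1/(1 + H/K_MH) the factor by which HDL limits inflammation; the
anti-inflammatory IL-10 effect is carried implicitly inside the IL-12
production constants.  The T-cell arm is quadratic in hill(M) (IL-12
production and antigen presentation both require macrophages), which makes
the adaptive response the steepest lipid-sensing stage.  Divergence
(chemotaxis/haptotaxis) terms are assembled weakly by the FEM layer; this
module supplies their coefficient fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fem import gradient, integrate
from .geometry import GAMMA_I, GAMMA_M, Mesh
from .parameters import ParameterSet

__all__ = [
    "SPECIES",
    "CELL_SPECIES",
    "TRANSPORTED",
    "FieldState",
    "OvercrowdingError",
    "reaction_rhs",
    "ecm_source",
    "chemotaxis_terms",
    "boundary_coefficients",
    "pressure_rhs",
    "close_state",
    "plaque_weight",
]

#: the fourteen species of the reaction network, in presentation order
SPECIES = ("L", "H", "Lox", "r", "M", "P", "T", "Ig", "S", "I12", "G", "Q", "Qr", "F")
#: species that advect with the tissue velocity
CELL_SPECIES = ("M", "T", "S", "F")
#: fields advanced by transport solves (foam cells are the closure residual)
TRANSPORTED = ("L", "H", "Lox", "r", "M", "P", "T", "Ig", "S", "I12", "G", "Q", "Qr", "rho")

_DIFFUSIVITY_KEY = {
    "L": "D_L",
    "H": "D_H",
    "Lox": "D_Lox",
    "r": "D_r",
    "M": "D_M",
    "P": "D_P",
    "T": "D_T",
    "Ig": "D_Ig",
    "S": "D_S",
    "I12": "D_I12",
    "G": "D_G",
    "Q": "D_Q",
    "Qr": "D_Qr",
    "F": "D_F",
}


class OvercrowdingError(RuntimeError):
    """Total cell density exceeded the closure constant somewhere."""


@dataclass
class FieldState:
    """Nodal values of all species plus the derived rho, sigma, u at a time."""

    mesh: Mesh
    fields: dict[str, np.ndarray]
    time: float = 0.0
    sigma: np.ndarray | None = None
    velocity: np.ndarray | None = None  # per-element, shape (M, 2)

    def __post_init__(self):
        n = self.mesh.n_nodes
        for name in SPECIES:
            if name not in self.fields:
                raise ValueError(f"missing species field {name!r}")
            arr = np.asarray(self.fields[name], dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"field {name!r} has shape {arr.shape}, expected ({n},)")
            self.fields[name] = arr

    def __getitem__(self, name: str) -> np.ndarray:
        return self.fields[name]

    @property
    def rho(self) -> np.ndarray:
        return self.fields["rho"]

    def cell_density(self) -> np.ndarray:
        return sum(self.fields[s] for s in CELL_SPECIES)

    def copy(self) -> "FieldState":
        return FieldState(
            self.mesh,
            {k: v.copy() for k, v in self.fields.items()},
            self.time,
            None if self.sigma is None else self.sigma.copy(),
            None if self.velocity is None else self.velocity.copy(),
        )

    @staticmethod
    def diffusivity(name: str, p: ParameterSet) -> float:
        return p[_DIFFUSIVITY_KEY[name]]


def _check_fields(fields: dict[str, np.ndarray]) -> None:
    for name in SPECIES:
        arr = np.asarray(fields[name], dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"species {name!r} contains NaN/inf")
        if np.any(arr < 0):
            raise ValueError(f"species {name!r} contains negative values")


def reaction_rhs(fields: dict[str, np.ndarray], p: ParameterSet) -> dict[str, np.ndarray]:
    """Local (non-divergence) reaction terms F_X for every species.

    ``fields`` maps species names to nodal arrays (or scalars for 0-D use).
    Chemotaxis/haptotaxis divergences are not included here; see
    :func:`chemotaxis_terms`.
    """
    _check_fields(fields)
    L, H, Lox, r = (np.asarray(fields[k], float) for k in ("L", "H", "Lox", "r"))
    M, P, T, Ig = (np.asarray(fields[k], float) for k in ("M", "P", "T", "Ig"))
    S, I12, G = (np.asarray(fields[k], float) for k in ("S", "I12", "G"))
    Q, Qr, F = (np.asarray(fields[k], float) for k in ("Q", "Qr", "F"))

    phi = Lox / (p.K_Lox + Lox)
    hill_M = M / (p.K_M + M)
    hdl = 1.0 / (1.0 + H / p.K_MH)
    oxidation_L = p.k_L * L * r
    oxidation_H = p.k_H * H * r
    ingestion = p.lambda_F * M * phi  # macrophage -> foam conversion

    out = {
        "L": -oxidation_L,
        "H": -oxidation_H,
        "Lox": oxidation_L - p.lambda_ox * (M / (p.K_ing + M)) * phi,
        "r": p.r0 - p.d_r * r - oxidation_L - oxidation_H,
        "M": p.lambda_MIg * M * Ig / (p.K_Ig_act + Ig) - ingestion - p.d_M * M,
        "P": p.lambda_P * phi - p.d_P * P,
        "T": p.lambda_TI12 * I12 * hill_M * hdl - p.d_T * T,
        "Ig": p.lambda_IgT * T - p.d_Ig * Ig,
        "S": -p.d_S * S,
        "I12": (
            (
                p.lambda_I12M * hill_M * (1.0 + Ig / (p.K_Ig_I12 + Ig))
                + p.lambda_I12F * F / (p.K_F + F)
            )
            * hdl
            - p.d_I12 * I12
        ),
        "G": p.lambda_GM * M + p.lambda_GF * F + p.lambda_GS * S - p.d_G * G,
        "Q": p.lambda_QS * S - p.k_QQr * Q * Qr - p.d_Q * Q,
        "Qr": p.lambda_QrS * S + p.lambda_QrM * M - p.k_QrQ * Q * Qr - p.d_Qr * Qr,
        "F": ingestion - p.d_F * F,
    }
    return out


def chemotaxis_terms(
    state: FieldState, p: ParameterSet
) -> dict[str, list[tuple[np.ndarray, str]]]:
    """Coefficient fields of the divergence terms -div(chi X grad w).

    Returns, per advected species, a list of (per-element coefficient,
    gradient-field name) pairs; the FEM layer adds ``int coef grad(w) .
    grad(v)`` to the weak right-hand side.  SMCs respond to MCP-1 and PDGF
    gradients (chemotaxis) and to the ECM gradient (haptotaxis);
    macrophages are recruited up MCP-1 gradients.
    """
    tri = state.mesh.triangles
    S_el = state["S"][tri].mean(axis=1)
    M_el = state["M"][tri].mean(axis=1)
    return {
        "S": [
            (p.chi_P * S_el, "P"),
            (p.chi_G * S_el, "G"),
            (p.chi_rho * S_el, "rho"),
        ],
        "M": [(p.chi_P * M_el, "P")],
    }


def boundary_coefficients(
    state: FieldState, p: ParameterSet
) -> dict[str, dict[str, tuple[np.ndarray | float, float, float]]]:
    """Robin influx data per boundary: ``{tag: {species: (beta, X0, eta)}}``.

    On the lumen boundary Gamma_I, LDL/HDL enter with constant
    coefficients; monocyte influx is enhanced by local ox-LDL and damped by
    local HDL (ox-LDL attracts monocytes, HDL limits the inflammation):

        beta_M(Lox, H) = beta_M * (1 + Lox/K_MLox) / (1 + H/K_MH)

    T cells enter at a constant rate.  On the media boundary Gamma_M, SMCs
    enter at a rate raised by local MCP-1 and PDGF (both attract SMCs):

        beta_S(P, G) = beta_S * (1 + P/P0 + G/K_SG)

    ``eta`` is the species' boundary mass-transfer coefficient (cm^2/day):
    the endothelial permeability for the lipoproteins (tissue levels
    approach the blood values over weeks, so the influx rates control the
    early lipid exposure), the transendothelial migration coefficient for
    cells.  All other species are no-flux.
    """
    if "Lox" not in state.fields or "H" not in state.fields:
        raise ValueError("boundary coefficients need the Lox and H fields")
    n = state.mesh.n_nodes
    Lox = state["Lox"]
    H = state["H"]
    beta_M = np.zeros(n)
    gi = state.mesh.boundary_nodes[GAMMA_I]
    beta_M[gi] = p.beta_M * (1.0 + Lox[gi] / p.K_MLox) / (1.0 + H[gi] / p.K_MH)
    beta_T = np.zeros(n)
    beta_T[gi] = p.beta_T
    beta_L = np.zeros(n)
    beta_L[gi] = p.beta_L
    beta_H = np.zeros(n)
    beta_H[gi] = p.beta_H

    out = {
        GAMMA_I: {
            "L": (beta_L, p.L0, p.eta_lipid),
            "H": (beta_H, p.H0, p.eta_lipid),
            "M": (beta_M, p.M0, p.eta_cell),
            "T": (beta_T, p.T0, p.eta_cell),
        }
    }
    if GAMMA_M in state.mesh.boundary_nodes:
        gm = state.mesh.boundary_nodes[GAMMA_M]
        beta_S = np.zeros(n)
        beta_S[gm] = p.beta_S * (1.0 + state["P"][gm] / p.P0 + state["G"][gm] / p.K_SG)
        out[GAMMA_M] = {"S": (beta_S, p.S0, p.eta_media)}
    return out


def ecm_source(fields: dict[str, np.ndarray], p: ParameterSet) -> np.ndarray:
    """ECM balance g: remodeling by the resident cells minus MMP attack.

    ``g = lambda_rho * rho * (1 - rho/rho0) - d_rhoQ * Q * rho``.  With
    ``rho0 = C_tot`` the logistic factor equals the local cell fraction, so
    remodeling is carried by the cells and vanishes in acellular tissue;
    the balance is self-stabilising (matrix loss raises the cell fraction,
    which raises remodeling).
    """
    rho = np.asarray(fields["rho"], float)
    Q = np.asarray(fields["Q"], float)
    return p.lambda_rho * rho * (1.0 - rho / p.rho0) - p.d_rhoQ * Q * rho


def pressure_rhs(state: FieldState, p: ParameterSet) -> dict[str, np.ndarray]:
    """Sources of the pressure equation ``-lap(sigma) = f + g``.

    ``f`` sums the local cell sources (the macrophage-to-foam conversion
    terms cancel within the sum); ``g`` is the ECM source
    (:func:`ecm_source`).  Because cells and ECM share one diffusivity and
    one velocity and their densities sum to the constant C_tot, adding the
    five transport equations leaves exactly ``div u = f + g``.
    Returns the two pieces and their sum (``total``).
    """
    rx = reaction_rhs({k: state[k] for k in SPECIES}, p)
    f = sum(rx[s] for s in CELL_SPECIES)
    g = ecm_source(state.fields, p)
    if not (np.all(np.isfinite(f)) and np.all(np.isfinite(g))):
        raise ValueError("non-finite pressure sources")
    return {"f": f, "g": g, "total": f + g}


def close_state(state: FieldState, p: ParameterSet, sigma: np.ndarray | None = None) -> FieldState:
    """Enforce the density closure and the Darcy velocity.

    Sets ``rho = C_tot - (M+T+S+F)`` nodewise, so the closure holds to
    machine precision by construction.  Raises
    :class:`OvercrowdingError` when the cells exceed the closure constant
    anywhere (the caller rejects the step and halves dt).  When a freshly
    solved pressure is supplied, sets ``u = -grad(sigma)`` per element.
    """
    cells = state.cell_density()
    rho = p.C_tot - cells
    if np.any(rho < 0.0):
        raise OvercrowdingError(
            f"total cell density {float(cells.max()):.6g} exceeds "
            f"C_tot={p.C_tot} at t={state.time:.3f} d"
        )
    state.fields["rho"] = rho
    if sigma is not None:
        sigma = np.asarray(sigma, dtype=float)
        state.sigma = sigma
        state.velocity = -gradient(state.mesh, sigma)
    return state


def plaque_weight(state: FieldState) -> float:
    """Plaque weight W = int (M+T+S+F) dx, per unit vessel depth (g/cm)."""
    return integrate(state.mesh, state.cell_density())
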