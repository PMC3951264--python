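"""Independent reference implementations used only by the test suite.

``wellmixed_rhs`` re-codes the 14-species reaction network at a single
point, written from the model description and deliberately sharing no
source with :mod:`atherosim.model`; ``radial_pressure`` gives the closed
form of the pressure problem in radial symmetry.  These are verification
oracles, never runtime dependencies of the simulator.
"""

from __future__ import annotations

import numpy as np


def wellmixed_rhs(state: dict, p) -> dict:
    """Scalar reaction terms of the well-mixed (0-D) reduction.

    ``state`` maps species names to scalars; ``p`` is any object exposing
    the model constants as attributes.  Chemotaxis has no 0-D analogue and
    is absent by construction.
    """
    L = state["L"]
    H = state["H"]
    Lox = state["Lox"]
    r = state["r"]
    M = state["M"]
    P = state["P"]
    T = state["T"]
    Ig = state["Ig"]
    S = state["S"]
    I12 = state["I12"]
    G = state["G"]
    Q = state["Q"]
    Qr = state["Qr"]
    F = state["F"]

    sat_lox = Lox / (p.K_Lox + Lox)
    sat_M = M / (p.K_M + M)
    sat_ing = M / (p.K_ing + M)
    damp_H = 1.0 / (1.0 + H / p.K_MH)

    d = {}
    d["L"] = -p.k_L * L * r
    d["H"] = -p.k_H * H * r
    d["Lox"] = p.k_L * L * r - p.lambda_ox * sat_ing * sat_lox
    d["r"] = p.r0 - p.d_r * r - p.k_L * L * r - p.k_H * H * r
    d["M"] = (
        p.lambda_MIg * M * Ig / (p.K_Ig_act + Ig)
        - p.lambda_F * M * sat_lox
        - p.d_M * M
    )
    d["P"] = p.lambda_P * sat_lox - p.d_P * P
    d["T"] = p.lambda_TI12 * I12 * sat_M * damp_H - p.d_T * T
    d["Ig"] = p.lambda_IgT * T - p.d_Ig * Ig
    d["S"] = -p.d_S * S
    d["I12"] = (
        p.lambda_I12M * sat_M * (1.0 + Ig / (p.K_Ig_I12 + Ig))
        + p.lambda_I12F * F / (p.K_F + F)
    ) * damp_H - p.d_I12 * I12
    d["G"] = p.lambda_GM * M + p.lambda_GF * F + p.lambda_GS * S - p.d_G * G
    d["Q"] = p.lambda_QS * S - p.k_QQr * Q * Qr - p.d_Q * Q
    d["Qr"] = p.lambda_QrS * S + p.lambda_QrM * M - p.k_QrQ * Q * Qr - p.d_Qr * Qr
    d["F"] = p.lambda_F * M * sat_lox - p.d_F * F
    return d


def wellmixed_with_exchange(state: dict, p, perimeter_over_area: float) -> dict:
    """0-D reduction including the boundary-influx surrogates.

    The Robin influxes become exchange terms ``eta*beta*(X0-X) * (P/A)``;
    monocyte recruitment keeps its ox-LDL/HDL modulation.
    """
    d = wellmixed_rhs(state, p)
    poa = perimeter_over_area
    d["L"] += p.eta_lipid * p.beta_L * (p.L0 - state["L"]) * poa
    d["H"] += p.eta_lipid * p.beta_H * (p.H0 - state["H"]) * poa
    beta_m = (
        p.beta_M
        * (1.0 + state["Lox"] / p.K_MLox)
        / (1.0 + state["H"] / p.K_MH)
    )
    d["M"] += p.eta_cell * beta_m * (p.M0 - state["M"]) * poa
    d["T"] += p.eta_cell * p.beta_T * (p.T0 - state["T"]) * poa
    beta_s = p.beta_S * (1.0 + state["P"] / p.P0 + state["G"] / p.K_SG)
    d["S"] += p.eta_media * beta_s * (p.S0 - state["S"]) * poa
    return d


def radial_pressure(r_i: float, r_o: float, f_const: float, kappa: float):
    """Closed-form sigma(r) for ``-lap(sigma) = f`` on an annulus.

    Boundary conditions: sigma(r_i) = kappa (adhesion on the free
    boundary), dsigma/dr(r_o) = 0 (natural on the media wall).  In radial
    coordinates ``-(1/r)(r sigma')' = f`` integrates to

        sigma'(r) = -f r / 2 + f r_o^2 / (2 r)
        sigma(r)  = kappa + f (r_i^2 - r^2)/4 + f r_o^2/2 * ln(r/r_i)

    Returns ``(sigma, dsigma_dr)`` as callables of r.
    """
    if not 0 < r_i < r_o:
        raise ValueError("need 0 < r_i < r_o")

    def dsigma(r):
        r = np.asarray(r, dtype=float)
        return -0.5 * f_const * r + 0.5 * f_const * r_o**2 / r

    def sigma(r):
        r = np.asarray(r, dtype=float)
        return (
            kappa
            + 0.25 * f_const * (r_i**2 - r**2)
            + 0.5 * f_const * r_o**2 * np.log(r / r_i)
        )

    return sigma, dsigma


def brute_force_prcc(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """PRCC by explicit rank residual correlation with dense least squares.

    Independent of :mod:`atherosim.sensitivity`: ranks computed by
    argsort-of-argsort (average ties not needed for continuous draws),
    residuals via ``numpy.linalg.pinv``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape

    def ranks(v):
        order = np.argsort(v, kind="mergesort")
        rr = np.empty(n)
        rr[order] = np.arange(1, n + 1)
        return rr

    rX = np.column_stack([ranks(X[:, j]) for j in range(k)])
    ry = ranks(y)
    out = np.empty(k)
    for j in range(k):
        Z = np.column_stack([np.ones(n), np.delete(rX, j, axis=1)])
        proj = Z @ np.linalg.pinv(Z)
        ex = rX[:, j] - proj @ rX[:, j]
        ey = ry - proj @ ry
        out[j] = (ex @ ey) / np.sqrt((ex @ ex) * (ey @ ey))
    return out
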