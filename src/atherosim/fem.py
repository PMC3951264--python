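"""P1 Galerkin spatial discretisation with backward-Euler time stepping.

Supports the boundary conditions the plaque model needs: Robin influx on
the lumen boundary (``D dX/dn + eta*beta*(X - X0) = 0``), natural (no-flux)
conditions elsewhere, periodic identification of the lateral channel
boundaries (master/slave degree-of-freedom merging, not penalties), and
Dirichlet pinning of the pressure on the free boundary.

Advection uses the conservation form ``div(u X)`` integrated by parts with
no boundary flux (the free boundary is material, the media wall has
``u.n = 0``).  Cell Peclet numbers in this model are far below one, so no
stabilisation is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import GAMMA_I, Mesh

__all__ = [
    "DiscreteField",
    "LinearSystem",
    "p1_geometry",
    "mass_matrix",
    "stiffness_matrix",
    "advection_matrix",
    "boundary_mass",
    "boundary_load",
    "assemble_transport",
    "assemble_pressure",
    "solve",
    "gradient",
    "integrate",
    "transfer_fields",
    "SolverError",
]


class SolverError(RuntimeError):
    """Linear solve failed or produced an unusable residual."""


@dataclass
class DiscreteField:
    """Nodal P1 field on a mesh."""

    mesh: Mesh
    values: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.mesh.n_nodes,):
            raise ValueError(
                f"field {self.label!r}: expected {self.mesh.n_nodes} nodal values, "
                f"got shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"field {self.label!r} contains non-finite values")


@dataclass
class LinearSystem:
    """Reduced sparse system with the maps back to full nodal vectors.

    ``expand`` holds the (n_full, n_reduced) prolongation: full values are
    ``expand @ x + fixed`` where ``fixed`` carries Dirichlet values.
    """

    A: sp.csr_matrix
    b: np.ndarray
    expand: sp.csr_matrix
    fixed: np.ndarray


def _mesh_cache(mesh: Mesh) -> dict:
    # per-mesh memo for geometry and constant operators; meshes are
    # immutable once built (remeshing creates new objects)
    return mesh.meta.setdefault("_fem_cache", {})


def p1_geometry(mesh: Mesh):
    """Per-element areas and P1 basis gradients.

    Returns ``(areas, grads)`` with ``grads[t, i]`` the constant gradient of
    the basis function of local node ``i`` on triangle ``t``.
    """
    cache = _mesh_cache(mesh)
    if "p1" in cache:
        return cache["p1"]
    pts = mesh.points[mesh.triangles]
    x = pts[..., 0]
    y = pts[..., 1]
    b = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1)
    c = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1)
    areas = 0.5 * (b[:, 0] * c[:, 1] - b[:, 1] * c[:, 0])
    # areas from this formula equal the signed triangle areas
    areas = mesh.triangle_areas()
    grads = np.stack([b, c], axis=2) / (2.0 * areas)[:, None, None]
    cache["p1"] = (areas, grads)
    return areas, grads


def _coo(mesh: Mesh, local: np.ndarray) -> sp.csr_matrix:
    """Scatter (M, 3, 3) local matrices into a global sparse matrix."""
    tri = mesh.triangles
    rows = np.repeat(tri, 3, axis=1).ravel()
    cols = np.tile(tri, (1, 3)).ravel()
    return sp.coo_matrix(
        (local.ravel(), (rows, cols)), shape=(mesh.n_nodes, mesh.n_nodes)
    ).tocsr()


def mass_matrix(mesh: Mesh, lumped: bool = False) -> sp.csr_matrix:
    cache = _mesh_cache(mesh)
    key = "mass_lumped" if lumped else "mass"
    if key in cache:
        return cache[key]
    areas, _ = p1_geometry(mesh)
    if lumped:
        diag = np.zeros(mesh.n_nodes)
        np.add.at(diag, mesh.triangles.ravel(), np.repeat(areas / 3.0, 3))
        out = sp.diags(diag).tocsr()
    else:
        base = np.array([[2, 1, 1], [1, 2, 1], [1, 1, 2]], dtype=float) / 12.0
        local = areas[:, None, None] * base[None]
        out = _coo(mesh, local)
    cache[key] = out
    return out


def stiffness_matrix(mesh: Mesh, diffusivity) -> sp.csr_matrix:
    """``int D grad(phi_i) . grad(phi_j)``; D scalar or per-element."""
    D = np.asarray(diffusivity, dtype=float)
    cache = _mesh_cache(mesh)
    if D.ndim == 0:
        key = ("stiffness", float(D))
        if key in cache:
            return cache[key]
    areas, grads = p1_geometry(mesh)
    if D.ndim == 0:
        local = np.einsum("t,tid,tjd->tij", float(D) * areas, grads, grads)
        out = _coo(mesh, local)
        cache[("stiffness", float(D))] = out
        return out
    local = np.einsum("t,tid,tjd->tij", D * areas, grads, grads)
    return _coo(mesh, local)


def advection_matrix(mesh: Mesh, u_elem: np.ndarray) -> sp.csr_matrix:
    """Weak transport-form advection: ``int (u . grad X) v``.

    ``u_elem`` is a per-element velocity, shape (M, 2).  The conservation
    form ``div(uX)`` is recovered by also passing the known velocity
    divergence as a nodal reaction rate (``div u = f + g`` from the
    pressure equation), which avoids advective boundary-flux terms
    entirely.
    """
    areas, grads = p1_geometry(mesh)
    u_dot_grad = np.einsum("td,tjd->tj", u_elem, grads)  # (M, 3) columns = X
    # int_T phi_i dx = area/3 for each test function i
    local = (areas / 3.0)[:, None, None] * u_dot_grad[:, None, :]
    local = np.broadcast_to(local, (len(areas), 3, 3)).copy()
    return _coo(mesh, local)


def boundary_mass(mesh: Mesh, tag: str, coef: np.ndarray | float) -> sp.csr_matrix:
    """Line-integral mass matrix ``oint c phi_i phi_j ds`` on a tagged boundary."""
    edges = mesh.boundary_edges(tag)
    n = mesh.n_nodes
    c = np.asarray(coef, dtype=float)
    if c.ndim == 0:
        c = np.full(n, float(c))
    pa, pb = mesh.points[edges[:, 0]], mesh.points[edges[:, 1]]
    L = np.linalg.norm(pb - pa, axis=1)
    ca, cb = c[edges[:, 0]], c[edges[:, 1]]
    # exact for nodal-linear c: int c phi_i phi_j over the edge
    m_aa = L / 12.0 * (3 * ca + cb)
    m_bb = L / 12.0 * (ca + 3 * cb)
    m_ab = L / 12.0 * (ca + cb)
    rows = np.concatenate([edges[:, 0], edges[:, 1], edges[:, 0], edges[:, 1]])
    cols = np.concatenate([edges[:, 0], edges[:, 1], edges[:, 1], edges[:, 0]])
    vals = np.concatenate([m_aa, m_bb, m_ab, m_ab])
    return sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


def boundary_load(mesh: Mesh, tag: str, coef: np.ndarray | float) -> np.ndarray:
    """Line-integral load vector ``oint c phi_i ds`` on a tagged boundary."""
    edges = mesh.boundary_edges(tag)
    c = np.asarray(coef, dtype=float)
    if c.ndim == 0:
        c = np.full(mesh.n_nodes, float(c))
    pa, pb = mesh.points[edges[:, 0]], mesh.points[edges[:, 1]]
    L = np.linalg.norm(pb - pa, axis=1)
    ca, cb = c[edges[:, 0]], c[edges[:, 1]]
    out = np.zeros(mesh.n_nodes)
    np.add.at(out, edges[:, 0], L / 6.0 * (2 * ca + cb))
    np.add.at(out, edges[:, 1], L / 6.0 * (ca + 2 * cb))
    return out


def _periodic_projection(mesh: Mesh) -> sp.csr_matrix | None:
    """Prolongation from reduced (master) to full dofs, or None."""
    if mesh.periodic_pairs is None:
        return None
    cache = _mesh_cache(mesh)
    if "periodic" in cache:
        return cache["periodic"]
    masters, slaves, _ = mesh.periodic_pairs
    n = mesh.n_nodes
    keep = np.setdiff1d(np.arange(n), slaves)
    red_index = -np.ones(n, dtype=np.int64)
    red_index[keep] = np.arange(len(keep))
    rows = np.arange(n)
    cols = red_index.copy()
    cols[slaves] = red_index[masters]
    data = np.ones(n)
    out = sp.coo_matrix((data, (rows, cols)), shape=(n, len(keep))).tocsr()
    cache["periodic"] = out
    return out


def _reduce(
    mesh: Mesh,
    A: sp.csr_matrix,
    b: np.ndarray,
    dirichlet: tuple[np.ndarray, np.ndarray] | None = None,
) -> LinearSystem:
    """Apply periodic merging then Dirichlet elimination."""
    n = mesh.n_nodes
    P = _periodic_projection(mesh)
    if P is None:
        P = sp.identity(n, format="csr")
    A1 = (P.T @ A @ P).tocsr()
    b1 = P.T @ b
    fixed_full = np.zeros(n)
    if dirichlet is None:
        return LinearSystem(A1, b1, P, fixed_full)
    dir_ids, dir_vals = dirichlet
    fixed_full[dir_ids] = dir_vals
    # map Dirichlet nodes through the periodic projection: a reduced dof is
    # fixed if any full dof it represents is fixed
    nred = P.shape[1]
    red_of_full = np.asarray(P.argmax(axis=1)).ravel()
    dir_red = np.unique(red_of_full[dir_ids])
    val_red = np.zeros(nred)
    val_red[red_of_full[dir_ids]] = dir_vals
    free = np.setdiff1d(np.arange(nred), dir_red)
    Aff = A1[free][:, free]
    bf = b1[free] - A1[free][:, dir_red] @ val_red[dir_red]
    # prolongation reduced-free -> full, with fixed part carried separately
    sel = sp.coo_matrix(
        (np.ones(len(free)), (free, np.arange(len(free)))), shape=(nred, len(free))
    ).tocsr()
    expand = (P @ sel).tocsr()
    fixed_total = P @ (val_red * np.isin(np.arange(nred), dir_red))
    return LinearSystem(Aff.tocsr(), bf, expand, fixed_total)


def assemble_transport(
    mesh: Mesh,
    diffusivity: float,
    dt: float | None,
    previous: np.ndarray | None,
    source: np.ndarray | float = 0.0,
    velocity: np.ndarray | None = None,
    robin: tuple[str, np.ndarray | float, np.ndarray | float, float] | None = None,
    linear_rate: np.ndarray | float = 0.0,
    grad_sources: list[tuple[np.ndarray | float, np.ndarray]] | None = None,
) -> LinearSystem:
    """Backward-Euler step of an advection-diffusion-reaction equation.

    Encodes ``(X - X_old)/dt + div(u X) - D lap(X) + linear_rate * X =
    source`` with the Robin condition ``D dX/dn + eta*beta*(X - X0) = 0`` on
    the tagged boundary, no-flux elsewhere and periodic identification of
    the lateral boundaries.  ``robin = (tag, beta, X0, eta)`` with ``beta``
    and ``X0`` scalar or nodal.  ``dt=None`` assembles the steady problem
    (used for verification).

    ``linear_rate`` treats the species' own linear decay implicitly
    (scalar, or nodal — assembled with the lumped mass matrix); cross-species
    terms belong in ``source`` (semi-implicit splitting).  ``grad_sources``
    adds explicit weak divergence sources ``int coef grad(w) . grad(v)``
    (chemotaxis/haptotaxis), with per-element or scalar ``coef``.
    """
    if dt is not None and dt <= 0:
        raise ValueError(f"dt must be positive, got {dt!r}")
    n = mesh.n_nodes
    cache = _mesh_cache(mesh)
    if "asm" not in cache:
        cache["asm"] = _assembly_tables(mesh)
    tab = cache["asm"]

    src = np.asarray(source, dtype=float)
    if src.ndim == 0:
        src = np.full(n, float(src))
    b = mass_matrix(mesh) @ src

    vals = [tab["K_unit"] * float(diffusivity)]
    if dt is not None:
        if previous is None:
            raise ValueError("previous field required for a time step")
        prev = np.asarray(previous, dtype=float)
        vals.append(tab["M_vals"] / dt)
        b = b + (mass_matrix(mesh) @ prev) / dt
    rate = np.asarray(linear_rate, dtype=float)
    diag_vals = None
    if rate.ndim == 0:
        if float(rate) != 0.0:
            vals.append(tab["M_vals"] * float(rate))
    else:
        diag_vals = rate * tab["lumped"]
    if velocity is not None:
        areas, grads = p1_geometry(mesh)
        u_dot_grad = np.einsum("td,tjd->tj", np.asarray(velocity, float), grads)
        local = (areas / 3.0)[:, None, None] * u_dot_grad[:, None, :]
        vals.append(np.broadcast_to(local, tab["block_shape"]).ravel())
    if grad_sources:
        areas, grads = p1_geometry(mesh)
        for coef, w in grad_sources:
            w = np.asarray(w, dtype=float)
            gw = np.einsum("tid,ti->td", grads, w[mesh.triangles])
            c = np.asarray(coef, dtype=float)
            if c.ndim == 0:
                c = np.full(len(areas), float(c))
            contrib = np.einsum("t,td,tid->ti", c * areas, gw, grads)
            np.add.at(b, mesh.triangles.ravel(), contrib.ravel())

    all_rows = [tab["erows"]]
    all_cols = [tab["ecols"]]
    all_vals = [np.sum(vals, axis=0)]
    if diag_vals is not None:
        all_rows.append(tab["drows"])
        all_cols.append(tab["drows"])
        all_vals.append(diag_vals)
    if robin is not None:
        tag, beta, x0, eta = robin
        if tag not in mesh.boundary_nodes:
            raise ValueError(f"Robin condition on untagged boundary {tag!r}")
        beta_arr = np.asarray(beta, dtype=float)
        if np.any(beta_arr < 0):
            raise ValueError("Robin coefficient beta must be non-negative")
        coef = eta * beta_arr
        Bm = boundary_mass(mesh, tag, coef).tocoo()
        all_rows.append(tab["red"][Bm.row])
        all_cols.append(tab["red"][Bm.col])
        all_vals.append(Bm.data)
        x0_arr = np.asarray(x0, dtype=float)
        if x0_arr.ndim == 0:
            x0_arr = np.full(n, float(x0_arr))
        cfull = coef if np.ndim(coef) else np.full(n, float(coef))
        b = b + boundary_load(mesh, tag, cfull * x0_arr)

    nred = tab["nred"]
    A_red = sp.coo_matrix(
        (np.concatenate(all_vals), (np.concatenate(all_rows), np.concatenate(all_cols))),
        shape=(nred, nred),
    ).tocsr()
    b_red = np.zeros(nred)
    np.add.at(b_red, tab["red"], b)
    return LinearSystem(A_red, b_red, tab["P"], np.zeros(n))


def _assembly_tables(mesh: Mesh) -> dict:
    """Precomputed COO patterns (mapped to reduced dofs) for fast assembly."""
    n = mesh.n_nodes
    tri = mesh.triangles
    P = _periodic_projection(mesh)
    if P is None:
        P = sp.identity(n, format="csr")
        red = np.arange(n)
    else:
        red = np.asarray(P.argmax(axis=1)).ravel()
    erows_full = np.repeat(tri, 3, axis=1).ravel()
    ecols_full = np.tile(tri, (1, 3)).ravel()
    areas, grads = p1_geometry(mesh)
    base = np.array([[2, 1, 1], [1, 2, 1], [1, 1, 2]], dtype=float) / 12.0
    M_vals = (areas[:, None, None] * base[None]).ravel()
    K_vals = np.einsum("t,tid,tjd->tij", areas, grads, grads).ravel()
    lumped = mass_matrix(mesh, lumped=True).diagonal()
    return {
        "P": P,
        "red": red,
        "nred": P.shape[1],
        "erows": red[erows_full],
        "ecols": red[ecols_full],
        "drows": red[np.arange(n)],
        "M_vals": M_vals,
        "K_unit": K_vals,
        "lumped": lumped,
        "block_shape": (len(areas), 3, 3),
    }


def assemble_pressure(
    mesh: Mesh,
    rhs: np.ndarray,
    kappa: np.ndarray,
    grad_sources: list[tuple[np.ndarray | float, np.ndarray]] | None = None,
) -> LinearSystem:
    """Elliptic pressure problem ``-lap(sigma) = rhs + sum div-terms``.

    ``sigma`` is fixed to ``kappa`` (adhesion, per Gamma_I node) on the free
    boundary, natural on the media boundary, periodic laterally.  Each
    ``(coef, w)`` in ``grad_sources`` adds ``int coef grad(w) . grad(v)`` to
    the weak right-hand side (per-element or scalar ``coef``), which is how
    the ECM-diffusion and chemotaxis divergence sources enter.
    """
    n = mesh.n_nodes
    kappa = np.asarray(kappa, dtype=float)
    ids = mesh.boundary_nodes[GAMMA_I]
    if kappa.shape != ids.shape:
        raise ValueError("kappa must supply one value per Gamma_I node")
    A = stiffness_matrix(mesh, 1.0)
    M = mass_matrix(mesh)
    b = M @ np.asarray(rhs, dtype=float)
    if grad_sources:
        areas, grads = p1_geometry(mesh)
        for coef, w in grad_sources:
            w = np.asarray(w, dtype=float)
            gw = np.einsum("tid,ti->td", grads, w[mesh.triangles])
            c = np.asarray(coef, dtype=float)
            if c.ndim == 0:
                c = np.full(len(areas), float(c))
            contrib = np.einsum("t,td,tid->ti", c * areas, gw, grads)
            np.add.at(b, mesh.triangles.ravel(), contrib.ravel())
    return _reduce(mesh, A, b, dirichlet=(ids, kappa))


def solve(system: LinearSystem) -> np.ndarray:
    """Direct sparse solve; returns the full nodal vector.

    Raises :class:`SolverError` when the normwise backward error
    ``||Ax-b|| / (||A|| ||x|| + ||b||)`` exceeds 1e-10 (with a condition
    estimate in the message) or the matrix is singular.  The backward-error
    form keeps the criterion meaningful for steady balances where ``Ax``
    cancels to a much smaller ``b``.
    """
    A, b = system.A, system.b
    if A.shape[0] == 0:
        return system.fixed.copy()
    try:
        lu = spla.splu(A.tocsc())
        x = lu.solve(b)
        for _ in range(3):  # iterative refinement for ill-conditioned steps
            r = b - A @ x
            bnorm = np.linalg.norm(b)
            if np.linalg.norm(r) <= 1e-12 * (bnorm if bnorm > 0 else 1.0):
                break
            x = x + lu.solve(r)
    except Exception as exc:  # singular factorisation
        raise SolverError(f"sparse solve failed: {exc}") from exc
    if not np.all(np.isfinite(x)):
        raise SolverError("sparse solve returned non-finite values (singular system?)")
    rnorm = np.linalg.norm(A @ x - b, np.inf)
    bnorm = np.linalg.norm(b, np.inf)
    if bnorm > 0 and rnorm > 1e-6 * bnorm:
        # an irreducible residual signals an inconsistent (singular) system
        raise SolverError(
            f"relative residual {rnorm / bnorm:.3e} cannot be reduced; "
            "system is singular or severely ill-posed"
        )
    denom = np.abs(A.data).max() * np.linalg.norm(x, np.inf) + bnorm
    resid = rnorm / (denom if denom > 0 else 1.0)
    if resid > 1e-10:
        try:
            cond = np.linalg.cond(A.toarray()) if A.shape[0] <= 2000 else np.inf
        except Exception:
            cond = np.nan
        raise SolverError(
            f"solver residual {resid:.3e} exceeds 1e-10 (cond ~ {cond:.3e})"
        )
    return system.expand @ x + system.fixed


def gradient(mesh: Mesh, nodal: np.ndarray) -> np.ndarray:
    """Exact per-element gradient of the P1 interpolant, shape (M, 2)."""
    _, grads = p1_geometry(mesh)
    return np.einsum("tid,ti->td", grads, np.asarray(nodal, float)[mesh.triangles])


def integrate(mesh: Mesh, nodal: np.ndarray) -> float:
    """``int_Omega X dx`` by P1 quadrature (exact for nodal-linear X)."""
    areas = mesh.triangle_areas()
    vals = np.asarray(nodal, float)[mesh.triangles]
    return float((areas * vals.mean(axis=1)).sum())


def transfer_fields(
    old_mesh: Mesh, new_mesh: Mesh, fields: dict[str, np.ndarray]
) -> dict[str, np.ndarray]:
    """Piecewise-linear interpolation of nodal fields onto a new mesh.

    Points that fall outside the old domain (the boundary moved outward)
    take nearest-neighbour values.  The caller may log conservation error
    via :func:`integrate` on both meshes.
    """
    from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator

    pts_old = old_mesh.points
    pts_new = new_mesh.points
    out: dict[str, np.ndarray] = {}

    # fast path: two mapped channel grids sharing the column structure
    # transfer by 1-D interpolation in y within each column
    if (
        old_mesh.kind == "channel"
        and new_mesh.kind == "channel"
        and old_mesh.meta.get("nx") == new_mesh.meta.get("nx")
        and old_mesh.meta.get("ny") == new_mesh.meta.get("ny")
        and np.array_equal(old_mesh.meta["x"], new_mesh.meta["x"])
    ):
        nxp = old_mesh.meta["nx"] + 1
        nyp = old_mesh.meta["ny"] + 1
        y_old = pts_old[:, 1].reshape(nxp, nyp)
        y_new = pts_new[:, 1].reshape(nxp, nyp)
        for name, vals in fields.items():
            v = np.asarray(vals, float).reshape(nxp, nyp)
            res = np.empty_like(v)
            for i in range(nxp):
                res[i] = np.interp(y_new[i], y_old[i], v[i])
            flat = res.ravel()
            if np.asarray(vals).min() >= 0.0:
                np.maximum(flat, 0.0, out=flat)
            out[name] = flat
        return out

    lin = LinearNDInterpolator(pts_old, np.zeros(len(pts_old)))
    tri = lin.tri  # reuse the Delaunay structure across fields
    for name, vals in fields.items():
        li = LinearNDInterpolator(tri, np.asarray(vals, float))
        v = li(pts_new)
        miss = ~np.isfinite(v)
        if np.any(miss):
            ni = NearestNDInterpolator(pts_old, np.asarray(vals, float))
            v[miss] = ni(pts_new[miss])
        # P1 interpolation of non-negative data can round below zero
        if np.asarray(vals).min() >= 0.0:
            np.maximum(v, 0.0, out=v)
        out[name] = v
    return out
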