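"""Free-boundary kinematics: V_n = -dsigma/dn on the lumen boundary.

The plaque surface is held together by cell-to-cell adhesion, which pins
the pressure there to ``sigma = gamma_adh * kappa``; continuity of the
tissue velocity then moves the surface with normal velocity
``V_n = -dsigma/dn`` (positive V_n grows the plaque into the lumen).

The boundary update is explicit (forward Euler) with a CFL-like cap on the
per-move displacement; remeshing regenerates the mapped grid from the
displaced boundary polyline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fem import gradient, p1_geometry
from .geometry import GAMMA_I, GeometryError, Mesh, remesh

__all__ = ["BoundaryMotion", "DisplacementCapError", "normal_velocity", "advance"]

#: maximum displacement per move, as a fraction of the local edge length
CAP_FRACTION = 0.2


class DisplacementCapError(RuntimeError):
    """Requested boundary displacement exceeds the stability cap."""


@dataclass
class BoundaryMotion:
    """Normal velocity data on the Gamma_I nodes."""

    node_ids: np.ndarray
    normals: np.ndarray  # unit outward (into the lumen)
    v_n: np.ndarray  # cm/day
    local_edge: np.ndarray  # local boundary edge length, cm

    def displacement(self, dt: float) -> np.ndarray:
        return self.v_n * dt

    def check_cap(self, dt: float) -> None:
        disp = np.abs(self.displacement(dt))
        cap = CAP_FRACTION * self.local_edge
        if np.any(disp > cap):
            worst = float((disp / cap).max())
            raise DisplacementCapError(
                f"boundary displacement exceeds the cap by factor {worst:.2f}; "
                "halve dt"
            )


def normal_velocity(mesh: Mesh, sigma: np.ndarray, smooth_passes: int = 2) -> BoundaryMotion:
    """Evaluate V_n = -dsigma/dn on Gamma_I.

    The normal derivative uses one-sided P1 gradients: the constant
    per-element gradient of sigma, area-averaged over the elements touching
    each boundary node, projected on the outward normal.  Periodic partner
    nodes pool their adjacent elements so the seam sees a full stencil.  A
    few passes of a 1-2-1 tangential filter remove node-scale noise before
    the boundary is moved (logged as part of the redistribution step).
    """
    if sigma is None:
        raise ValueError("sigma must be solved before computing boundary motion")
    ids = mesh.boundary_nodes[GAMMA_I]
    grads = gradient(mesh, sigma)  # (n_tri, 2)
    areas = np.abs(mesh.triangle_areas())
    n = mesh.n_nodes
    acc = np.zeros((n, 2))
    wsum = np.zeros(n)
    tri = mesh.triangles
    for loc in range(3):
        np.add.at(acc, tri[:, loc], grads * areas[:, None])
        np.add.at(wsum, tri[:, loc], areas)
    if mesh.periodic_pairs is not None:
        masters, slaves, _ = mesh.periodic_pairs
        pooled = acc[masters] + acc[slaves]
        wpool = wsum[masters] + wsum[slaves]
        acc[masters] = acc[slaves] = pooled
        wsum[masters] = wsum[slaves] = wpool
    nodal_grad = acc[ids] / wsum[ids, None]
    normals = mesh.outward_normals(GAMMA_I)
    v_n = -np.einsum("ij,ij->i", nodal_grad, normals)

    closed_curve = mesh.meta.get("closed_tags", {}).get(GAMMA_I, False)
    periodic = mesh.periodic_pairs is not None
    for _ in range(smooth_passes):
        if closed_curve:
            v_n = 0.25 * np.roll(v_n, 1) + 0.5 * v_n + 0.25 * np.roll(v_n, -1)
        elif periodic:
            # first and last Gamma_I nodes are periodic partners
            core = v_n[:-1]
            sm = 0.25 * np.roll(core, 1) + 0.5 * core + 0.25 * np.roll(core, -1)
            v_n = np.append(sm, sm[0])
        else:
            inner = 0.25 * v_n[:-2] + 0.5 * v_n[1:-1] + 0.25 * v_n[2:]
            v_n = np.concatenate([[v_n[0]], inner, [v_n[-1]]])

    pts = mesh.points[ids]
    closed = mesh.meta.get("closed_tags", {}).get(GAMMA_I, False)
    if closed:
        e_next = np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1)
        e_prev = np.roll(e_next, 1)
    else:
        seg = np.linalg.norm(pts[1:] - pts[:-1], axis=1)
        e_next = np.append(seg, seg[-1])
        e_prev = np.concatenate([[seg[0]], seg])
    local_edge = 0.5 * (e_next + e_prev)
    return BoundaryMotion(ids, normals, v_n, local_edge)


def advance(mesh: Mesh, motion: BoundaryMotion, dt: float) -> Mesh:
    """Move Gamma_I along its normals by V_n*dt and rebuild the mesh.

    Raises :class:`DisplacementCapError` when the displacement cap is
    violated (the caller halves dt) and propagates
    :class:`~atherosim.geometry.GeometryError` on boundary collapse.
    Mapped-grid regeneration re-samples the boundary at the structured
    columns, which doubles as tangential node redistribution.
    """
    motion.check_cap(dt)
    disp = motion.displacement(dt)
    if np.all(disp == 0.0):
        return mesh
    new_pts = mesh.points[motion.node_ids] + disp[:, None] * motion.normals
    return remesh(mesh, new_pts)
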