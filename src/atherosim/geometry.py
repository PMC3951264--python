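"""2D intima domains: a periodic channel strip and an annulus cross-section.

Both domains are graphs over a base coordinate (x along the vessel for the
channel, the polar angle for the annulus), so they are meshed with mapped
structured triangulations: a tensor grid in parameter space pushed through
the boundary profile.  Remeshing after free-boundary motion regenerates the
mapped grid from the displaced lumen profile, which keeps element quality
bounded without iterative relaxation.

Boundary tags follow the anatomy: ``GAMMA_I`` is the lumen-facing free
boundary, ``GAMMA_M`` the media side, ``GAMMA_L``/``GAMMA_R`` the lateral
(periodic) ends of the channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "Mesh",
    "GAMMA_I",
    "GAMMA_M",
    "GAMMA_L",
    "GAMMA_R",
    "build_channel_domain",
    "build_annulus_domain",
    "boundary_curvature",
    "remesh",
    "GeometryError",
]

GAMMA_I = "Gamma_I"
GAMMA_M = "Gamma_M"
GAMMA_L = "Gamma_L"
GAMMA_R = "Gamma_R"


class GeometryError(ValueError):
    """Degenerate or self-intersecting geometry."""


@dataclass
class Mesh:
    """Triangulated 2D domain with tagged boundaries.

    Attributes
    ----------
    points : (N, 2) array, cm
    triangles : (M, 3) int array, positively oriented
    boundary_nodes : tag -> ordered node index array (polylines; closed
        curves do not repeat the first node)
    periodic_pairs : (left_ids, right_ids, translation) or None; partner
        nodes coincide up to the translation vector
    kind : "channel" | "annulus"
    meta : geometry parameters needed to regenerate the mapped grid
    """

    points: np.ndarray
    triangles: np.ndarray
    boundary_nodes: dict[str, np.ndarray]
    periodic_pairs: tuple[np.ndarray, np.ndarray, np.ndarray] | None
    kind: str
    meta: dict = field(default_factory=dict)

    # -- derived quantities -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.points)

    def triangle_areas(self) -> np.ndarray:
        p = self.points[self.triangles]
        d1 = p[:, 1] - p[:, 0]
        d2 = p[:, 2] - p[:, 0]
        return 0.5 * (d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])

    def area(self) -> float:
        return float(self.triangle_areas().sum())

    def quality(self) -> np.ndarray:
        """Per-triangle 2*inradius/circumradius (1 for equilateral)."""
        p = self.points[self.triangles]
        a = np.linalg.norm(p[:, 1] - p[:, 2], axis=1)
        b = np.linalg.norm(p[:, 2] - p[:, 0], axis=1)
        c = np.linalg.norm(p[:, 0] - p[:, 1], axis=1)
        s = 0.5 * (a + b + c)
        area = np.abs(self.triangle_areas())
        with np.errstate(divide="ignore", invalid="ignore"):
            inradius = area / s
            circumradius = a * b * c / (4.0 * area)
            q = 2.0 * inradius / circumradius
        return np.nan_to_num(q)

    def boundary_edges(self, tag: str) -> np.ndarray:
        """(E, 2) node-index pairs of consecutive boundary nodes."""
        ids = self.boundary_nodes[tag]
        if self.meta.get("closed_tags", {}).get(tag, False):
            nxt = np.roll(ids, -1)
        else:
            nxt = ids[1:]
            ids = ids[:-1]
        return np.column_stack([ids, nxt])

    def boundary_length(self, tag: str) -> float:
        e = self.boundary_edges(tag)
        return float(
            np.linalg.norm(self.points[e[:, 1]] - self.points[e[:, 0]], axis=1).sum()
        )

    def outward_normals(self, tag: str) -> np.ndarray:
        """Unit outward normals at the nodes of a tagged boundary."""
        ids = self.boundary_nodes[tag]
        closed = self.meta.get("closed_tags", {}).get(tag, False)
        pts = self.points[ids]
        if closed:
            tang = np.roll(pts, -1, axis=0) - np.roll(pts, 1, axis=0)
        else:
            tang = np.empty_like(pts)
            tang[1:-1] = pts[2:] - pts[:-2]
            tang[0] = pts[1] - pts[0]
            tang[-1] = pts[-1] - pts[-2]
            if self.periodic_pairs is not None and self.kind == "channel":
                # periodic continuation across the lateral boundaries
                tang[0] = pts[1] - (pts[-2] - self._translation())
                tang[-1] = (pts[1] + self._translation()) - pts[-2]
        tang /= np.linalg.norm(tang, axis=1)[:, None] + 1e-300
        # rotate tangent by -90 deg, then orient away from the domain
        nrm = np.column_stack([tang[:, 1], -tang[:, 0]])
        centroid = self.points.mean(axis=0)
        sign = np.sign(np.einsum("ij,ij->i", nrm, pts - centroid))
        if self.kind == "annulus" and tag == GAMMA_I:
            sign = -np.abs(sign)  # inner boundary: outward means toward the axis
        elif self.kind == "annulus" and tag == GAMMA_M:
            sign = np.abs(sign)
        else:
            sign = np.where(sign == 0, 1.0, sign)
        return nrm * sign[:, None]

    def _translation(self) -> np.ndarray:
        assert self.periodic_pairs is not None
        return self.periodic_pairs[2]

    def min_quality(self) -> float:
        return float(self.quality().min())


def _grid_triangles(ni: int, nj: int) -> np.ndarray:
    """Union-jack split of an (ni+1) x (nj+1) node grid, column-major ids."""
    tris = []
    for i in range(ni):
        for j in range(nj):
            n00 = i * (nj + 1) + j
            n10 = (i + 1) * (nj + 1) + j
            n01 = n00 + 1
            n11 = n10 + 1
            if (i + j) % 2 == 0:
                tris.append((n00, n10, n11))
                tris.append((n00, n11, n01))
            else:
                tris.append((n00, n10, n01))
                tris.append((n10, n11, n01))
    return np.asarray(tris, dtype=np.int64)


def _fix_orientation(points: np.ndarray, tris: np.ndarray) -> np.ndarray:
    p = points[tris]
    det = (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1]) - (
        p[:, 1, 1] - p[:, 0, 1]
    ) * (p[:, 2, 0] - p[:, 0, 0])
    flip = det < 0
    tris[flip] = tris[flip][:, [0, 2, 1]]
    return tris


def build_channel_domain(
    length: float = 0.1,
    thickness: float = 0.01,
    bump_amplitude: float = 0.005,
    bump_width: float = 0.02,
    h: float = 0.001,
    lumen_clearance: float = 0.05,
    profile: Callable[[np.ndarray], np.ndarray] | None = None,
) -> Mesh:
    """Periodic channel strip with a Gaussian plaque bump on the lumen side.

    The domain is {0 <= x <= length, 0 <= y <= ytop(x)} with
    ytop(x) = thickness + A exp(-(x - length/2)^2 / (2 w^2)), Gamma_M at
    y = 0, Gamma_I at y = ytop, and periodic lateral boundaries.  ``profile``
    overrides ytop (used by remeshing).
    """
    if h <= 0:
        raise GeometryError("target edge length h must be positive")
    if bump_amplitude < 0:
        raise GeometryError("bump amplitude must be non-negative")
    if bump_amplitude >= lumen_clearance:
        raise GeometryError(
            f"bump amplitude {bump_amplitude} pinches the lumen "
            f"(clearance {lumen_clearance})"
        )
    nx = max(4, int(round(length / h)))
    ny = max(2, int(round(thickness / h)))
    x = np.linspace(0.0, length, nx + 1)
    if profile is None:
        xm = 0.5 * length
        ytop = thickness + bump_amplitude * np.exp(-((x - xm) ** 2) / (2.0 * bump_width**2))
    else:
        ytop = np.asarray(profile(x), dtype=float)
        if ytop.shape != x.shape:
            raise GeometryError("profile must return one height per x sample")
    if np.any(ytop <= 0):
        raise GeometryError("lumen profile collapses the strip (ytop <= 0)")
    if abs(ytop[0] - ytop[-1]) > 1e-12 * max(1.0, thickness):
        raise GeometryError("periodic channel requires ytop(0) == ytop(length)")

    eta = np.linspace(0.0, 1.0, ny + 1)
    X = np.repeat(x, ny + 1)
    Y = np.concatenate([eta * yt for yt in ytop])
    points = np.column_stack([X, Y])
    tris = _fix_orientation(points, _grid_triangles(nx, ny))

    col = lambda i: np.arange(i * (ny + 1), (i + 1) * (ny + 1))
    bottom = np.arange(0, (nx + 1) * (ny + 1), ny + 1)
    top = bottom + ny
    boundary = {
        GAMMA_M: bottom,
        GAMMA_I: top,
        GAMMA_L: col(0),
        GAMMA_R: col(nx),
    }
    periodic = (col(0), col(nx), np.array([length, 0.0]))
    meta = {
        "length": length,
        "thickness": thickness,
        "nx": nx,
        "ny": ny,
        "h": h,
        "lumen_clearance": lumen_clearance,
        "x": x,
        "ytop": ytop,
        "closed_tags": {},
    }
    return Mesh(points, tris, boundary, periodic, "channel", meta)


def build_annulus_domain(
    inner_radius: float = 0.9,
    outer_radius: float = 1.0,
    h: float = 0.02,
    inner_profile: np.ndarray | None = None,
) -> Mesh:
    """Annular intima cross-section: Gamma_I inner circle, Gamma_M outer.

    ``inner_profile`` optionally gives r_inner(theta) at uniform angles
    (used by remeshing); otherwise the inner boundary is circular.
    """
    if not 0 < inner_radius < outer_radius:
        raise GeometryError(
            f"need 0 < inner < outer radius, got ({inner_radius}, {outer_radius})"
        )
    if h <= 0:
        raise GeometryError("target edge length h must be positive")
    ntheta = max(8, int(round(2.0 * np.pi * inner_radius / h)))
    nr = max(2, int(round((outer_radius - inner_radius) / h)))
    theta = np.linspace(0.0, 2.0 * np.pi, ntheta, endpoint=False)
    if inner_profile is None:
        r_in = np.full(ntheta, float(inner_radius))
    else:
        r_in = np.asarray(inner_profile, dtype=float)
        if r_in.shape != theta.shape:
            raise GeometryError("inner_profile must give one radius per angle sample")
        if np.any(r_in <= 0) or np.any(r_in >= outer_radius):
            raise GeometryError("inner profile must stay inside (0, outer_radius)")

    # nodes: ring-major, radial index fastest
    pts = []
    for i in range(ntheta):
        radii = np.linspace(r_in[i], outer_radius, nr + 1)
        ct, st = np.cos(theta[i]), np.sin(theta[i])
        pts.append(np.column_stack([radii * ct, radii * st]))
    points = np.vstack(pts)

    tris = []
    for i in range(ntheta):
        ip = (i + 1) % ntheta
        for j in range(nr):
            n00 = i * (nr + 1) + j
            n10 = ip * (nr + 1) + j
            n01 = n00 + 1
            n11 = n10 + 1
            if (i + j) % 2 == 0:
                tris.append((n00, n10, n11))
                tris.append((n00, n11, n01))
            else:
                tris.append((n00, n10, n01))
                tris.append((n10, n11, n01))
    tris = _fix_orientation(points, np.asarray(tris, dtype=np.int64))

    inner = np.arange(0, ntheta * (nr + 1), nr + 1)
    outer = inner + nr
    boundary = {GAMMA_I: inner, GAMMA_M: outer}
    meta = {
        "inner_radius": inner_radius,
        "outer_radius": outer_radius,
        "ntheta": ntheta,
        "nr": nr,
        "h": h,
        "theta": theta,
        "r_in": r_in,
        "closed_tags": {GAMMA_I: True, GAMMA_M: True},
    }
    return Mesh(points, tris, boundary, None, "annulus", meta)


def _stencil_indices(n: int, k: int, closed: bool, half: int = 2) -> np.ndarray:
    offs = np.arange(-half, half + 1)
    if closed:
        return (k + offs) % n
    return np.clip(k + offs, 0, n - 1)


def boundary_curvature(mesh: Mesh, tag: str = GAMMA_I) -> np.ndarray:
    """Signed curvature (1/cm) at the nodes of a tagged boundary curve.

    Convention: positive where the boundary is convex toward the lumen
    (the plaque protrudes), so a convex domain boundary such as a circular
    disk edge has kappa = 1/R, a straight segment 0.  Computed by a local
    least-squares quadratic fit over a 5-node stencil in the frame spanned
    by the tangent and the outward normal; kappa = -y''/(1+y'^2)^(3/2) in
    that frame.
    """
    if tag not in mesh.boundary_nodes:
        raise KeyError(f"unknown boundary tag {tag!r}")
    ids = mesh.boundary_nodes[tag]
    closed = mesh.meta.get("closed_tags", {}).get(tag, False)
    periodic = mesh.periodic_pairs is not None and mesh.kind == "channel"
    if not closed and not periodic:
        raise GeometryError("curvature requires a closed or periodic-continued curve")
    pts = mesh.points[ids]
    n = len(pts)
    if periodic and not closed:
        # continue the curve across the periodic seam (last node duplicates
        # the first up to the translation, so wrap on n-1 samples)
        tr = mesh._translation()
        base = pts[:-1]
        m = len(base)
        ext = np.vstack([base[-2:] - tr, base, base[:2] + tr])

        def stencil(k):
            return ext[k : k + 5]

        samples = [stencil(k) for k in range(m)]
    else:
        samples = [pts[_stencil_indices(n, k, True)] for k in range(n)]
        m = n

    normals = mesh.outward_normals(tag)
    kappa = np.empty(m)
    for k, st in enumerate(samples):
        c = st[2]
        nrm = normals[k]
        tang = np.array([-nrm[1], nrm[0]])
        rel = st - c
        s = rel @ tang
        y = rel @ nrm
        # quadratic fit y(s) = a2 s^2 + a1 s + a0
        A = np.column_stack([s**2, s, np.ones_like(s)])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        a2, a1 = coef[0], coef[1]
        kappa[k] = -2.0 * a2 / (1.0 + a1**2) ** 1.5
    if periodic and not closed:
        kappa = np.append(kappa, kappa[0])
    return kappa


def curvature_circumcircle(mesh: Mesh, tag: str = GAMMA_I) -> np.ndarray:
    """Independent curvature estimate from the 3-point circumcircle.

    Retained as a cross-check for :func:`boundary_curvature`; same sign
    convention.
    """
    ids = mesh.boundary_nodes[tag]
    closed = mesh.meta.get("closed_tags", {}).get(tag, False)
    pts = mesh.points[ids]
    n = len(pts)
    if not closed and mesh.periodic_pairs is not None:
        tr = mesh._translation()
        base = pts[:-1]
        m = len(base)
        prev = np.vstack([base[-1] - tr, base[:-1]])
        nxt = np.vstack([base[1:], base[0] + tr])
        pts_c, pts_p, pts_n = base, prev, nxt
    else:
        m = n
        pts_c = pts
        pts_p = np.roll(pts, 1, axis=0)
        pts_n = np.roll(pts, -1, axis=0)
    normals = mesh.outward_normals(tag)[:m]
    a = np.linalg.norm(pts_n - pts_c, axis=1)
    b = np.linalg.norm(pts_c - pts_p, axis=1)
    c = np.linalg.norm(pts_n - pts_p, axis=1)
    cross = (pts_c[:, 0] - pts_p[:, 0]) * (pts_n[:, 1] - pts_p[:, 1]) - (
        pts_c[:, 1] - pts_p[:, 1]
    ) * (pts_n[:, 0] - pts_p[:, 0])
    with np.errstate(divide="ignore", invalid="ignore"):
        k = 2.0 * cross / (a * b * c)
    k = np.nan_to_num(k)
    # cross > 0 means the curve bends left while traversing; convert to the
    # lumen-convexity sign using the outward normal: bending away from the
    # outward normal is convex-toward-lumen.
    mid = 0.5 * (pts_p + pts_n) - pts_c
    sgn = -np.sign(np.einsum("ij,ij->i", mid, normals))
    kap = np.abs(k) * sgn
    if not closed and mesh.periodic_pairs is not None:
        kap = np.append(kap, kap[0])
    return kap


def _polyline_self_intersects(pts: np.ndarray, closed: bool) -> bool:
    """O(n^2) segment intersection test (boundary polylines are short)."""
    n = len(pts)
    segs = [(pts[i], pts[(i + 1) % n]) for i in range(n if closed else n - 1)]

    def inter(p1, p2, p3, p4):
        d1 = p2 - p1
        d2 = p4 - p3
        denom = d1[0] * d2[1] - d1[1] * d2[0]
        if abs(denom) < 1e-30:
            return False
        t = ((p3[0] - p1[0]) * d2[1] - (p3[1] - p1[1]) * d2[0]) / denom
        u = ((p3[0] - p1[0]) * d1[1] - (p3[1] - p1[1]) * d1[0]) / denom
        eps = 1e-12
        return eps < t < 1 - eps and eps < u < 1 - eps

    m = len(segs)
    for i in range(m):
        for j in range(i + 2, m):
            if closed and i == 0 and j == m - 1:
                continue
            if inter(*segs[i], *segs[j]):
                return True
    return False


def remesh(mesh: Mesh, displaced_gamma_i: np.ndarray, quality_floor: float = 0.3) -> Mesh:
    """Rebuild the mapped mesh conforming to a displaced lumen boundary.

    ``displaced_gamma_i`` holds the new coordinates of the Gamma_I nodes in
    their stored order.  Interior fields must be re-interpolated by the
    caller (see :func:`atherosim.fem.transfer_fields`).  Raises
    :class:`GeometryError` when the displaced boundary self-intersects or
    collapses the domain.
    """
    new_b = np.asarray(displaced_gamma_i, dtype=float)
    ids = mesh.boundary_nodes[GAMMA_I]
    if new_b.shape != (len(ids), 2):
        raise GeometryError("displaced boundary must give one point per Gamma_I node")
    if mesh.kind == "channel":
        if _polyline_self_intersects(new_b, closed=False):
            raise GeometryError("displaced Gamma_I self-intersects (boundary collapse)")
        length = mesh.meta["length"]
        x = mesh.meta["x"]
        clear = mesh.meta["lumen_clearance"]
        thickness = mesh.meta["thickness"]
        # sample the displaced polyline back onto the uniform columns
        bx = np.mod(new_b[:, 0], length)
        order = np.argsort(bx)
        bx_s, by_s = bx[order], new_b[order, 1]
        bx_ext = np.concatenate([[bx_s[-1] - length], bx_s, [bx_s[0] + length]])
        by_ext = np.concatenate([[by_s[-1]], by_s, [by_s[0]]])
        ytop = np.interp(x, bx_ext, by_ext)
        ytop[-1] = ytop[0]
        if np.any(ytop <= 0.05 * thickness):
            raise GeometryError("displaced Gamma_I collapses the intima strip")
        if np.any(ytop - thickness >= clear):
            raise GeometryError("plaque reaches the opposite lumen wall")
        out = build_channel_domain(
            length,
            thickness,
            0.0,
            1.0,
            mesh.meta["h"],
            clear,
            profile=lambda xs: np.interp(xs, x, ytop),
        )
        out.meta["lumen_clearance"] = clear
        return out
    elif mesh.kind == "annulus":
        if _polyline_self_intersects(new_b, closed=True):
            raise GeometryError("displaced Gamma_I self-intersects (boundary collapse)")
        theta = mesh.meta["theta"]
        r_out = mesh.meta["outer_radius"]
        ang = np.mod(np.arctan2(new_b[:, 1], new_b[:, 0]), 2.0 * np.pi)
        rad = np.hypot(new_b[:, 0], new_b[:, 1])
        order = np.argsort(ang)
        a_s, r_s = ang[order], rad[order]
        a_ext = np.concatenate([[a_s[-1] - 2 * np.pi], a_s, [a_s[0] + 2 * np.pi]])
        r_ext = np.concatenate([[r_s[-1]], r_s, [r_s[0]]])
        r_in = np.interp(theta, a_ext, r_ext)
        if np.any(r_in <= 0.05 * r_out) or np.any(r_in >= 0.98 * r_out):
            raise GeometryError("displaced Gamma_I leaves the admissible annulus")
        return build_annulus_domain(
            mesh.meta["inner_radius"], r_out, mesh.meta["h"], inner_profile=r_in
        )
    raise GeometryError(f"unknown mesh kind {mesh.kind!r}")
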