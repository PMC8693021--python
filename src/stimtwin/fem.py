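"""Laplace field solver for the stimulation chamber.

Solves ``div(sigma grad Phi) = 0`` in the liquid domain (cylindrical well +
meniscus cap, minus two L-shaped wire electrodes) with the electrode
potentials imposed as Dirichlet conditions (+U0/2 and -U0/2) and zero normal
current elsewhere.  Everything is computed at the reference state ``U0 = 1 V,
sigma0 = 1 S/m``; currents and fields at other voltages/conductivities follow
by exact linear scaling.

Discretisation: first-order Lagrange elements on tetrahedral meshes obtained
by Delaunay triangulation of structured point clouds (dense shells around the
wires, coarser grid in the bulk), with tetrahedra filtered by their centroid
against the exact domain description.  Adaptive refinement inserts points at
the centroids of elements flagged by a Zienkiewicz-Zhu recovered-gradient
error estimator and re-triangulates.

Outputs:

* ``I_0`` — reference current, from the power dissipation
  ``I = (1/U) int sigma |grad Phi|^2 dOmega`` (more accurate than surface-flux
  integration, which is also provided for cross-checking),
* ``E_0`` — field magnitude at the probe point (centre of the well bottom,
  where the cells sit), per applied volt.

Geometry lengths are mm (converted to metres internally); results are SI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import Delaunay

from .geometry import ChamberGeometry, meniscus_height, solve_fill_height

__all__ = [
    "FieldSolution",
    "solve_laplace",
    "solve_with_robin",
    "compute_current",
    "surface_flux_current",
    "adaptive_refine",
    "solve_box_oracle",
    "solve_coax_oracle",
    "export_point_cloud",
]

MM = 1e-3  # mm -> m


# ---------------------------------------------------------------------------
# generic P1 machinery


def _tet_geometry(nodes: np.ndarray, tets: np.ndarray):
    """Volumes (m^3) and P1 shape-function gradients (1/m) per tet."""
    p = nodes[tets]  # (m, 4, 3), metres
    v1 = p[:, 1] - p[:, 0]
    v2 = p[:, 2] - p[:, 0]
    v3 = p[:, 3] - p[:, 0]
    det = np.einsum("ij,ij->i", v1, np.cross(v2, v3))
    vol = np.abs(det) / 6.0
    # gradients of barycentric coordinates
    J = np.stack([v1, v2, v3], axis=2)  # (m,3,3), columns are edge vectors
    Jinv = np.linalg.inv(J)
    g = np.empty((tets.shape[0], 4, 3))
    g[:, 1:, :] = Jinv  # row i of J^-1 is grad of barycentric coord i
    g[:, 0, :] = -g[:, 1:, :].sum(axis=1)
    return vol, g


class TetMesh:
    """Tetrahedral mesh with nodes in mm."""

    def __init__(self, nodes_mm: np.ndarray, tets: np.ndarray):
        self.nodes_mm = np.asarray(nodes_mm, dtype=float)
        self.tets = np.asarray(tets, dtype=np.int64)
        self.volumes, self.grads = _tet_geometry(self.nodes_mm * MM, self.tets)

    @property
    def n_nodes(self) -> int:
        return self.nodes_mm.shape[0]

    @property
    def n_elements(self) -> int:
        return self.tets.shape[0]

    def stiffness(self) -> sp.csr_matrix:
        m = self.n_elements
        Ke = np.einsum("tad,tbd->tab", self.grads, self.grads) * self.volumes[:, None, None]
        rows = np.repeat(self.tets, 4, axis=1).reshape(m, 4, 4)
        cols = np.tile(self.tets[:, None, :], (1, 4, 1))
        K = sp.coo_matrix(
            (Ke.ravel(), (rows.ravel(), cols.ravel())),
            shape=(self.n_nodes, self.n_nodes),
        )
        return K.tocsr()

    def element_gradients(self, phi: np.ndarray) -> np.ndarray:
        """Piecewise-constant gradient of a P1 field, V/m, shape (m, 3)."""
        return np.einsum("tad,ta->td", self.grads, phi[self.tets])

    def recovered_gradients(self, phi: np.ndarray) -> np.ndarray:
        """Volume-weighted nodal average of element gradients (ZZ recovery)."""
        g = self.element_gradients(phi)
        num = np.zeros((self.n_nodes, 3))
        den = np.zeros(self.n_nodes)
        for k in range(4):
            np.add.at(num, self.tets[:, k], g * self.volumes[:, None])
            np.add.at(den, self.tets[:, k], self.volumes)
        den[den == 0] = 1.0
        return num / den[:, None]

    def boundary_faces(self) -> np.ndarray:
        """Faces that belong to exactly one tetrahedron, shape (k, 3)."""
        faces = np.concatenate(
            [
                self.tets[:, [0, 1, 2]],
                self.tets[:, [0, 1, 3]],
                self.tets[:, [0, 2, 3]],
                self.tets[:, [1, 2, 3]],
            ]
        )
        key = np.sort(faces, axis=1)
        _, idx, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
        return faces[idx[counts == 1]]


def solve_system(
    K: sp.csr_matrix, fixed: np.ndarray, fixed_values: np.ndarray,
    rhs: np.ndarray | None = None,
) -> np.ndarray:
    """Solve ``K phi = rhs`` with Dirichlet values on ``fixed`` nodes."""
    n = K.shape[0]
    phi = np.zeros(n)
    phi[fixed] = fixed_values
    free = np.setdiff1d(np.arange(n), fixed)
    b = (rhs if rhs is not None else np.zeros(n)) - K @ phi
    Kff = K[free][:, free]
    phi[free] = spla.spsolve(Kff.tocsc(), b[free])
    return phi


# ---------------------------------------------------------------------------
# solution container


@dataclass
class FieldSolution:
    """Reference solve of the chamber at U0 = 1 V, sigma0 = 1 S/m."""

    I_0: float  # A
    E_0: float  # V/m at the probe point, per applied volt
    U_0: float = 1.0
    sigma_0: float = 1.0
    n_elements: int = 0
    n_nodes: int = 0
    order: int = 1
    refinement_history: list = dc_field(default_factory=list)
    converged: bool = True
    mesh: TetMesh | None = None
    phi: np.ndarray | None = None
    _ctx: dict = dc_field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.I_0 <= 0 or self.E_0 <= 0:
            raise ValueError("reference current and field must be positive")


def _probe_field(mesh: TetMesh, phi: np.ndarray, probe_mm: np.ndarray,
                 radius_mm: float = 1.5) -> float:
    """Field magnitude near the probe: volume-weighted mean gradient of the
    elements whose centroid lies within ``radius_mm`` of the probe point."""
    cent = mesh.nodes_mm[mesh.tets].mean(axis=1)
    d = np.linalg.norm(cent - probe_mm, axis=1)
    sel = d <= radius_mm
    if not np.any(sel):
        sel = d <= 2.0 * np.min(d) + 1e-9
    g = mesh.element_gradients(phi)[sel]
    w = mesh.volumes[sel]
    gmean = (g * w[:, None]).sum(axis=0) / w.sum()
    return float(np.linalg.norm(gmean))


def _probe_tangential_ratio(mesh, phi, probe_mm, radius_mm=1.5, axis=0):
    """Each transverse field component over the magnitude at the probe."""
    cent = mesh.nodes_mm[mesh.tets].mean(axis=1)
    d = np.linalg.norm(cent - probe_mm, axis=1)
    sel = d <= radius_mm
    g = mesh.element_gradients(phi)[sel]
    w = mesh.volumes[sel]
    gmean = (g * w[:, None]).sum(axis=0) / w.sum()
    mag = np.linalg.norm(gmean)
    others = [k for k in range(3) if k != axis]
    return [abs(gmean[k]) / mag for k in others]


# ---------------------------------------------------------------------------
# chamber point cloud


def _segments(geometry: ChamberGeometry, surface_z) -> list[list[np.ndarray]]:
    """Wire skeleton segments per electrode (capsule axes), mm."""
    a = geometry.wire_radius
    d2 = geometry.electrode_spacing / 2.0
    half = geometry.bottom_length / 2.0 - a
    out = []
    for sgn, h in ((-1.0, geometry.electrode_height_1),
                   (+1.0, geometry.electrode_height_2)):
        x = sgn * d2
        zh = h + a  # axis of the horizontal part
        p1 = np.array([x, -half, zh])
        p2 = np.array([x, +half, zh])
        ztop = surface_z(abs(math.hypot(x, half))) + 2.0 * a
        p3 = np.array([x, half, min(zh + geometry.vertical_length, ztop)])
        segs = [[p1, p2]]
        if p3[2] > zh + 1e-9:
            segs.append([p2, p3])
        out.append(segs)
    return out


def _dist_to_segments(points: np.ndarray, segs) -> np.ndarray:
    d = np.full(points.shape[0], np.inf)
    for p1, p2 in segs:
        v = p2 - p1
        L2 = float(v @ v)
        t = np.clip(((points - p1) @ v) / L2, 0.0, 1.0)
        proj = p1 + t[:, None] * v
        d = np.minimum(d, np.linalg.norm(points - proj, axis=1))
    return d


def _wire_shell_points(segs, a: float, spacing: float) -> np.ndarray:
    """Points on (and just outside) a capsule surface around segment axes."""
    pts = []
    for p1, p2 in segs:
        v = p2 - p1
        L = float(np.linalg.norm(v))
        v = v / L
        # orthonormal frame
        ref = np.array([0.0, 0.0, 1.0]) if abs(v[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        e1 = np.cross(v, ref)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(v, e1)
        n_st = max(2, int(math.ceil(L / spacing)) + 1)
        stations = np.linspace(0.0, L, n_st)
        for radius in (a, a + spacing, a + 2.5 * spacing):
            n_th = max(6, int(math.ceil(2 * math.pi * radius / spacing)))
            th = 2 * math.pi * np.arange(n_th) / n_th
            ring = np.outer(np.cos(th), e1) + np.outer(np.sin(th), e2)
            for s in stations:
                pts.append(p1 + s * v + radius * ring)
        # spherical end caps on the wire surface
        for centre, sign in ((p1, -1.0), (p2, +1.0)):
            for polar in (0.35, 0.7, 1.0):
                r_ring = a * math.sin(polar * math.pi / 2)
                z_off = sign * a * math.cos(polar * math.pi / 2)
                if r_ring < 0.2 * a:
                    pts.append(centre[None, :] + sign * a * v[None, :])
                    continue
                n_th = max(6, int(math.ceil(2 * math.pi * r_ring / spacing)))
                th = 2 * math.pi * np.arange(n_th) / n_th
                ring = np.outer(np.cos(th), e1) + np.outer(np.sin(th), e2)
                pts.append(centre + z_off * v + r_ring * ring)
    return np.concatenate(pts)


def _chamber_points(geometry: ChamberGeometry, base_height: float,
                    resolution: float, wire_resolution: float) -> np.ndarray:
    R = geometry.well_radius

    def surface_z(r):
        return base_height + meniscus_height(min(r, R), geometry)

    pts = []
    n_r = max(3, int(math.ceil(R / resolution)) + 1)
    for r in np.linspace(0.0, R, n_r):
        n_th = 1 if r == 0 else max(6, int(math.ceil(2 * math.pi * r / resolution)))
        th = 2 * math.pi * np.arange(n_th) / n_th + (0.1 * r)  # stagger rings
        H = surface_z(r)
        n_z = max(4, int(math.ceil(H / resolution)) + 1)
        for z in np.linspace(0.0, H, n_z):
            pts.append(np.column_stack(
                [r * np.cos(th), r * np.sin(th), np.full(n_th, z)]))
    pts = np.concatenate(pts)

    segs = [s for el in _segments(geometry, surface_z) for s in el]
    shell = _wire_shell_points(segs, geometry.wire_radius, wire_resolution)
    pts = np.concatenate([pts, shell])

    # keep points in the closed liquid region, outside the open wire capsules
    r = np.linalg.norm(pts[:, :2], axis=1)
    zs = base_height + meniscus_height(np.minimum(r, R), geometry)
    keep = (r <= R + 1e-9) & (pts[:, 2] >= -1e-9) & (pts[:, 2] <= zs + 1e-9)
    dist = _dist_to_segments(pts, segs)
    keep &= dist >= geometry.wire_radius * (1 - 1e-9)
    pts = pts[keep]
    # dedupe (keep original coordinates)
    keys = np.round(pts / (0.05 * wire_resolution)).astype(np.int64)
    _, idx = np.unique(keys, axis=0, return_index=True)
    return pts[np.sort(idx)]


def _drop_degenerate(points: np.ndarray, tets: np.ndarray,
                     rel_tol: float = 1e-9) -> np.ndarray:
    """Remove tets whose volume is negligible (Delaunay slivers)."""
    p = points[tets]
    det = np.einsum(
        "ij,ij->i", p[:, 1] - p[:, 0],
        np.cross(p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]),
    )
    vol = np.abs(det) / 6.0
    return tets[vol > rel_tol * np.median(vol)]


def _build_chamber_mesh(points: np.ndarray, geometry: ChamberGeometry,
                        base_height: float):
    R = geometry.well_radius

    def surface_z(r):
        return base_height + meniscus_height(min(r, R), geometry)

    segs = [s for el in _segments(geometry, surface_z) for s in el]
    tri = Delaunay(points, qhull_options="QJ")
    cent = points[tri.simplices].mean(axis=1)
    r_c = np.linalg.norm(cent[:, :2], axis=1)
    z_surf = base_height + meniscus_height(np.minimum(r_c, R), geometry)
    inside = (r_c <= R) & (cent[:, 2] >= 0) & (cent[:, 2] <= z_surf)
    inside &= _dist_to_segments(cent, segs) > geometry.wire_radius
    tets = _drop_degenerate(points, tri.simplices[inside])
    # drop unused nodes
    used = np.unique(tets)
    remap = -np.ones(points.shape[0], dtype=np.int64)
    remap[used] = np.arange(used.size)
    mesh = TetMesh(points[used], remap[tets])

    dist = _dist_to_segments(mesh.nodes_mm, segs)
    on_wire = dist <= geometry.wire_radius * (1 + 1e-6) + 1e-9
    # assign electrode side by x sign
    side = np.sign(mesh.nodes_mm[:, 0])
    elec1 = on_wire & (side < 0)
    elec2 = on_wire & (side > 0)
    return mesh, elec1, elec2


def _solve_chamber(mesh: TetMesh, elec1, elec2, probe_mm,
                   robin: dict | None = None):
    """Dirichlet (+-0.5 V) or mixed Dirichlet/Robin solve; returns phi."""
    K = mesh.stiffness()
    rhs = np.zeros(mesh.n_nodes)
    fixed_mask = np.zeros(mesh.n_nodes, dtype=bool)
    fixed_val = np.zeros(mesh.n_nodes)
    for mask, val in ((elec1, +0.5), (elec2, -0.5)):
        treat_robin = robin is not None and val in robin
        if treat_robin:
            beta = robin[val]  # S/m^2
            faces = _electrode_surface_faces(mesh, mask)
            Ms = _surface_mass(mesh, faces)
            K = K + beta * Ms
            rhs = rhs + beta * (Ms @ np.full(mesh.n_nodes, val))
        else:
            fixed_mask |= mask
            fixed_val[mask] = val
    fixed = np.nonzero(fixed_mask)[0]
    if fixed.size == 0 and robin is None:
        raise RuntimeError("no electrode nodes found; refine the wire mesh")
    phi = solve_system(K, fixed, fixed_val[fixed], rhs)
    return phi


def _electrode_surface_faces(mesh: TetMesh, elec_mask: np.ndarray) -> np.ndarray:
    bf = mesh.boundary_faces()
    sel = elec_mask[bf].all(axis=1)
    faces = bf[sel]
    if faces.shape[0] == 0:
        raise RuntimeError("no surface faces found on electrode")
    return faces


def _face_areas(mesh: TetMesh, faces: np.ndarray) -> np.ndarray:
    p = mesh.nodes_mm[faces] * MM
    return 0.5 * np.linalg.norm(
        np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
    )


def _surface_mass(mesh: TetMesh, faces: np.ndarray) -> sp.csr_matrix:
    areas = _face_areas(mesh, faces)
    Me = (areas[:, None, None] / 12.0) * (np.ones((3, 3)) + np.eye(3))
    rows = np.repeat(faces, 3, axis=1).reshape(-1, 3, 3)
    cols = np.tile(faces[:, None, :], (1, 3, 1))
    M = sp.coo_matrix(
        (Me.ravel(), (rows.ravel(), cols.ravel())),
        shape=(mesh.n_nodes, mesh.n_nodes),
    )
    return M.tocsr()


def _power_current(mesh: TetMesh, phi: np.ndarray, U: float = 1.0,
                   sigma: float = 1.0) -> float:
    g = mesh.element_gradients(phi)
    P = sigma * float(np.einsum("td,td,t->", g, g, mesh.volumes))
    return P / U


# ---------------------------------------------------------------------------
# public chamber API


def solve_laplace(
    geometry: ChamberGeometry,
    resolution: float = 1.2,
    wire_resolution: float | None = None,
    order: int = 1,
    bc: str = "dirichlet",
) -> FieldSolution:
    """Reference Laplace solve of the chamber at U0 = 1 V, sigma0 = 1 S/m.

    ``resolution`` is the target bulk point spacing in mm;
    ``wire_resolution`` the spacing near the electrode wires (default
    ``min(resolution, wire_radius/2)``).  The probe point for ``E_0`` is the
    centre of the well bottom.
    """
    if bc != "dirichlet":
        raise ValueError("use solve_with_robin for distributed interface conditions")
    if order != 1:
        raise NotImplementedError("only first-order Lagrange elements are implemented")
    if wire_resolution is None:
        wire_resolution = min(resolution, geometry.wire_radius / 2.0)
    b = solve_fill_height(geometry)
    points = _chamber_points(geometry, b, resolution, wire_resolution)
    mesh, e1, e2 = _build_chamber_mesh(points, geometry, b)
    probe = np.array([0.0, 0.0, 0.0])
    phi = _solve_chamber(mesh, e1, e2, probe)
    I0 = _power_current(mesh, phi)
    E0 = _probe_field(mesh, phi, probe)
    sol = FieldSolution(
        I_0=I0, E_0=E0, n_elements=mesh.n_elements, n_nodes=mesh.n_nodes,
        mesh=mesh, phi=phi,
    )
    sol._ctx = {
        "points": points, "probe": probe, "probe_radius": 1.5, "robin": None,
        "rebuild": lambda pts: _build_chamber_mesh(pts, geometry, b),
    }
    return sol


def solve_with_robin(
    geometry: ChamberGeometry,
    z_interface: float,
    split: str = "asymmetric",
    resolution: float = 1.2,
    wire_resolution: float | None = None,
) -> FieldSolution:
    """Distributed electrode-interface solve via a Robin boundary condition.

    On the treated electrode(s) the Dirichlet condition is replaced by
    ``sigma dPhi/dn = (Phi_ref - Phi) / (z_interface * A_e)`` with ``A_e`` the
    electrode surface area — i.e. the lumped interface impedance spread
    uniformly over the surface.  ``split="asymmetric"`` applies the full
    impedance on one electrode (the other stays Dirichlet);
    ``split="symmetric"`` applies half on each.

    Only real interface impedances are supported: the solver is real-valued.
    For complex interface impedances use the lumped voltage-divider path.
    """
    if isinstance(z_interface, complex) or np.iscomplexobj(z_interface):
        raise NotImplementedError(
            "complex interface impedance is not supported by the real-valued "
            "solver; evaluate at a frequency where Im(z) is negligible or use "
            "the lumped voltage-divider approach"
        )
    if z_interface < 0:
        raise ValueError("z_interface must be >= 0")
    if split not in ("asymmetric", "symmetric"):
        raise ValueError(f"unknown split {split!r}")
    if wire_resolution is None:
        wire_resolution = min(resolution, geometry.wire_radius / 2.0)
    b = solve_fill_height(geometry)
    points = _chamber_points(geometry, b, resolution, wire_resolution)
    mesh, e1, e2 = _build_chamber_mesh(points, geometry, b)
    probe = np.array([0.0, 0.0, 0.0])

    def beta_for(mask, z):
        faces = _electrode_surface_faces(mesh, mask)
        A_e = float(_face_areas(mesh, faces).sum())
        if z == 0:
            return None  # degenerate: plain Dirichlet
        return 1.0 / (z * A_e)

    robin: dict[float, float] = {}
    if split == "asymmetric":
        bta = beta_for(e1, z_interface)
        if bta is not None:
            robin[+0.5] = bta
    else:
        for mask, val in ((e1, +0.5), (e2, -0.5)):
            bta = beta_for(mask, z_interface / 2.0)
            if bta is not None:
                robin[val] = bta
    phi = _solve_chamber(mesh, e1, e2, probe, robin=robin or None)
    I0 = _power_current(mesh, phi)
    E0 = _probe_field(mesh, phi, probe)
    sol = FieldSolution(
        I_0=I0, E_0=E0, n_elements=mesh.n_elements, n_nodes=mesh.n_nodes,
        mesh=mesh, phi=phi,
    )
    sol._ctx = {
        "points": points, "probe": probe, "probe_radius": 1.5,
        "robin": robin or None,
        "rebuild": lambda pts: _build_chamber_mesh(pts, geometry, b),
    }
    return sol


def compute_current(solution: FieldSolution, sigma: float = 1.0,
                    U: float = 1.0) -> float:
    """Current at conductivity ``sigma`` and voltage ``U`` by linear scaling."""
    if sigma <= 0 or U <= 0:
        raise ValueError("sigma and U must be > 0")
    return (sigma / solution.sigma_0) * (U / solution.U_0) * solution.I_0


def surface_flux_current(solution: FieldSolution, electrode: str = "positive") -> float:
    """Current by integrating the normal current density over one electrode.

    Cross-check for :func:`compute_current`; converges more slowly than the
    power-dissipation route.
    """
    mesh, phi = solution.mesh, solution.phi
    if mesh is None or phi is None:
        raise ValueError("solution carries no mesh")
    val = 0.5 if electrode == "positive" else -0.5
    on = np.isclose(phi, val, atol=1e-9)
    faces = _electrode_surface_faces(mesh, on)
    # adjacent tet gradient per face
    face_key = {tuple(sorted(f)): k for k, f in enumerate(faces)}
    g = mesh.element_gradients(phi)
    total = 0.0
    areas = _face_areas(mesh, faces)
    # find owning tet for each boundary face
    for t_idx, tet in enumerate(mesh.tets):
        for combo in ((0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)):
            key = tuple(sorted(tet[list(combo)]))
            k = face_key.get(key)
            if k is None:
                continue
            f = faces[k]
            p = mesh.nodes_mm[f] * MM
            n = np.cross(p[1] - p[0], p[2] - p[0])
            n /= np.linalg.norm(n)
            # orient outward from the liquid (towards the electrode):
            opp = [v for v in tet if v not in f]
            interior = mesh.nodes_mm[opp[0]] * MM
            if np.dot(n, interior - p[0]) > 0:
                n = -n
            total += -np.dot(g[t_idx], n) * areas[k]  # sigma0 = 1
    return abs(total)


def adaptive_refine(solution: FieldSolution, max_steps: int = 3,
                    rel_change: float = 1e-4, mark_fraction: float = 0.3) -> FieldSolution:
    """Adaptive refinement driven by a Zienkiewicz-Zhu error estimator.

    Elements carrying the top ``mark_fraction`` of the estimated error get a
    new point at their centroid; the cloud is re-triangulated and re-solved.
    Stops when both ``I_0`` and ``E_0`` change by less than ``rel_change``
    (0.01% by default) between steps, else flags ``converged=False``.
    """
    ctx = solution._ctx
    if not ctx:
        raise ValueError("solution carries no refinement context")
    rebuild = ctx["rebuild"]
    points = ctx["points"]
    probe = ctx["probe"]
    probe_radius = ctx.get("probe_radius", 1.5)
    robin = ctx.get("robin")
    history = list(solution.refinement_history)
    prev_I, prev_E = solution.I_0, solution.E_0
    mesh, phi = solution.mesh, solution.phi
    converged = False
    for _ in range(max_steps):
        eta = _zz_errors(mesh, phi)
        order = np.argsort(eta)[::-1]
        cum = np.cumsum(eta[order])
        n_mark = int(np.searchsorted(cum, mark_fraction * cum[-1])) + 1
        marked = order[:n_mark]
        new_pts = mesh.nodes_mm[mesh.tets[marked]].mean(axis=1)
        points = np.concatenate([points, new_pts])
        mesh, e1, e2 = rebuild(points)
        phi = _solve_chamber(mesh, e1, e2, probe, robin=robin)
        I0 = _power_current(mesh, phi)
        E0 = _probe_field(mesh, phi, probe, radius_mm=probe_radius)
        dI = abs(I0 - prev_I) / prev_I
        dE = abs(E0 - prev_E) / prev_E
        history.append({
            "n_elements": mesh.n_elements, "I_0": I0, "E_0": E0,
            "dI": dI, "dE": dE, "eta_total": float(np.sqrt(eta.sum())),
        })
        prev_I, prev_E = I0, E0
        if dI < rel_change and dE < rel_change:
            converged = True
            break
    out = FieldSolution(
        I_0=prev_I, E_0=prev_E, n_elements=mesh.n_elements, n_nodes=mesh.n_nodes,
        refinement_history=history, converged=converged, mesh=mesh, phi=phi,
    )
    out._ctx = dict(ctx, points=points)
    return out


def _zz_errors(mesh: TetMesh, phi: np.ndarray) -> np.ndarray:
    """Squared ZZ error indicator per element."""
    g = mesh.element_gradients(phi)
    gr = mesh.recovered_gradients(phi)
    g_nodes = gr[mesh.tets].mean(axis=1)
    diff = g_nodes - g
    return np.einsum("td,td->t", diff, diff) * mesh.volumes


def export_point_cloud(solution: FieldSolution, path) -> None:
    """Write the solution as CSV columns x_mm, y_mm, z_mm, phi_V, E_V_per_m."""
    import pandas as pd

    mesh, phi = solution.mesh, solution.phi
    if mesh is None or phi is None:
        raise ValueError("solution carries no mesh")
    g = mesh.recovered_gradients(phi)
    pd.DataFrame(
        {
            "x_mm": mesh.nodes_mm[:, 0],
            "y_mm": mesh.nodes_mm[:, 1],
            "z_mm": mesh.nodes_mm[:, 2],
            "phi_V": phi,
            "E_V_per_m": np.linalg.norm(g, axis=1),
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# oracle geometries (closed-form verification)


def solve_box_oracle(L: float = 25.0, W: float = 10.0, H: float = 10.0,
                     n: int = 8) -> FieldSolution:
    """Rectangular channel with full-face electrodes at x = 0 and x = L (mm).

    Closed form: uniform field U/L, conductance ``sigma A / L``.  The P1
    solution is exact up to round-off because the potential is linear.
    """
    xs = np.linspace(0.0, L, max(2, n))
    ys = np.linspace(0.0, W, max(2, int(n * W / L) + 1))
    zs = np.linspace(0.0, H, max(2, int(n * H / L) + 1))
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    # Deterministic tangential jitter breaks the co-sphericity of the regular
    # grid so Delaunay output is conforming (no degenerate slivers).  Boundary
    # nodes stay exactly on their planes, so the domain is unchanged and the
    # P1 solution remains exact for the linear potential.
    rng = np.random.default_rng(1234)
    spacing = np.array([xs[1] - xs[0], ys[1] - ys[0], zs[1] - zs[0]])
    jit = (rng.random(pts.shape) - 0.5) * 0.2 * spacing
    for dim, (lo, hi) in enumerate(((0.0, L), (0.0, W), (0.0, H))):
        on_bound = np.isclose(pts[:, dim], lo) | np.isclose(pts[:, dim], hi)
        jit[on_bound, dim] = 0.0
    pts = pts + jit

    def rebuild(points):
        tri = Delaunay(points, qhull_options="QJ")
        mesh = TetMesh(points, _drop_degenerate(points, tri.simplices))
        e1 = np.isclose(mesh.nodes_mm[:, 0], 0.0, atol=1e-7)
        e2 = np.isclose(mesh.nodes_mm[:, 0], L, atol=1e-7)
        return mesh, e1, e2

    mesh, e1, e2 = rebuild(pts)
    phi = _solve_chamber(mesh, e1, e2, np.zeros(3))
    I0 = _power_current(mesh, phi)
    probe = np.array([L / 2.0, W / 2.0, H / 2.0])
    E0 = _probe_field(mesh, phi, probe, radius_mm=0.3 * L)
    sol = FieldSolution(I_0=I0, E_0=E0, n_elements=mesh.n_elements,
                        n_nodes=mesh.n_nodes, mesh=mesh, phi=phi)
    sol._ctx = {"points": pts, "probe": probe, "probe_radius": 0.3 * L,
                "robin": None, "rebuild": rebuild}
    return sol


def solve_coax_oracle(a: float = 2.0, b: float = 15.0, h: float = 5.0,
                      n_r: int = 25, n_theta: int = 48, n_z: int = 4) -> FieldSolution:
    """Coaxial cylinders (inner radius a, outer b, height h, mm).

    Closed form: conductance ``2 pi sigma h / ln(b/a)``; field at radius r is
    ``U / (r ln(b/a))``.
    """
    radii = np.geomspace(a, b, n_r)
    zs = np.linspace(0.0, h, n_z)
    pts = []
    for k, r in enumerate(radii):
        th = 2 * math.pi * (np.arange(n_theta) + 0.5 * (k % 2)) / n_theta
        for z in zs:
            pts.append(np.column_stack(
                [r * np.cos(th), r * np.sin(th), np.full(n_theta, z)]))
    pts = np.concatenate(pts)
    tri = Delaunay(pts, qhull_options="QJ")
    cent = pts[tri.simplices].mean(axis=1)
    r_c = np.linalg.norm(cent[:, :2], axis=1)
    keep = (r_c >= a) & (r_c <= b)
    tets = _drop_degenerate(pts, tri.simplices[keep])
    used = np.unique(tets)
    remap = -np.ones(pts.shape[0], dtype=np.int64)
    remap[used] = np.arange(used.size)
    mesh = TetMesh(pts[used], remap[tets])
    r_n = np.linalg.norm(mesh.nodes_mm[:, :2], axis=1)
    e1 = np.isclose(r_n, a, rtol=1e-6)
    e2 = np.isclose(r_n, b, rtol=1e-6)
    phi = _solve_chamber(mesh, e1, e2, np.zeros(3))
    I0 = _power_current(mesh, phi)
    r_mid = math.sqrt(a * b)
    probe = np.array([r_mid, 0.0, h / 2.0])
    E0 = _probe_field(mesh, phi, probe, radius_mm=0.15 * (b - a))
    sol = FieldSolution(I_0=I0, E_0=E0, n_elements=mesh.n_elements,
                        n_nodes=mesh.n_nodes, mesh=mesh, phi=phi)
    sol._ctx = {}
    return sol
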