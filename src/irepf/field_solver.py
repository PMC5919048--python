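"""2-D nonlinear electrostatic field solver for a two-needle electrode pair.

Solves the quasi-static potential problem

    -div( sigma(|E|) grad(phi) ) = 0

on a rectangular tissue domain containing two circular needle-electrode
cross-sections, with Dirichlet conditions phi = V0 on the anode and phi = 0 on
the cathode and an insulated (zero normal current) outer boundary.  The
field-dependent conductivity makes the problem nonlinear; it is solved by
Picard (successive substitution) iteration: assemble with the conductivity of
the previous field iterate, solve the linear system, recompute |E|, repeat
until the relative L2 change of |E| drops below tolerance.

Discretization: linear (P1) finite elements on an unstructured triangulation.
The mesh is a Delaunay triangulation of a deterministic graded point cloud —
concentric rings around each electrode, nested background grids coarsening
away from the electrodes, and points along the outer rectangle — with the
triangles inside the electrode discs removed.  Node coordinates are in mm,
potentials in V, field magnitudes reported in V/cm.

Mesh refinement for the ablation-area convergence study scales every point
spacing by 1/sqrt(2) per step and stops when the ablation area changes by
less than 0.1 % between consecutive meshes.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu
from scipy.spatial import Delaunay

from .conductivity import ConductivityParams, sigma_of_field
from .errors import ConvergenceError, MeshError

__all__ = [
    "SimulationDomain",
    "Mesh",
    "FieldSolution",
    "build_mesh",
    "solve_potential",
    "electrode_currents",
    "converge_mesh",
]

#: mm -> cm gradient conversion: d(phi)/d(mm) in V/mm equals 10 V/cm.
_V_PER_MM_TO_V_PER_CM = 10.0


@dataclass(frozen=True)
class SimulationDomain:
    """Rectangular tissue domain with a centred pair of needle electrodes.

    The electrode axis runs along x through the domain centre; the anode is
    the electrode at smaller x.  Dimensions in mm, voltage in V.
    """

    width_mm: float = 100.0
    height_mm: float = 80.0
    electrode_diameter_mm: float = 1.0
    electrode_spacing_mm: float = 10.0
    applied_voltage_v: float = 1000.0

    def __post_init__(self):
        if self.electrode_spacing_mm <= self.electrode_diameter_mm:
            raise MeshError("electrode spacing must exceed electrode diameter")
        half_extent = self.electrode_spacing_mm / 2 + self.electrode_diameter_mm / 2
        if half_extent >= self.width_mm / 2 or self.electrode_diameter_mm >= self.height_mm:
            raise MeshError("electrodes must lie fully inside the domain")
        if self.applied_voltage_v <= 0:
            raise MeshError("applied voltage must be positive")

    @property
    def center(self):
        return (self.width_mm / 2.0, self.height_mm / 2.0)

    @property
    def electrode_centers(self):
        cx, cy = self.center
        h = self.electrode_spacing_mm / 2.0
        return np.array([[cx - h, cy], [cx + h, cy]])  # [anode, cathode]

    @property
    def electrode_radius_mm(self):
        return self.electrode_diameter_mm / 2.0


@dataclass(frozen=True)
class Mesh:
    """Conforming triangulation of the domain minus the electrode discs."""

    points: np.ndarray          # (N, 2) node coordinates, mm
    triangles: np.ndarray       # (M, 3) node indices
    areas: np.ndarray           # (M,) element areas, mm^2
    anode_nodes: np.ndarray     # indices of nodes on the anode surface
    cathode_nodes: np.ndarray   # indices of nodes on the cathode surface
    boundary_nodes: np.ndarray  # indices of nodes on the outer rectangle
    resolution: float           # target element size in the region of interest
    domain: SimulationDomain

    @property
    def n_nodes(self) -> int:
        return int(self.points.shape[0])

    @property
    def n_elements(self) -> int:
        return int(self.triangles.shape[0])

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())


@dataclass
class FieldSolution:
    """Converged nodal potential and derived field on one mesh."""

    mesh: Mesh
    phi: np.ndarray           # (N,) potential, V
    e_mag_node: np.ndarray    # (N,) field magnitude, V/cm (area-weighted recovery)
    e_mag_elem: np.ndarray    # (M,) element field magnitude, V/cm
    sigma_elem: np.ndarray    # (M,) element conductivity, S/m
    applied_voltage_v: float
    iterations: int
    residual_history: list = dc_field(default_factory=list)


def _ring_points(center, radius_inner, radius_outer, h0, h_cap, growth=1.22):
    """Concentric rings of points from the electrode surface outwards."""
    pts = []
    surface = None
    r, h, k = radius_inner, h0, 0
    while r < radius_outer:
        n = max(12, int(np.ceil(2 * np.pi * r / h)))
        theta = (np.arange(n) + 0.5 * (k % 2)) * (2 * np.pi / n)
        ring = np.column_stack(
            [center[0] + r * np.cos(theta), center[1] + r * np.sin(theta)]
        )
        pts.append(ring)
        if k == 0:
            surface = ring
        r += h
        h = min(h * growth, h_cap)
        k += 1
    return np.vstack(pts), surface


def _grid_points(xlo, xhi, ylo, yhi, spacing, rng, jitter=0.18):
    nx = max(2, int(round((xhi - xlo) / spacing)) + 1)
    ny = max(2, int(round((yhi - ylo) / spacing)) + 1)
    xs = np.linspace(xlo, xhi, nx)
    ys = np.linspace(ylo, yhi, ny)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    pts += rng.uniform(-jitter, jitter, pts.shape) * spacing
    return pts


def build_mesh(domain: SimulationDomain, resolution: float) -> Mesh:
    """Triangulate the domain at a target element size ``resolution`` (mm).

    ``resolution`` sets the point spacing in the treatment region between and
    around the electrodes; spacing near the electrode surfaces is about a
    third of it and grows geometrically outwards, and background spacing
    coarsens in nested boxes toward the outer boundary.  The point cloud is
    deterministic (fixed jitter stream), so identical inputs give identical
    meshes.
    """
    if not (0 < resolution < domain.electrode_diameter_mm):
        raise MeshError(
            f"resolution must lie in (0, electrode diameter); got {resolution}"
        )
    rng = np.random.default_rng(987_1461)  # fixed stream: meshing is deterministic
    a = domain.electrode_radius_mm
    cx, cy = domain.center
    W, H = domain.width_mm, domain.height_mm
    centers = domain.electrode_centers
    h0 = 0.35 * resolution
    ring_outer = 0.45 * domain.electrode_spacing_mm

    clouds, surfaces = [], []
    for c in centers:
        ring, surface = _ring_points(c, a, ring_outer, h0, h_cap=resolution)
        clouds.append(ring)
        surfaces.append(surface)

    # Nested background boxes, coarsening away from the electrodes.
    s1 = resolution
    b1 = (16.0 + domain.electrode_spacing_mm, 12.0 + domain.electrode_spacing_mm / 2)
    g1 = _grid_points(cx - b1[0], cx + b1[0], cy - b1[1], cy + b1[1], s1, rng)
    d_elec = np.min(
        [np.hypot(g1[:, 0] - c[0], g1[:, 1] - c[1]) for c in centers], axis=0
    )
    g1 = g1[d_elec > ring_outer + 0.55 * s1]
    clouds.append(g1)

    s2 = 2.4 * resolution
    b2 = (min(2 * b1[0], W / 2 - s2), min(2 * b1[1], H / 2 - s2))
    g2 = _grid_points(cx - b2[0], cx + b2[0], cy - b2[1], cy + b2[1], s2, rng)
    inside_b1 = (np.abs(g2[:, 0] - cx) < b1[0] + 0.4 * s2) & (
        np.abs(g2[:, 1] - cy) < b1[1] + 0.4 * s2
    )
    clouds.append(g2[~inside_b1])

    s3 = min(6.0 * resolution, 5.0)
    g3 = _grid_points(0.7 * s3, W - 0.7 * s3, 0.7 * s3, H - 0.7 * s3, s3, rng, jitter=0.12)
    inside_b2 = (np.abs(g3[:, 0] - cx) < b2[0] + 0.4 * s3) & (
        np.abs(g3[:, 1] - cy) < b2[1] + 0.4 * s3
    )
    clouds.append(g3[~inside_b2])

    # Outer rectangle: exact boundary points (no jitter) including corners.
    nbx = max(2, int(np.ceil(W / s3)) + 1)
    nby = max(2, int(np.ceil(H / s3)) + 1)
    ex = np.linspace(0.0, W, nbx)
    ey = np.linspace(0.0, H, nby)
    edge = np.vstack(
        [
            np.column_stack([ex, np.zeros(nbx)]),
            np.column_stack([ex, np.full(nbx, H)]),
            np.column_stack([np.zeros(nby - 2), ey[1:-1]]),
            np.column_stack([np.full(nby - 2, W), ey[1:-1]]),
        ]
    )
    clouds.append(edge)

    points = np.vstack(clouds)
    # Clip any jittered stragglers into the open domain.
    margin = 0.2 * s3
    interior = points[: -edge.shape[0]]
    np.clip(interior[:, 0], margin, W - margin, out=interior[:, 0])
    np.clip(interior[:, 1], margin, H - margin, out=interior[:, 1])

    tri = Delaunay(points)
    simplices = tri.simplices
    p = points
    centroids = p[simplices].mean(axis=1)
    keep = np.ones(len(simplices), dtype=bool)
    for c in centers:
        keep &= np.hypot(centroids[:, 0] - c[0], centroids[:, 1] - c[1]) > a
    simplices = simplices[keep]

    x, y = p[simplices, 0], p[simplices, 1]
    areas = 0.5 * (
        (x[:, 1] - x[:, 0]) * (y[:, 2] - y[:, 0])
        - (x[:, 2] - x[:, 0]) * (y[:, 1] - y[:, 0])
    )
    flip = areas < 0
    simplices[flip] = simplices[flip][:, ::-1]
    areas = np.abs(areas)
    good = areas > 1e-12
    simplices, areas = simplices[good], areas[good]

    dist = [np.hypot(p[:, 0] - c[0], p[:, 1] - c[1]) for c in centers]
    anode = np.flatnonzero(np.abs(dist[0] - a) < 1e-9)
    cathode = np.flatnonzero(np.abs(dist[1] - a) < 1e-9)
    if anode.size < 8 or cathode.size < 8:
        raise MeshError("resolution too coarse to resolve the electrodes")
    on_edge = (
        (np.abs(p[:, 0]) < 1e-9)
        | (np.abs(p[:, 0] - W) < 1e-9)
        | (np.abs(p[:, 1]) < 1e-9)
        | (np.abs(p[:, 1] - H) < 1e-9)
    )
    return Mesh(
        points=p,
        triangles=simplices,
        areas=areas,
        anode_nodes=anode,
        cathode_nodes=cathode,
        boundary_nodes=np.flatnonzero(on_edge),
        resolution=float(resolution),
        domain=domain,
    )


def _shape_gradients(mesh: Mesh):
    """P1 shape-function gradient coefficients b_i, c_i per element."""
    p, t = mesh.points, mesh.triangles
    x, y = p[t, 0], p[t, 1]
    b = y[:, [1, 2, 0]] - y[:, [2, 0, 1]]
    c = x[:, [2, 0, 1]] - x[:, [1, 2, 0]]
    return b, c


def _assemble(mesh: Mesh, sigma_elem, b, c):
    coef = sigma_elem / (4.0 * mesh.areas)
    ke = coef[:, None, None] * (
        b[:, :, None] * b[:, None, :] + c[:, :, None] * c[:, None, :]
    )
    t = mesh.triangles
    rows = np.repeat(t, 3, axis=1).ravel()
    cols = np.tile(t, (1, 3)).ravel()
    K = sparse.coo_matrix(
        (ke.ravel(), (rows, cols)), shape=(mesh.n_nodes, mesh.n_nodes)
    ).tocsr()
    return K


def _element_field(mesh: Mesh, phi, b, c):
    """Element |E| in V/cm from the nodal potential."""
    ph = phi[mesh.triangles]
    ex = -(b * ph).sum(axis=1) / (2.0 * mesh.areas)  # V/mm
    ey = -(c * ph).sum(axis=1) / (2.0 * mesh.areas)
    return np.hypot(ex, ey) * _V_PER_MM_TO_V_PER_CM


def _nodal_field(mesh: Mesh, e_elem):
    """Area-weighted recovery of the element field at the nodes."""
    num = np.zeros(mesh.n_nodes)
    den = np.zeros(mesh.n_nodes)
    w = mesh.areas
    for k in range(3):
        np.add.at(num, mesh.triangles[:, k], w * e_elem)
        np.add.at(den, mesh.triangles[:, k], w)
    return num / np.where(den > 0, den, 1.0)


def solve_potential(
    mesh: Mesh,
    v0: float,
    cond,
    *,
    tol: float = 1e-6,
    max_iter: int = 100,
    relax: float = 1.0,
) -> FieldSolution:
    """Solve the (possibly nonlinear) potential problem on ``mesh``.

    ``cond`` is either a :class:`~irepf.conductivity.ConductivityParams`
    (field-dependent Gompertz conductivity, solved by Picard iteration with
    the uniform sigma0 state as initial iterate) or a plain number for a
    constant-conductivity (linear) solve.  Convergence is declared when the
    relative L2 change of the element field magnitude between consecutive
    iterates falls below ``tol``.  If the residual sequence grows, the
    conductivity update is automatically under-relaxed (factor 0.7).

    Raises
    ------
    ConvergenceError
        No convergence within ``max_iter`` iterations (history attached).
    """
    if v0 <= 0:
        raise ValueError("v0 must be positive")
    b, c = _shape_gradients(mesh)
    fixed = np.concatenate([mesh.anode_nodes, mesh.cathode_nodes])
    fixed_vals = np.concatenate(
        [np.full(mesh.anode_nodes.size, float(v0)), np.zeros(mesh.cathode_nodes.size)]
    )
    free = np.setdiff1d(np.arange(mesh.n_nodes), fixed)

    nonlinear = isinstance(cond, ConductivityParams)
    sigma_elem = np.full(
        mesh.n_elements, cond.sigma0 if nonlinear else float(cond)
    )

    def linear_solve(sig):
        K = _assemble(mesh, sig, b, c)
        K_ff = K[free][:, free].tocsc()
        rhs = -K[free][:, fixed] @ fixed_vals
        phi = np.empty(mesh.n_nodes)
        phi[fixed] = fixed_vals
        try:
            phi[free] = splu(K_ff).solve(rhs)
        except RuntimeError as exc:  # singular factorization
            raise MeshError(f"singular system: {exc}") from exc
        return phi

    history = []
    prev_e = None
    relax_eff = relax
    for it in range(1, max_iter + 1):
        phi = linear_solve(sigma_elem)
        e_elem = _element_field(mesh, phi, b, c)
        if not nonlinear:
            return FieldSolution(
                mesh=mesh,
                phi=phi,
                e_mag_node=_nodal_field(mesh, e_elem),
                e_mag_elem=e_elem,
                sigma_elem=sigma_elem,
                applied_voltage_v=float(v0),
                iterations=1,
                residual_history=[0.0],
            )
        if prev_e is not None:
            delta = float(
                np.linalg.norm(e_elem - prev_e) / max(np.linalg.norm(e_elem), 1e-300)
            )
            history.append(delta)
            if delta < tol:
                return FieldSolution(
                    mesh=mesh,
                    phi=phi,
                    e_mag_node=_nodal_field(mesh, e_elem),
                    e_mag_elem=e_elem,
                    sigma_elem=sigma_elem,
                    applied_voltage_v=float(v0),
                    iterations=it,
                    residual_history=history,
                )
            if len(history) >= 2 and history[-1] > history[-2]:
                relax_eff = 0.7 * relax
        prev_e = e_elem
        target = sigma_of_field(e_elem, cond)
        sigma_elem = relax_eff * target + (1.0 - relax_eff) * sigma_elem
    raise ConvergenceError(
        f"Picard iteration did not reach tol={tol:g} in {max_iter} iterations",
        history=history,
    )


def electrode_currents(sol: FieldSolution):
    """Total current (per unit depth) through anode and cathode.

    Computed from the discrete reaction fluxes sum_i (K phi)_i over the
    Dirichlet nodes of each electrode; on a conservative discretization the
    two should balance.  Units: S*V per metre of electrode depth.
    """
    mesh = sol.mesh
    b, c = _shape_gradients(mesh)
    K = _assemble(mesh, sol.sigma_elem, b, c)
    r = K @ sol.phi
    return float(r[mesh.anode_nodes].sum()), float(r[mesh.cathode_nodes].sum())


def converge_mesh(
    domain: SimulationDomain,
    cond,
    target,
    start_resolution: float = 0.8,
    *,
    area_rtol: float = 1e-3,
    max_refinements: int = 12,
    solver_kwargs: dict | None = None,
):
    """Refine the mesh until the ablation area is grid-independent.

    ``target`` selects the area being monitored: a plain number is a lethal
    field threshold in V/cm (binary threshold-model area), while a tuple
    ``(family, x)`` of a survival family and its covariate value monitors the
    statistical-model ablation area (viability <= 1 %).  The resolution is
    scaled by 1/sqrt(2) each step and refinement stops when the area changes
    by less than ``area_rtol`` (default 0.1 %) between consecutive meshes.

    Returns ``(mesh, solution, history)`` where history is a list of
    ``(resolution, n_elements, area_mm2)`` records for every mesh visited.

    Raises
    ------
    ConvergenceError
        Criterion not met within ``max_refinements`` steps (history attached).
    """
    from .ablation import ablation_area, eft_model_area, viability_map

    solver_kwargs = solver_kwargs or {}
    res = float(start_resolution)
    history = []
    prev = None
    for _ in range(max_refinements + 1):
        mesh = build_mesh(domain, res)
        sol = solve_potential(mesh, domain.applied_voltage_v, cond, **solver_kwargs)
        if isinstance(target, tuple):
            fam, x = target
            area = ablation_area(mesh, viability_map(sol, fam, x))
        else:
            area = eft_model_area(sol, float(target))
        history.append((res, mesh.n_elements, area))
        if prev is not None and abs(area - prev[1]) / max(abs(prev[1]), 1e-300) < area_rtol:
            return mesh, sol, history
        prev = (res, area)
        res /= np.sqrt(2.0)
    raise ConvergenceError(
        f"ablation area not converged to {area_rtol:.1%} within "
        f"{max_refinements} refinements",
        history=history,
    )
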