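"""Discrete modal analysis of the layered circular plate.

Transverse vibration of the equivalent single-layer Kirchhoff plate is
discretized with Morley triangles — the simplest convergent nonconforming
element for the biharmonic operator, with vertex deflections and edge-midpoint
normal slopes as degrees of freedom. The generalized eigenproblem

    K v = omega^2 M v,   K = bending(D_eff, nu_eff) + k_winkler * Gram,
                         M = mu * Gram,

is solved sparse shift-inverted. Edge conditions: full clamp, free, or three
clamped arcs ("tri-arc") emulating the packaging supports under the Transwell;
the Winkler term models the agar/media bed. Free edges are natural in this
formulation (no constraint), so mixed arc/free boundaries need no special
treatment; a free plate without foundation exposes its three rigid-body modes
at ~0 Hz, which are flagged rather than treated as an error.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sparse
import scipy.sparse.linalg as splinalg
from scipy.interpolate import LinearNDInterpolator

from .fields import DisplacementField, raster_coords
from .plate_theory import PlateAssembly, laminate_rigidity

logger = logging.getLogger("holovib")

__all__ = ["CircularMesh", "BoundaryPattern", "FEMode", "Operators",
           "build_mesh", "assemble", "solve_modes", "fe_modes"]

_MAX_DOFS = 2_000_000  # keeps factorization within a desktop memory budget

# degree-4 Dunavant quadrature on the reference triangle (barycentric)
_QW = np.array([0.109951743655322] * 3 + [0.223381589678011] * 3)
_QB = np.array([
    [0.816847572980459, 0.091576213509771, 0.091576213509771],
    [0.091576213509771, 0.816847572980459, 0.091576213509771],
    [0.091576213509771, 0.091576213509771, 0.816847572980459],
    [0.108103018168070, 0.445948490915965, 0.445948490915965],
    [0.445948490915965, 0.108103018168070, 0.445948490915965],
    [0.445948490915965, 0.445948490915965, 0.108103018168070],
])


# ---------------------------------------------------------------------------
# mesh
# ---------------------------------------------------------------------------

@dataclass
class CircularMesh:
    radius: float
    nodes: np.ndarray            # (N, 2)
    triangles: np.ndarray        # (T, 3)
    edges: np.ndarray            # (E, 2) sorted node pairs
    tri_edges: np.ndarray        # (T, 3) edge ids, local edge k opposite vertex k
    edge_mid: np.ndarray         # (E, 2)
    edge_normal: np.ndarray      # (E, 2) global unit normal per edge
    boundary_nodes: np.ndarray   # node indices on the rim
    boundary_theta: np.ndarray   # angle (rad) of each boundary node
    boundary_edges: np.ndarray   # edge indices on the rim
    worst_aspect: float = 0.0

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.triangles)

    @property
    def n_dofs(self) -> int:
        return self.n_nodes + len(self.edges)

    def dump(self) -> str:
        """Plain-text node/cell dump (one node or cell per line)."""
        lines = [f"# circular mesh  radius_m={self.radius}  nodes={self.n_nodes} "
                 f"cells={self.n_elements}"]
        lines += [f"n {x:.9e} {y:.9e}" for x, y in self.nodes]
        lines += [f"c {a} {b} {c}" for a, b, c in self.triangles]
        return "\n".join(lines) + "\n"


def _merge_rings(inner_ids, inner_ang, outer_ids, outer_ang):
    """Triangulate the annulus between concentric rings of 6i and 6(i+1) nodes.

    One 60-degree sector is merged by angle and replicated to the other five
    by index rotation, so the connectivity is exactly 6-fold symmetric and
    symmetry-degenerate mode pairs are not split by the discretization.
    """
    ni, no = len(inner_ids), len(outer_ids)
    ki, ko = ni // 6, no // 6
    sector: list[tuple[int, int, int]] = []   # (kind, a, b): kind 0 advances inner
    a = b = 0
    while a < ki or b < ko:
        nxt_i = inner_ang[(a + 1) % ni] + 2 * np.pi * ((a + 1) // ni)
        nxt_j = outer_ang[(b + 1) % no] + 2 * np.pi * ((b + 1) // no)
        if a < ki and (b >= ko or nxt_i <= nxt_j):
            sector.append((0, a, b))
            a += 1
        else:
            sector.append((1, a, b))
            b += 1
    tris = []
    for s in range(6):
        oi, oo = s * ki, s * ko
        for kind, a, b in sector:
            if kind == 0:
                tris.append((inner_ids[(a + oi) % ni], outer_ids[(b + oo) % no],
                             inner_ids[(a + 1 + oi) % ni]))
            else:
                tris.append((inner_ids[(a + oi) % ni], outer_ids[(b + oo) % no],
                             outer_ids[(b + 1 + oo) % no]))
    return tris


def build_mesh(radius: float, target_edge: float) -> CircularMesh:
    """Quasi-uniform Delaunay triangulation of the disc from concentric rings."""
    if not 0 < target_edge < radius:
        raise ValueError("need 0 < target_edge < radius")
    n_rings = max(3, round(radius / target_edge))
    est_nodes = 1 + 3 * n_rings * (n_rings + 1)
    if 4 * est_nodes > _MAX_DOFS:
        raise MemoryError(
            f"target_edge {target_edge:g} m implies ~{4 * est_nodes} DOFs, "
            f"beyond the {_MAX_DOFS} budget; coarsen the mesh")

    pts = [(0.0, 0.0)]
    ring_ids: list[np.ndarray] = [np.array([0])]
    ring_ang: list[np.ndarray] = [np.array([0.0])]
    for i in range(1, n_rings + 1):
        r = radius * i / n_rings
        k = 6 * i
        ang = 2 * np.pi * np.arange(k) / k + (np.pi / k) * (i % 2)  # stagger rings
        ring_ids.append(np.arange(len(pts), len(pts) + k))
        ring_ang.append(ang)
        pts.extend(zip(r * np.cos(ang), r * np.sin(ang)))
    nodes = np.array(pts)
    # structured ring-to-ring triangulation: deterministic and exactly 6-fold
    # symmetric, so symmetry-degenerate mode pairs stay unmixed
    tris: list[tuple[int, int, int]] = []
    first = ring_ids[1]
    for j in range(6):
        tris.append((0, first[j], first[(j + 1) % 6]))
    for i in range(1, n_rings):
        tris.extend(_merge_rings(ring_ids[i], ring_ang[i],
                                 ring_ids[i + 1], ring_ang[i + 1]))
    triangles = np.array(tris)

    # unique edges; local edge k of a triangle is opposite local vertex k
    e_all = np.sort(triangles[:, [[1, 2], [2, 0], [0, 1]]].reshape(-1, 2), axis=1)
    edges, inv = np.unique(e_all, axis=0, return_inverse=True)
    tri_edges = inv.reshape(-1, 3)

    p, q = nodes[edges[:, 0]], nodes[edges[:, 1]]
    edge_mid = 0.5 * (p + q)
    tvec = q - p
    tvec /= np.linalg.norm(tvec, axis=1, keepdims=True)
    edge_normal = np.column_stack([-tvec[:, 1], tvec[:, 0]])

    boundary_nodes = ring_ids[-1]
    boundary_theta = np.mod(np.arctan2(nodes[boundary_nodes, 1],
                                       nodes[boundary_nodes, 0]), 2 * np.pi)
    on_rim = np.isin(edges, boundary_nodes).all(axis=1)
    # rim edges connect angularly adjacent rim nodes; interior chords are longer
    rim_len = np.linalg.norm(q - p, axis=1)
    boundary_edges = np.flatnonzero(on_rim & (rim_len < 2.5 * radius * np.pi / (6 * n_rings)))

    el = np.linalg.norm(
        nodes[triangles] - nodes[np.roll(triangles, -1, axis=1)], axis=2)
    worst = float((el.max(axis=1) / el.min(axis=1)).max())

    mesh = CircularMesh(radius, nodes, triangles, edges, tri_edges, edge_mid,
                        edge_normal, boundary_nodes, boundary_theta,
                        boundary_edges, worst)
    logger.debug("mesh: %d nodes, %d cells, worst edge-length ratio %.2f",
                 mesh.n_nodes, mesh.n_elements, worst)
    return mesh


# ---------------------------------------------------------------------------
# boundary pattern
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoundaryPattern:
    """Edge support layout: full clamp, free, or three clamped arcs
    (default 30 deg wide, centred at 90/210/330 deg, matching the three
    packaging indentations)."""

    kind: str = "full_clamp"
    arc_width: float = 30.0
    arc_centers: tuple[float, ...] = (90.0, 210.0, 330.0)

    def __post_init__(self) -> None:
        if self.kind not in ("full_clamp", "free", "tri_arc"):
            raise ValueError(f"unknown boundary pattern {self.kind!r}")
        if not 0 < self.arc_width < 120:
            raise ValueError("arc width must be in (0, 120) degrees")
        c = np.sort(np.mod(self.arc_centers, 360.0))
        gaps = np.diff(np.concatenate([c, [c[0] + 360.0]]))
        if len(c) and gaps.min() < self.arc_width:
            raise ValueError("clamped arcs overlap")

    def covers(self, theta: np.ndarray) -> np.ndarray:
        """True where angle theta (rad) lies inside a clamped arc."""
        theta = np.atleast_1d(theta)
        if self.kind == "full_clamp":
            return np.ones(theta.shape, dtype=bool)
        if self.kind == "free":
            return np.zeros(theta.shape, dtype=bool)
        deg = np.degrees(theta)[:, None]
        d = np.abs((deg - np.asarray(self.arc_centers)[None, :] + 180.0) % 360.0 - 180.0)
        # the tolerance keeps nodes sitting exactly on an arc edge classified
        # identically at all three arcs despite arctan2 rounding
        return (d <= self.arc_width / 2.0 + 1e-9).any(axis=1)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

@dataclass
class Operators:
    stiffness: sparse.csr_matrix
    mass: sparse.csr_matrix
    free: np.ndarray            # unconstrained dof indices
    mesh: CircularMesh
    assembly: PlateAssembly
    pattern: BoundaryPattern


def _element_matrices(mesh: CircularMesh, d_eff: np.ndarray, nu_eff: float,
                      mu: np.ndarray, k_winkler: float):
    """Batched Morley element stiffness/mass matrices (T, 6, 6)."""
    tri = mesh.triangles
    v = mesh.nodes[tri]                       # (T, 3, 2)
    centroid = v.mean(axis=1, keepdims=True)
    e1 = v[:, 1] - v[:, 0]
    e2 = v[:, 2] - v[:, 0]
    area = 0.5 * np.abs(e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0])
    L = np.sqrt(area)                         # local length scale
    xi = (v - centroid) / L[:, None, None]    # scaled vertex coords

    eid = mesh.tri_edges                      # (T, 3)
    mid = (mesh.edge_mid[eid] - centroid) / L[:, None, None]
    nrm = mesh.edge_normal[eid]               # global normals, unit length

    # B[t, row, coef]: DOF functionals applied to monomials 1, x, y, x2, xy, y2
    T = len(tri)
    B = np.zeros((T, 6, 6))
    B[:, 0:3, 0] = 1.0
    B[:, 0:3, 1] = xi[:, :, 0]
    B[:, 0:3, 2] = xi[:, :, 1]
    B[:, 0:3, 3] = xi[:, :, 0] ** 2
    B[:, 0:3, 4] = xi[:, :, 0] * xi[:, :, 1]
    B[:, 0:3, 5] = xi[:, :, 1] ** 2
    # d/dn in physical coords = (1/L) d/dn in scaled coords
    B[:, 3:6, 1] = nrm[:, :, 0]
    B[:, 3:6, 2] = nrm[:, :, 1]
    B[:, 3:6, 3] = 2.0 * mid[:, :, 0] * nrm[:, :, 0]
    B[:, 3:6, 4] = mid[:, :, 0] * nrm[:, :, 1] + mid[:, :, 1] * nrm[:, :, 0]
    B[:, 3:6, 5] = 2.0 * mid[:, :, 1] * nrm[:, :, 1]
    B[:, 3:6, :] /= L[:, None, None]
    coef = np.linalg.inv(B)                   # columns: monomial coeffs per basis fn

    # constant Hessians of each basis function (physical coords)
    hxx = 2.0 * coef[:, 3, :] / (L ** 2)[:, None]
    hxy = coef[:, 4, :] / (L ** 2)[:, None]
    hyy = 2.0 * coef[:, 5, :] / (L ** 2)[:, None]
    bend = (np.einsum("ta,tb->tab", hxx, hxx)
            + np.einsum("ta,tb->tab", hyy, hyy)
            + nu_eff * (np.einsum("ta,tb->tab", hxx, hyy)
                        + np.einsum("ta,tb->tab", hyy, hxx))
            + 2.0 * (1.0 - nu_eff) * np.einsum("ta,tb->tab", hxy, hxy))
    Ke = d_eff[:, None, None] * area[:, None, None] * bend

    # Gram matrix via quadrature (exact for quartics)
    qp = np.einsum("qk,tkd->tqd", _QB, xi)    # (T, Q, 2) scaled quad points
    mono = np.stack([np.ones_like(qp[:, :, 0]), qp[:, :, 0], qp[:, :, 1],
                     qp[:, :, 0] ** 2, qp[:, :, 0] * qp[:, :, 1],
                     qp[:, :, 1] ** 2], axis=2)          # (T, Q, 6)
    basis = np.einsum("tqm,tmb->tqb", mono, coef)        # (T, Q, 6)
    gram = np.einsum("q,tqa,tqb->tab", _QW, basis, basis) * area[:, None, None]

    Me = mu[:, None, None] * gram
    Ke = Ke + k_winkler * gram
    return Ke, Me


def assemble(mesh: CircularMesh, assembly: PlateAssembly,
             pattern: BoundaryPattern | None = None,
             inhomogeneity=None) -> Operators:
    """Build the stiffness/mass pair with the pattern's constraints recorded.

    ``inhomogeneity``, if given, is called with element centroid coordinates
    ``(xc, yc)`` (arrays) and must return per-element ``(d_eff, areal_density)``
    overriding the uniform laminate values — used for spatial defect studies.
    """
    if pattern is None:
        pattern = {"clamped": BoundaryPattern("full_clamp"),
                   "free": BoundaryPattern("free"),
                   "tri_arc_clamped": BoundaryPattern("tri_arc"),
                   "simply_supported": None}.get(assembly.boundary)
        if pattern is None:
            raise ValueError("simply supported edges are closed-form only; "
                             "pass an explicit BoundaryPattern for FE use")
    lam = laminate_rigidity(assembly.layers)
    nu_eff = assembly.effective_poisson()
    T = mesh.n_elements
    if inhomogeneity is None:
        d_eff = np.full(T, lam.d_eff)
        mu = np.full(T, lam.areal_density)
    else:
        cx = mesh.nodes[mesh.triangles].mean(axis=1)
        d_eff, mu = inhomogeneity(cx[:, 0], cx[:, 1])
        d_eff = np.broadcast_to(np.asarray(d_eff, float), (T,)).copy()
        mu = np.broadcast_to(np.asarray(mu, float), (T,)).copy()

    Ke, Me = _element_matrices(mesh, d_eff, nu_eff, mu,
                               assembly.foundation_stiffness)

    n_nodes = mesh.n_nodes
    dofs = np.concatenate([mesh.triangles, mesh.tri_edges + n_nodes], axis=1)  # (T, 6)
    rows = np.repeat(dofs, 6, axis=1).ravel()
    cols = np.tile(dofs, (1, 6)).ravel()
    nd = mesh.n_dofs
    K = sparse.coo_matrix((Ke.ravel(), (rows, cols)), shape=(nd, nd)).tocsr()
    M = sparse.coo_matrix((Me.ravel(), (rows, cols)), shape=(nd, nd)).tocsr()

    clamp_nodes = mesh.boundary_nodes[pattern.covers(mesh.boundary_theta)]
    mid = mesh.edge_mid[mesh.boundary_edges]
    mid_theta = np.mod(np.arctan2(mid[:, 1], mid[:, 0]), 2 * np.pi)
    clamp_edges = mesh.boundary_edges[pattern.covers(mid_theta)]
    constrained = np.concatenate([clamp_nodes, clamp_edges + n_nodes])
    free = np.setdiff1d(np.arange(nd), constrained)
    return Operators(K, M, free, mesh, assembly, pattern)


# ---------------------------------------------------------------------------
# eigensolution
# ---------------------------------------------------------------------------

@dataclass
class FEMode:
    frequency_hz: float
    shape: DisplacementField
    mass_norm: float
    rigid: bool = False
    vector: np.ndarray | None = None   # full dof vector, M-orthonormal


def _canonicalize_degenerate(vals: np.ndarray, vecs: np.ndarray,
                             M: sparse.csc_matrix) -> np.ndarray:
    """Fix the arbitrary basis inside degenerate eigenvalue clusters.

    Within each cluster the combination with the largest mass-weighted mean
    (the most piston/axisymmetric member) is rotated to the front via a
    deterministic Householder reflection; M-orthonormality is preserved. For
    isolated eigenvalues this is a no-op.
    """
    scale = max(abs(vals).max(), 1.0)
    i = 0
    while i < len(vals):
        j = i + 1
        while j < len(vals) and abs(vals[j] - vals[i]) < 1e-6 * scale:
            j += 1
        if j - i > 1:
            V = vecs[:, i:j]
            t = np.ones(M.shape[0]) @ (M @ V)     # ~ integral mu phi dA per vector
            nt = np.linalg.norm(t)
            if nt > 1e-12 * np.sqrt(M.sum()):
                u = t / nt
                w = u.copy()
                w[0] -= 1.0                        # H e1 = u
                if np.linalg.norm(w) > 1e-12:
                    H = np.eye(j - i) - 2.0 * np.outer(w, w) / (w @ w)
                    vecs[:, i:j] = V @ H
        i = j
    return vecs


def solve_modes(operators: Operators, n_modes: int, grid: int = 65) -> list[FEMode]:
    """Smallest ``n_modes`` eigenpairs, frequencies ascending, shapes on the raster.

    Deterministic: shift-invert about a small negative shift (so that free
    plates with singular stiffness still factorize) with a fixed all-ones
    ARPACK start vector. Shapes are max-abs normalized with the sign fixed so
    the value nearest the plate centre is >= 0.
    """
    if n_modes < 1:
        raise ValueError("need n_modes >= 1")
    free = operators.free
    K = operators.stiffness[np.ix_(free, free)].tocsc()
    M = operators.mass[np.ix_(free, free)].tocsc()
    scale = (K.diagonal().mean() / M.diagonal().mean())
    sigma = -1e-6 * scale  # documented equivalent of a zero shift
    try:
        vals, vecs = splinalg.eigsh(K, k=min(n_modes, K.shape[0] - 1), M=M,
                                    sigma=sigma, which="LM",
                                    v0=np.ones(K.shape[0]))
    except splinalg.ArpackNoConvergence as err:  # pragma: no cover
        raise RuntimeError(
            f"eigensolver failed to converge: {len(err.eigenvalues)} of "
            f"{n_modes} pairs after ARPACK's iteration budget") from err
    order = np.argsort(vals)
    vals, vecs = vals[order], vecs[:, order]
    vecs = _canonicalize_degenerate(vals, vecs, M)

    mesh = operators.mesh
    rigid_tol = 1e-8 * scale
    x, y, mask, pixel = raster_coords(mesh.radius, grid)
    modes: list[FEMode] = []
    for lam_val, vec in zip(vals, vecs.T):
        full = np.zeros(operators.mesh.n_dofs)
        full[free] = vec
        interp = LinearNDInterpolator(mesh.nodes, full[:mesh.n_nodes], fill_value=np.nan)
        w = interp(x, y)
        w = np.where(mask, w, np.nan)
        peak = np.nanmax(np.abs(w))
        if peak > 0:
            w = w / peak
        ci = (grid - 1) // 2
        if np.isfinite(w[ci, ci]) and w[ci, ci] < 0:
            w, full = -w, -full
        shape = DisplacementField(w, mask, pixel, mesh.radius, unit="1")
        freq = math.sqrt(max(lam_val, 0.0)) / (2.0 * math.pi)
        rigid = lam_val < rigid_tol
        if rigid:
            logger.info("rigid-body mode flagged at %.3g Hz", freq)
        modes.append(FEMode(freq, shape, float(vec @ (M @ vec)), rigid, full))
    return modes


def fe_modes(assembly: PlateAssembly, pattern: BoundaryPattern | None = None,
             target_edge: float | None = None, n_modes: int = 6,
             grid: int = 65, inhomogeneity=None) -> list[FEMode]:
    """Convenience pipeline: mesh, assemble, solve."""
    mesh = build_mesh(assembly.radius, target_edge or assembly.radius / 12)
    ops = assemble(mesh, assembly, pattern, inhomogeneity)
    return solve_modes(ops, n_modes, grid=grid)
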