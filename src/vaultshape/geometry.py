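"""Geometric primitives: mirroring, Procrustes alignment, volumes,
voxelization, axial contours and rigid ICP registration.

Conventions (shared package-wide): midsagittal plane at x = 0, right = +x,
anterior = +y; contour angles start at anterior (θ = 0) and increase toward
the subject's left, so θ ∈ (0, π) is the left half.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .mesh import CorrespondedShapeSet, MeshError, SymmetryPairing, TriangleMesh

_MIRROR = np.diag([-1.0, 1.0, 1.0])


def mirror_shape(shape: np.ndarray, pairing: SymmetryPairing) -> np.ndarray:
    """Reflect a V×3 shape across x = 0 and re-order rows by the symmetry
    pairing so the result stays in correspondence with the input.

    The operation is an involution: ``mirror_shape(mirror_shape(s)) == s``.
    """
    if pairing is None:
        raise MeshError("mirroring requires a symmetry pairing")
    shape = np.asarray(shape, dtype=float)
    if shape.shape != (pairing.n_vertices, 3):
        raise MeshError("shape does not match pairing size")
    reflected = shape @ _MIRROR
    return reflected[pairing.partner]


def mirror_mesh(mesh: TriangleMesh) -> TriangleMesh:
    return mesh.with_vertices(mirror_shape(mesh.vertices, mesh.pairing))


@dataclass
class AlignedShapeSet:
    """Output of generalized Procrustes analysis.

    ``aligned`` is N×V×3 in the consensus frame; ``consensus`` is its mean.
    ``rotations``/``translations``/``scales`` map each raw shape into the
    consensus frame as ``scale * (x - translation) @ rotation``.
    """

    aligned: np.ndarray
    consensus: np.ndarray
    rotations: np.ndarray
    translations: np.ndarray
    scales: np.ndarray
    centroid_sizes: np.ndarray
    procrustes_ss: float
    n_iterations: int
    source: CorrespondedShapeSet | None = None

    @property
    def n_shapes(self) -> int:
        return int(self.aligned.shape[0])

    @property
    def flattened(self) -> np.ndarray:
        """N×3V row-per-shape matrix (x0 y0 z0 x1 y1 z1 …)."""
        n = self.aligned.shape[0]
        return self.aligned.reshape(n, -1)


def centroid_size(shape: np.ndarray) -> float:
    """Root-sum-of-squares distance of vertices to their centroid."""
    c = shape - shape.mean(axis=0)
    return float(np.sqrt(np.sum(c * c)))


def _optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Kabsch rotation-only solution (det +1; reflections forbidden)."""
    h = source.T @ target
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    diag = np.diag([1.0, 1.0, d])
    return u @ diag @ vt


def generalized_procrustes(
    shape_set: CorrespondedShapeSet | np.ndarray,
    with_scaling: bool = True,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> AlignedShapeSet:
    """Iterative generalized Procrustes alignment of N corresponded shapes.

    Translation to zero centroid, optional scaling to unit centroid size,
    and rotation-only orthogonal alignment to the running consensus, until
    the consensus moves less than ``tol`` (RMS).  Reflections are never
    introduced, so mirrored cohort instances stay mirrored.
    """
    source = shape_set if isinstance(shape_set, CorrespondedShapeSet) else None
    shapes = shape_set.shapes if source is not None else np.asarray(shape_set, float)
    n = shapes.shape[0]
    if n < 2:
        raise MeshError("GPA needs at least two shapes")

    translations = shapes.mean(axis=1)
    centred = shapes - translations[:, None, :]
    sizes = np.sqrt(np.sum(centred**2, axis=(1, 2)))
    if np.any(sizes < 1e-12):
        raise MeshError("degenerate (all-coincident) shape in GPA input")
    if with_scaling:
        aligned = centred / sizes[:, None, None]
        scales = 1.0 / sizes
    else:
        aligned = centred.copy()
        scales = np.ones(n)

    rotations = np.tile(np.eye(3), (n, 1, 1))
    # order-invariant initial consensus (the mean of the centred shapes)
    # fixes the rotational gauge of the solution, so the result does not
    # depend on input ordering
    consensus = aligned.mean(axis=0)
    if centroid_size(consensus) < 1e-9:
        raise MeshError("degenerate initial consensus (cancelling shapes)")
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        for i in range(n):
            r = _optimal_rotation(aligned[i], consensus)
            aligned[i] = aligned[i] @ r
            rotations[i] = rotations[i] @ r
        new_consensus = aligned.mean(axis=0)
        if with_scaling:
            # keep consensus on the unit-size manifold for stable convergence
            new_consensus /= centroid_size(new_consensus)
        shift = np.sqrt(np.mean((new_consensus - consensus) ** 2))
        consensus = new_consensus
        if shift < tol:
            break
    consensus = aligned.mean(axis=0)
    ss = float(np.sum((aligned - consensus[None]) ** 2))
    return AlignedShapeSet(
        aligned=aligned,
        consensus=consensus,
        rotations=rotations,
        translations=translations,
        scales=scales,
        centroid_sizes=sizes,
        procrustes_ss=ss,
        n_iterations=n_iter,
        source=source,
    )


def closed_mesh_volume(mesh: TriangleMesh) -> tuple[float, float]:
    """Volume (mm³) and surface area (mm²) of a watertight mesh.

    Volume is the absolute value of the divergence-theorem signed volume, so
    the result does not depend on face orientation.
    """
    tm = mesh.to_trimesh()
    if not tm.is_watertight:
        raise MeshError(
            f"mesh is not watertight ({mesh.open_edge_count()} open edges)"
        )
    return abs(float(tm.volume)), float(tm.area)


@dataclass
class VoxelMask:
    """Axis-aligned binary occupancy grid; ``origin`` is the minimum corner
    of the grid in mm, voxel centres at origin + (i + 0.5) * resolution."""

    origin: np.ndarray
    resolution: float
    occupancy: np.ndarray

    @property
    def count(self) -> int:
        return int(self.occupancy.sum())

    @property
    def volume(self) -> float:
        return self.count * self.resolution**3


def voxelize(
    mesh: TriangleMesh, resolution: float, origin: np.ndarray | None = None,
    shape: tuple[int, int, int] | None = None,
) -> VoxelMask:
    """Voxelize a watertight mesh: a voxel is occupied iff its centre lies
    inside the surface (even–odd count of triangle crossings along +z).

    The grid tightly bounds the mesh plus a one-voxel margin unless an
    explicit ``origin``/``shape`` is given (used to voxelize two meshes on
    one shared grid for Dice).
    """
    if resolution <= 0:
        raise MeshError("voxel resolution must be positive")
    tm = mesh.to_trimesh()
    if not tm.is_watertight:
        raise MeshError(
            f"mesh is not watertight ({mesh.open_edge_count()} open edges)"
        )
    verts, faces = mesh.vertices, mesh.faces
    lo = verts.min(axis=0)
    hi = verts.max(axis=0)
    if origin is None:
        origin = lo - resolution
    origin = np.asarray(origin, dtype=float)
    if shape is None:
        shape = tuple(
            int(np.ceil((hi[k] - origin[k]) / resolution)) + 1 for k in range(3)
        )
    nx, ny, nz = shape
    occ = np.zeros(shape, dtype=bool)

    # Column rasterization: for every (x, y) voxel-centre column, collect the
    # z values where the column's +z ray crosses a triangle; voxel centres
    # with an odd number of crossings above them are inside.  A tiny
    # irrational offset keeps ray/edge coincidences from double counting.
    eps = resolution * 1.0e-6 * np.sqrt(2.0)
    cx = origin[0] + (np.arange(nx) + 0.5) * resolution + eps
    cy = origin[1] + (np.arange(ny) + 0.5) * resolution + eps * np.sqrt(3.0)
    cz = origin[2] + (np.arange(nz) + 0.5) * resolution

    crossings: dict[tuple[int, int], list[float]] = {}
    tri = verts[faces]  # F×3×3
    for a, b, c in tri:
        xmin = min(a[0], b[0], c[0])
        xmax = max(a[0], b[0], c[0])
        ymin = min(a[1], b[1], c[1])
        ymax = max(a[1], b[1], c[1])
        i0 = int(np.searchsorted(cx, xmin, side="left"))
        i1 = int(np.searchsorted(cx, xmax, side="right"))
        j0 = int(np.searchsorted(cy, ymin, side="left"))
        j1 = int(np.searchsorted(cy, ymax, side="right"))
        if i0 >= i1 or j0 >= j1:
            continue
        det = (b[1] - c[1]) * (a[0] - c[0]) + (c[0] - b[0]) * (a[1] - c[1])
        if abs(det) < 1e-14:
            continue  # triangle parallel to z rays
        px, py = np.meshgrid(cx[i0:i1], cy[j0:j1], indexing="ij")
        l1 = ((b[1] - c[1]) * (px - c[0]) + (c[0] - b[0]) * (py - c[1])) / det
        l2 = ((c[1] - a[1]) * (px - c[0]) + (a[0] - c[0]) * (py - c[1])) / det
        l3 = 1.0 - l1 - l2
        inside = (l1 >= 0) & (l2 >= 0) & (l3 >= 0)
        if not inside.any():
            continue
        zhit = l1 * a[2] + l2 * b[2] + l3 * c[2]
        ii, jj = np.nonzero(inside)
        for i, j, z in zip(ii + i0, jj + j0, zhit[inside]):
            crossings.setdefault((int(i), int(j)), []).append(float(z))

    for (i, j), zs in crossings.items():
        zs = np.sort(zs)
        # parity of crossings strictly below each voxel centre
        parity = np.searchsorted(zs, cz, side="left") % 2
        occ[i, j, :] = parity == 1
    return VoxelMask(origin=origin, resolution=float(resolution), occupancy=occ)


@dataclass
class RadialCurve:
    """Radial head-contour samples r(θ) at uniform angles in [0, 2π).

    θ = 0 points anterior (+y) and increases toward the subject's left
    (−x), so θ ∈ (0, π) covers the left half of the contour.
    """

    angles: np.ndarray
    radii: np.ndarray
    plane_height: float
    centroid: np.ndarray

    def radius_at(self, theta: float | np.ndarray) -> np.ndarray:
        """Periodic linear interpolation of r(θ)."""
        theta = np.mod(np.asarray(theta, dtype=float), 2 * np.pi)
        n = len(self.angles)
        step = 2 * np.pi / n
        idx = theta / step
        i0 = np.floor(idx).astype(int) % n
        i1 = (i0 + 1) % n
        frac = idx - np.floor(idx)
        return self.radii[i0] * (1 - frac) + self.radii[i1] * frac


def axial_radial_contour(
    mesh: TriangleMesh, plane_height: float, n_samples: int = 360
) -> RadialCurve:
    """Intersect the mesh with the horizontal plane z = plane_height and
    resample the resulting closed section at uniform angles about its
    centroid.  The section must be a single star-shaped loop."""
    tm = mesh.to_trimesh()
    section = tm.section(
        plane_origin=[0.0, 0.0, float(plane_height)], plane_normal=[0.0, 0.0, 1.0]
    )
    if section is None:
        raise MeshError(f"plane z={plane_height} does not intersect the mesh")
    # use the 3-D discrete loops directly: x, y retain the anatomical frame
    loops = section.discrete
    if len(loops) != 1:
        raise MeshError(
            f"plane z={plane_height} yields {len(loops)} loops; expected one"
        )
    pts = np.asarray(loops[0])[:, :2]
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    centroid = _polygon_centroid(pts)
    rel = pts - centroid
    # θ measured from +y toward −x (subject's left)
    seg_a = rel
    seg_b = np.roll(rel, -1, axis=0)
    thetas = np.arange(n_samples) * (2 * np.pi / n_samples)
    dirs = np.stack([-np.sin(thetas), np.cos(thetas)], axis=1)
    radii = _ray_polygon_radii(dirs, seg_a, seg_b)
    if np.any(~np.isfinite(radii)) or np.any(radii <= 0):
        raise MeshError("section is not star-shaped about its centroid")
    return RadialCurve(
        angles=thetas, radii=radii, plane_height=float(plane_height),
        centroid=centroid,
    )


def _polygon_centroid(pts: np.ndarray) -> np.ndarray:
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = cross.sum() / 2.0
    if abs(area) < 1e-12:
        return pts.mean(axis=0)
    cx = np.sum((x + xn) * cross) / (6.0 * area)
    cy = np.sum((y + yn) * cross) / (6.0 * area)
    return np.array([cx, cy])


def _ray_polygon_radii(
    dirs: np.ndarray, seg_a: np.ndarray, seg_b: np.ndarray
) -> np.ndarray:
    """Distance from the origin to the polygon boundary along each ray
    direction (segments given relative to the origin)."""
    radii = np.full(len(dirs), np.nan)
    e = seg_b - seg_a
    for k, d in enumerate(dirs):
        denom = d[0] * e[:, 1] - d[1] * e[:, 0]
        ok = np.abs(denom) > 1e-14
        t = np.full(len(e), np.nan)
        s = np.full(len(e), np.nan)
        t[ok] = (seg_a[ok, 0] * e[ok, 1] - seg_a[ok, 1] * e[ok, 0]) / denom[ok]
        s[ok] = (seg_a[ok, 0] * d[1] - seg_a[ok, 1] * d[0]) / denom[ok]
        hit = ok & (t > 0) & (s >= -1e-12) & (s <= 1 + 1e-12)
        if hit.any():
            radii[k] = np.max(t[hit])
    return radii


@dataclass
class RigidTransform:
    """x ↦ x @ rotation + translation."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other (apply ``other`` first)."""
        return RigidTransform(
            rotation=other.rotation @ self.rotation,
            translation=other.translation @ self.rotation + self.translation,
        )


def corresponded_rigid_align(
    source: np.ndarray, target: np.ndarray
) -> RigidTransform:
    """Least-squares rotation+translation mapping corresponded source points
    onto target (no scaling, no reflection)."""
    sc, tc = source.mean(axis=0), target.mean(axis=0)
    r = _optimal_rotation(source - sc, target - tc)
    return RigidTransform(rotation=r, translation=tc - sc @ r)


def closest_point_on_triangles(
    points: np.ndarray, tri_a: np.ndarray, tri_b: np.ndarray, tri_c: np.ndarray
) -> np.ndarray:
    """Closest point on each triangle (a, b, c) to each query point,
    vectorized over rows (standard barycentric region-case analysis)."""
    ab = tri_b - tri_a
    ac = tri_c - tri_a
    ap = points - tri_a
    d1 = np.sum(ab * ap, axis=1)
    d2 = np.sum(ac * ap, axis=1)
    bp = points - tri_b
    d3 = np.sum(ab * bp, axis=1)
    d4 = np.sum(ac * bp, axis=1)
    cp = points - tri_c
    d5 = np.sum(ab * cp, axis=1)
    d6 = np.sum(ac * cp, axis=1)
    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = d1 / (d1 - d3)
        v_ac = d2 / (d2 - d6)
        v_bc = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        denom = va + vb + vc
        v_in = vb / denom
        w_in = vc / denom

    out = tri_a + v_in[:, None] * ab + w_in[:, None] * ac  # interior default
    on_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    out[on_bc] = tri_b[on_bc] + v_bc[on_bc, None] * (tri_c - tri_b)[on_bc]
    on_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    out[on_ac] = tri_a[on_ac] + v_ac[on_ac, None] * ac[on_ac]
    on_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    out[on_ab] = tri_a[on_ab] + v_ab[on_ab, None] * ab[on_ab]
    at_c = (d6 >= 0) & (d5 <= d6)
    out[at_c] = tri_c[at_c]
    at_b = (d3 >= 0) & (d4 <= d3)
    out[at_b] = tri_b[at_b]
    at_a = (d1 <= 0) & (d2 <= 0)
    out[at_a] = tri_a[at_a]
    return out


class _SurfaceCorrespondence:
    """Nearest point on the target surface, searching the faces incident to
    each query's nearest target vertex."""

    def __init__(self, mesh: TriangleMesh):
        self.vertices = mesh.vertices
        self.tree = cKDTree(mesh.vertices)
        faces = mesh.faces
        incident: list[list[int]] = [[] for _ in range(len(mesh.vertices))]
        for f, (i, j, k) in enumerate(faces):
            incident[i].append(f)
            incident[j].append(f)
            incident[k].append(f)
        self.face_lists = [np.asarray(fl, dtype=np.intp) for fl in incident]
        self.tri = mesh.vertices[faces]

    def query(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        _, nn = self.tree.query(points)
        cand_faces = [self.face_lists[v] for v in nn]
        counts = np.array([len(c) for c in cand_faces])
        flat_faces = np.concatenate(cand_faces)
        rep = np.repeat(np.arange(len(points)), counts)
        tri = self.tri[flat_faces]
        closest = closest_point_on_triangles(
            points[rep], tri[:, 0], tri[:, 1], tri[:, 2]
        )
        d2 = np.sum((closest - points[rep]) ** 2, axis=1)
        # per-point argmin over its candidate block, vectorized
        offsets = np.cumsum(np.concatenate([[0], counts]))
        mins = np.minimum.reduceat(d2, offsets[:-1])
        hit = np.flatnonzero(d2 <= mins[rep])
        _, first = np.unique(rep[hit], return_index=True)
        pick = hit[first]
        return np.sqrt(d2[pick]), closest[pick]


class _VertexCorrespondence:
    """Nearest-vertex matching for bare point clouds."""

    def __init__(self, points: np.ndarray):
        self.points = points
        self.tree = cKDTree(points)

    def query(self, queries: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        dist, idx = self.tree.query(queries)
        return dist, self.points[idx]


def rigid_align_icp(
    source: TriangleMesh | np.ndarray,
    target: TriangleMesh | np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> tuple[RigidTransform, float, list[float]]:
    """Iterative closest point, rigid only (rotation + translation).

    Correspondence is the nearest point on the target surface when the
    target carries faces (robust against the vertex-lattice locking of
    nearest-vertex matching), else the nearest target vertex.  Returns the
    transform mapping source onto target, the final RMS distance, and the
    per-iteration RMS history (monotonically non-increasing).
    """
    src = source.vertices if isinstance(source, TriangleMesh) else np.asarray(source)
    if len(src) == 0:
        raise MeshError("ICP requires non-empty meshes")
    if isinstance(target, TriangleMesh) and target.n_faces > 0:
        matcher = _SurfaceCorrespondence(target)
        tgt_centroid = target.vertices.mean(axis=0)
    else:
        tgt = target.vertices if isinstance(target, TriangleMesh) else np.asarray(target)
        if len(tgt) == 0:
            raise MeshError("ICP requires non-empty meshes")
        matcher = _VertexCorrespondence(tgt)
        tgt_centroid = tgt.mean(axis=0)
    # centroid pre-alignment
    transform = RigidTransform(np.eye(3), tgt_centroid - src.mean(axis=0))
    moved = transform.apply(src)
    history: list[float] = []
    rms_prev = np.inf
    for _ in range(max_iter):
        dist, matched = matcher.query(moved)
        rms = float(np.sqrt(np.mean(dist**2)))
        history.append(rms)
        if rms_prev - rms < tol:
            break
        rms_prev = rms
        step = corresponded_rigid_align(moved, matched)
        moved = step.apply(moved)
        transform = step.compose(transform)
    dist, _ = matcher.query(moved)
    final_rms = float(np.sqrt(np.mean(dist**2)))
    return transform, final_rms, history
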