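"""Classical cranial severity and asymmetry indices.

The benchmark battery against which the shape-model severity index is
compared: cephalometrics (anteroposterior length, latero-lateral width,
cephalic index), cranial vault asymmetry (CVA) and its percentage index
(CVAI), head-contour measures in the Utrecht Cranial Shape Quantifier
family, hemisphere volume/surface ratios, vertex-wise mirror asymmetry,
left/right contour-difference AUC, and the mirror-overlap Dice coefficient.

The UCSQ-family formulas here are a documented local operationalization of
the named variables (forehead asymmetry ratio, gradient ratio, peak
positions) on the uniform radial contour; they are not the canonical
published definitions.

Angle convention matches :mod:`vaultshape.geometry`: θ = 0 anterior,
increasing toward the subject's left, so θ ∈ (0°, 90°) is the left anterior
quadrant and (270°, 360°) the right.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import trimesh

from .geometry import (
    RadialCurve,
    axial_radial_contour,
    corresponded_rigid_align,
    mirror_shape,
    rigid_align_icp,
    voxelize,
)
from .mesh import CorrespondedShapeSet, MeshError, SymmetryPairing, TriangleMesh


class IndexError_(ValueError):
    """Index computation failure (named to avoid shadowing the builtin)."""


def find_measurement_plane(
    mesh: TriangleMesh, n_heights: int = 19, n_samples: int = 180
) -> float:
    """Height of the axial section with maximal enclosed area, scanned over
    the central 5–95% of the mesh's vertical extent."""
    zmin, zmax = mesh.vertices[:, 2].min(), mesh.vertices[:, 2].max()
    heights = zmin + (zmax - zmin) * np.linspace(0.05, 0.95, n_heights)
    best_h, best_area = None, -np.inf
    for h in heights:
        try:
            curve = axial_radial_contour(mesh, h, n_samples)
        except MeshError:
            continue
        # polygon area from the radial samples
        area = 0.5 * np.sum(curve.radii * np.roll(curve.radii, -1)) * np.sin(
            2 * np.pi / n_samples
        )
        if area > best_area:
            best_area, best_h = area, h
    if best_h is None:
        raise IndexError_("no valid axial section found")
    return float(best_h)


def cephalometrics(
    mesh: TriangleMesh, plane_height: float | None = None, n_samples: int = 360
) -> dict:
    """AP length, latero-lateral width and cephalic index at an axial plane.

    cephalic_index = 100 · width / length, measured on the section contour
    in the anatomical frame (y = anteroposterior, x = latero-lateral).
    """
    if plane_height is None:
        plane_height = find_measurement_plane(mesh)
    curve = axial_radial_contour(mesh, plane_height, n_samples)
    x = -curve.radii * np.sin(curve.angles) + curve.centroid[0]
    y = curve.radii * np.cos(curve.angles) + curve.centroid[1]
    ap = float(y.max() - y.min())
    ll = float(x.max() - x.min())
    return {
        "AP_length": ap,
        "LL_width": ll,
        "cephalic_index": 100.0 * ll / ap,
        "plane_height": float(plane_height),
    }


def cva_cvai(
    mesh: TriangleMesh,
    plane_height: float | None = None,
    diagonal_angle: float = 30.0,
    n_samples: int = 360,
) -> dict:
    """Cranial vault asymmetry (CVA, mm) and asymmetry index (CVAI, %).

    The two cross-diagonals run through the section centroid at
    ±diagonal_angle from the anteroposterior axis: d1 joins anterior-left
    to posterior-right, d2 anterior-right to posterior-left.
    CVA = |d1 − d2|; CVAI = 100 · |d1 − d2| / max(d1, d2).
    """
    if plane_height is None:
        plane_height = find_measurement_plane(mesh)
    curve = axial_radial_contour(mesh, plane_height, n_samples)
    out = cva_cvai_from_curve(curve, diagonal_angle)
    out["plane_height"] = float(plane_height)
    out["diagonal_angle"] = float(diagonal_angle)
    return out


def cva_cvai_from_curve(curve: RadialCurve, diagonal_angle: float = 30.0) -> dict:
    """CVA/CVAI from a radial contour: d1 and d2 are the cross-diagonal
    lengths through the section centroid at ±diagonal_angle off anterior."""
    a = np.deg2rad(diagonal_angle)
    d1 = float(curve.radius_at(a) + curve.radius_at(np.pi + a))
    d2 = float(curve.radius_at(2 * np.pi - a) + curve.radius_at(np.pi - a))
    cva = abs(d1 - d2)
    return {"CVA": cva, "CVAI": 100.0 * cva / max(d1, d2), "d1": d1, "d2": d2}


def ucsq_measures(curve: RadialCurve) -> dict:
    """Head-contour measures in the UCSQ family (local operationalization).

    On each anterior quadrant (left: θ ∈ (0°, 90°); right: θ ∈ (270°,
    360°)): the peak position is the angle of maximal radius (reported in
    degrees from anterior, so symmetric heads give equal left/right
    values), the peak gradient is max |dr/dθ|;
    forehead_asymmetry_ratio = left max radius / right max radius and
    gradient_ratio = left peak gradient / right peak gradient.
    """
    theta_deg = np.rad2deg(curve.angles)
    left = (theta_deg > 0) & (theta_deg < 90)
    right = (theta_deg > 270) & (theta_deg < 360)
    if not left.any() or not right.any():
        raise IndexError_("curve resolution too coarse for quadrant measures")
    r = curve.radii
    dr = np.gradient(r, curve.angles, edge_order=2)
    grad_left = float(np.max(np.abs(dr[left])))
    grad_right = float(np.max(np.abs(dr[right])))
    if grad_left == 0 or grad_right == 0:
        raise IndexError_("flat contour: no gradient peak in a quadrant")
    r_left = float(r[left].max())
    r_right = float(r[right].max())
    peak_left = float(theta_deg[left][np.argmax(r[left])])
    peak_right = float(360.0 - theta_deg[right][np.argmax(r[right])])
    return {
        "forehead_asymmetry_ratio": r_left / r_right,
        "gradient_ratio": grad_left / grad_right,
        "peak_position_left": peak_left,
        "peak_position_right": peak_right,
    }


def hemisphere_ratios(mesh: TriangleMesh) -> dict:
    """Left/right hemisphere volume and outer-surface ratios.

    The mesh is clipped at the midsagittal plane x = 0; volumes use capped
    (closed) halves, surface areas use the open halves so the cut face does
    not count.  Ratios are left / right.
    """
    tm = mesh.to_trimesh()
    if not tm.is_watertight:
        raise MeshError(
            f"mesh is not watertight ({mesh.open_edge_count()} open edges)"
        )
    halves = {}
    for name, normal in (("left", [-1.0, 0, 0]), ("right", [1.0, 0, 0])):
        open_half = trimesh.intersections.slice_mesh_plane(
            tm, plane_normal=normal, plane_origin=[0.0, 0, 0], cap=False
        )
        if open_half is None or len(open_half.faces) == 0:
            raise IndexError_(f"clipping left nothing on the {name} side")
        # the open boundary must lie in the cut plane, else the half cannot
        # be closed by a planar cap
        open_half.merge_vertices()
        edge_idx = trimesh.grouping.group_rows(
            open_half.edges_sorted, require_count=1
        )
        if len(edge_idx):
            bx = open_half.vertices[
                np.unique(open_half.edges_sorted[edge_idx])
            ][:, 0]
            if np.max(np.abs(bx)) > 1e-6:
                raise IndexError_(f"{name} half boundary leaves the midplane")
        # capped-half volume via the divergence theorem with field (x,0,0):
        # the planar cap at x = 0 has zero x-flux, so the open half already
        # integrates to the closed volume.
        v = open_half.vertices
        tri = v[open_half.faces]
        n_vec = 0.5 * np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        centroid_x = tri[:, :, 0].mean(axis=1)
        volume = abs(float(np.sum(centroid_x * n_vec[:, 0])))
        halves[name] = (volume, float(open_half.area))
    return {
        "volume_ratio": halves["left"][0] / halves["right"][0],
        "surface_ratio": halves["left"][1] / halves["right"][1],
    }


def vertexwise_asymmetry(
    shape: np.ndarray, pairing: SymmetryPairing
) -> dict:
    """Per-vertex distance between a shape and its rigidly re-aligned
    mirror image, using the known vertex correspondence.

    Rigid (rotation + translation) alignment first removes any global pose
    component, so the measure is invariant to rigid motion of the input.
    """
    if pairing is None:
        raise MeshError("vertex-wise asymmetry requires a symmetry pairing")
    shape = np.asarray(shape, dtype=float)
    mirrored = mirror_shape(shape, pairing)
    transform = corresponded_rigid_align(mirrored, shape)
    aligned = transform.apply(mirrored)
    dist = np.linalg.norm(shape - aligned, axis=1)
    return {
        "distances": dist,
        "mean_asymmetry": float(dist.mean()),
        "max_asymmetry": float(dist.max()),
    }


def contour_curve_difference(curve: RadialCurve) -> float:
    """Left/right contour-difference AUC (mm·rad):
    ∫₀^π |r(θ) − r(2π − θ)| dθ by the trapezoid rule."""
    n = len(curve.angles)
    half = n // 2
    theta = curve.angles[: half + 1]
    r_left = curve.radii[: half + 1]
    idx_right = (-np.arange(half + 1)) % n
    r_right = curve.radii[idx_right]
    return float(np.trapezoid(np.abs(r_left - r_right), theta))


def dice_coefficient(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice similarity of two boolean occupancy grids, in percent."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    total = a.sum() + b.sum()
    if total == 0:
        raise IndexError_("both masks are empty")
    return 100.0 * 2.0 * np.logical_and(a, b).sum() / total


def dice_asymmetry(
    mesh: TriangleMesh, resolution: float = 1.0, icp_max_iter: int = 30
) -> float:
    """Mirror-overlap symmetry score in percent (100 = perfect symmetry).

    The mesh is mirrored, rigidly ICP-aligned back onto the native mesh,
    both are voxelized on one shared grid, and the Dice coefficient of the
    two occupancy masks is returned.
    """
    if mesh.pairing is None:
        raise MeshError("dice asymmetry requires a symmetry pairing")
    mirrored_mesh = mesh.with_vertices(mirror_shape(mesh.vertices, mesh.pairing))
    transform, _, _ = rigid_align_icp(mirrored_mesh, mesh, max_iter=icp_max_iter)
    aligned = mesh.with_vertices(transform.apply(mirrored_mesh.vertices))
    lo = np.minimum(mesh.vertices.min(axis=0), aligned.vertices.min(axis=0))
    hi = np.maximum(mesh.vertices.max(axis=0), aligned.vertices.max(axis=0))
    origin = lo - resolution
    shape = tuple(int(np.ceil((hi[k] - origin[k]) / resolution)) + 1 for k in range(3))
    mask_a = voxelize(mesh, resolution, origin=origin, shape=shape)
    mask_b = voxelize(aligned, resolution, origin=origin, shape=shape)
    return dice_coefficient(mask_a.occupancy, mask_b.occupancy)


@dataclass
class IndexConfig:
    """Parameters of the classical-index battery."""

    plane_height: float | None = None  # None → per-subject max-area section
    diagonal_angle: float = 30.0
    n_contour_samples: int = 360
    dice_resolution: float = 2.0
    include_dice: bool = True
    include_hemispheres: bool = True


def compute_all_indices(
    shape_set: CorrespondedShapeSet,
    config: IndexConfig | None = None,
) -> pd.DataFrame:
    """One row per shape instance with the full classical-index battery.

    Per-subject failures are recorded in the ``failures`` column and leave
    NaN in the affected cells; they are never silently dropped.  Shape-model
    scores and UCS-SI are merged in by the pipeline, which owns the models.
    """
    config = config or IndexConfig()
    rows = []
    for i in range(shape_set.n_shapes):
        mesh = shape_set.mesh(i)
        row: dict = {
            "subject_id": shape_set.subject_ids[i],
            "group": shape_set.groups[i],
            "laterality": shape_set.lateralities[i],
            "mirrored": bool(shape_set.mirrored[i]),
        }
        failures: list[str] = []
        try:
            h = (config.plane_height if config.plane_height is not None
                 else find_measurement_plane(mesh))
            curve = axial_radial_contour(mesh, h, config.n_contour_samples)
        except (MeshError, IndexError_) as exc:
            failures.append(f"contour: {exc}")
            curve, h = None, np.nan
        row["plane_height"] = h
        if curve is not None:
            try:
                row.update(
                    {k: v for k, v in cephalometrics(mesh, h).items()
                     if k != "plane_height"}
                )
            except (MeshError, IndexError_) as exc:
                failures.append(f"cephalometrics: {exc}")
            try:
                res = cva_cvai(mesh, h, config.diagonal_angle,
                               config.n_contour_samples)
                row["CVA"] = res["CVA"]
                row["CVAI"] = res["CVAI"]
            except (MeshError, IndexError_) as exc:
                failures.append(f"cva_cvai: {exc}")
            try:
                row.update(ucsq_measures(curve))
            except (MeshError, IndexError_) as exc:
                failures.append(f"ucsq: {exc}")
            try:
                row["contour_auc"] = contour_curve_difference(curve)
            except (MeshError, IndexError_) as exc:
                failures.append(f"contour_auc: {exc}")
        if config.include_hemispheres:
            try:
                row.update(hemisphere_ratios(mesh))
            except (MeshError, IndexError_) as exc:
                failures.append(f"hemispheres: {exc}")
        try:
            asym = vertexwise_asymmetry(mesh.vertices, shape_set.pairing)
            row["vertex_asymmetry_mean"] = asym["mean_asymmetry"]
            row["vertex_asymmetry_max"] = asym["max_asymmetry"]
        except (MeshError, IndexError_) as exc:
            failures.append(f"vertexwise: {exc}")
        if config.include_dice:
            try:
                row["dice_symmetry"] = dice_asymmetry(
                    mesh, resolution=config.dice_resolution
                )
            except (MeshError, IndexError_) as exc:
                failures.append(f"dice: {exc}")
        row["failures"] = ";".join(failures)
        rows.append(row)
    return pd.DataFrame(rows)
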