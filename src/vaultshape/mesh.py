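"""Triangle-mesh containers with an explicit left/right symmetry pairing.

All modules share one anatomical convention: the midsagittal plane is
``x = 0``, the subject's right is ``+x``, anterior is ``+y`` and superior is
``+z``.  Coordinates are millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import trimesh


class MeshError(ValueError):
    """Raised for invalid meshes or mesh parameters."""


@dataclass(frozen=True)
class SymmetryPairing:
    """Involutive vertex permutation linking left/right partner vertices.

    ``partner[i] == i`` marks a midline (self-paired) vertex.
    """

    partner: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.partner, dtype=np.intp)
        object.__setattr__(self, "partner", p)
        if p.ndim != 1:
            raise MeshError("pairing must be a 1-D permutation")
        idx = np.arange(p.size)
        if not np.array_equal(np.sort(p), idx):
            raise MeshError("pairing is not a permutation")
        if not np.array_equal(p[p], idx):
            raise MeshError("pairing is not an involution")

    @property
    def n_vertices(self) -> int:
        return int(self.partner.size)

    @property
    def midline(self) -> np.ndarray:
        """Indices of self-paired (midsagittal) vertices."""
        return np.flatnonzero(self.partner == np.arange(self.partner.size))


@dataclass
class TriangleMesh:
    """Vertices (V×3, mm) and faces (F×3) with optional symmetry pairing."""

    vertices: np.ndarray
    faces: np.ndarray
    pairing: SymmetryPairing | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.intp)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError("vertices must be V×3")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshError("faces must be F×3")
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise MeshError("face indices out of range")
        if self.pairing is not None and self.pairing.n_vertices != len(self.vertices):
            raise MeshError("pairing size does not match vertex count")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def with_vertices(self, vertices: np.ndarray) -> "TriangleMesh":
        """Same connectivity and pairing, new vertex positions."""
        return replace(self, vertices=np.asarray(vertices, dtype=float))

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices.copy(), faces=self.faces.copy(), process=False
        )

    @property
    def is_watertight(self) -> bool:
        return bool(self.to_trimesh().is_watertight)

    def open_edge_count(self) -> int:
        """Number of edges not shared by exactly two faces."""
        tm = self.to_trimesh()
        counts = np.bincount(tm.edges_unique_inverse)
        return int(np.sum(counts != 2))

    def save(self, path: str | Path, vertex_scalar: np.ndarray | None = None) -> None:
        """Write PLY/OBJ/STL; an optional per-vertex scalar goes into the
        PLY ``quality`` channel (used for VIP surface maps)."""
        path = Path(path)
        tm = self.to_trimesh()
        if vertex_scalar is not None:
            if path.suffix.lower() != ".ply":
                raise MeshError("vertex scalars are only supported for PLY output")
            scal = np.asarray(vertex_scalar, dtype=float)
            if scal.shape != (self.n_vertices,):
                raise MeshError("vertex scalar must have one value per vertex")
            _write_ply_with_quality(path, self.vertices, self.faces, scal)
            return
        tm.export(path)

    @classmethod
    def load(cls, path: str | Path) -> "TriangleMesh":
        tm = trimesh.load_mesh(str(path), process=False)
        return cls(vertices=np.asarray(tm.vertices, float), faces=np.asarray(tm.faces))


def _write_ply_with_quality(
    path: Path, vertices: np.ndarray, faces: np.ndarray, quality: np.ndarray
) -> None:
    # ASCII PLY so the scalar channel survives any viewer / round-trip exactly
    # as printed.
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(vertices)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write("property float quality\n")
        fh.write(f"element face {len(faces)}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for (x, y, z), q in zip(vertices, quality):
            fh.write(f"{x:.9g} {y:.9g} {z:.9g} {q:.9g}\n")
        for a, b, c in faces:
            fh.write(f"3 {a} {b} {c}\n")


def read_ply_quality(path: str | Path) -> tuple[TriangleMesh, np.ndarray]:
    """Read back an ASCII PLY written by :meth:`TriangleMesh.save` with a
    quality channel; returns (mesh, per-vertex scalar)."""
    with open(path) as fh:
        line = fh.readline().strip()
        if line != "ply":
            raise MeshError("not a PLY file")
        n_vert = n_face = 0
        props: list[str] = []
        while True:
            line = fh.readline().strip()
            if line.startswith("element vertex"):
                n_vert = int(line.split()[-1])
            elif line.startswith("element face"):
                n_face = int(line.split()[-1])
            elif line.startswith("property float"):
                props.append(line.split()[-1])
            elif line == "end_header":
                break
        verts = np.empty((n_vert, 3))
        quality = np.empty(n_vert)
        qi = props.index("quality")
        for i in range(n_vert):
            vals = fh.readline().split()
            verts[i] = [float(v) for v in vals[:3]]
            quality[i] = float(vals[qi])
        faces = np.empty((n_face, 3), dtype=np.intp)
        for i in range(n_face):
            vals = fh.readline().split()
            faces[i] = [int(v) for v in vals[1:4]]
    return TriangleMesh(vertices=verts, faces=faces), quality


@dataclass
class CorrespondedShapeSet:
    """Stacked vertex matrices of N corresponded shapes plus metadata.

    ``shapes`` is N×V×3; all shapes share the template's connectivity and
    symmetry pairing.  Metadata columns: subject_id, group, laterality,
    mirrored (bool); a subject may appear at most twice (native + mirrored).
    """

    shapes: np.ndarray
    subject_ids: list[str]
    groups: list[str]
    lateralities: list[str]
    mirrored: np.ndarray
    faces: np.ndarray
    pairing: SymmetryPairing
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.shapes = np.asarray(self.shapes, dtype=float)
        self.mirrored = np.asarray(self.mirrored, dtype=bool)
        n = self.shapes.shape[0]
        if self.shapes.ndim != 3 or self.shapes.shape[2] != 3:
            raise MeshError("shapes must be N×V×3")
        if not (len(self.subject_ids) == len(self.groups) == len(self.lateralities) == n):
            raise MeshError("metadata length mismatch")
        if self.mirrored.shape != (n,):
            raise MeshError("mirrored flags length mismatch")
        if self.pairing.n_vertices != self.shapes.shape[1]:
            raise MeshError("pairing size mismatch")

    @property
    def n_shapes(self) -> int:
        return int(self.shapes.shape[0])

    @property
    def n_vertices(self) -> int:
        return int(self.shapes.shape[1])

    def mesh(self, index: int) -> TriangleMesh:
        return TriangleMesh(
            vertices=self.shapes[index].copy(), faces=self.faces, pairing=self.pairing
        )

    def save(self, path: str | Path) -> None:
        """Persist as an .npz array container with a CSV metadata table
        alongside (same stem, ``_metadata.csv`` suffix)."""
        path = Path(path)
        np.savez_compressed(
            path, shapes=self.shapes, faces=self.faces,
            pairing=self.pairing.partner,
        )
        import pandas as pd

        meta = pd.DataFrame(
            {
                "subject_id": self.subject_ids,
                "group": self.groups,
                "laterality": self.lateralities,
                "mirrored": self.mirrored,
            }
        )
        meta.to_csv(path.with_name(path.stem + "_metadata.csv"), index=False)

    @classmethod
    def load(cls, path: str | Path) -> "CorrespondedShapeSet":
        path = Path(path)
        data = np.load(path)
        import pandas as pd

        meta = pd.read_csv(path.with_name(path.stem + "_metadata.csv"))
        return cls(
            shapes=data["shapes"],
            subject_ids=[str(s) for s in meta["subject_id"]],
            groups=[str(g) for g in meta["group"]],
            lateralities=[str(l) for l in meta["laterality"]],
            mirrored=meta["mirrored"].to_numpy(dtype=bool),
            faces=data["faces"],
            pairing=SymmetryPairing(partner=data["pairing"]),
        )

    def subset(self, mask: np.ndarray) -> "CorrespondedShapeSet":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CorrespondedShapeSet(
            shapes=self.shapes[idx],
            subject_ids=[self.subject_ids[i] for i in idx],
            groups=[self.groups[i] for i in idx],
            lateralities=[self.lateralities[i] for i in idx],
            mirrored=self.mirrored[idx],
            faces=self.faces,
            pairing=self.pairing,
            extra=dict(self.extra),
        )
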