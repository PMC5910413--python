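"""Mesh, landmark and label I/O.

Surface meshes arrive as STL (binary or ASCII) exported from CT bone
reconstructions or stereophotogrammetry. STL files carry no units;
millimetre coordinates are assumed throughout (the CT / 3dMD convention).
On load every mesh is cleaned — duplicate vertices merged, zero-area faces
dropped — and its face windings are repaired to a consistent, outward
orientation, so downstream curvature signs (convex ridge positive, retruded
orbit negative) are well defined.

Landmarks (glabella, anterior fontanelle, left/right supraorbital rim
polylines) come from JSON or long-format CSV and are snapped to the nearest
point on the mesh surface; a snap farther than ``SNAP_TOLERANCE_MM`` aborts
the load, since that almost always means a coordinate-frame mismatch.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
from scipy.spatial import cKDTree

from .errors import (
    DegenerateMeshError,
    InputError,
    LandmarkPlacementError,
    LandmarkSchemaError,
    MeshFormatError,
)

log = logging.getLogger(__name__)

#: vertices closer than this (mm) are merged on load — far below scanner
#: precision, removes STL triangle-soup duplication only
MERGE_TOLERANCE_MM = 1e-6

#: landmarks farther than this (mm) from the surface indicate a frame mismatch
SNAP_TOLERANCE_MM = 10.0


@dataclass
class LandmarkSet:
    """Anatomical landmarks in the mesh coordinate frame (millimetres).

    ``glabella`` and ``anterior_fontanelle`` anchor the mid-forehead strip;
    the rim polylines trace each superior orbital rim from lateral to
    mid-orbit and anchor the supraorbital strips.
    """

    glabella: np.ndarray
    anterior_fontanelle: np.ndarray
    rim_left: np.ndarray
    rim_right: np.ndarray
    snap_distances: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.glabella = np.asarray(self.glabella, dtype=float).reshape(3)
        self.anterior_fontanelle = np.asarray(
            self.anterior_fontanelle, dtype=float
        ).reshape(3)
        self.rim_left = np.asarray(self.rim_left, dtype=float).reshape(-1, 3)
        self.rim_right = np.asarray(self.rim_right, dtype=float).reshape(-1, 3)
        for name in ("rim_left", "rim_right"):
            if getattr(self, name).shape[0] < 2:
                raise LandmarkSchemaError(f"{name} needs at least 2 points")
        if np.allclose(self.glabella, self.anterior_fontanelle):
            raise LandmarkSchemaError("glabella and anterior_fontanelle coincide")


REQUIRED_LANDMARKS = ("glabella", "anterior_fontanelle", "rim_left", "rim_right")


def clean_mesh(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    """Merge duplicate vertices, drop degenerate faces, repair orientation.

    Orientation repair makes windings consistent and, for closed meshes,
    outward (positive signed volume). Open meshes (stereophotogrammetry
    captures have boundaries) are flipped wholesale if the majority of face
    normals point toward the mesh centroid.
    """
    mesh = trimesh.Trimesh(
        vertices=np.asarray(mesh.vertices, dtype=float),
        faces=np.asarray(mesh.faces, dtype=np.int64),
        process=False,
    )
    mesh.merge_vertices(merge_tex=True, merge_norm=True, digits_vertex=6)
    mesh.update_faces(mesh.nondegenerate_faces())
    mesh.remove_unreferenced_vertices()
    if len(mesh.vertices) < 4:
        raise DegenerateMeshError(
            f"mesh has only {len(mesh.vertices)} vertices after cleaning"
        )
    trimesh.repair.fix_winding(mesh)
    if mesh.is_volume or mesh.is_watertight:
        if mesh.volume < 0:
            mesh.invert()
    else:
        centers = mesh.triangles_center - mesh.centroid
        outward_votes = np.einsum("ij,ij->i", mesh.face_normals, centers) > 0
        if outward_votes.mean() < 0.5:
            mesh.invert()
    return mesh


def read_stl(path: str | Path) -> trimesh.Trimesh:
    """Read an STL file (binary or ASCII dialect) and return a cleaned mesh."""
    path = Path(path)
    if not path.exists():
        raise MeshFormatError(f"no such file: {path}")
    try:
        raw = trimesh.load_mesh(path, file_type="stl", process=False)
    except Exception as exc:  # trimesh raises heterogeneous parse errors
        raise MeshFormatError(f"could not parse STL {path}: {exc}") from exc
    if not isinstance(raw, trimesh.Trimesh) or len(raw.faces) == 0:
        raise MeshFormatError(f"{path} contains no triangle geometry")
    mesh = clean_mesh(raw)
    log.info(
        "read %s: %d vertices, %d faces after cleaning",
        path.name,
        len(mesh.vertices),
        len(mesh.faces),
    )
    return mesh


def write_stl(mesh: trimesh.Trimesh, path: str | Path, ascii_dialect: bool = False) -> None:
    """Write a mesh as STL (binary by default)."""
    path = Path(path)
    if ascii_dialect:
        path.write_text(mesh.export(file_type="stl_ascii"))
    else:
        path.write_bytes(mesh.export(file_type="stl"))


def closest_surface_points(
    mesh: trimesh.Trimesh, points: np.ndarray, n_candidate_faces: int = 64
) -> tuple[np.ndarray, np.ndarray]:
    """Exact nearest points on the triangulated surface.

    Candidate triangles are shortlisted by a k-d tree on face centroids,
    then resolved with exact point-triangle projection; with a candidate
    pool much larger than a one-ring this is exact for smooth meshes.
    Returns (snapped points, distances).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tree = cKDTree(mesh.triangles_center)
    k = min(n_candidate_faces, len(mesh.faces))
    _, face_idx = tree.query(points, k=k)
    face_idx = np.atleast_2d(face_idx)
    snapped = np.empty_like(points)
    dists = np.empty(len(points))
    for i, (p, faces) in enumerate(zip(points, face_idx)):
        tris = mesh.triangles[faces]
        cand = trimesh.triangles.closest_point(tris, np.tile(p, (len(tris), 1)))
        d = np.linalg.norm(cand - p, axis=1)
        j = int(np.argmin(d))
        snapped[i] = cand[j]
        dists[i] = d[j]
    return snapped, dists


def snap_landmarks(lm: LandmarkSet, mesh: trimesh.Trimesh) -> LandmarkSet:
    """Project every landmark onto the mesh surface, recording snap distances."""
    snapped = {}
    distances = {}
    for name in ("glabella", "anterior_fontanelle"):
        pt, d = closest_surface_points(mesh, getattr(lm, name))
        snapped[name] = pt[0]
        distances[name] = float(d[0])
    for name in ("rim_left", "rim_right"):
        pts, d = closest_surface_points(mesh, getattr(lm, name))
        snapped[name] = pts
        distances[name] = float(d.max())
    for name, d in distances.items():
        if d > SNAP_TOLERANCE_MM:
            raise LandmarkPlacementError(
                f"landmark {name!r} lies {d:.1f} mm from the surface "
                f"(limit {SNAP_TOLERANCE_MM} mm) — check the coordinate frame"
            )
        log.debug("snapped %s by %.3f mm", name, d)
    return LandmarkSet(snap_distances=distances, **snapped)


def _landmarks_from_json(path: Path) -> dict:
    data = json.loads(path.read_text())
    missing = [k for k in REQUIRED_LANDMARKS if k not in data]
    if missing:
        raise LandmarkSchemaError(f"{path} is missing landmark(s): {missing}")
    return {k: np.asarray(data[k], dtype=float) for k in REQUIRED_LANDMARKS}


def _landmarks_from_csv(path: Path) -> dict:
    rows: dict[str, list] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        fields = set(reader.fieldnames or ())
        needed = {"landmark", "ordinal", "x", "y", "z"}
        if not needed <= fields:
            raise LandmarkSchemaError(
                f"{path} lacks columns {sorted(needed - fields)}"
            )
        for row in reader:
            rows.setdefault(row["landmark"], []).append(
                (int(row["ordinal"]), float(row["x"]), float(row["y"]), float(row["z"]))
            )
    missing = [k for k in REQUIRED_LANDMARKS if k not in rows]
    if missing:
        raise LandmarkSchemaError(f"{path} is missing landmark(s): {missing}")
    out = {}
    for name, pts in rows.items():
        pts.sort()
        arr = np.array([(x, y, z) for _, x, y, z in pts])
        out[name] = arr[0] if name in ("glabella", "anterior_fontanelle") else arr
    return out


def read_landmarks(path: str | Path, mesh: trimesh.Trimesh) -> LandmarkSet:
    """Read a landmark file (JSON or long-format CSV) and snap it to ``mesh``."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        raw = _landmarks_from_json(path)
    else:
        raw = _landmarks_from_csv(path)
    return snap_landmarks(LandmarkSet(**raw), mesh)


def read_labels(path: str | Path) -> pd.DataFrame:
    """Read the clinician-label table: columns subject_id, clinician_label.

    Labels must be 'conservative' or 'operative'; subject ids must be unique.
    """
    df = pd.read_csv(path, dtype=str)
    needed = {"subject_id", "clinician_label"}
    if not needed <= set(df.columns):
        raise InputError(f"{path} lacks columns {sorted(needed - set(df.columns))}")
    df = df[["subject_id", "clinician_label"]].copy()
    df["clinician_label"] = df["clinician_label"].str.strip().str.lower()
    bad = set(df["clinician_label"]) - {"conservative", "operative"}
    if bad:
        raise InputError(f"unknown clinician labels: {sorted(bad)}")
    if df["subject_id"].duplicated().any():
        dups = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise InputError(f"duplicate subject ids: {dups}")
    return df
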