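"""Landmark-anchored orbitofrontal regions of interest.

Three strips are segmented on each head, mirroring the clinically defined
regions used to grade metopic deformity:

* **mid-forehead strip** — a vertical band of configurable full width
  (default 10 mm) straddling the midline plane and running from glabella to
  anterior fontanelle, over the metopic ridge;
* **left / right supraorbital strips** — bands of configurable depth
  (default 10 mm) immediately above each superior orbital rim polyline.

A "rectangular" region on a curved surface is realised as a slab
(plane-distance band) intersected with an axial extent for the mid-forehead
strip, and as a polyline-distance band for the supraorbital strips — both
reproducible from point landmarks alone, with no geodesic machinery.
Region means are area-weighted so they are invariant to tessellation
density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .curvature import CurvatureField
from .errors import SegmentationError
from .mesh_io import LandmarkSet

REGION_NAMES = ("midforehead", "supraorbital_left", "supraorbital_right")


@dataclass
class RegionMask:
    """Vertex subset realising one anatomical strip, with area weights (mm²)."""

    region_name: str
    vertex_ids: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.vertex_ids = np.asarray(self.vertex_ids, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.vertex_ids.size == 0:
            raise SegmentationError(f"region {self.region_name!r} is empty")


def _perpendicular(v: np.ndarray) -> np.ndarray:
    """A deterministic unit vector orthogonal to v."""
    helper = np.zeros(3)
    helper[int(np.argmin(np.abs(v)))] = 1.0
    p = np.cross(v, helper)
    return p / np.linalg.norm(p)


def midline_plane_normal(
    glabella: np.ndarray, fontanelle: np.ndarray, centroid: np.ndarray
) -> np.ndarray:
    """Unit normal of the midline plane through glabella, fontanelle, centroid.

    If the three points are (near-)collinear — e.g. antipodal landmarks on a
    sphere — any plane containing the axis is equivalent by symmetry; a
    deterministic perpendicular is used.
    """
    axis = fontanelle - glabella
    n = np.cross(axis, centroid - glabella)
    norm = np.linalg.norm(n)
    if norm < 1e-9 * max(np.linalg.norm(axis), 1.0):
        return _perpendicular(axis)
    return n / norm


def segment_midforehead(
    mesh: trimesh.Trimesh,
    lm: LandmarkSet,
    width_mm: float = 10.0,
    vertex_areas: np.ndarray | None = None,
) -> RegionMask:
    """Select the mid-forehead strip from glabella to anterior fontanelle.

    A vertex belongs iff (a) its distance to the midline plane — through
    glabella, anterior fontanelle and the mesh centroid — is at most
    ``width_mm / 2``, and (b) its scalar projection onto the glabella →
    fontanelle axis falls within the axis extent.
    """
    if width_mm <= 0:
        raise SegmentationError(f"width_mm must be positive, got {width_mm}")
    g, f = lm.glabella, lm.anterior_fontanelle
    axis = f - g
    axis_len = np.linalg.norm(axis)
    axis_dir = axis / axis_len
    normal = midline_plane_normal(g, f, mesh.centroid)
    rel = mesh.vertices - g
    plane_dist = np.abs(rel @ normal)
    t = rel @ axis_dir
    member = (plane_dist <= width_mm / 2.0) & (t >= 0.0) & (t <= axis_len)
    ids = np.flatnonzero(member)
    if ids.size == 0:
        raise SegmentationError(
            "empty mid-forehead selection: glabella "
            f"{g.round(1).tolist()}, fontanelle {f.round(1).tolist()}, "
            f"width {width_mm} mm"
        )
    if vertex_areas is None:
        from .curvature import mixed_voronoi_areas

        vertex_areas = mixed_voronoi_areas(mesh)
    return RegionMask("midforehead", ids, vertex_areas[ids])


def polyline_closest(points: np.ndarray, poly: np.ndarray):
    """Closest point on a 3D polyline for each query point.

    Returns (closest points, distances, arc-length parameters, clamped flag);
    ``clamped`` marks queries whose unclamped projection falls beyond either
    end of the polyline.
    """
    points = np.atleast_2d(points)
    starts, ends = poly[:-1], poly[1:]
    seg = ends - starts
    seg_len = np.linalg.norm(seg, axis=1)
    seg_dir = seg / np.maximum(seg_len, 1e-12)[:, None]
    arc0 = np.concatenate([[0.0], np.cumsum(seg_len)])[:-1]

    rel = points[:, None, :] - starts[None, :, :]  # (Q, S, 3)
    raw = np.einsum("qsj,sj->qs", rel, seg_dir)  # unclamped param per segment
    clamped_t = np.clip(raw, 0.0, seg_len[None, :])
    proj = starts[None, :, :] + clamped_t[..., None] * seg_dir[None, :, :]
    d = np.linalg.norm(points[:, None, :] - proj, axis=2)
    best = np.argmin(d, axis=1)
    q = np.arange(len(points))
    closest = proj[q, best]
    dist = d[q, best]
    arc = arc0[best] + clamped_t[q, best]
    total = seg_len.sum()
    raw_best = raw[q, best]
    clamped = ((best == 0) & (raw_best < 0.0)) | (
        (best == len(starts) - 1) & (raw_best > seg_len[-1])
    )
    return closest, dist, arc, clamped, total


def segment_supraorbital(
    mesh: trimesh.Trimesh,
    rim: np.ndarray,
    width_mm: float = 10.0,
    up_hint: np.ndarray = (0.0, 0.0, 1.0),
    region_name: str = "supraorbital_left",
    vertex_areas: np.ndarray | None = None,
) -> RegionMask:
    """Select the band of depth ``width_mm`` above a superior orbital rim.

    A vertex belongs iff (i) its distance to the rim polyline is at most
    ``width_mm``, (ii) its displacement from the nearest rim point has a
    positive component along ``up_hint`` ("above" the rim), and (iii) its
    projection parameter lies within the polyline's arc-length extent.
    """
    if width_mm <= 0:
        raise SegmentationError(f"width_mm must be positive, got {width_mm}")
    rim = np.asarray(rim, dtype=float).reshape(-1, 3)
    up = np.asarray(up_hint, dtype=float)
    up = up / np.linalg.norm(up)
    closest, dist, arc, clamped, total = polyline_closest(mesh.vertices, rim)
    above = np.einsum("ij,j->i", mesh.vertices - closest, up) > 0.0
    member = (dist <= width_mm) & above & ~clamped & (arc >= 0.0) & (arc <= total)
    ids = np.flatnonzero(member)
    if ids.size == 0:
        raise SegmentationError(f"empty selection for {region_name!r}")
    if vertex_areas is None:
        from .curvature import mixed_voronoi_areas

        vertex_areas = mixed_voronoi_areas(mesh)
    return RegionMask(region_name, ids, vertex_areas[ids])


def region_mean_curvature(field: CurvatureField, mask: RegionMask) -> float:
    """Area-weighted mean of H (m⁻¹) over the valid vertices of a region."""
    sel = mask.vertex_ids
    ok = field.valid[sel]
    if not ok.any():
        raise SegmentationError(
            f"all {sel.size} vertices of {mask.region_name!r} are invalid"
        )
    w = mask.weights[ok]
    h = field.H[sel[ok]]
    return float(np.sum(w * h) / np.sum(w))


def export_masks_csv(masks: dict[str, RegionMask], subject_id: str, path) -> None:
    """Write region masks as long CSV (subject_id, region, vertex_id, weight)."""
    import pandas as pd

    rows = []
    for mask in masks.values():
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": subject_id,
                    "region": mask.region_name,
                    "vertex_id": mask.vertex_ids,
                    "weight": mask.weights,
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
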