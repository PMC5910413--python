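"""Synthetic inputs for every pipeline stage.

Three generators, all bit-reproducible given their seed:

* :func:`make_fixture` — meshes of known analytic mean curvature (sphere,
  open cylinder, plane, dented sphere) for certifying the estimators;
* :func:`make_head` — a parametric head: an ellipsoid with a controllable
  midline frontal ridge (``ridge_sharpness``) and supraorbital scooping
  (``orb_retrusion``), plus true landmarks and true region membership. It
  targets qualitative fidelity of the two phenotypes — keel-shaped convex
  ridge, concave retruded orbits, bilateral symmetry — not anatomical
  realism;
* :func:`simulate_cohort` — subject-level feature tables drawn from
  bivariate normals at clinically reported group means/SDs, for exercising
  the statistics and clustering stages without any mesh work.

The head frame is: +x left lateral, +y anterior (face), +z superior,
origin at the ellipsoid centre, millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import trimesh

from .errors import InputError
from .mesh_io import LandmarkSet

# ---------------------------------------------------------------------------
# analytic fixtures
# ---------------------------------------------------------------------------


@dataclass
class Fixture:
    """A fixture mesh plus the analytic mean curvature of its interior."""

    mesh: trimesh.Trimesh
    analytic_H: float  # m^-1, interior vertices
    kind: str


def _octasphere(resolution: int) -> trimesh.Trimesh:
    """Unit sphere by subdividing an octahedron — mirror-symmetric in x, y, z."""
    verts = np.array(
        [
            [1, 0, 0], [-1, 0, 0],
            [0, 1, 0], [0, -1, 0],
            [0, 0, 1], [0, 0, -1],
        ],
        dtype=float,
    )
    faces = np.array(
        [
            [0, 2, 4], [2, 1, 4], [1, 3, 4], [3, 0, 4],
            [2, 0, 5], [1, 2, 5], [3, 1, 5], [0, 3, 5],
        ]
    )
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    for _ in range(resolution):
        mesh = mesh.subdivide()
    v = mesh.vertices / np.linalg.norm(mesh.vertices, axis=1)[:, None]
    return trimesh.Trimesh(vertices=v, faces=mesh.faces, process=False)


def _open_cylinder(radius: float, height: float, n_theta: int, n_z: int) -> trimesh.Trimesh:
    th = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    z = np.linspace(0.0, height, n_z)
    T, Z = np.meshgrid(th, z)
    V = np.column_stack(
        [radius * np.cos(T).ravel(), radius * np.sin(T).ravel(), Z.ravel()]
    )
    faces = []
    def idx(i: int, j: int) -> int:
        return i * n_theta + (j % n_theta)
    for i in range(n_z - 1):
        for j in range(n_theta):
            faces.append([idx(i, j), idx(i, j + 1), idx(i + 1, j)])
            faces.append([idx(i, j + 1), idx(i + 1, j + 1), idx(i + 1, j)])
    return trimesh.Trimesh(vertices=V, faces=np.array(faces), process=False)


def _plane_grid(size: float, n: int) -> trimesh.Trimesh:
    xs = np.linspace(-size / 2, size / 2, n)
    X, Y = np.meshgrid(xs, xs)
    V = np.column_stack([X.ravel(), Y.ravel(), np.zeros(n * n)])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a, b, c, d = i * n + j, i * n + j + 1, (i + 1) * n + j, (i + 1) * n + j + 1
            faces.append([a, b, c])
            faces.append([b, d, c])
    return trimesh.Trimesh(vertices=V, faces=np.array(faces), process=False)


def make_fixture(kind: str, size_mm: float = 100.0, resolution: int = 4) -> Fixture:
    """Build a mesh of known analytic mean curvature.

    kinds: ``sphere`` (radius ``size_mm``, H = 1/r), ``cylinder`` (open, no
    caps, radius ``size_mm``, H = 1/2r on interior rows), ``plane`` (square
    grid of side ``size_mm``, H = 0), ``dented_sphere`` (sphere with an
    inward Gaussian dent about +z; its analytic H refers to the undented
    part). Curvatures are returned in m⁻¹ for millimetre meshes.
    """
    if size_mm <= 0:
        raise InputError("size_mm must be positive")
    if resolution < 1:
        raise InputError("resolution too low to triangulate")
    if kind == "sphere":
        mesh = trimesh.creation.icosphere(subdivisions=resolution, radius=size_mm)
        return Fixture(mesh, 1000.0 / size_mm, kind)
    if kind == "cylinder":
        n = 24 * resolution
        mesh = _open_cylinder(size_mm, 2.4 * size_mm, n, n // 2)
        return Fixture(mesh, 1000.0 / (2 * size_mm), kind)
    if kind == "plane":
        mesh = _plane_grid(size_mm, 8 * resolution)
        return Fixture(mesh, 0.0, kind)
    if kind == "dented_sphere":
        mesh = trimesh.creation.icosphere(subdivisions=resolution, radius=size_mm)
        v = mesh.vertices.copy()
        u = v / np.linalg.norm(v, axis=1)[:, None]
        # inward Gaussian dent about +z, deep enough to invert local curvature
        ang = np.arccos(np.clip(u[:, 2], -1, 1))
        dent = 0.25 * size_mm * np.exp(-((ang / 0.35) ** 2))
        v -= dent[:, None] * u
        mesh = trimesh.Trimesh(vertices=v, faces=mesh.faces, process=False)
        return Fixture(mesh, 1000.0 / size_mm, kind)
    raise InputError(f"unknown fixture kind {kind!r}")


# ---------------------------------------------------------------------------
# parametric head
# ---------------------------------------------------------------------------


@dataclass
class HeadParams:
    """Dials for the parametric head generator.

    ``ridge_sharpness`` drives the amplitude of a keel-like midline frontal
    ridge (0 = smooth ellipsoid); ``orb_retrusion`` drives the depth of the
    supraorbital scoop (at high values the band above the rim turns
    concave). Semi-axes default to an infant-head-scale ellipsoid.
    """

    semi_axes: tuple = (65.0, 80.0, 75.0)  # x lateral, y anterior, z superior (mm)
    ridge_sharpness: float = 0.0
    orb_retrusion: float = 0.0
    mesh_resolution: int = 6  # octasphere subdivision level
    noise_sd: float = 0.0  # vertex jitter along normals (mm)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.ridge_sharpness <= 1.0):
            raise InputError("ridge_sharpness must be in [0, 1]")
        if not (0.0 <= self.orb_retrusion <= 1.0):
            raise InputError("orb_retrusion must be in [0, 1]")
        if any(a <= 0 for a in self.semi_axes):
            raise InputError("semi-axes must be positive")


@dataclass
class SyntheticHead:
    """Generator output: mesh, true landmarks, true region membership."""

    mesh: trimesh.Trimesh
    landmarks: LandmarkSet
    true_regions: dict  # region name -> boolean vertex mask
    params: HeadParams


# forehead ridge path: polar angle in the midline (x=0) plane, measured from
# the anterior (+y) axis toward superior (+z)
_PHI_GLABELLA = np.deg2rad(15.0)
_PHI_FONTANELLE = np.deg2rad(80.0)
_RIM_Z_MM = 8.0  # rim height above orbital level in head frame
_RIM_X_RANGE = (10.0, 45.0)  # mid to lateral extent of each rim (mm)


def _ellipsoid_point(u: np.ndarray, axes) -> np.ndarray:
    return np.asarray(u, dtype=float) * np.asarray(axes, dtype=float)


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def make_head(params: HeadParams) -> SyntheticHead:
    """Generate a head-like mesh with controllable ridge and orbital scoop.

    Both deformations displace vertices along the ellipsoid normal:

    * ridge: a Gaussian profile across the midline (sd ~6 mm), windowed to
      the glabella→fontanelle arc, amplitude ``1 + 7·ridge_sharpness`` mm —
      a sharper dial yields a taller keel and a higher strip curvature;
    * scoop: an inward Gaussian trough centred ~6 mm above each rim,
      windowed laterally over the orbit, depth ``7·orb_retrusion`` mm.
    """
    ax, ay, az = params.semi_axes
    base = _octasphere(params.mesh_resolution)
    u = base.vertices  # unit sphere
    V = u * np.array([ax, ay, az])

    # outward ellipsoid normals
    n = u / np.array([ax, ay, az])
    n /= np.linalg.norm(n, axis=1)[:, None]

    x, y, z = V[:, 0], V[:, 1], V[:, 2]
    phi = np.arctan2(z, y)  # angle from anterior axis in the sagittal sense

    # --- midline ridge ---
    amp_r = 1.0 + 7.0 * params.ridge_sharpness
    ridge_profile = np.exp(-(x**2) / (2.0 * 6.0**2))
    front = (y > 0) | (z > 0)
    arc_window = (
        _smoothstep((phi - (_PHI_GLABELLA - 0.15)) / 0.2)
        * _smoothstep(((_PHI_FONTANELLE + 0.15) - phi) / 0.2)
        * front
    )
    disp = amp_r * ridge_profile * arc_window

    # --- supraorbital scoops (bilaterally symmetric) ---
    amp_s = 7.0 * params.orb_retrusion
    z_center = _RIM_Z_MM + 6.0
    scoop_z = np.exp(-((z - z_center) ** 2) / (2.0 * 5.0**2))
    lat_center = 0.5 * (_RIM_X_RANGE[0] + _RIM_X_RANGE[1])
    scoop_x = np.exp(-((np.abs(x) - lat_center) ** 2) / (2.0 * 12.0**2))
    anterior = _smoothstep(y / 20.0)
    disp -= amp_s * scoop_z * scoop_x * anterior

    V = V + disp[:, None] * n

    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        V = V + rng.normal(0.0, params.noise_sd, len(V))[:, None] * n

    mesh = trimesh.Trimesh(vertices=V, faces=base.faces, process=False)

    # --- true landmarks, emitted at deformed mesh vertices so they lie
    # exactly on the generated surface (midline anchors stay at x = 0,
    # keeping the landmark-derived midline plane aligned with the
    # generator's true symmetry plane) ---
    on_midline = np.abs(u[:, 0]) < 1e-9

    def midline_vertex(phi_val: float) -> np.ndarray:
        target = _ellipsoid_point(
            np.array([0.0, np.cos(phi_val), np.sin(phi_val)]), params.semi_axes
        )
        cand = np.flatnonzero(on_midline)
        i = cand[np.argmin(np.linalg.norm(V[cand] - target, axis=1))]
        return V[i].copy()

    glabella = midline_vertex(_PHI_GLABELLA)
    fontanelle = midline_vertex(_PHI_FONTANELLE)

    def rim_polyline(side: float) -> np.ndarray:
        xs = np.linspace(_RIM_X_RANGE[1], _RIM_X_RANGE[0], 5) * side
        pts = []
        for xv in xs:
            # target on the ellipsoid at (x, z_rim), then nearest mesh vertex
            rest = 1.0 - (xv / ax) ** 2 - (_RIM_Z_MM / az) ** 2
            target = np.array([xv, ay * np.sqrt(max(rest, 1e-6)), _RIM_Z_MM])
            i = int(np.argmin(np.linalg.norm(V - target, axis=1)))
            if not pts or not np.array_equal(V[i], pts[-1]):  # coarse meshes may repeat
                pts.append(V[i])
        return np.array(pts)

    lm = LandmarkSet(
        glabella=glabella,
        anterior_fontanelle=fontanelle,
        rim_left=rim_polyline(+1.0),
        rim_right=rim_polyline(-1.0),
    )

    # --- true region membership from generator geometry ---
    axis = fontanelle - glabella
    axis_len = np.linalg.norm(axis)
    t = (V - glabella) @ (axis / axis_len)
    true_mid = (np.abs(V[:, 0]) <= 5.0) & (t >= 0) & (t <= axis_len)
    band = (z >= _RIM_Z_MM) & (z <= _RIM_Z_MM + 10.0) & (y > 0)
    lat = (np.abs(x) >= _RIM_X_RANGE[0]) & (np.abs(x) <= _RIM_X_RANGE[1])
    true_regions = {
        "midforehead": true_mid,
        "supraorbital_left": band & lat & (x > 0),
        "supraorbital_right": band & lat & (x < 0),
    }
    return SyntheticHead(mesh=mesh, landmarks=lm, true_regions=true_regions, params=params)


# ---------------------------------------------------------------------------
# feature-level cohorts
# ---------------------------------------------------------------------------


@dataclass
class GroupSpec:
    """One group's generating parameters: n and (mean, sd) per feature."""

    name: str
    n: int
    h_mid_mean: float
    h_mid_sd: float
    h_orb_mean: float
    h_orb_sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InputError(f"group {self.name!r} needs n >= 2")
        if self.h_mid_sd < 0 or self.h_orb_sd < 0:
            raise InputError("standard deviations must be non-negative")


@dataclass
class CohortParams:
    """Two-group cohort generator parameters.

    Defaults are the reported severity-cluster statistics: a severe group
    (n=16, mid-forehead 38.6 ± 7.1 m⁻¹, orbital −6.7 ± 4.7 m⁻¹) and a mild
    group (n=27, 28.0 ± 4.9 and 10.6 ± 5.5 m⁻¹). ``rho`` is the
    between-feature correlation (unreported clinically; default 0).
    ``lr_split_sd`` perturbs left/right orbital values about their mean.
    """

    groups: tuple = (
        GroupSpec("severe", 16, 38.6, 7.1, -6.7, 4.7),
        GroupSpec("mild", 27, 28.0, 4.9, 10.6, 5.5),
    )
    rho: float = 0.0
    lr_split_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (-1.0 <= self.rho <= 1.0):
            raise InputError("rho must lie in [-1, 1]")


SURGICAL_COHORT = CohortParams(
    groups=(
        GroupSpec("surgical", 16, 39.0, 6.9, -5.9, 5.7),
        GroupSpec("nonsurgical", 27, 27.7, 4.6, 10.2, 6.3),
    )
)


def simulate_cohort(params: CohortParams) -> pd.DataFrame:
    """Draw a cohort of per-subject curvature features.

    Per group, (h_mid, h_orb) are drawn from a bivariate normal with the
    group's means/SDs and correlation ``rho``; left/right orbital values are
    h_orb ± δ with δ ~ N(0, lr_split_sd), so their mean is exactly h_orb.
    Returns a DataFrame with columns subject_id, group, h_mid, h_orb_left,
    h_orb_right, h_orb, source.
    """
    rng = np.random.default_rng(params.seed)
    frames = []
    for gi, g in enumerate(params.groups):
        cov = np.array(
            [
                [g.h_mid_sd**2, params.rho * g.h_mid_sd * g.h_orb_sd],
                [params.rho * g.h_mid_sd * g.h_orb_sd, g.h_orb_sd**2],
            ]
        )
        draws = rng.multivariate_normal([g.h_mid_mean, g.h_orb_mean], cov, size=g.n)
        delta = rng.normal(0.0, params.lr_split_sd, g.n)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": [f"{g.name}_{i:03d}" for i in range(g.n)],
                    "group": g.name,
                    "h_mid": draws[:, 0],
                    "h_orb_left": draws[:, 1] + delta,
                    "h_orb_right": draws[:, 1] - delta,
                    "h_orb": draws[:, 1],
                    "source": "synthetic",
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
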