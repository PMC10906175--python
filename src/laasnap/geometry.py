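"""Synthetic left-atrial-appendage geometry generation and meshing.

Patient CT reconstructions are not publicly available, so the study geometries
are emulated parametrically: a closed inner cavity surface is swept along a
(possibly bent) centerline with a tapering radius, class-specific lobes and
bulges are added as smooth radial perturbations, the outer wall is produced by
offsetting the inner surface externally by the average wall thickness
(2.1 mm), the two surfaces are coupled into a conforming first-order
tetrahedral mesh, and trabeculae are added as tension-only cables spanning
near-opposing inner-surface nodes.  Four morphology presets (chicken wing,
cactus, windsock, cauliflower) mirror the standard appendage classification;
two benchmark shapes (clamped spherical cap, closed tube) exercise the
snap-through and eversion mechanisms in isolation.

All generators are pure functions of their parameters and seed.  Lengths are
in mm, indices 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "MorphologyParams",
    "SurfaceMesh",
    "VolumeMesh",
    "QualityReport",
    "MORPHOLOGY_CLASSES",
    "preset_params",
    "radius_profile",
    "generate_inner_surface",
    "offset_surface",
    "solidify",
    "add_trabeculae",
    "build_appendage",
    "make_benchmark",
    "mesh_series",
    "quality_report",
    "uv_sphere",
    "sphere_shell",
]

MORPHOLOGY_CLASSES = (
    "chicken_wing", "cactus", "windsock", "cauliflower", "tube", "spherical_cap",
)


@dataclass(frozen=True)
class MorphologyParams:
    """Parameters of a synthetic appendage morphology.

    ``taper_ratio`` is tip radius / orifice radius; ``bend_angle`` the total
    centerline bend in degrees; ``trabecula_diameter_range`` in mm.
    ``wall_thickness`` defaults to the 2.1 mm average appendage wall.
    """

    morphology_class: str
    orifice_diameter: float
    height: float
    bend_angle: float = 0.0
    taper_ratio: float = 0.5
    lobe_count: int = 0
    trabecula_count: int = 0
    trabecula_diameter_range: tuple[float, float] = (0.8, 4.3)
    wall_thickness: float = 2.1
    target_edge_length: float = 1.25
    n_layers: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.morphology_class not in MORPHOLOGY_CLASSES:
            raise ValueError(f"unknown morphology {self.morphology_class!r}; "
                             f"choose from {MORPHOLOGY_CLASSES}")
        if self.orifice_diameter <= 0 or self.height <= 0:
            raise ValueError("orifice_diameter and height must be positive")
        if not (0.0 < self.taper_ratio <= 1.0):
            raise ValueError("taper_ratio must lie in (0, 1]")
        if self.wall_thickness <= 0:
            raise ValueError("wall_thickness must be positive")
        if self.target_edge_length <= 0:
            raise ValueError("target_edge_length must be positive")
        lo, hi = self.trabecula_diameter_range
        if not (0.0 < lo <= hi < self.orifice_diameter):
            raise ValueError("trabecula_diameter_range must lie within "
                             "(0, orifice_diameter)")
        if self.lobe_count < 0 or self.trabecula_count < 0:
            raise ValueError("counts must be non-negative")
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")


#: Literature-plausible defaults per morphology class.  These emulate the
#: qualitative features of each class (bend, taper, lobulation, trabecular
#: burden and diameters); they do not reproduce any specific patient anatomy.
_PRESETS: dict[str, dict] = {
    "chicken_wing": dict(orifice_diameter=20.0, height=35.0, bend_angle=100.0,
                         taper_ratio=0.45, lobe_count=2, trabecula_count=6,
                         trabecula_diameter_range=(2.0, 4.3)),
    "cactus": dict(orifice_diameter=22.0, height=28.0, bend_angle=35.0,
                   taper_ratio=0.55, lobe_count=4, trabecula_count=12,
                   trabecula_diameter_range=(2.0, 4.3)),
    "windsock": dict(orifice_diameter=18.0, height=42.0, bend_angle=25.0,
                     taper_ratio=0.35, lobe_count=1, trabecula_count=5,
                     trabecula_diameter_range=(0.8, 1.2)),
    "cauliflower": dict(orifice_diameter=24.0, height=20.0, bend_angle=15.0,
                        taper_ratio=0.70, lobe_count=5, trabecula_count=0,
                        trabecula_diameter_range=(0.8, 4.3)),
    "tube": dict(orifice_diameter=12.0, height=30.0, bend_angle=0.0,
                 taper_ratio=1.0, lobe_count=0, trabecula_count=0,
                 trabecula_diameter_range=(0.8, 1.2)),
}


def preset_params(name: str, **overrides) -> MorphologyParams:
    """Morphology parameters for a named preset, with optional overrides."""
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from "
                         f"{sorted(_PRESETS)}")
    d = dict(_PRESETS[name])
    d.update(overrides)
    return MorphologyParams(morphology_class=name, **d)


# ---------------------------------------------------------------------------
# surface container


@dataclass
class SurfaceMesh:
    """Triangulated surface.  ``cap_faces`` indexes triangles that close the
    orifice opening (excluded when solidifying into a wall); ``vertex_normals``
    are analytic normals attached by generators when available (falling back
    to angle-weighted averages)."""

    vertices: np.ndarray          # (V, 3) float
    triangles: np.ndarray         # (T, 3) int
    cap_faces: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    vertex_normals: np.ndarray | None = None
    param_coords: np.ndarray | None = None  # per-vertex (s, theta) if swept

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64)
        self.cap_faces = np.asarray(self.cap_faces, dtype=np.int64)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def face_normals_areas(self) -> tuple[np.ndarray, np.ndarray]:
        v = self.vertices
        t = self.triangles
        c = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
        a2 = np.linalg.norm(c, axis=1)
        n = c / np.where(a2 > 0, a2, 1.0)[:, None]
        return n, 0.5 * a2

    def area(self) -> float:
        return float(self.face_normals_areas()[1].sum())

    def signed_volume(self) -> float:
        v = self.vertices
        t = self.triangles
        return float(np.einsum("ij,ij->i", v[t[:, 0]],
                               np.cross(v[t[:, 1]], v[t[:, 2]])).sum() / 6.0)

    def edges(self) -> np.ndarray:
        t = self.triangles
        e = np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        return np.sort(e, axis=1)

    def is_watertight(self) -> bool:
        """Closed 2-manifold: every edge shared by exactly two triangles."""
        e = self.edges()
        _, counts = np.unique(e, axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    def euler_characteristic(self) -> int:
        n_e = len(np.unique(self.edges(), axis=0))
        return self.n_vertices - n_e + self.n_triangles

    def has_degenerate_triangles(self, tol: float = 1e-12) -> bool:
        return bool(np.any(self.face_normals_areas()[1] <= tol))

    def angle_weighted_normals(self, exclude_faces: np.ndarray | None = None
                               ) -> np.ndarray:
        """Per-vertex normals: face normals averaged with the face's interior
        angle at the vertex as weight (robust to uneven triangulation)."""
        tri = self.triangles
        if exclude_faces is not None and len(exclude_faces):
            mask = np.ones(len(tri), bool)
            mask[exclude_faces] = False
            tri = tri[mask]
        v = self.vertices
        fn, _ = SurfaceMesh(v, tri).face_normals_areas()
        out = np.zeros_like(v)
        for k in range(3):
            a = v[tri[:, (k + 1) % 3]] - v[tri[:, k]]
            b = v[tri[:, (k + 2) % 3]] - v[tri[:, k]]
            na = np.linalg.norm(a, axis=1)
            nb = np.linalg.norm(b, axis=1)
            cosang = np.clip(np.einsum("ij,ij->i", a, b)
                             / np.where(na * nb > 0, na * nb, 1.0), -1, 1)
            w = np.arccos(cosang)
            np.add.at(out, tri[:, k], w[:, None] * fn)
        norm = np.linalg.norm(out, axis=1)
        out /= np.where(norm > 0, norm, 1.0)[:, None]
        return out

    def normals(self) -> np.ndarray:
        if self.vertex_normals is not None:
            return self.vertex_normals
        return self.angle_weighted_normals(exclude_faces=self.cap_faces
                                           if len(self.cap_faces) else None)


# ---------------------------------------------------------------------------
# volume container


@dataclass
class VolumeMesh:
    """First-order tetrahedral mesh with cavity facets, orifice ring and
    optional trabecula cables."""

    nodes: np.ndarray                 # (N, 3)
    tets: np.ndarray                  # (E, 4), positive signed volume
    inner_facets: np.ndarray          # (F, 3), normals away from the cavity
    orifice_ring: np.ndarray          # node ids on the outer wall at the rim
    trabecula_cables: list[tuple[int, int, float]] = field(default_factory=list)
    element_sets: dict[str, np.ndarray] = field(default_factory=dict)
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)
    node_data: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.ascontiguousarray(self.nodes, dtype=float)
        self.tets = np.ascontiguousarray(self.tets, dtype=np.int64)
        self.inner_facets = np.asarray(self.inner_facets, dtype=np.int64)
        self.orifice_ring = np.asarray(self.orifice_ring, dtype=np.int64)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.tets)

    def tet_volumes(self) -> np.ndarray:
        x = self.nodes[self.tets]
        return np.linalg.det(x[:, 1:] - x[:, :1]) / 6.0

    def edge_lengths(self) -> np.ndarray:
        t = self.tets
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        e = np.vstack([t[:, [a, b]] for a, b in pairs])
        e = np.unique(np.sort(e, axis=1), axis=0)
        d = self.nodes[e[:, 0]] - self.nodes[e[:, 1]]
        return np.linalg.norm(d, axis=1)

    def boundary_faces(self) -> np.ndarray:
        """Faces of the tet mesh that belong to exactly one element."""
        t = self.tets
        faces = np.vstack([t[:, [1, 2, 3]], t[:, [0, 3, 2]],
                           t[:, [0, 1, 3]], t[:, [0, 2, 1]]])
        key = np.sort(faces, axis=1)
        _, idx, counts = np.unique(key, axis=0, return_index=True,
                                   return_counts=True)
        return faces[idx[counts == 1]]

    def scaled_jacobians(self) -> np.ndarray:
        """Minimum corner scaled Jacobian per element (1 for a regular tet)."""
        x = self.nodes[self.tets]
        out = np.full(self.n_elements, np.inf)
        # orientation-preserving corner orderings
        for others in ((1, 2, 3), (0, 3, 2), (0, 1, 3), (0, 2, 1)):
            a = ({0, 1, 2, 3} - set(others)).pop()
            e = x[:, others, :] - x[:, a:a + 1, :]
            det = np.linalg.det(e)
            ln = np.prod(np.linalg.norm(e, axis=2), axis=1)
            out = np.minimum(out, np.sqrt(2.0) * det / np.where(ln > 0, ln, 1.0))
        return out

    def inner_surface(self) -> SurfaceMesh:
        return SurfaceMesh(self.nodes, self.inner_facets)


@dataclass(frozen=True)
class QualityReport:
    n_elements: int
    min_edge: float
    mean_edge: float
    max_edge: float
    min_scaled_jacobian: float
    shortest_edge: float
    watertight: bool

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (f"{self.n_elements} elements; edge min/mean/max = "
                f"{self.min_edge:.3f}/{self.mean_edge:.3f}/{self.max_edge:.3f} mm; "
                f"min scaled Jacobian {self.min_scaled_jacobian:.3f}; "
                f"watertight={self.watertight}")


# ---------------------------------------------------------------------------
# inner-surface generation


def radius_profile(params: MorphologyParams, s: np.ndarray | float):
    """Unperturbed cavity radius at normalized sweep coordinate s.

    s in [0, 1] spans the swept side wall (linear taper from the orifice
    radius to the tip radius); s in (1, 2] spans the hemispherical tip cap,
    where the radius follows r_tip * cos((s - 1) * pi / 2).
    """
    s = np.asarray(s, dtype=float)
    r0 = 0.5 * params.orifice_diameter
    r_tip = r0 * params.taper_ratio
    side = r0 + (r_tip - r0) * np.clip(s, 0.0, 1.0)
    cap = r_tip * np.cos(np.clip(s - 1.0, 0.0, 1.0) * np.pi / 2.0)
    out = np.where(s <= 1.0, side, cap)
    return float(out) if out.ndim == 0 else out


def _draw_lobes(params: MorphologyParams, rng: np.random.Generator):
    """Seeded bump parameters (s-center, theta-center, amplitude, widths)."""
    return [(rng.uniform(0.25, 0.85), rng.uniform(0.0, 2.0 * np.pi),
             rng.uniform(0.12, 0.30), rng.uniform(0.10, 0.20),
             rng.uniform(0.45, 0.80)) for _ in range(params.lobe_count)]


def _eval_lobes(lobes, s: float, theta: np.ndarray) -> np.ndarray:
    """Multiplicative radial perturbation 1 + sum of smooth bumps."""
    g = np.ones_like(theta)
    for s0, th0, amp, ss, st in lobes:
        dth = np.angle(np.exp(1j * (theta - th0)))
        g = g + amp * np.exp(-0.5 * ((s - s0) / ss) ** 2
                             - 0.5 * (dth / st) ** 2)
    return g


def generate_inner_surface(params: MorphologyParams) -> SurfaceMesh:
    """Closed (watertight) inner cavity surface from a centerline sweep.

    The centerline is a constant-curvature arc turning through ``bend_angle``
    in the x–z plane; rings of vertices are placed at sweep stations with the
    taper of :func:`radius_profile`, class lobes added as smooth radial bumps,
    a rounded tip closes the far end and a triangle fan (tagged in
    ``cap_faces``) closes the orifice plane.  Deterministic per seed.
    """
    rng = np.random.default_rng(params.seed)
    edge = params.target_edge_length
    r0 = 0.5 * params.orifice_diameter
    r_tip = r0 * params.taper_ratio

    n_c = max(12, int(np.ceil(np.pi * params.orifice_diameter / edge)))
    L_sweep = max(params.height - r_tip, 0.25 * params.height)
    n_s = max(4, int(np.ceil(L_sweep / edge)))
    n_cap = max(2, int(np.ceil(0.5 * np.pi * r_tip / edge)))

    theta = np.arange(n_c) * (2.0 * np.pi / n_c)
    bend = np.deg2rad(params.bend_angle)

    # centerline stations and local frames (arc in the x-z plane)
    s_vals = np.arange(n_s + 1) / n_s
    phis = bend * s_vals
    ds = L_sweep / n_s
    centers = np.zeros((n_s + 1, 3))
    d_axis = np.zeros((n_s + 1, 3))
    d_axis[:, 0] = np.sin(phis)
    d_axis[:, 2] = np.cos(phis)
    for j in range(1, n_s + 1):
        step_dir = np.array([np.sin(0.5 * (phis[j - 1] + phis[j])), 0.0,
                             np.cos(0.5 * (phis[j - 1] + phis[j]))])
        centers[j] = centers[j - 1] + ds * step_dir

    lobes = _draw_lobes(params, rng)
    verts: list[np.ndarray] = []
    params_sv: list[tuple[float, float]] = []
    for j, s in enumerate(s_vals):
        e1 = np.array([np.cos(phis[j]), 0.0, -np.sin(phis[j])])
        e2 = np.array([0.0, 1.0, 0.0])
        r_base = radius_profile(params, s)
        g = _eval_lobes(lobes, s, theta) if lobes else np.ones(n_c)
        r = r_base * g
        ring = (centers[j][None, :]
                + np.outer(r * np.cos(theta), e1)
                + np.outer(r * np.sin(theta), e2))
        verts.append(ring)
        params_sv.extend((s, t) for t in theta)

    # hemispherical tip cap rings
    tip_center = centers[-1]
    e1 = np.array([np.cos(bend), 0.0, -np.sin(bend)])
    e2 = np.array([0.0, 1.0, 0.0])
    for k in range(1, n_cap):
        psi = 0.5 * np.pi * k / n_cap
        s_cap = 1.0 + k / n_cap
        r = r_tip * np.cos(psi)
        ring = (tip_center[None, :] + r_tip * np.sin(psi) * d_axis[-1][None, :]
                + np.outer(r * np.cos(theta), e1)
                + np.outer(r * np.sin(theta), e2))
        verts.append(ring)
        params_sv.extend((s_cap, t) for t in theta)
    apex = tip_center + r_tip * d_axis[-1]
    base_center = np.zeros(3)

    V_rings = np.vstack(verts)
    vertices = np.vstack([V_rings, apex[None, :], base_center[None, :]])
    params_sv.extend([(2.0, 0.0), (0.0, 0.0)])
    i_apex = len(vertices) - 2
    i_base = len(vertices) - 1
    n_rings = (n_s + 1) + (n_cap - 1)

    tris: list[tuple[int, int, int]] = []
    for j in range(n_rings - 1):
        a = j * n_c
        b = (j + 1) * n_c
        for i in range(n_c):
            i2 = (i + 1) % n_c
            tris.append((a + i, a + i2, b + i2))
            tris.append((a + i, b + i2, b + i))
    # tip fan
    last = (n_rings - 1) * n_c
    for i in range(n_c):
        i2 = (i + 1) % n_c
        tris.append((last + i, last + i2, i_apex))
    # orifice cap fan (tagged)
    cap_start = len(tris)
    for i in range(n_c):
        i2 = (i + 1) % n_c
        tris.append((i2, i, i_base))
    triangles = np.asarray(tris, dtype=np.int64)
    cap_faces = np.arange(cap_start, len(tris), dtype=np.int64)

    surf = SurfaceMesh(vertices, triangles, cap_faces=cap_faces,
                       param_coords=np.asarray(params_sv))
    if surf.signed_volume() < 0:
        surf.triangles = surf.triangles[:, [0, 2, 1]]
    if surf.has_degenerate_triangles():
        raise ValueError("degenerate triangles in generated surface "
                         "(parameters too coarse?)")
    return surf


# ---------------------------------------------------------------------------
# offset / solidify


def _ray_surface_distance(origins: np.ndarray, directions: np.ndarray,
                          surf: SurfaceMesh) -> np.ndarray:
    """First-hit distances of rays against a surface (vectorized
    Moller–Trumbore over all triangles).  NaN where no hit."""
    v = surf.vertices
    tri = surf.triangles
    p0 = v[tri[:, 0]]
    e1 = v[tri[:, 1]] - p0
    e2 = v[tri[:, 2]] - p0
    out = np.full(len(origins), np.nan)
    for i, (o, d) in enumerate(zip(origins, directions)):
        h = np.cross(d[None, :], e2)
        a = np.einsum("ij,ij->i", e1, h)
        ok = np.abs(a) > 1e-14
        f = np.where(ok, 1.0 / np.where(ok, a, 1.0), 0.0)
        sv = o[None, :] - p0
        u = f * np.einsum("ij,ij->i", sv, h)
        q = np.cross(sv, e1)
        vv = f * (q @ d)
        t_hit = f * np.einsum("ij,ij->i", e2, q)
        hit = (ok & (u >= -1e-9) & (vv >= -1e-9) & (u + vv <= 1 + 1e-9)
               & (t_hit > 1e-9))
        if np.any(hit):
            out[i] = t_hit[hit].min()
    return out


def offset_distances(inner: SurfaceMesh, outer: SurfaceMesh,
                     sample: int | None = 400, seed: int = 0) -> np.ndarray:
    """Ray-cast distances from inner vertices along their normals to the
    outer surface (the operative wall-thickness measurement)."""
    n = inner.normals()
    idx = np.arange(inner.n_vertices)
    if len(inner.cap_faces):
        on_cap = np.unique(inner.triangles[inner.cap_faces])
        idx = np.setdiff1d(idx, on_cap)
    if sample is not None and len(idx) > sample:
        rng = np.random.default_rng(seed)
        idx = rng.choice(idx, size=sample, replace=False)
    d = _ray_surface_distance(inner.vertices[idx], n[idx], outer)
    return d[np.isfinite(d)]


def check_self_intersections(surf: SurfaceMesh, max_pairs: int = 20
                             ) -> list[tuple[int, int]]:
    """Return non-adjacent triangle pairs that intersect (empty if clean).

    Broad phase: KD-tree on circumspheres; narrow phase: plane-crossing plus
    segment-in-triangle tests.
    """
    v = surf.vertices
    tri = surf.triangles
    cent = v[tri].mean(axis=1)
    rad = np.linalg.norm(v[tri] - cent[:, None, :], axis=2).max(axis=1)
    tree = cKDTree(cent)
    rmax = float(rad.max())
    offending: list[tuple[int, int]] = []
    neighbors = tree.query_ball_tree(tree, 2.0 * rmax)
    vsets = [set(t) for t in tri]
    for i, cand in enumerate(neighbors):
        for j in cand:
            if j <= i:
                continue
            if np.linalg.norm(cent[i] - cent[j]) > rad[i] + rad[j]:
                continue
            if vsets[i] & vsets[j]:
                continue
            if _tris_intersect(v[tri[i]], v[tri[j]]):
                offending.append((i, j))
                if len(offending) >= max_pairs:
                    return offending
    return offending


def _seg_tri(p, q, t) -> bool:
    """Does segment pq cross triangle t (proper intersection)?"""
    n = np.cross(t[1] - t[0], t[2] - t[0])
    dp = (p - t[0]) @ n
    dq = (q - t[0]) @ n
    if dp * dq >= -1e-14:
        return False
    s = dp / (dp - dq)
    x = p + s * (q - p)
    # barycentric inside test
    v0 = t[1] - t[0]
    v1 = t[2] - t[0]
    v2 = x - t[0]
    d00 = v0 @ v0
    d01 = v0 @ v1
    d11 = v1 @ v1
    d20 = v2 @ v0
    d21 = v2 @ v1
    den = d00 * d11 - d01 * d01
    if den <= 0:
        return False
    a = (d11 * d20 - d01 * d21) / den
    b = (d00 * d21 - d01 * d20) / den
    return a > 1e-10 and b > 1e-10 and a + b < 1 - 1e-10


def _tris_intersect(t1, t2) -> bool:
    for k in range(3):
        if _seg_tri(t1[k], t1[(k + 1) % 3], t2):
            return True
        if _seg_tri(t2[k], t2[(k + 1) % 3], t1):
            return True
    return False


class SelfIntersectionError(ValueError):
    def __init__(self, pairs):
        self.pairs = pairs
        super().__init__(f"offset surface self-intersects; offending triangle "
                         f"pairs (first {len(pairs)}): {pairs}")


def offset_surface(inner: SurfaceMesh, thickness: float,
                   scale: np.ndarray | None = None,
                   check: bool = True) -> SurfaceMesh:
    """Outer surface: every vertex displaced along its outward normal.

    ``scale`` is an optional per-vertex thickness multiplier (mean-normalized
    by the caller); ``check=True`` runs the self-intersection test and raises
    :class:`SelfIntersectionError` naming offending triangle pairs.
    """
    if thickness < 0:
        raise ValueError("thickness must be non-negative")
    n = inner.normals()
    if scale is not None:
        outer_v = inner.vertices + (thickness * np.asarray(scale)[:, None]) * n
    else:
        outer_v = inner.vertices + thickness * n
    outer = SurfaceMesh(outer_v, inner.triangles.copy(),
                        cap_faces=inner.cap_faces.copy(),
                        vertex_normals=None if inner.vertex_normals is None
                        else inner.vertex_normals.copy(),
                        param_coords=inner.param_coords)
    if check and thickness > 0:
        bad = check_self_intersections(outer)
        if bad:
            raise SelfIntersectionError(bad)
    return outer


def _split_prisms(tris: np.ndarray, V: int) -> np.ndarray:
    """Split each prism (bottom triangle ids, top = ids + V) into 3 tets with
    the lowest-global-vertex-id diagonal rule, so shared quad faces of
    neighbouring prisms receive the same diagonal and the mesh conforms."""
    tets: list[tuple[int, int, int, int]] = []
    for (a0, a1, a2) in tris:
        bot = (int(a0), int(a1), int(a2))
        k = int(np.argmin(bot))        # smallest global id to corner 0
        bot = bot[k:] + bot[:k]
        i0, i1, i2 = bot
        j0, j1, j2 = (b + V for b in bot)
        if min(i1, j2) < min(i2, j1):  # diagonal i1-j2 on quad (i1,i2,j2,j1)
            tets += [(i0, i1, i2, j2), (i0, i1, j2, j1), (i0, j1, j2, j0)]
        else:                          # diagonal i2-j1
            tets += [(i0, i1, i2, j1), (i0, j1, i2, j2), (i0, j1, j2, j0)]
    return np.asarray(tets, dtype=np.int64)


def solidify(inner: SurfaceMesh, outer: SurfaceMesh,
             n_layers: int = 1) -> VolumeMesh:
    """Couple the two surfaces into a conforming first-order tet mesh.

    The wall is stacked from ``n_layers`` prism layers between linearly
    interpolated surface copies; each prism splits into three tets using the
    lowest-global-vertex-id diagonal rule, so that shared quad faces of
    neighbouring prisms receive the same diagonal.  Orifice-cap triangles are
    skipped, leaving the orifice annulus open; the outer boundary loop there
    becomes the orifice ring.
    """
    if inner.triangles.shape != outer.triangles.shape or \
            not np.array_equal(inner.triangles, outer.triangles):
        raise ValueError("inner and outer surfaces must share triangle "
                         "topology (offset-generated)")
    V = inner.n_vertices
    keep = np.ones(inner.n_triangles, bool)
    if len(inner.cap_faces):
        keep[inner.cap_faces] = False
    wall_tris = inner.triangles[keep]

    fracs = np.linspace(0.0, 1.0, n_layers + 1)
    nodes = np.vstack([(1 - f) * inner.vertices + f * outer.vertices
                       for f in fracs])
    tets_arr = np.vstack([_split_prisms(wall_tris + l * V, V)
                          for l in range(n_layers)])

    # drop unused nodes (orifice-cap interiors and their copies)
    used = np.unique(tets_arr)
    remap = -np.ones((n_layers + 1) * V, dtype=np.int64)
    remap[used] = np.arange(len(used))
    new_nodes = nodes[used]
    new_tets = remap[tets_arr]

    # positive volumes under the fixed ordering convention
    x = new_nodes[new_tets]
    vol = np.linalg.det(x[:, 1:] - x[:, :1]) / 6.0
    neg = vol < 0
    if np.any(neg):
        new_tets[neg] = new_tets[neg][:, [0, 2, 1, 3]]
    vol = np.abs(vol)
    if np.any(vol <= 0):
        bad = np.where(vol <= 0)[0]
        raise ValueError(f"degenerate/inverted tets at elements {bad[:20]}")

    inner_facets = remap[wall_tris]
    if np.any(inner_facets < 0):
        raise AssertionError("inner facet node lost in remap")

    # orifice ring: boundary loop of the kept inner triangles, outer copies
    e = np.vstack([wall_tris[:, [0, 1]], wall_tris[:, [1, 2]],
                   wall_tris[:, [2, 0]]])
    key = np.sort(e, axis=1)
    uniq, counts = np.unique(key, axis=0, return_counts=True)
    rim_inner = np.unique(uniq[counts == 1])
    ring = remap[rim_inner + n_layers * V]
    if len(ring) == 0 or np.any(ring < 0):
        raise ValueError("orifice ring empty — inner surface had no opening "
                         "after cap removal")

    mesh = VolumeMesh(
        nodes=new_nodes, tets=new_tets, inner_facets=inner_facets,
        orifice_ring=np.sort(ring),
        element_sets={"wall": np.arange(len(new_tets))},
        node_sets={"ORIFICE": np.sort(ring),
                   "inner_surface": remap[np.unique(wall_tris)]},
    )
    if inner.param_coords is not None:
        # sweep-parameter coordinates of the kept inner-surface nodes, used
        # for mesh-independent trabecula anchoring (NaN elsewhere)
        sp = np.full((len(new_nodes), 2), np.nan)
        kept = remap[:V] >= 0
        sp[remap[:V][kept]] = inner.param_coords[:V][kept]
        mesh.node_data["surface_param"] = sp
    return mesh


# ---------------------------------------------------------------------------
# trabeculae


def add_trabeculae(mesh: VolumeMesh, params: MorphologyParams) -> VolumeMesh:
    """Add tension-only trabecula cables between near-opposing cavity nodes.

    Anchor locations are drawn (seeded) in the sweep's (s, theta) parameter
    space, so the same morphology meshed at different densities receives
    geometrically matching cables (needed for mesh-convergence studies); each
    anchor snaps to the nearest inner-surface node and pairs with the node
    best aligned with its inward normal on the facing wall.  Diameters are
    drawn uniformly from the preset range.  The cauliflower class carries no
    columnar trabeculae (its septum-like wall thickening is emulated by
    thickness ridges at offset time): ``trabecula_count=0`` returns the mesh
    unchanged.
    """
    if params.trabecula_count == 0:
        return mesh
    rng = np.random.default_rng(params.seed + 1)
    surf_nodes = mesh.node_sets.get("inner_surface")
    if surf_nodes is None:
        surf_nodes = np.unique(mesh.inner_facets)
    inner = SurfaceMesh(mesh.nodes, mesh.inner_facets)
    normals = inner.angle_weighted_normals()

    x = mesh.nodes[surf_nodes]
    n = normals[surf_nodes]
    tree = cKDTree(x)
    span = float(np.ptp(mesh.nodes, axis=0).max())
    sp = mesh.node_data.get("surface_param")
    sp_surf = sp[surf_nodes] if sp is not None else None

    def nearest_by_param(s0: float, th0: float) -> int:
        dth = np.angle(np.exp(1j * (sp_surf[:, 1] - th0)))
        d2 = (sp_surf[:, 0] - s0) ** 2 + (0.3 * dth) ** 2
        return int(np.nanargmin(d2))

    def opposite(idx: int, taken: set[int]) -> int:
        xi, ni = x[idx], n[idx]
        cand = tree.query_ball_point(xi, 0.6 * span)
        best, best_d = -1, np.inf
        for j in cand:
            if j == idx or j in taken:
                continue
            d = x[j] - xi
            dist = float(np.linalg.norm(d))
            if dist < 1.5 or dist >= best_d:
                continue
            u = d / dist
            # chord along the inward direction of idx, arriving against j's
            # inward direction: walls facing each other
            if (u @ (-ni)) > 0.75 and (u @ n[j]) > 0.75:
                best, best_d = j, dist
        return best

    cables: list[tuple[int, int, float]] = []
    taken: set[int] = set()
    attempts = 0
    while len(cables) < params.trabecula_count and attempts < 20 * params.trabecula_count:
        attempts += 1
        s0 = rng.uniform(0.2, 0.9)
        th0 = rng.uniform(0.0, 2.0 * np.pi)
        dia = rng.uniform(*params.trabecula_diameter_range)
        if sp_surf is None:
            idx = int(rng.integers(len(surf_nodes)))
        else:
            idx = nearest_by_param(s0, th0)
        if idx in taken:
            continue
        j = opposite(idx, taken)
        if j < 0:
            continue
        cables.append((int(surf_nodes[idx]), int(surf_nodes[j]), float(dia)))
        taken.add(idx)
        taken.add(j)
    if not cables:
        raise ValueError("no valid opposing inner-surface node pairs found "
                         "for trabeculae")
    out = VolumeMesh(mesh.nodes.copy(), mesh.tets.copy(),
                     mesh.inner_facets.copy(), mesh.orifice_ring.copy(),
                     trabecula_cables=cables,
                     element_sets=dict(mesh.element_sets),
                     node_sets=dict(mesh.node_sets),
                     node_data=dict(mesh.node_data))
    return out


# ---------------------------------------------------------------------------
# full pipeline and presets


def _thickness_ridges(inner: SurfaceMesh, params: MorphologyParams
                      ) -> np.ndarray | None:
    """Mean-normalized per-vertex wall-thickness multiplier emulating the
    cauliflower's embedded septum-like stiffening ridges."""
    if params.morphology_class != "cauliflower":
        return None
    pc = inner.param_coords
    if pc is None:
        return None
    rng = np.random.default_rng(params.seed + 2)
    s, th = pc[:, 0], pc[:, 1]
    m = np.ones(inner.n_vertices)
    for _ in range(max(3, params.lobe_count)):
        th0 = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.2, 0.4)
        dth = np.angle(np.exp(1j * (th - th0)))
        m = m + amp * np.exp(-0.5 * (dth / 0.25) ** 2) * (s <= 1.0)
    return m / m.mean()


def build_appendage(params: MorphologyParams, check_offset: bool = False
                    ) -> VolumeMesh:
    """Full synthetic pipeline: inner surface → offset → solidify →
    trabeculae.  ``check_offset`` enables the (slower) self-intersection
    scan of the offset surface."""
    inner = generate_inner_surface(params)
    scale = _thickness_ridges(inner, params)
    outer = offset_surface(inner, params.wall_thickness, scale=scale,
                           check=check_offset)
    mesh = solidify(inner, outer, n_layers=params.n_layers)
    return add_trabeculae(mesh, params)


# ---------------------------------------------------------------------------
# benchmarks


def uv_sphere(radius: float, edge: float) -> SurfaceMesh:
    """Closed UV sphere with exact radial vertex normals attached."""
    n_phi = max(6, int(np.ceil(np.pi * radius / edge)))
    n_c = max(12, int(np.ceil(2 * np.pi * radius / edge)))
    theta = np.arange(n_c) * (2 * np.pi / n_c)
    verts = [np.array([0.0, 0.0, radius])]
    for k in range(1, n_phi):
        phi = np.pi * k / n_phi
        ring = radius * np.column_stack([
            np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta),
            np.full(n_c, np.cos(phi))])
        verts.append(ring)
    verts.append(np.array([0.0, 0.0, -radius]))
    vertices = np.vstack([v if v.ndim == 2 else v[None, :] for v in verts])
    tris = []
    for i in range(n_c):
        i2 = (i + 1) % n_c
        tris.append((0, 1 + i, 1 + i2))
    for k in range(n_phi - 2):
        a = 1 + k * n_c
        b = 1 + (k + 1) * n_c
        for i in range(n_c):
            i2 = (i + 1) % n_c
            tris.append((a + i, b + i, b + i2))
            tris.append((a + i, b + i2, a + i2))
    last = 1 + (n_phi - 2) * n_c
    bot = len(vertices) - 1
    for i in range(n_c):
        i2 = (i + 1) % n_c
        tris.append((last + i, bot, last + i2))
    surf = SurfaceMesh(vertices, np.asarray(tris, np.int64))
    if surf.signed_volume() < 0:
        surf.triangles = surf.triangles[:, [0, 2, 1]]
    surf.vertex_normals = surf.vertices / np.linalg.norm(
        surf.vertices, axis=1, keepdims=True)
    return surf


def sphere_shell(radius: float = 10.0, thickness: float = 2.1,
                 edge: float = 1.25, n_layers: int = 1) -> VolumeMesh:
    """Closed thick spherical shell (Lamé benchmark).  The entire inner
    sphere is the pressurized cavity; there is no orifice, so the ring set is
    empty and the shell must be run unconstrained."""
    inner = uv_sphere(radius, edge)
    outer = offset_surface(inner, thickness, check=False)
    V = inner.n_vertices
    fracs = np.linspace(0.0, 1.0, n_layers + 1)
    nodes = np.vstack([(1 - f) * inner.vertices + f * outer.vertices
                       for f in fracs])
    tets = np.vstack([_split_prisms(inner.triangles + l * V, V)
                      for l in range(n_layers)])
    x = nodes[tets]
    vol = np.linalg.det(x[:, 1:] - x[:, :1]) / 6.0
    tets[vol < 0] = tets[vol < 0][:, [0, 2, 1, 3]]
    return VolumeMesh(nodes=nodes, tets=tets,
                      inner_facets=inner.triangles.copy(),
                      orifice_ring=np.empty(0, np.int64),
                      element_sets={"wall": np.arange(len(tets))},
                      node_sets={"inner_surface": np.arange(V)})


def make_benchmark(kind: str, radius: float = 10.0, thickness: float = 1.0,
                   half_angle: float = 60.0, length: float = 30.0,
                   edge: float = 1.25) -> VolumeMesh:
    """Validation geometries: ``spherical_cap`` (clamped-rim bistable
    snap-through shell) or ``closed_tube`` (flat-capped eversion tube)."""
    if kind == "spherical_cap":
        if not (0.0 < half_angle < 90.0):
            raise ValueError("half_angle must lie in (0, 90) degrees")
        alpha = np.deg2rad(half_angle)
        n_psi = max(4, int(np.ceil(alpha * radius / edge)))
        n_c = max(12, int(np.ceil(2 * np.pi * radius * np.sin(alpha) / edge)))
        theta = np.arange(n_c) * (2 * np.pi / n_c)
        verts = [np.array([[0.0, 0.0, radius]])]
        for k in range(1, n_psi + 1):
            psi = alpha * k / n_psi
            ring = radius * np.column_stack([
                np.sin(psi) * np.cos(theta), np.sin(psi) * np.sin(theta),
                np.full(n_c, np.cos(psi))])
            verts.append(ring)
        vertices = np.vstack(verts)
        tris = []
        for i in range(n_c):
            i2 = (i + 1) % n_c
            tris.append((0, 1 + i, 1 + i2))
        for k in range(n_psi - 1):
            a = 1 + k * n_c
            b = 1 + (k + 1) * n_c
            for i in range(n_c):
                i2 = (i + 1) % n_c
                tris.append((a + i, b + i, b + i2))
                tris.append((a + i, b + i2, a + i2))
        inner = SurfaceMesh(vertices, np.asarray(tris, np.int64))
        inner.vertex_normals = vertices / np.linalg.norm(vertices, axis=1,
                                                         keepdims=True)
        outer = offset_surface(inner, thickness, check=False)
        mesh = _solidify_open(inner, outer)
        rim = np.arange(1 + (n_psi - 1) * n_c, 1 + n_psi * n_c)
        mesh.orifice_ring = np.sort(mesh._remap[rim + inner.n_vertices])
        mesh.node_sets["ORIFICE"] = mesh.orifice_ring
        return mesh
    elif kind == "closed_tube":
        inner = _closed_tube_surface(radius, length, edge)
        outer = offset_surface(inner, thickness, check=False)
        return solidify(inner, outer)
    raise ValueError(f"unknown benchmark kind {kind!r}")


def _closed_tube_surface(radius: float, length: float, edge: float
                         ) -> SurfaceMesh:
    """Cylinder closed by a flat tip disk, open orifice cap at z=0 tagged."""
    n_c = max(12, int(np.ceil(2 * np.pi * radius / edge)))
    n_s = max(4, int(np.ceil(length / edge)))
    theta = np.arange(n_c) * (2 * np.pi / n_c)
    rings = [np.column_stack([radius * np.cos(theta), radius * np.sin(theta),
                              np.full(n_c, length * j / n_s)])
             for j in range(n_s + 1)]
    vertices = np.vstack(rings)
    # flat tip: inner disk rings for regular triangulation
    n_r = max(2, int(np.ceil(radius / edge)))
    tip_rings = []
    for k in range(1, n_r):
        r = radius * (1 - k / n_r)
        tip_rings.append(np.column_stack([r * np.cos(theta),
                                          r * np.sin(theta),
                                          np.full(n_c, length)]))
    tip_center = np.array([[0.0, 0.0, length]])
    base_center = np.array([[0.0, 0.0, 0.0]])
    vertices = np.vstack([vertices] + tip_rings + [tip_center, base_center])
    i_tip = len(vertices) - 2
    i_base = len(vertices) - 1

    tris = []
    for j in range(n_s):
        a, b = j * n_c, (j + 1) * n_c
        for i in range(n_c):
            i2 = (i + 1) % n_c
            tris.append((a + i, a + i2, b + i2))
            tris.append((a + i, b + i2, b + i))
    # tip disk
    ring_ids = [np.arange(n_s * n_c, (n_s + 1) * n_c)]
    for k in range(n_r - 1):
        ring_ids.append(np.arange((n_s + 1 + k) * n_c, (n_s + 2 + k) * n_c))
    for a_ids, b_ids in zip(ring_ids[:-1], ring_ids[1:]):
        for i in range(n_c):
            i2 = (i + 1) % n_c
            tris.append((a_ids[i], a_ids[i2], b_ids[i2]))
            tris.append((a_ids[i], b_ids[i2], b_ids[i]))
    for i in range(n_c):
        i2 = (i + 1) % n_c
        tris.append((ring_ids[-1][i], ring_ids[-1][i2], i_tip))
    cap_start = len(tris)
    for i in range(n_c):
        i2 = (i + 1) % n_c
        tris.append((i2, i, i_base))
    surf = SurfaceMesh(vertices, np.asarray(tris, np.int64),
                       cap_faces=np.arange(cap_start, len(tris)))
    if surf.signed_volume() < 0:
        surf.triangles = surf.triangles[:, [0, 2, 1]]
    return surf


def _solidify_open(inner: SurfaceMesh, outer: SurfaceMesh) -> VolumeMesh:
    """Solidify an open surface pair (no cap faces to remove); keeps the
    inner→node remap for rim lookups."""
    V = inner.n_vertices
    nodes = np.vstack([inner.vertices, outer.vertices])
    tets = _split_prisms(inner.triangles, V)
    x = nodes[tets]
    vol = np.linalg.det(x[:, 1:] - x[:, :1]) / 6.0
    tets[vol < 0] = tets[vol < 0][:, [0, 2, 1, 3]]
    mesh = VolumeMesh(nodes=nodes, tets=tets,
                      inner_facets=inner.triangles.copy(),
                      orifice_ring=np.empty(0, np.int64),
                      element_sets={"wall": np.arange(len(tets))},
                      node_sets={"inner_surface": np.arange(V)})
    mesh._remap = np.arange(2 * V)  # type: ignore[attr-defined]
    return mesh


# ---------------------------------------------------------------------------
# series / quality


def mesh_series(params: MorphologyParams, n: int = 3,
                increment: float = 0.20, tol: float = 0.05
                ) -> list[VolumeMesh]:
    """n meshes of the same geometry with element counts increasing by
    ``increment`` between consecutive members, via target-edge-length scaling
    (counts scale roughly as edge^-2 for these shell-like meshes)."""
    if n < 2:
        raise ValueError("need n >= 2 meshes")

    def predicted_count(edge: float) -> int:
        # mirrors generate_inner_surface's tessellation arithmetic
        r0 = 0.5 * params.orifice_diameter
        r_tip = r0 * params.taper_ratio
        n_c = max(12, int(np.ceil(np.pi * params.orifice_diameter / edge)))
        L_sweep = max(params.height - r_tip, 0.25 * params.height)
        n_s = max(4, int(np.ceil(L_sweep / edge)))
        n_cap = max(2, int(np.ceil(0.5 * np.pi * r_tip / edge)))
        n_rings = n_s + n_cap
        wall_tris = 2 * n_c * (n_rings - 1) + n_c
        return 3 * params.n_layers * wall_tris

    meshes = [build_appendage(params)]
    c0 = meshes[0].n_elements
    edge0 = params.target_edge_length
    for k in range(1, n):
        target = c0 * (1.0 + increment) ** k
        cand = edge0 * np.linspace(0.55, 1.25, 400)
        errs = [abs(predicted_count(e) / target - 1.0) for e in cand]
        best_edge = cand[int(np.argmin(errs))]
        m = build_appendage(replace(params, target_edge_length=float(best_edge)))
        err = m.n_elements / target - 1.0
        if abs(err) > tol:
            raise ValueError(
                f"could not reach element count {target:.0f} within "
                f"{tol:.0%} (best {err:+.1%}) — element counts are quantized "
                f"by the ring tessellation; try a finer base mesh")
        meshes.append(m)
    return meshes


def quality_report(mesh: VolumeMesh) -> QualityReport:
    """Edge statistics, worst scaled Jacobian and boundary-closure flag."""
    if mesh.n_elements == 0:
        raise ValueError("empty mesh")
    el = mesh.edge_lengths()
    bf = mesh.boundary_faces()
    be = np.vstack([bf[:, [0, 1]], bf[:, [1, 2]], bf[:, [2, 0]]])
    _, counts = np.unique(np.sort(be, axis=1), axis=0, return_counts=True)
    watertight = bool(np.all(counts == 2))
    return QualityReport(
        n_elements=mesh.n_elements,
        min_edge=float(el.min()), mean_edge=float(el.mean()),
        max_edge=float(el.max()),
        min_scaled_jacobian=float(mesh.scaled_jacobians().min()),
        shortest_edge=float(el.min()),
        watertight=watertight,
    )
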