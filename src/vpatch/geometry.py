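"""Parametric stenosed-vessel shell meshes and analytic lumen-area profiles.

The vessel is an idealized main-pulmonary-artery segment: a straight tube
of inner diameter ``D`` with an axisymmetric area stenosis.  The lumen
radius follows a cosine bump,

    r_lumen(z) = r0 * sqrt(1 - s * w(z)),
    w(z) = 1/2 * (1 + cos(2*pi*(z - z_c)/L_sten))   inside the bump, else 0,

so that the cross-sectional lumen AREA at the throat equals ``(1 - s)``
times the healthy area exactly (``s`` is the area-stenosis fraction).
The finite-element shell discretizes the wall mid-surface, offset from
the lumen by half the wall thickness; thickness is carried per element.

Axial coordinate ``z`` increases from inlet (z = 0) to outlet.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional

import numpy as np

ARTERY = 0
PATCH = 1

REGION_NAMES = {ARTERY: "artery", PATCH: "patch"}


class VesselSpecError(ValueError):
    """A vessel specification violates one of its invariants."""


@dataclass
class VesselSpec:
    """Parametric description of the stenosed tube (SI units).

    Defaults correspond to a 9-year-old child's main pulmonary artery:
    18 mm inner diameter, 1 mm uniform wall, 50 mm long stenosis centered
    on a 100 mm segment.
    """

    inner_diameter: float = 0.018
    wall_thickness: float = 0.001
    total_length: float = 0.100
    stenosis_fraction: float = 0.70
    stenosis_length: float = 0.050
    stenosis_center: Optional[float] = None
    profile_kind: str = "cosine"
    mesh_edge_length: float = 0.0005

    def __post_init__(self) -> None:
        if self.stenosis_center is None:
            self.stenosis_center = self.total_length / 2.0
        self.validate()

    def validate(self) -> None:
        if not (0.0 <= self.stenosis_fraction < 1.0):
            raise VesselSpecError(
                f"stenosis_fraction must be in [0, 1), got {self.stenosis_fraction}"
            )
        if self.stenosis_length > self.total_length:
            raise VesselSpecError(
                f"stenosis_length {self.stenosis_length} exceeds total_length "
                f"{self.total_length}"
            )
        if self.wall_thickness >= self.inner_diameter / 4.0:
            raise VesselSpecError(
                f"wall_thickness {self.wall_thickness} must be < inner_diameter/4 "
                f"= {self.inner_diameter / 4.0}"
            )
        if self.profile_kind != "cosine":
            raise VesselSpecError(f"unknown profile_kind {self.profile_kind!r}")
        for name in ("inner_diameter", "wall_thickness", "total_length",
                     "stenosis_length", "mesh_edge_length"):
            if getattr(self, name) <= 0:
                raise VesselSpecError(f"{name} must be positive")

    # -- analytic profile -------------------------------------------------

    @property
    def inner_radius(self) -> float:
        return self.inner_diameter / 2.0

    def bump(self, z: np.ndarray) -> np.ndarray:
        """Cosine bump w(z): 1 at the throat, 0 outside the stenosed span."""
        z = np.asarray(z, dtype=float)
        half = self.stenosis_length / 2.0
        x = z - self.stenosis_center
        w = 0.5 * (1.0 + np.cos(2.0 * np.pi * x / self.stenosis_length))
        return np.where(np.abs(x) <= half, w, 0.0)

    def lumen_radius(self, z: np.ndarray) -> np.ndarray:
        return self.inner_radius * np.sqrt(
            1.0 - self.stenosis_fraction * self.bump(z))

    def mid_surface_radius(self, z: np.ndarray) -> np.ndarray:
        return self.lumen_radius(z) + self.wall_thickness / 2.0

    def lumen_area(self, z: np.ndarray) -> np.ndarray:
        r = self.lumen_radius(z)
        return np.pi * r * r

    def to_dict(self) -> dict:
        return {
            "inner_diameter_mm": self.inner_diameter * 1e3,
            "wall_thickness_mm": self.wall_thickness * 1e3,
            "total_length_mm": self.total_length * 1e3,
            "stenosis_fraction": self.stenosis_fraction,
            "stenosis_length_mm": self.stenosis_length * 1e3,
            "stenosis_center_mm": self.stenosis_center * 1e3,
            "profile_kind": self.profile_kind,
            "mesh_edge_length_mm": self.mesh_edge_length * 1e3,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VesselSpec":
        kw = {}
        mapping = {
            "inner_diameter_mm": "inner_diameter",
            "wall_thickness_mm": "wall_thickness",
            "total_length_mm": "total_length",
            "stenosis_length_mm": "stenosis_length",
            "stenosis_center_mm": "stenosis_center",
            "mesh_edge_length_mm": "mesh_edge_length",
        }
        for key, val in d.items():
            if key in mapping:
                kw[mapping[key]] = float(val) * 1e-3
            elif key in ("stenosis_fraction", "profile_kind"):
                kw[key] = val
            else:
                raise VesselSpecError(f"unknown vessel key {key!r}")
        return cls(**kw)


def analytic_area_profile(spec: VesselSpec, axial_samples: int) -> np.ndarray:
    """Closed-form lumen area at uniformly spaced axial stations.

    Returns an ``(axial_samples, 2)`` array of ``(z, area)`` in SI units.
    """
    if axial_samples < 2:
        raise ValueError("axial_samples must be >= 2")
    z = np.linspace(0.0, spec.total_length, axial_samples)
    return np.column_stack([z, spec.lumen_area(z)])


# ---------------------------------------------------------------------------
# Shell mesh container
# ---------------------------------------------------------------------------


@dataclass
class ShellMesh:
    """Triangulated wall mid-surface with per-element region and thickness.

    ``node_tags`` maps tag names (``inlet_ring``, ``outlet_ring``,
    ``cut_edge_left``, ``cut_edge_right``, ``suture_line``) to node-index
    arrays; cut-edge arrays are ordered along the incision path.
    Triangles are wound so normals point outward (away from the axis).
    """

    nodes: np.ndarray            # (N, 3) float
    tris: np.ndarray             # (M, 3) int, 0-based
    element_region: np.ndarray   # (M,) int, ARTERY / PATCH
    element_thickness: np.ndarray  # (M,) float
    node_tags: Dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.tris)

    def copy(self) -> "ShellMesh":
        return ShellMesh(
            self.nodes.copy(), self.tris.copy(), self.element_region.copy(),
            self.element_thickness.copy(),
            {k: v.copy() for k, v in self.node_tags.items()})

    # -- differential geometry --------------------------------------------

    def tri_vectors(self, nodes: Optional[np.ndarray] = None):
        p = self.nodes if nodes is None else nodes
        a, b, c = (p[self.tris[:, i]] for i in range(3))
        return a, b - a, c - a

    def tri_normals(self, nodes: Optional[np.ndarray] = None) -> np.ndarray:
        _, e1, e2 = self.tri_vectors(nodes)
        n = np.cross(e1, e2)
        return n / np.linalg.norm(n, axis=1, keepdims=True)

    def tri_areas(self, nodes: Optional[np.ndarray] = None) -> np.ndarray:
        _, e1, e2 = self.tri_vectors(nodes)
        return 0.5 * np.linalg.norm(np.cross(e1, e2), axis=1)

    # -- topology ----------------------------------------------------------

    def edge_counts(self):
        """Sorted (undirected) edges and their triangle-incidence counts."""
        e = np.concatenate([self.tris[:, [0, 1]], self.tris[:, [1, 2]],
                            self.tris[:, [2, 0]]])
        e = np.sort(e, axis=1)
        edges, counts = np.unique(e, axis=0, return_counts=True)
        return edges, counts

    def boundary_edges(self) -> np.ndarray:
        edges, counts = self.edge_counts()
        return edges[counts == 1]

    def is_manifold(self) -> bool:
        _, counts = self.edge_counts()
        return bool(np.all(counts <= 2))

    def to_trimesh(self, nodes: Optional[np.ndarray] = None):
        import trimesh
        p = self.nodes if nodes is None else nodes
        return trimesh.Trimesh(vertices=p, faces=self.tris, process=False)

    # -- export ------------------------------------------------------------

    def export_surface(self, path: str, nodes: Optional[np.ndarray] = None) -> None:
        """Write STL or PLY (by extension) via trimesh."""
        self.to_trimesh(nodes).export(path)

    def export_vtk(self, path: str, nodes: Optional[np.ndarray] = None,
                   point_data: Optional[dict] = None,
                   cell_data: Optional[dict] = None) -> None:
        from .io_vtk import write_vtk
        cd = {"region": self.element_region.astype(float),
              "thickness": self.element_thickness}
        if cell_data:
            cd.update(cell_data)
        write_vtk(path, self.nodes if nodes is None else nodes, self.tris,
                  point_data=point_data or {}, cell_data=cd)


# ---------------------------------------------------------------------------
# Structured tube generator
# ---------------------------------------------------------------------------


def _grid_dimensions(spec: VesselSpec):
    r_mid = spec.inner_radius + spec.wall_thickness / 2.0
    h = spec.mesh_edge_length
    ntheta = max(8, int(round(2.0 * np.pi * r_mid / h)))
    ntheta += ntheta % 2  # even: node columns at both theta=0 and theta=pi
    nz = max(4, int(round(spec.total_length / h)))
    nz += nz % 2          # even: node row at the stenosis mid-plane
    return ntheta, nz


def build_stenosed_tube(spec: VesselSpec) -> ShellMesh:
    """Mesh the wall mid-surface of the stenosed tube.

    Nodes form a structured cylindrical grid with a node column exactly at
    azimuth 0 (and pi), so axial incisions trace along grid lines.  Quad
    cells are split along diagonals whose orientation flips across both the
    stenosis mid-plane and the theta = 0/pi plane, keeping the triangulation
    mirror-symmetric.
    """
    spec.validate()
    if spec.stenosis_fraction > 0 and spec.mesh_edge_length > spec.stenosis_length / 10.0:
        raise VesselSpecError(
            f"mesh_edge_length {spec.mesh_edge_length} must be <= "
            f"stenosis_length/10 = {spec.stenosis_length / 10.0} to resolve "
            "the stenosis")

    ntheta, nz = _grid_dimensions(spec)
    theta = 2.0 * np.pi * np.arange(ntheta) / ntheta
    z = np.linspace(0.0, spec.total_length, nz + 1)
    r = spec.mid_surface_radius(z)

    # nodes: index = j * ntheta + k  (j axial row, k circumferential)
    zz = np.repeat(z, ntheta)
    tt = np.tile(theta, nz + 1)
    rr = np.repeat(r, ntheta)
    nodes = np.column_stack([rr * np.cos(tt), rr * np.sin(tt), zz])

    tris = []
    half_k = ntheta // 2
    half_j = nz // 2
    for j in range(nz):
        for k in range(ntheta):
            k1 = (k + 1) % ntheta
            a = j * ntheta + k
            b = j * ntheta + k1
            c = (j + 1) * ntheta + k1
            d = (j + 1) * ntheta + k
            # flip diagonal across each symmetry plane
            flip = (j < half_j) ^ (k < half_k)
            if flip:
                tris.append((a, b, c))
                tris.append((a, c, d))
            else:
                tris.append((a, b, d))
                tris.append((b, c, d))
    tris = np.asarray(tris, dtype=np.int64)

    m = len(tris)
    mesh = ShellMesh(
        nodes=nodes,
        tris=tris,
        element_region=np.full(m, ARTERY, dtype=np.int64),
        element_thickness=np.full(m, spec.wall_thickness, dtype=float),
        node_tags={
            "inlet_ring": np.arange(ntheta, dtype=np.int64),
            "outlet_ring": np.arange(nz * ntheta, (nz + 1) * ntheta,
                                     dtype=np.int64),
        },
    )
    mesh.grid_shape = (nz + 1, ntheta)  # kept for structured-path tracing
    return mesh


def sliced_area_profile(mesh: ShellMesh, spec: VesselSpec,
                        axial_samples: int = 41) -> np.ndarray:
    """Lumen areas by slicing the generated mesh with z-normal planes.

    Independent of the analytic formula: slices the triangulated
    mid-surface, measures the enclosed polygon area, and offsets the
    equivalent radius inward by half the wall thickness.  Returns
    ``(z, area)`` rows.
    """
    from .indices import _section_polygon
    t = spec.wall_thickness
    eps = 1e-6 * spec.total_length
    zs = np.linspace(eps, spec.total_length - eps, axial_samples)
    out = []
    tm = mesh.to_trimesh()
    z_hat = np.array([0.0, 0.0, 1.0])
    for zi in zs:
        origin = np.array([0.0, 0.0, zi])
        poly = _section_polygon(tm, origin, z_hat)
        if poly is None:
            continue
        _, area_mid, nv = poly
        if nv >= 3:
            # inscribed-polygon deficit of a circular section
            area_mid /= nv * np.sin(2 * np.pi / nv) / (2 * np.pi)
        r_lum = np.sqrt(area_mid / np.pi) - t / 2.0
        out.append((zi, np.pi * r_lum ** 2))
    return np.asarray(out)
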