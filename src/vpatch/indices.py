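"""Biomechanical performance indices of the reconstructed vessel.

Implements the post-operative evaluation metrics: centerline extraction
with cross-sectional lumen areas, local percent stenosis (relative to the
maximum post-operative section area), residual stenosis at the throat,
centerline offset (tortuosity), regional von Mises stress summaries and
the suture-line stress jump caused by material mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.interpolate import splev, splprep

from .geometry import ShellMesh, ARTERY, PATCH, REGION_NAMES
from .shellfem import FemState


class CenterlineError(RuntimeError):
    pass


def _section_polygon(tm, origin: np.ndarray, normal: np.ndarray):
    """Slice a trimesh with a plane; return (centroid_3d, area, n_vertices).

    Returns None when the plane misses the mesh or yields no closed
    contour.  Raises CenterlineError if the section splits into several
    comparable closed contours (pinched lumen).  The polygon area and
    centroid are computed directly in the slicing plane (shoelace), so
    only the raw intersection polylines are needed.
    """
    sec = tm.section(plane_origin=origin, plane_normal=normal)
    if sec is None:
        return None
    loops = [np.asarray(d) for d in sec.discrete]
    closed = [lp for lp in loops
              if len(lp) > 3 and np.linalg.norm(lp[0] - lp[-1]) < 1e-9]
    if not closed:
        return None
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    u = np.cross(n, [1.0, 0.0, 0.0])
    if np.linalg.norm(u) < 1e-6:
        u = np.cross(n, [0.0, 1.0, 0.0])
    u /= np.linalg.norm(u)
    v = np.cross(n, u)

    results = []
    for lp in closed:
        rel = lp[:-1] - origin
        x2 = rel @ u
        y2 = rel @ v
        x3, y3 = np.roll(x2, -1), np.roll(y2, -1)
        cross = x2 * y3 - x3 * y2
        area = 0.5 * cross.sum()
        if abs(area) < 1e-16:
            continue
        cx = ((x2 + x3) * cross).sum() / (6.0 * area)
        cy = ((y2 + y3) * cross).sum() / (6.0 * area)
        c3 = origin + cx * u + cy * v
        results.append((abs(area), c3, len(x2)))
    if not results:
        return None
    results.sort(key=lambda t: -t[0])
    if len(results) > 1 and results[1][0] > 0.25 * results[0][0]:
        raise CenterlineError(
            f"lumen splits into {len(results)} comparable contours near "
            f"z={origin[2]:.4f}")
    area, c3, nv = results[0]
    return c3, float(area), int(nv)


@dataclass
class CenterlineProfile:
    """Arclength-sampled lumen profile of a (possibly deformed) vessel.

    ``reference_area`` is the healthy reference lumen section under the
    same loading; local percent stenosis is measured against it, so a
    locally dilated (bulging) section shows up as a negative percentage.
    When no reference is supplied the profile's own maximum section is
    used instead.
    """

    arclength: np.ndarray          # (S,) strictly increasing, m
    centroids: np.ndarray          # (S, 3)
    areas: np.ndarray              # (S,) lumen area, m^2
    reference_axis: Optional[np.ndarray] = None   # (S, 3) pre-op centerline
    reference_area: Optional[float] = None        # m^2

    @property
    def local_stenosis_pct(self) -> np.ndarray:
        ref = (self.areas.max() if self.reference_area is None
               else self.reference_area)
        return 100.0 * (1.0 - self.areas / ref)

    @property
    def throat_index(self) -> int:
        return int(np.argmax(self.local_stenosis_pct))

    def to_table(self):
        import pandas as pd
        df = pd.DataFrame({
            "s_mm": self.arclength * 1e3,
            "area_mm2": self.areas * 1e6,
            "stenosis_pct": self.local_stenosis_pct,
        })
        if self.reference_axis is not None:
            df["offset_mm"] = np.linalg.norm(
                self.centroids - self.reference_axis, axis=1) * 1e3
        return df


def extract_centerline(mesh: ShellMesh, nodes: Optional[np.ndarray] = None,
                       n_samples: int = 40, wall_thickness: float = 0.001,
                       max_iter: int = 5,
                       reference_axis: Optional[np.ndarray] = None
                       ) -> CenterlineProfile:
    """Centerline and lumen-area profile by iterative plane slicing.

    Slices the wall mid-surface with planes normal to the current axis
    estimate, takes the contour centroids, refits a smoothing spline and
    repeats until the centroids move by less than 1% of the vessel radius.
    The mid-surface section area is converted to a lumen area by shrinking
    the equivalent radius by half the wall thickness.
    """
    x = mesh.nodes if nodes is None else nodes
    tm = mesh.to_trimesh(x)
    z0, z1 = x[:, 2].min(), x[:, 2].max()
    margin = 0.03 * (z1 - z0)
    zs = np.linspace(z0 + margin, z1 - margin, n_samples)
    radius = np.sqrt(tm.area / (2 * np.pi * (z1 - z0)))
    z_axis = np.array([0.0, 0.0, 1.0])

    def _slice(origin, normal):
        """Section at a station; falls back to the z-normal near the ends
        where a tilted plane can exit the tube."""
        res = _section_polygon(tm, origin, normal)
        if res is None and abs(normal[2]) < 1.0 - 1e-9:
            res = _section_polygon(tm, origin, z_axis)
        return res

    # initial axis: straight line through the z-extent of the mesh
    centroids = np.column_stack([np.zeros_like(zs), np.zeros_like(zs), zs])
    normals = np.tile(z_axis, (n_samples, 1))
    areas = np.full(n_samples, np.nan)
    for _ in range(max_iter):
        new_c = centroids.copy()
        valid = np.ones(n_samples, dtype=bool)
        for i in range(n_samples):
            res = _slice(centroids[i], normals[i])
            if res is None:
                valid[i] = False
                continue
            new_c[i], areas[i], _ = res
        if valid.sum() < max(4, n_samples // 2):
            raise CenterlineError(
                f"only {int(valid.sum())} of {n_samples} sections hit the mesh")
        move = np.linalg.norm(new_c[valid] - centroids[valid], axis=1).max()
        # refit a smoothing spline through the valid centroids and update
        # both the stations and the slicing normals
        tck, _ = splprep(new_c[valid].T,
                         s=int(valid.sum()) * (0.05 * radius) ** 2)
        u = np.linspace(0.0, 1.0, n_samples)
        centroids = np.column_stack(splev(u, tck))
        tangents = np.column_stack(splev(u, tck, der=1))
        normals = tangents / np.linalg.norm(tangents, axis=1, keepdims=True)
        if move < 0.01 * radius:
            break

    # final measurement pass at the converged stations
    keep, cents, final_areas = [], [], []
    for i in range(n_samples):
        res = _slice(centroids[i], normals[i])
        if res is None:
            continue
        c, a, _ = res
        keep.append(i)
        cents.append(c)
        final_areas.append(a)
    if len(keep) < 4:
        raise CenterlineError("too few valid sections for a profile")
    centroids = np.asarray(cents)
    areas = np.asarray(final_areas)

    r_lumen = np.sqrt(areas / np.pi) - wall_thickness / 2.0
    lumen_areas = np.pi * r_lumen ** 2
    seg = np.linalg.norm(np.diff(centroids, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if np.any(np.diff(s) <= 0):
        raise CenterlineError("degenerate (non-increasing) arclength")
    if reference_axis is not None and len(reference_axis) != len(s):
        reference_axis = None
    return CenterlineProfile(s, centroids, lumen_areas,
                             reference_axis=reference_axis)


def residual_stenosis(profile: CenterlineProfile) -> float:
    """Percent stenosis at the throat: the maximum of the local-stenosis
    profile (normalized by the healthy reference section when available,
    else by the profile's own maximum area)."""
    return float(profile.local_stenosis_pct[profile.throat_index])


def centerline_offset(profile: CenterlineProfile,
                      reference_axis: Optional[np.ndarray] = None) -> float:
    """Distance between the post-op centerline and the initial vessel
    pathway at the throat (the tortuosity index), in meters."""
    ref = reference_axis if reference_axis is not None else profile.reference_axis
    if ref is None:
        raise ValueError("no reference axis supplied")
    i = profile.throat_index
    return float(np.linalg.norm(profile.centroids[i] - ref[i]))


# ---------------------------------------------------------------------------
# Stress summaries
# ---------------------------------------------------------------------------


def stress_summary(state: FemState, mesh: ShellMesh,
                   region: str) -> Tuple[float, float]:
    """(max, area-weighted mean) von Mises stress over a region's elements."""
    codes = {v: k for k, v in REGION_NAMES.items()}
    if region not in codes:
        raise ValueError(f"region must be one of {sorted(codes)}")
    sel = mesh.element_region == codes[region]
    if not np.any(sel):
        raise ValueError(f"mesh has no {region} elements")
    vm = state.element_von_mises[sel]
    areas = mesh.tri_areas(state.node_positions)[sel]
    return float(vm.max()), float(np.average(vm, weights=areas))


def suture_stress_jump(state: FemState, mesh: ShellMesh) -> float:
    """Largest patch-vs-artery von Mises mismatch along the suture line.

    For every suture node: |max adjacent patch-element stress - max
    adjacent artery-element stress|; returns the maximum over nodes.
    """
    if "suture_line" not in mesh.node_tags:
        raise ValueError("mesh has no suture_line tag")
    vm = state.element_von_mises
    node_tris: dict = {}
    for ti, tri in enumerate(mesh.tris):
        for v in tri:
            node_tris.setdefault(int(v), []).append(ti)
    jump = 0.0
    for v in mesh.node_tags["suture_line"]:
        tris_v = node_tris.get(int(v), [])
        pa = [vm[t] for t in tris_v if mesh.element_region[t] == PATCH]
        ar = [vm[t] for t in tris_v if mesh.element_region[t] == ARTERY]
        if pa and ar:
            jump = max(jump, abs(max(pa) - max(ar)))
    return float(jump)


def gap_region_mean_stress(state: FemState, mesh: ShellMesh,
                           label: str = "", n_rings: int = 2) -> float:
    """Mean von Mises over elements within ``n_rings`` node-neighborhoods
    of the slit edges — the intra-operative stress around the gap."""
    seeds = set()
    for tag in (f"cut_edge_left{label}", f"cut_edge_right{label}"):
        seeds |= set(int(v) for v in mesh.node_tags[tag])
    nodes = set(seeds)
    for _ in range(n_rings - 1):
        grown = set(nodes)
        for tri in mesh.tris:
            if any(int(v) in nodes for v in tri):
                grown |= {int(v) for v in tri}
        nodes = grown
    sel = np.array([any(int(v) in nodes for v in tri) for tri in mesh.tris])
    vm = state.element_von_mises[sel]
    areas = mesh.tri_areas(state.node_positions)[sel]
    return float(np.average(vm, weights=areas))


def plot_stenosis_profiles(profiles: dict, path: str,
                           preop: Optional[CenterlineProfile] = None) -> None:
    """Plot local-percent-stenosis curves along the centerline for a set
    of named cases (optionally with the pre-operative curve on top) and
    save the figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    if preop is not None:
        ax.plot(preop.arclength * 1e3, preop.local_stenosis_pct,
                "k--", lw=2, label="pre-op")
    for name, prof in profiles.items():
        ax.plot(prof.arclength * 1e3, prof.local_stenosis_pct, label=name)
    ax.axhline(0.0, color="0.7", lw=0.5)
    ax.set_xlabel("centerline arclength (mm)")
    ax.set_ylabel("local stenosis (%)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
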