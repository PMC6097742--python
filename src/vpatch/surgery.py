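"""Virtual-surgery geometric operators.

The simulated operation follows the clinical sequence on the meshed
vessel: trace the incision curve on the wall, convert it to a zero-gap
slit by node duplication, pull the slit open with a distributed edge
traction until the surgeon's target gap width is reached, synthesize a
tangent patch over the lens-shaped opening, and suture it to the artery
as a bonded (shared-node) connection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .geometry import ShellMesh, ARTERY, PATCH
from .materials import MaterialModel, get_material
from .shellfem import FemState, NonConvergenceError, ShellModel


class IncisionError(ValueError):
    pass


class SutureError(ValueError):
    pass


@dataclass
class IncisionSpec:
    """Surgical incision parameters (SI units internally)."""

    shape: str = "straight"          # straight | oblique | double
    cut_length: float = 0.050
    helix_angle_deg: float = 0.0     # 5 deg for the oblique cut
    target_gap_width: float = 0.016  # the intra-operative "slit stretch"
    azimuths: Tuple[float, ...] = (0.0,)

    def __post_init__(self) -> None:
        if self.shape not in ("straight", "oblique", "double"):
            raise IncisionError(f"unknown incision shape {self.shape!r}")
        if self.shape == "double":
            if len(self.azimuths) == 1:
                self.azimuths = (self.azimuths[0], self.azimuths[0] + np.pi)
            if len(self.azimuths) != 2 or not np.isclose(
                    abs((self.azimuths[1] - self.azimuths[0]) % (2 * np.pi)),
                    np.pi):
                raise IncisionError(
                    "double incision requires two azimuths separated by pi")
        elif len(self.azimuths) != 1:
            raise IncisionError(f"{self.shape} incision takes one azimuth")
        if self.shape == "oblique" and self.helix_angle_deg == 0.0:
            self.helix_angle_deg = 5.0
        if self.shape == "straight" and self.helix_angle_deg != 0.0:
            raise IncisionError("straight incision must have zero helix angle")
        if self.cut_length <= 0 or self.target_gap_width < 0:
            raise IncisionError("cut_length/gap must be positive")

    def validate_for(self, mesh: ShellMesh) -> None:
        z = mesh.nodes[:, 2]
        if self.cut_length > z.max() - z.min():
            raise IncisionError(
                f"cut_length {self.cut_length} exceeds vessel length")
        r = np.linalg.norm(mesh.nodes[:, :2], axis=1).max()
        if self.target_gap_width >= np.pi * r:
            raise IncisionError("target gap exceeds the half circumference")


# ---------------------------------------------------------------------------
# Incision tracing
# ---------------------------------------------------------------------------


def _mesh_graph(mesh: ShellMesh) -> nx.Graph:
    g = nx.Graph()
    edges, _ = mesh.edge_counts()
    p = mesh.nodes
    for i, j in edges:
        g.add_edge(int(i), int(j),
                   weight=float(np.linalg.norm(p[i] - p[j])))
    return g


def trace_incision(mesh: ShellMesh, inc: IncisionSpec,
                   center_z: Optional[float] = None) -> List[np.ndarray]:
    """Trace the ideal incision curve(s) and snap them to mesh nodes.

    The ideal curve runs axially (or helically at the given helix angle)
    over the wall, centered at ``center_z`` (default: the stenosis throat,
    taken as the mesh z mid-extent).  Snapped sample nodes are stitched
    into a connected simple chain by shortest paths along mesh edges; the
    chain is truncated once its geodesic length reaches the cut length.
    """
    inc.validate_for(mesh)
    p = mesh.nodes
    z = p[:, 2]
    if center_z is None:
        center_z = 0.5 * (z.min() + z.max())
    z0 = center_z - inc.cut_length / 2.0
    z1 = center_z + inc.cut_length / 2.0
    if z0 <= z.min() + 1e-12 or z1 >= z.max() - 1e-12:
        raise IncisionError("incision reaches the vessel end rings")

    tree = cKDTree(p)
    graph = _mesh_graph(mesh)
    tan_a = np.tan(np.radians(inc.helix_angle_deg))

    paths = []
    for theta0 in inc.azimuths:
        # sample the ideal curve densely; integrate the helical azimuth
        # advance with the local radius (the stenosis narrows the wall)
        n_s = 400
        zs = np.linspace(z0, z1, n_s)
        radii = np.interp(zs, np.sort(z), np.linalg.norm(
            p[np.argsort(z), :2], axis=1))
        thetas = theta0 + np.concatenate(
            [[0.0], np.cumsum(tan_a * np.diff(zs) / radii[:-1])])
        pts = np.column_stack([radii * np.cos(thetas),
                               radii * np.sin(thetas), zs])
        snapped = tree.query(pts)[1]
        chain = [int(snapped[0])]
        for nid in snapped[1:]:
            nid = int(nid)
            if nid == chain[-1]:
                continue
            if graph.has_edge(chain[-1], nid):
                chain.append(nid)
            else:
                sub = nx.shortest_path(graph, chain[-1], nid, weight="weight")
                chain.extend(int(v) for v in sub[1:])
        # truncate at the target geodesic length
        path, length = [chain[0]], 0.0
        for v in chain[1:]:
            seg = float(np.linalg.norm(p[v] - p[path[-1]]))
            if length + seg > inc.cut_length + seg / 2.0:
                break
            path.append(v)
            length += seg
        path = np.asarray(path, dtype=np.int64)
        if len(path) < 3 or len(np.unique(path)) != len(path):
            raise IncisionError("incision path is degenerate")
        rings = set(mesh.node_tags.get("inlet_ring", [])) \
            | set(mesh.node_tags.get("outlet_ring", []))
        if rings & set(path.tolist()):
            raise IncisionError("incision path touches a boundary ring")
        paths.append(path)

    if len(paths) == 2 and set(paths[0].tolist()) & set(paths[1].tolist()):
        raise IncisionError("double incision paths overlap")
    return paths


def path_length(mesh: ShellMesh, path: np.ndarray) -> float:
    p = mesh.nodes[path]
    return float(np.linalg.norm(np.diff(p, axis=0), axis=1).sum())


# ---------------------------------------------------------------------------
# Slit cutting
# ---------------------------------------------------------------------------


def cut_slit(mesh: ShellMesh, path: np.ndarray,
             label: str = "") -> ShellMesh:
    """Convert an incision node path into a zero-gap slit.

    Every interior path node is duplicated; triangles on the left side of
    the path reconnect to the duplicate.  The two resulting free edges are
    tagged ``cut_edge_left{label}`` / ``cut_edge_right{label}`` (ordered
    along the path, sharing the two tip nodes).  Geometry is unchanged —
    the slit has zero width until a solve releases the residual stress.
    """
    path = np.asarray(path, dtype=np.int64)
    if len(path) < 3:
        raise IncisionError("path must contain at least 3 nodes")
    if len(np.unique(path)) != len(path):
        raise IncisionError("path is self-intersecting")
    if not mesh.is_manifold():
        raise IncisionError("mesh is non-manifold")
    rings = set(mesh.node_tags.get("inlet_ring", [])) \
        | set(mesh.node_tags.get("outlet_ring", []))
    if rings & set(path.tolist()):
        raise IncisionError("path touches a boundary ring")

    out = mesh.copy()
    tris = out.tris
    node_to_tris: dict = {}
    for ti, tri in enumerate(tris):
        for v in tri:
            node_to_tris.setdefault(int(v), []).append(ti)

    n0 = out.n_nodes
    dup_pos: List[np.ndarray] = []

    def _pos(i: int) -> np.ndarray:
        return out.nodes[i] if i < n0 else dup_pos[i - n0]

    left_ids = [int(path[0])]
    next_id = out.n_nodes
    dup_of: dict = {}
    for k in range(1, len(path) - 1):
        v, prev, nxt = int(path[k]), int(path[k - 1]), int(path[k + 1])
        inc_tris = node_to_tris[v]
        # split the triangle fan at the two path edges (gates); the
        # previous node may already be duplicated, so both copies gate
        gates = {prev, nxt}
        if prev in dup_of:
            gates.add(dup_of[prev])
        adj = nx.Graph()
        adj.add_nodes_from(inc_tris)
        edge_owner: dict = {}
        for ti in inc_tris:
            others = [int(u) for u in tris[ti] if u != v]
            for u in others:
                if u in gates:
                    continue
                if u in edge_owner:
                    adj.add_edge(edge_owner[u], ti)
                else:
                    edge_owner[u] = ti
        comps = list(nx.connected_components(adj))
        if len(comps) != 2:
            raise IncisionError(
                f"cannot split triangle fan at path node {v}")
        # orient: left = side of cross(vertex normal, path direction)
        nrm = np.zeros(3)
        for ti in inc_tris:
            a, b, c = (int(u) for u in tris[ti])
            nrm += np.cross(_pos(b) - _pos(a), _pos(c) - _pos(a))
        nrm /= np.linalg.norm(nrm)
        tdir = _pos(nxt) - _pos(prev)
        tdir /= np.linalg.norm(tdir)
        side_vec = np.cross(nrm, tdir)

        def _side(comp):
            s = 0.0
            for ti in comp:
                cen = np.mean([_pos(int(u)) for u in tris[ti]], axis=0)
                s += float(np.dot(cen - _pos(v), side_vec))
            return s

        left_comp = comps[0] if _side(comps[0]) > _side(comps[1]) else comps[1]
        dup = next_id
        dup_of[v] = dup
        next_id += 1
        dup_pos.append(out.nodes[v].copy())
        for ti in left_comp:
            tris[ti][tris[ti] == v] = dup
        left_ids.append(dup)
    left_ids.append(int(path[-1]))

    out.nodes = np.vstack([out.nodes] + [q[None, :] for q in dup_pos]) \
        if dup_pos else out.nodes
    out.tris = tris
    out.node_tags[f"cut_edge_left{label}"] = np.asarray(left_ids, np.int64)
    out.node_tags[f"cut_edge_right{label}"] = path.copy()
    # provenance: each node's source in the pre-cut mesh (duplicates map
    # to their originals) so solver state can be carried across the cut
    parent = np.arange(n0 + len(dup_pos), dtype=np.int64)
    parent[n0:] = path[1:-1]
    if hasattr(mesh, "parent_nodes"):
        parent = mesh.parent_nodes[parent]
    out.parent_nodes = parent
    if hasattr(out, "grid_shape"):
        del out.grid_shape
    return out


def cut_edge_pairs(mesh: ShellMesh, label: str = ""):
    left = mesh.node_tags[f"cut_edge_left{label}"]
    right = mesh.node_tags[f"cut_edge_right{label}"]
    return left, right


def gap_widths(mesh: ShellMesh, x: np.ndarray, label: str = "") -> np.ndarray:
    """Distances between corresponding left/right slit-edge nodes."""
    left, right = cut_edge_pairs(mesh, label)
    return np.linalg.norm(x[left] - x[right], axis=1)


def max_gap(mesh: ShellMesh, x: np.ndarray, labels: Sequence[str] = ("",)):
    return float(np.mean([gap_widths(mesh, x, lab).max() for lab in labels]))


# ---------------------------------------------------------------------------
# Traction-controlled opening
# ---------------------------------------------------------------------------


@dataclass
class OpeningResult:
    state: FemState
    traction: float            # converged edge traction, N/m
    gap: float                 # achieved maximum opening width, m
    control_history: List[Tuple[float, float]] = field(default_factory=list)


def open_gap(model: ShellModel, mesh: ShellMesh, target_gap: float,
             labels: Sequence[str] = ("",),
             rel_tol: float = 0.01,
             n_increments: int = 6,
             extra_force: Optional[np.ndarray] = None,
             fading_force: Optional[np.ndarray] = None) -> OpeningResult:
    """Pull the slit open with edge traction until the gap hits the target.

    The traction is a uniform distributed load (N per meter of edge)
    normal to the cut faces, its direction recomputed on the deformed
    geometry every load increment — the numerical counterpart of the
    surgeon's pull.  The magnitude is controlled against the opening
    width by gap-driven continuation (the gap is ramped, the traction is
    the resulting load unknown), which remains stable through the
    force-controlled snap of the soft cut lips.  Returns the converged
    state and the traction magnitude holding the target gap.
    """
    chains = []
    for lab in labels:
        l, r = cut_edge_pairs(mesh, lab)
        chains += [l, r]
    model.set_traction_edges(chains)

    g0 = max_gap(mesh, model.x, labels)
    history = [(model.traction, g0)]
    if target_gap <= g0 * (1 + rel_tol) or target_gap == 0.0:
        state = model.solve(n_increments=1, extra_force_start=extra_force,
                            extra_force_end=extra_force)
        return OpeningResult(state, model.traction, g0, history)

    # drive every interior pair to a standardized parabolic lens profile:
    # widest (= target) at mid-slit, zero at the tips — the precisely
    # controlled intra-operative gap
    pairs, targets = [], []
    for lab in labels:
        l, r = cut_edge_pairs(mesh, lab)
        gw = np.linalg.norm(model.x[l] - model.x[r], axis=1)
        if gw[1:-1].min() < 1e-6:
            raise NonConvergenceError(
                "released slit shows no measurable opening to control from",
                {"history": history})
        seg = np.linalg.norm(np.diff(model.x[l], axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        xi = s / s[-1]
        lens = target_gap * (1.0 - (2.0 * xi - 1.0) ** 2)
        for a, b, g in zip(l[1:-1], r[1:-1], lens[1:-1]):
            pairs.append((int(a), int(b)))
            targets.append(float(g))

    solver_hist: list = []
    try:
        state = model.solve_opening_controlled(
            pairs, targets, extra_force=extra_force,
            fading_force=fading_force,
            n_increments=n_increments, history=solver_hist)
    except NonConvergenceError:
        # pair forces only constrain lip separations; if a strip between
        # slits still flaps, finish the ramp with prescribed lip motion
        state = model.solve_opening_prescribed(
            pairs, targets, extra_force=extra_force,
            fading_force=fading_force,
            n_increments=n_increments, history=solver_hist)
    g = max_gap(mesh, model.x, labels)
    history += [(h.get("tau", np.nan), np.nan)
                for h in solver_hist if h["iter"] == 0]
    history.append((model.traction, g))
    if abs(g - target_gap) > rel_tol * target_gap:
        raise NonConvergenceError(
            f"opening converged to {g:g} m, outside {rel_tol:.0%} of "
            f"{target_gap:g} m", {"history": history})
    return OpeningResult(state, model.traction, g, history)


# ---------------------------------------------------------------------------
# Tangent patch
# ---------------------------------------------------------------------------


@dataclass
class PatchSurface:
    """Triangulated patch over one slit opening, built in the opened
    (deformed) configuration with tangent-plane continuity to the artery."""

    vertices: np.ndarray            # (P, 3) as-built positions
    faces: np.ndarray               # (F, 3) into vertices
    boundary_loop: np.ndarray       # ordered patch-vertex indices
    artery_nodes: np.ndarray        # artery node id per boundary vertex
    material_name: str = "PTFE"
    max_normal_kink_deg: float = 0.0

    @property
    def mid_surface_area(self) -> float:
        a = self.vertices[self.faces[:, 0]]
        b = self.vertices[self.faces[:, 1]]
        c = self.vertices[self.faces[:, 2]]
        return float(0.5 * np.linalg.norm(
            np.cross(b - a, c - a), axis=1).sum())

    def export_surface(self, path: str) -> None:
        import trimesh
        trimesh.Trimesh(self.vertices, self.faces, process=False).export(path)


def _edge_frames(mesh: ShellMesh, x: np.ndarray, chain: np.ndarray):
    """Per-node inward transverse tangents along a free-edge chain.

    For each chain node: the unit vector tangent to the deformed artery
    surface, perpendicular to the edge direction, pointing away from the
    artery material (into the gap).
    """
    tris = mesh.tris
    node_tris: dict = {}
    for ti, tri in enumerate(tris):
        for v in tri:
            node_tris.setdefault(int(v), []).append(ti)
    m_hat = np.zeros((len(chain), 3))
    for k, v in enumerate(chain):
        v = int(v)
        nbr = node_tris[v]
        nrm = np.zeros(3)
        cen = np.zeros(3)
        for ti in nbr:
            a, b, c = tris[ti]
            nrm += np.cross(x[b] - x[a], x[c] - x[a])
            cen += x[tris[ti]].mean(axis=0)
        nrm /= np.linalg.norm(nrm)
        cen /= len(nbr)
        lo, hi = max(0, k - 1), min(len(chain) - 1, k + 1)
        tdir = x[chain[hi]] - x[chain[lo]]
        tdir /= np.linalg.norm(tdir)
        m = np.cross(nrm, tdir)
        if np.dot(m, x[v] - cen) < 0:
            m = -m
        m_hat[k] = m / np.linalg.norm(m)
    return m_hat


def generate_tangent_patch(mesh: ShellMesh, x: np.ndarray,
                           material_name: str = "PTFE",
                           label: str = "",
                           transverse_points: Optional[int] = None
                           ) -> PatchSurface:
    """Fill the opened slit with a tangent-continuous cambered patch.

    Each transverse section is a cubic Hermite curve from the left to the
    right slit edge whose end tangents continue the deformed artery
    surface (tangent magnitude equal to the chord), producing the
    characteristic outward camber of a "tangent patch".  The boundary
    vertices coincide with the artery slit-edge nodes, so suturing is an
    exact node merge.
    """
    left, right = cut_edge_pairs(mesh, label)
    if left[0] != right[0] or left[-1] != right[-1]:
        raise SutureError("slit edge chains do not share tip nodes")
    k = len(left)
    mL = _edge_frames(mesh, x, left)
    mR = _edge_frames(mesh, x, right)

    chords = np.linalg.norm(x[right] - x[left], axis=1)
    if transverse_points is None:
        # sample the cambered Hermite sections finer than the artery mesh
        # so the patch curvature (and its area) is resolved
        h = np.mean(np.linalg.norm(np.diff(x[left], axis=0), axis=1))
        transverse_points = max(5, int(round(1.5 * chords.max() / h)))
    m = transverse_points
    ts = np.linspace(0.0, 1.0, m + 2)[1:-1]

    verts = [x[left[0]]]
    rows: List[np.ndarray] = []        # vertex ids per interior station
    bnd_left, bnd_right = [0], [0]
    vid = 1
    for i in range(1, k - 1):
        P0, P1 = x[left[i]], x[right[i]]
        c = chords[i]
        T0 = mL[i] * c
        T1 = -mR[i] * c
        h00 = 2 * ts ** 3 - 3 * ts ** 2 + 1
        h10 = ts ** 3 - 2 * ts ** 2 + ts
        h01 = -2 * ts ** 3 + 3 * ts ** 2
        h11 = ts ** 3 - ts ** 2
        pts = (h00[:, None] * P0 + h10[:, None] * T0
               + h01[:, None] * P1 + h11[:, None] * T1)
        ids = [vid]                    # left edge vertex
        verts.append(P0)
        vid += 1
        for q in pts:
            verts.append(q)
            ids.append(vid)
            vid += 1
        verts.append(P1)
        ids.append(vid)
        bnd_left.append(ids[0])
        bnd_right.append(ids[-1])
        vid += 1
        rows.append(np.asarray(ids))
    verts.append(x[left[-1]])
    tip1 = vid
    bnd_left.append(tip1)
    bnd_right.append(tip1)
    verts = np.asarray(verts)

    faces = []
    first = rows[0]
    for a, b in zip(first[:-1], first[1:]):
        faces.append((0, a, b))
    for r0, r1 in zip(rows[:-1], rows[1:]):
        for j in range(len(r0) - 1):
            faces.append((r0[j], r1[j], r1[j + 1]))
            faces.append((r0[j], r1[j + 1], r0[j + 1]))
    last = rows[-1]
    for a, b in zip(last[:-1], last[1:]):
        faces.append((tip1, b, a))
    faces = np.asarray(faces, dtype=np.int64)

    # orient outward: match the mean artery normal around the opening
    fa, fb, fc = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    pn = np.cross(fb - fa, fc - fa)
    mean_pn = pn.sum(axis=0)
    axis_dir = verts.mean(axis=0).copy()
    axis_dir[2] = 0.0
    if np.dot(mean_pn, axis_dir) < 0:
        faces = faces[:, ::-1]

    # boundary loop: left chain forward, right chain backward (closed)
    loop = np.asarray(bnd_left + bnd_right[-2:0:-1], dtype=np.int64)
    artery_nodes = np.concatenate([left, right[-2:0:-1]]).astype(np.int64)

    patch = PatchSurface(verts, faces, loop, artery_nodes,
                         material_name=material_name)
    patch.max_normal_kink_deg = _normal_kink(mesh, x, patch, left, right)
    return patch


def _normal_kink(mesh: ShellMesh, x: np.ndarray, patch: PatchSurface,
                 left: np.ndarray, right: np.ndarray) -> float:
    """Largest angle between patch and artery surface normals along the
    suture boundary — the tangent-continuity diagnostic."""
    def vertex_normals(vs, fs):
        n = np.zeros((len(vs), 3))
        fn = np.cross(vs[fs[:, 1]] - vs[fs[:, 0]], vs[fs[:, 2]] - vs[fs[:, 0]])
        for kk in range(3):
            np.add.at(n, fs[:, kk], fn)
        ln = np.linalg.norm(n, axis=1, keepdims=True)
        return n / np.where(ln == 0, 1, ln)
    an = vertex_normals(x, mesh.tris)
    pn = vertex_normals(patch.vertices, patch.faces)
    worst = 0.0
    for pv, av in zip(patch.boundary_loop, patch.artery_nodes):
        # skip tips, where the surface normal is ill-defined
        if av in (left[0], left[-1]):
            continue
        cosang = float(np.clip(np.dot(pn[pv], an[av]), -1.0, 1.0))
        worst = max(worst, np.degrees(np.arccos(abs(cosang))))
    return worst


# ---------------------------------------------------------------------------
# Suturing
# ---------------------------------------------------------------------------


def suture(mesh: ShellMesh, x: np.ndarray, patch: PatchSurface,
           label: str = "") -> Tuple[ShellMesh, np.ndarray]:
    """Bond the patch to the artery by merging boundary nodes.

    Returns the combined mesh (node coordinates = the as-sutured, opened
    configuration) and the patch-vertex -> combined-node index map.  The
    merged nodes are tagged ``suture_line``; the patch elements carry the
    patch material thickness and region label.
    """
    left, right = cut_edge_pairs(mesh, label)
    if len(patch.boundary_loop) != len(patch.artery_nodes):
        raise SutureError("patch boundary/artery correspondence mismatch")
    # patch boundary vertices must coincide with their artery nodes
    err = np.linalg.norm(patch.vertices[patch.boundary_loop]
                         - x[patch.artery_nodes], axis=1).max()
    if err > 1e-9:
        raise SutureError(
            f"patch boundary does not coincide with the slit edge ({err:g} m)")

    mat = get_material(patch.material_name)
    n_art = mesh.n_nodes
    is_bnd = np.zeros(len(patch.vertices), dtype=bool)
    is_bnd[patch.boundary_loop] = True
    vmap = np.full(len(patch.vertices), -1, dtype=np.int64)
    vmap[patch.boundary_loop] = patch.artery_nodes
    interior = np.where(~is_bnd)[0]
    vmap[interior] = n_art + np.arange(len(interior))

    nodes = np.vstack([x, patch.vertices[interior]])
    tris = np.vstack([mesh.tris, vmap[patch.faces]])
    region = np.concatenate([mesh.element_region,
                             np.full(len(patch.faces), PATCH, np.int64)])
    thick = np.concatenate([mesh.element_thickness,
                            np.full(len(patch.faces), mat.thickness)])
    tags = {k: v.copy() for k, v in mesh.node_tags.items()
            if not k.startswith("cut_edge")}
    suture_nodes = np.unique(np.concatenate([left, right]))
    if "suture_line" in tags:
        suture_nodes = np.unique(np.concatenate(
            [tags["suture_line"], suture_nodes]))
    tags["suture_line"] = suture_nodes
    # keep remaining cut edges (double-cut case) for the next suture
    for kk, vv in mesh.node_tags.items():
        if kk.startswith("cut_edge") and not kk.endswith(label):
            tags[kk] = vv.copy()
    combined = ShellMesh(nodes, tris, region, thick, tags)
    if not combined.is_manifold():
        raise SutureError("sutured mesh is non-manifold")
    return combined, vmap
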