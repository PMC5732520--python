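"""Specimen geometry: segmentation, the distal cut, and tetrahedral meshing.

The analysis geometry follows the experimental preparation: the proximal
femur is cut 12 cm distal to the tip of the greater trochanter on a plane
sloping 20 degrees to the shaft axis in the coronal plane, stood up in the
stance configuration (load axis = global -z), meshed with linear tetrahedra
at a 1.5 mm global edge length, and overlaid with 0.2 mm triangular
membrane shells standing in for the thin outer cortex.

Tetrahedralization is Delaunay-based: the surface is sampled at the target
edge length, the interior is filled with a body-centred-cubic lattice, and
scipy's Qhull Delaunay of the combined cloud is filtered to tetrahedra
whose centroids lie inside the surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import trimesh
from scipy.spatial import Delaunay, cKDTree

from ._geometry import SurfaceGrid, boundary_loops, ear_clip, tet_signed_volumes
from .ct_calibration import CTVolume


class MeshingError(RuntimeError):
    pass


@dataclass
class Surface:
    """Closed triangulated surface in world millimetres."""

    vertices: np.ndarray
    triangles: np.ndarray
    #: (point, normal) of the distal cut plane, if this surface has been cut
    cut_plane: tuple[np.ndarray, np.ndarray] | None = None
    #: 4x4 affine mapping CT-frame coordinates to this surface's frame
    ct_transform: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.triangles, process=False)

    @property
    def is_closed(self) -> bool:
        tm = self.to_trimesh()
        return bool(tm.is_watertight)

    @property
    def euler_characteristic(self) -> int:
        return int(self.to_trimesh().euler_number)

    @property
    def volume(self) -> float:
        return float(abs(self.to_trimesh().volume))

    def save(self, path: str | Path) -> None:
        self.to_trimesh().export(str(path))

    @classmethod
    def load(cls, path: str | Path) -> "Surface":
        tm = trimesh.load_mesh(str(path), process=False)
        return cls(np.asarray(tm.vertices), np.asarray(tm.faces))


@dataclass
class TetMesh:
    """Tetrahedral mesh with boundary triangles, shells and node sets.

    ``shell`` maps boundary-triangle index -> thickness (mm). Node and
    element indices are 0-based; exporters emit 1-based decks.
    """

    nodes: np.ndarray
    tets: np.ndarray
    boundary_tris: np.ndarray
    shell: dict[int, float] = field(default_factory=dict)
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)
    cut_plane: tuple[np.ndarray, np.ndarray] | None = None
    ct_transform: np.ndarray | None = None

    def nodes_in_ct_frame(self) -> np.ndarray:
        """Node coordinates mapped back to the CT volume's frame."""
        if self.ct_transform is None:
            return self.nodes
        inv = np.linalg.inv(self.ct_transform)
        return self.nodes @ inv[:3, :3].T + inv[:3, 3]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    def tet_volumes(self) -> np.ndarray:
        return tet_signed_volumes(self.nodes, self.tets)

    @property
    def volume(self) -> float:
        return float(self.tet_volumes().sum())

    def edge_lengths(self) -> np.ndarray:
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        e = np.concatenate([self.tets[:, [a, b]] for a, b in pairs])
        e = np.unique(np.sort(e, axis=1), axis=0)
        d = self.nodes[e[:, 0]] - self.nodes[e[:, 1]]
        return np.linalg.norm(d, axis=1)


# ---------------------------------------------------------------------------
# segmentation


def segment_bone(volume: CTVolume, threshold: float) -> Surface:
    """Iso-surface of the largest connected component above ``threshold``."""
    from scipy import ndimage
    from skimage import measure

    vmin, vmax = float(volume.values.min()), float(volume.values.max())
    mask = volume.values >= threshold
    if not mask.any():
        raise MeshingError(
            f"empty segmentation at threshold {threshold} (volume HU range [{vmin}, {vmax}])"
        )
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        mask = labels == keep
    # masked field padded with background so the iso-surface closes
    fld = np.where(mask, volume.values, vmin)
    fld = np.pad(fld, 1, constant_values=vmin)
    level = threshold if vmin < threshold < fld.max() else 0.5 * (vmin + fld.max())
    verts, faces, _, _ = measure.marching_cubes(fld, level=level)
    verts = (verts - 1.0) * np.asarray(volume.spacing) + np.asarray(volume.origin)
    return Surface(verts, faces)


# ---------------------------------------------------------------------------
# specimen cut and stance orientation


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length direction vector")
    return v / n


def cut_and_orient(
    surface: Surface,
    landmark_gt_tip,
    shaft_axis,
    cut_distance: float = 120.0,
    coronal_slope_deg: float = 20.0,
    anterior_axis=(0.0, 1.0, 0.0),
) -> Surface:
    """Apply the distal specimen cut and rotate into the stance frame.

    ``shaft_axis`` points distally (away from the head). The cut plane lies
    ``cut_distance`` mm from the greater-trochanter-tip landmark along the
    shaft axis, tilted ``coronal_slope_deg`` about the anterior axis. The
    output is translated so the landmark is at the origin and rotated so the
    load axis is global -z, leaving the shaft at ``coronal_slope_deg`` to
    vertical in the x-z (coronal) plane. The closed cut face is recorded in
    ``cut_plane``.
    """
    shaft = _unit(shaft_axis)
    ant = _unit(anterior_axis)
    ant = _unit(ant - shaft * (ant @ shaft))  # orthogonalize
    landmark = np.asarray(landmark_gt_tip, dtype=float)

    s = np.deg2rad(coronal_slope_deg)
    # cut normal: shaft axis tilted about the anterior axis (Rodrigues)
    n_cut = shaft * np.cos(s) + np.cross(ant, shaft) * np.sin(s)
    p0 = landmark + cut_distance * shaft

    d = (surface.vertices - p0) @ n_cut
    if d.min() > -1e-9 or d.max() < 1e-9:
        raise MeshingError(
            f"cut plane at {cut_distance} mm along the shaft axis does not intersect the surface"
        )
    # keep the proximal (landmark) side
    keep_normal = -n_cut if (landmark - p0) @ n_cut < 0 else n_cut
    tm = trimesh.intersections.slice_mesh_plane(
        surface.to_trimesh(), plane_normal=keep_normal, plane_origin=p0, cap=False
    )
    verts, faces = _cap_open_boundary(np.asarray(tm.vertices), np.asarray(tm.faces), p0, keep_normal)

    # rotation into the stance frame
    lateral = np.cross(shaft, ant)
    e = np.column_stack([shaft, ant, lateral])
    f1 = np.array([np.sin(s), 0.0, -np.cos(s)])  # distal shaft direction
    f2 = np.array([0.0, 1.0, 0.0])
    e_t = np.column_stack([f1, f2, np.cross(f1, f2)])
    rot = e_t @ e.T
    verts = (verts - landmark) @ rot.T
    p0r = rot @ (p0 - landmark)
    nr = rot @ n_cut
    xform = np.eye(4)
    xform[:3, :3] = rot
    xform[:3, 3] = -rot @ landmark
    if surface.ct_transform is not None:
        xform = xform @ surface.ct_transform
    return Surface(verts, faces, cut_plane=(p0r, _unit(nr)), ct_transform=xform)


def _cap_open_boundary(verts: np.ndarray, faces: np.ndarray, p0, normal) -> tuple[np.ndarray, np.ndarray]:
    """Close planar holes left by an uncapped plane slice via ear clipping."""
    # weld duplicate vertices the slicer introduced along the cut line
    keys = np.round(verts / 1e-7).astype(np.int64)
    _, first, inverse = np.unique(keys, axis=0, return_index=True, return_inverse=True)
    verts = verts[first]
    faces = inverse[faces]
    faces = faces[
        (faces[:, 0] != faces[:, 1]) & (faces[:, 1] != faces[:, 2]) & (faces[:, 0] != faces[:, 2])
    ]
    loops = boundary_loops(faces)
    if not loops:
        return verts, faces
    n = _unit(normal)
    u = _unit(np.cross(n, [1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.cross(n, [0.0, 1.0, 0.0]))
    v = np.cross(n, u)
    new_faces = [faces]
    for loop in loops:
        pts = verts[loop]
        p2 = np.column_stack([(pts - p0) @ u, (pts - p0) @ v])
        tris = ear_clip(p2)
        cap = loop[tris]
        # orient the cap outward: away from the kept half-space
        c = verts[cap[0]]
        nrm = np.cross(c[1] - c[0], c[2] - c[0])
        if nrm @ n > 0:
            cap = cap[:, ::-1]
        new_faces.append(cap)
    return verts, np.vstack(new_faces)


# ---------------------------------------------------------------------------
# tetrahedralization


def tetrahedralize(surface: Surface, target_edge: float = 1.5) -> TetMesh:
    """Delaunay tet mesh of a closed surface at a target global edge length.

    Surface samples at ~``target_edge`` spacing plus an interior BCC lattice
    are triangulated with Qhull; tetrahedra whose centroids fall outside the
    surface are discarded. Median edge length tracks ``target_edge`` and all
    returned tetrahedra are positively oriented.
    """
    if target_edge <= 0:
        raise ValueError("target_edge must be positive")
    tm = surface.to_trimesh()
    if len(tm.faces) < 4:
        raise MeshingError("surface has too few triangles to mesh")

    # densify for sampling / distance queries
    dv, df = trimesh.remesh.subdivide_to_size(
        tm.vertices, tm.faces, max_edge=0.6 * target_edge, max_iter=12
    )
    dense = np.asarray(dv)

    # surface samples at ~target_edge spacing. A coarse analytic surface is
    # subdivided (samples stay exactly on it, preserving edges and corners);
    # a dense scanned/iso-surface is grid-clustered and snapped back.
    edges = np.unique(np.sort(np.concatenate(
        [tm.faces[:, [0, 1]], tm.faces[:, [1, 2]], tm.faces[:, [2, 0]]]), axis=1), axis=0)
    med_edge = float(np.median(np.linalg.norm(
        tm.vertices[edges[:, 0]] - tm.vertices[edges[:, 1]], axis=1)))
    if med_edge >= 0.45 * target_edge:
        sv, _ = trimesh.remesh.subdivide_to_size(
            tm.vertices, tm.faces, max_edge=1.3 * target_edge, max_iter=12
        )
        boundary_pts = np.unique(np.asarray(sv), axis=0)
    else:
        cell = 0.7 * target_edge
        keys = np.floor(dense / cell).astype(np.int64)
        _, inv = np.unique(keys, axis=0, return_inverse=True)
        order = np.argsort(inv, kind="stable")
        bounds = np.searchsorted(inv[order], np.arange(inv.max() + 2))
        reps = []
        for a, b in zip(bounds[:-1], bounds[1:]):
            if b > a:
                grp = dense[order[a:b]]
                mean = grp.mean(axis=0)
                reps.append(grp[np.argmin(np.einsum("ij,ij->i", grp - mean, grp - mean))])
        boundary_pts = np.array(reps)

    # interior BCC lattice, kept clear of the boundary
    h = 1.05 * target_edge
    lo = tm.bounds[0] + 0.25 * h
    hi = tm.bounds[1]
    axes = [np.arange(lo[d], hi[d], h) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    lattice = np.vstack([pts, pts + 0.5 * h])

    grid = SurfaceGrid(surface.vertices, surface.triangles)
    inside = grid.contains(lattice)
    lattice = lattice[inside]
    if len(lattice):
        dist, _ = cKDTree(dense).query(lattice, workers=-1)
        lattice = lattice[dist > 0.5 * target_edge]

    points = np.vstack([boundary_pts, lattice]) if len(lattice) else boundary_pts
    if len(points) < 4:
        raise MeshingError("not enough sample points; surface may be smaller than target_edge")
    try:
        tri = Delaunay(points)
    except Exception as exc:  # pragma: no cover
        raise MeshingError(f"Delaunay triangulation failed: {exc}") from exc

    tets = tri.simplices
    centroids = points[tets].mean(axis=1)
    keep = grid.contains(centroids)
    vols = tet_signed_volumes(points, tets)
    keep &= np.abs(vols) > 1e-7 * target_edge**3
    tets = tets[keep]
    vols = vols[keep]
    flip = vols < 0
    tets[flip] = tets[flip][:, [0, 1, 3, 2]]

    # compact unused nodes
    used, tets = np.unique(tets, return_inverse=True)
    tets = tets.reshape(-1, 4)
    nodes = points[used]

    mesh = TetMesh(
        nodes=nodes,
        tets=tets.astype(np.int64),
        boundary_tris=_boundary_triangles(tets),
        cut_plane=surface.cut_plane,
        ct_transform=surface.ct_transform,
    )
    if mesh.n_tets == 0:
        raise MeshingError("all candidate tetrahedra were filtered out")
    return mesh


def _boundary_triangles(tets: np.ndarray) -> np.ndarray:
    # local faces oriented outward for a positively oriented tet
    faces = np.concatenate(
        [tets[:, [0, 2, 1]], tets[:, [0, 1, 3]], tets[:, [1, 2, 3]], tets[:, [0, 3, 2]]]
    )
    key = np.sort(faces, axis=1)
    _, idx, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
    return faces[idx[counts == 1]]


# ---------------------------------------------------------------------------
# shells and node sets


def overlay_shell(mesh: TetMesh, thickness: float = 0.2, cut_tol: float = 1e-6) -> TetMesh:
    """Attach membrane shells to every boundary triangle off the cut face.

    Triangles whose three nodes lie on the recorded cut plane (or entirely
    inside the ``fixed_distal`` node set, when tagged) carry no shell; they
    correspond to sawed bone or resin-embedded surface, not cortex.
    """
    if len(mesh.boundary_tris) == 0:
        raise MeshingError("mesh has no boundary triangles")
    shell: dict[int, float] = {}
    on_cut = np.zeros(len(mesh.boundary_tris), dtype=bool)
    if mesh.cut_plane is not None:
        p0, n = mesh.cut_plane
        d = np.abs((mesh.nodes - p0) @ n)
        tol = max(cut_tol, 1e-6 * float(np.ptp(d)))
        on_plane = d <= max(tol, 1e-3)
        on_cut = on_plane[mesh.boundary_tris].all(axis=1)
    if "fixed_distal" in mesh.node_sets:
        fixed = np.zeros(mesh.n_nodes, dtype=bool)
        fixed[mesh.node_sets["fixed_distal"]] = True
        on_cut |= fixed[mesh.boundary_tris].all(axis=1)
    for i in np.where(~on_cut)[0]:
        shell[int(i)] = float(thickness)
    return replace(mesh, shell=shell)


def tag_boundary_sets(
    mesh: TetMesh,
    distal_depth: float = 30.0,
    cap_angle_deg: float = 30.0,
    head_center=None,
    load_axis=(0.0, 0.0, -1.0),
) -> TetMesh:
    """Tag the resin-box and resin-cap node sets.

    ``fixed_distal`` collects all nodes within ``distal_depth`` mm of the cut
    plane (the 3 cm resin box); ``cap_contact`` collects boundary nodes whose
    direction from the femoral-head centre is within ``cap_angle_deg`` of the
    upward load axis (the molded resin cap). The head centre is taken from
    ``head_center`` or fitted by least squares to the proximal boundary nodes.
    """
    if cap_angle_deg <= 0:
        raise MeshingError("cap_contact: cap_angle_deg must be positive")
    up = -_unit(load_axis)
    if mesh.cut_plane is not None:
        p0, n = mesh.cut_plane
        # orient the normal toward the bulk of the mesh
        if (mesh.nodes.mean(axis=0) - p0) @ n < 0:
            n = -n
        dist = (mesh.nodes - p0) @ n
    else:
        # fall back: distal = extreme along -up
        t = mesh.nodes @ up
        dist = t - t.min()
    fixed = np.where(dist <= distal_depth + 1e-9)[0]
    if fixed.size == 0:
        raise MeshingError("fixed_distal: no nodes within distal_depth of the cut plane")

    bnodes = np.unique(mesh.boundary_tris)
    if head_center is None:
        t = mesh.nodes[bnodes] @ up
        top = mesh.nodes[bnodes[t >= np.quantile(t, 0.7)]]
        head_center = _fit_sphere_center(top)
    c = np.asarray(head_center, dtype=float)
    rel = mesh.nodes[bnodes] - c
    norm = np.linalg.norm(rel, axis=1)
    with np.errstate(invalid="ignore"):
        cosang = np.where(norm > 0, rel @ up / np.maximum(norm, 1e-300), -1.0)
    cap = bnodes[cosang >= np.cos(np.deg2rad(cap_angle_deg))]
    cap = np.setdiff1d(cap, fixed)
    if cap.size == 0:
        raise MeshingError("cap_contact: empty node set (cap angle too small?)")
    sets = dict(mesh.node_sets)
    sets["fixed_distal"] = fixed.astype(np.int64)
    sets["cap_contact"] = cap.astype(np.int64)
    return replace(mesh, node_sets=sets)


def _fit_sphere_center(pts: np.ndarray) -> np.ndarray:
    """Algebraic least-squares sphere fit; returns the centre."""
    a = np.column_stack([2 * pts, np.ones(len(pts))])
    b = np.einsum("ij,ij->i", pts, pts)
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    return sol[:3]


# ---------------------------------------------------------------------------
# export


def write_vtu(mesh: TetMesh, path: str | Path, cell_data: dict[str, np.ndarray] | None = None) -> None:
    """Minimal ASCII VTK unstructured-grid writer (tet cells only)."""
    n, t = mesh.n_nodes, mesh.n_tets
    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{n}" NumberOfCells="{t}">',
        "<Points>",
        '<DataArray type="Float64" NumberOfComponents="3" format="ascii">',
    ]
    lines += [" ".join(f"{x:.9g}" for x in p) for p in mesh.nodes]
    lines += ["</DataArray>", "</Points>", "<Cells>",
              '<DataArray type="Int64" Name="connectivity" format="ascii">']
    lines += [" ".join(map(str, tet)) for tet in mesh.tets]
    lines += ["</DataArray>", '<DataArray type="Int64" Name="offsets" format="ascii">',
              " ".join(str(4 * (i + 1)) for i in range(t)),
              "</DataArray>", '<DataArray type="UInt8" Name="types" format="ascii">',
              " ".join("10" for _ in range(t)), "</DataArray>", "</Cells>"]
    if cell_data:
        lines.append("<CellData>")
        for name, arr in cell_data.items():
            lines.append(f'<DataArray type="Float64" Name="{name}" format="ascii">')
            lines.append(" ".join(f"{v:.9g}" for v in np.asarray(arr, float)))
            lines.append("</DataArray>")
        lines.append("</CellData>")
    lines += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    Path(path).write_text("\n".join(lines))


def write_inp(mesh: TetMesh, path: str | Path, materials=None) -> None:
    """Abaqus-style deck: nodes, C3D4 tets, S3 shells with section thickness."""
    out = ["*NODE"]
    out += [f"{i + 1}, {p[0]:.9g}, {p[1]:.9g}, {p[2]:.9g}" for i, p in enumerate(mesh.nodes)]
    out.append("*ELEMENT, TYPE=C3D4, ELSET=BONE")
    out += [
        f"{i + 1}, {t[0] + 1}, {t[1] + 1}, {t[2] + 1}, {t[3] + 1}"
        for i, t in enumerate(mesh.tets)
    ]
    if mesh.shell:
        out.append("*ELEMENT, TYPE=S3, ELSET=CORTEX_SHELL")
        base = mesh.n_tets
        for j, tri_idx in enumerate(sorted(mesh.shell)):
            tri = mesh.boundary_tris[tri_idx]
            out.append(f"{base + j + 1}, {tri[0] + 1}, {tri[1] + 1}, {tri[2] + 1}")
        thick = mesh.shell[sorted(mesh.shell)[0]]
        out.append("*SHELL SECTION, ELSET=CORTEX_SHELL")
        out.append(f"{thick:.6g}")
    for name, nodes in mesh.node_sets.items():
        out.append(f"*NSET, NSET={name.upper()}")
        vals = [str(v + 1) for v in nodes]
        out += [", ".join(vals[k : k + 10]) for k in range(0, len(vals), 10)]
    if materials is not None:
        out.append("** per-element materials: see CSV export")
    Path(path).write_text("\n".join(out) + "\n")
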