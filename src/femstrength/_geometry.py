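"""Low-level geometric kernels shared by meshing and material mapping.

Point-in-mesh queries use parity ray casting along +z with a uniform 2-D
bucket grid over the triangle footprint; queries are jittered by an
irrational sub-micron offset so lattice points never hit triangle edges
exactly. The kernel is jitted with numba when available.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap

# jitter breaks exact edge/vertex alignment between rays and triangles
_JITTER = np.array([1.0e-6, 2.0e-6 * np.sqrt(2.0) / 2, 0.0])


@njit(cache=True)
def _raycast_kernel(points, tris, cell_start, cell_tris, nx, ny, x0, y0, dx, dy):
    n = points.shape[0]
    out = np.zeros(n, dtype=np.bool_)
    for p in range(n):
        px, py, pz = points[p, 0], points[p, 1], points[p, 2]
        ix = int((px - x0) / dx)
        iy = int((py - y0) / dy)
        if ix < 0 or ix >= nx or iy < 0 or iy >= ny:
            continue
        c = iy * nx + ix
        crossings = 0
        for j in range(cell_start[c], cell_start[c + 1]):
            t = cell_tris[j]
            ax, ay, az = tris[t, 0, 0], tris[t, 0, 1], tris[t, 0, 2]
            bx, by, bz = tris[t, 1, 0], tris[t, 1, 1], tris[t, 1, 2]
            cx, cy, cz = tris[t, 2, 0], tris[t, 2, 1], tris[t, 2, 2]
            # 2-D orientation tests against the projected triangle
            d1 = (bx - ax) * (py - ay) - (by - ay) * (px - ax)
            d2 = (cx - bx) * (py - by) - (cy - by) * (px - bx)
            d3 = (ax - cx) * (py - cy) - (ay - cy) * (px - cx)
            if (d1 > 0 and d2 > 0 and d3 > 0) or (d1 < 0 and d2 < 0 and d3 < 0):
                area2 = (bx - ax) * (cy - ay) - (by - ay) * (cx - ax)
                if area2 == 0.0:
                    continue
                # barycentric z at (px, py)
                w1 = d2 / area2
                w2 = d3 / area2
                w3 = d1 / area2
                z = w1 * az + w2 * bz + w3 * cz
                if z > pz:
                    crossings += 1
        out[p] = (crossings % 2) == 1
    return out


class SurfaceGrid:
    """Bucketed triangle soup supporting repeated containment queries."""

    def __init__(self, vertices: np.ndarray, faces: np.ndarray):
        vertices = np.asarray(vertices, dtype=np.float64)
        faces = np.asarray(faces, dtype=np.int64)
        self.tris = vertices[faces]  # (T, 3, 3)
        lo = self.tris[:, :, :2].min(axis=1)
        hi = self.tris[:, :, :2].max(axis=1)
        gx0, gy0 = lo.min(axis=0) - 1e-9
        gx1, gy1 = hi.max(axis=0) + 1e-9
        # target a handful of triangles per bucket
        ntris = len(faces)
        target = max(8, int(np.sqrt(ntris)))
        self.nx = min(target, 512)
        self.ny = min(target, 512)
        self.x0, self.y0 = gx0, gy0
        self.dx = (gx1 - gx0) / self.nx
        self.dy = (gy1 - gy0) / self.ny
        i0 = np.clip(((lo[:, 0] - gx0) / self.dx).astype(np.int64), 0, self.nx - 1)
        i1 = np.clip(((hi[:, 0] - gx0) / self.dx).astype(np.int64), 0, self.nx - 1)
        j0 = np.clip(((lo[:, 1] - gy0) / self.dy).astype(np.int64), 0, self.ny - 1)
        j1 = np.clip(((hi[:, 1] - gy0) / self.dy).astype(np.int64), 0, self.ny - 1)
        cells: list[list[int]] = [[] for _ in range(self.nx * self.ny)]
        for t in range(ntris):
            for jy in range(j0[t], j1[t] + 1):
                base = jy * self.nx
                for jx in range(i0[t], i1[t] + 1):
                    cells[base + jx].append(t)
        counts = np.array([len(c) for c in cells], dtype=np.int64)
        self.cell_start = np.concatenate([[0], np.cumsum(counts)])
        self.cell_tris = (
            np.concatenate([np.array(c, dtype=np.int64) for c in cells if c])
            if counts.sum()
            else np.zeros(0, dtype=np.int64)
        )

    def contains(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=np.float64)
        if points.ndim == 1:
            points = points[None, :]
        return _raycast_kernel(
            points + _JITTER,
            np.ascontiguousarray(self.tris),
            self.cell_start,
            self.cell_tris,
            self.nx,
            self.ny,
            self.x0,
            self.y0,
            self.dx,
            self.dy,
        )


def tet_signed_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volume of each 4-node tetrahedron (positive = right-handed)."""
    p = nodes[tets]
    a = p[:, 1] - p[:, 0]
    b = p[:, 2] - p[:, 0]
    c = p[:, 3] - p[:, 0]
    return np.einsum("ij,ij->i", np.cross(a, b), c) / 6.0


def boundary_loops(faces: np.ndarray) -> list[np.ndarray]:
    """Ordered vertex loops of edges used by exactly one triangle."""
    faces = np.asarray(faces)
    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    key = np.sort(edges, axis=1)
    _, idx, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
    open_edges = edges[idx[counts == 1]]
    nxt = {int(a): int(b) for a, b in open_edges}
    loops = []
    seen: set[int] = set()
    for start in list(nxt):
        if start in seen:
            continue
        loop = [start]
        seen.add(start)
        cur = nxt[start]
        while cur != start and cur not in seen:
            loop.append(cur)
            seen.add(cur)
            if cur not in nxt:
                break
            cur = nxt[cur]
        if len(loop) >= 3:
            loops.append(np.array(loop, dtype=np.int64))
    return loops


def ear_clip(points2d: np.ndarray) -> np.ndarray:
    """Triangulate a simple polygon (CCW or CW) by ear clipping.

    Returns (n-2, 3) index triples into the input ring.
    """
    pts = np.asarray(points2d, dtype=float)
    n = len(pts)
    if n < 3:
        return np.zeros((0, 3), dtype=np.int64)
    # enforce CCW
    area2 = np.sum(pts[:, 0] * np.roll(pts[:, 1], -1) - np.roll(pts[:, 0], -1) * pts[:, 1])
    order = np.arange(n) if area2 >= 0 else np.arange(n)[::-1]
    idx = list(order)
    tris = []
    guard = 0
    while len(idx) > 3 and guard < 10 * n:
        guard += 1
        m = len(idx)
        clipped = False
        for k in range(m):
            i0, i1, i2 = idx[(k - 1) % m], idx[k], idx[(k + 1) % m]
            a, b, c = pts[i0], pts[i1], pts[i2]
            cross = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
            if cross <= 1e-14:
                continue  # reflex or degenerate corner
            ear = True
            for j in idx:
                if j in (i0, i1, i2):
                    continue
                p = pts[j]
                d1 = (b[0] - a[0]) * (p[1] - a[1]) - (b[1] - a[1]) * (p[0] - a[0])
                d2 = (c[0] - b[0]) * (p[1] - b[1]) - (c[1] - b[1]) * (p[0] - b[0])
                d3 = (a[0] - c[0]) * (p[1] - c[1]) - (a[1] - c[1]) * (p[0] - c[0])
                if d1 >= 0 and d2 >= 0 and d3 >= 0:
                    ear = False
                    break
            if ear:
                tris.append((i0, i1, i2))
                del idx[k]
                clipped = True
                break
        if not clipped:  # numerically stuck: fan the rest
            break
    if len(idx) >= 3:
        for k in range(1, len(idx) - 1):
            tris.append((idx[0], idx[k], idx[k + 1]))
    return np.array(tris, dtype=np.int64)
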