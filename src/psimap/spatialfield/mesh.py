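"""Triangulated meshes for SPDE field approximation.

A mesh is built from the data locations thinned at a cutoff distance, plus a
regular in-fill of interior points (so no interior edge exceeds the interior
max-edge limit) and a coarser ring of exterior points extending beyond the
convex hull of the data (to push boundary effects of the SPDE approximation
away from the observations).  Triangulation is Delaunay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay


@dataclass
class Mesh:
    vertices: np.ndarray  # (nv, 2)
    triangles: np.ndarray  # (nt, 3) vertex indices
    cutoff_m: float
    max_edge_m: tuple[float, float]  # (interior, exterior)
    interior_mask: np.ndarray  # per-vertex: inside the data hull

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def edges(self) -> np.ndarray:
        e = np.vstack([self.triangles[:, [0, 1]], self.triangles[:, [1, 2]],
                       self.triangles[:, [0, 2]]])
        return np.unique(np.sort(e, axis=1), axis=0)

    def edge_lengths(self) -> np.ndarray:
        e = self.edges()
        return np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)

    def projector(self, points: np.ndarray) -> np.ndarray:
        """Barycentric projection matrix A (n_points x nv): A @ u evaluates the
        piecewise-linear field at the points.  Points outside the mesh hull get
        all-zero rows."""
        tri = Delaunay(self.vertices)  # same point set; used for point location
        pts = np.atleast_2d(points)
        A = np.zeros((len(pts), self.n_vertices))
        simplex = tri.find_simplex(pts)
        for i, s in enumerate(simplex):
            if s < 0:
                continue
            verts = tri.simplices[s]
            T = tri.transform[s]
            b = T[:2] @ (pts[i] - T[2])
            bary = np.append(b, 1 - b.sum())
            A[i, verts] = bary
        return A


def thin_points(points: np.ndarray, cutoff: float) -> np.ndarray:
    """Greedy thinning: keep a point iff it is >= cutoff from every kept one,
    so any group of mutually-close locations collapses to one vertex seed."""
    kept: list[np.ndarray] = []
    for p in points:
        if all(np.hypot(*(p - q)) >= cutoff for q in kept):
            kept.append(p)
    return np.asarray(kept)


def build_mesh(
    locations: np.ndarray,
    cutoff_m: float,
    max_edge_m: tuple[float, float],
) -> Mesh:
    """Build a mesh covering the data locations plus an exterior extension.

    The in-fill grid spacing is max_edge / sqrt(2) (with a tiny deterministic
    jitter to break co-circular degeneracy), which bounds Delaunay edge
    lengths by the max-edge limits.
    """
    locations = np.asarray(locations, dtype=float)
    if len(locations) < 3:
        raise ValueError("need at least 3 locations")
    if np.linalg.matrix_rank(locations - locations.mean(axis=0)) < 2:
        raise ValueError("locations are collinear; cannot build a 2-D mesh")
    max_int, max_ext = max_edge_m
    seeds = thin_points(locations, cutoff_m)

    minx, miny = locations.min(axis=0)
    maxx, maxy = locations.max(axis=0)
    ext_width = 1.5 * max_ext  # extension ring beyond the data bounding box

    def grid_points(x0, y0, x1, y1, h, phase):
        xs = np.arange(x0, x1 + h, h)
        ys = np.arange(y0, y1 + h, h)
        gx, gy = np.meshgrid(xs, ys)
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        return pts + phase * h * 1e-3 * np.array([1.0, -1.0])

    h_int = max_int / np.sqrt(2.0) * 0.99
    h_ext = max_ext / np.sqrt(2.0) * 0.99
    interior = grid_points(minx, miny, maxx, maxy, h_int, 1.0)
    outer = grid_points(minx - ext_width, miny - ext_width,
                        maxx + ext_width, maxy + ext_width, h_ext, 2.0)
    in_box = ((outer[:, 0] > minx - h_ext / 2) & (outer[:, 0] < maxx + h_ext / 2)
              & (outer[:, 1] > miny - h_ext / 2) & (outer[:, 1] < maxy + h_ext / 2))
    candidates = np.vstack([interior, outer[~in_box]])
    # drop in-fill points that crowd a data seed
    keep = np.ones(len(candidates), dtype=bool)
    for s in seeds:
        d = np.hypot(candidates[:, 0] - s[0], candidates[:, 1] - s[1])
        keep &= d >= max(cutoff_m, 0.4 * h_int)
    vertices = np.vstack([seeds, candidates[keep]])

    tri = Delaunay(vertices)
    interior_mask = (
        (vertices[:, 0] >= minx - 1e-9) & (vertices[:, 0] <= maxx + 1e-9)
        & (vertices[:, 1] >= miny - 1e-9) & (vertices[:, 1] <= maxy + 1e-9)
    )
    return Mesh(vertices, tri.simplices.copy(), cutoff_m, (max_int, max_ext), interior_mask)
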