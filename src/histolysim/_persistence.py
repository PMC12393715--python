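"""Degree-1 persistent homology of planar point clouds.

The growing-disk (Čech) filtration restricted to the Delaunay triangulation
— the alpha complex — has the same persistence diagram as the full Čech
filtration for points in the plane, with all filtration values expressed
directly as disk radii.  In two dimensions the H1 pairs can be read off a
dual construction: triangles are nodes (weighted by circumradius, plus an
unbounded outer face at +inf), Delaunay edges connect the two faces they
border, and a Kruskal sweep over edges in decreasing filtration order with
the elder rule yields one (birth = edge value, death = max triangle value
of the absorbed component) pair per merge.

Filtration values (radius convention):
  vertex   0
  edge     half its length if Gabriel (no adjacent opposite vertex inside
           the diametral circle), else the smallest circumradius among its
           incident triangles
  triangle circumradius
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import Delaunay, QhullError

__all__ = ["alpha_h1_pairs"]


def _circumradius(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    ab = b - a
    ac = c - a
    cross = ab[0] * ac[1] - ab[1] * ac[0]
    la = np.hypot(*(b - c))
    lb = np.hypot(*ac)
    lc = np.hypot(*ab)
    if cross == 0.0:
        return 0.5 * max(la, lb, lc)
    return la * lb * lc / (2.0 * abs(cross))


class _UnionFind:
    __slots__ = ("parent", "maxval")

    def __init__(self, n: int, values: np.ndarray):
        self.parent = list(range(n))
        self.maxval = list(values)

    def find(self, i: int) -> int:
        p = self.parent
        while p[i] != i:
            p[i] = p[p[i]]
            i = p[i]
        return i

    def union(self, i: int, j: int) -> float:
        """Merge the components of i and j; returns the birth value (max
        triangle value) of the younger (absorbed) component."""
        ri, rj = self.find(i), self.find(j)
        di, dj = self.maxval[ri], self.maxval[rj]
        if di < dj:
            ri, rj = rj, ri
            di, dj = dj, di
        # ri is elder (larger max); rj dies
        self.parent[rj] = ri
        return dj


def alpha_h1_pairs(points: np.ndarray) -> list[tuple[float, float]]:
    """(birth, death) radii of all finite H1 classes of the alpha filtration.

    Degenerate inputs (fewer than 3 points, all collinear) have no loops and
    return an empty list.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if len(pts) < 3:
        return []
    try:
        tri = Delaunay(pts)
    except QhullError:
        return []
    simplices = tri.simplices
    n_tri = len(simplices)
    if n_tri == 0:
        return []

    tri_val = np.empty(n_tri)
    for t in range(n_tri):
        ia, ib, ic = simplices[t]
        tri_val[t] = _circumradius(pts[ia], pts[ib], pts[ic])

    # edge -> [incident triangle ids]
    edges: dict[tuple[int, int], list[int]] = {}
    for t in range(n_tri):
        a, b, c = sorted(simplices[t])
        for e in ((a, b), (a, c), (b, c)):
            edges.setdefault(e, []).append(t)

    edge_list = []
    for (a, b), tris in edges.items():
        half = 0.5 * np.hypot(*(pts[b] - pts[a]))
        mid = 0.5 * (pts[a] + pts[b])
        gabriel = True
        for t in tris:
            for v in simplices[t]:
                if v != a and v != b:
                    if np.hypot(*(pts[v] - mid)) < half:
                        gabriel = False
        val = half if gabriel else min(tri_val[t] for t in tris)
        f1 = tris[0]
        f2 = tris[1] if len(tris) > 1 else n_tri  # outer face
        edge_list.append((val, a, b, f1, f2))

    # dual Kruskal, decreasing edge value; outer face is the eternal elder
    values = np.concatenate([tri_val, [np.inf]])
    uf = _UnionFind(n_tri + 1, values)
    edge_list.sort(key=lambda e: (-e[0], e[1], e[2]))
    pairs = []
    for val, _a, _b, f1, f2 in edge_list:
        if uf.find(f1) == uf.find(f2):
            continue
        death = uf.union(f1, f2)
        # drop zero-persistence classes (degenerate, e.g. cocircular points,
        # up to floating-point noise)
        if death - val > 1e-9 * max(1.0, death):
            pairs.append((float(val), float(death)))
    pairs.sort()
    return pairs
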