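"""Independent brute-force oracles used across the test suite.

Everything here is deliberately naive (O(n^2)/O(n^3) loops, explicit sums)
and shares no code with the package's implementation paths.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial import Voronoi
from shapely.geometry import LineString, box


def threshold_edges_bruteforce(points: np.ndarray, labels, dmax: float) -> set:
    """All-pairs closed-ball adjacency: 0 < ||pi - pj|| <= dmax."""
    n = len(points)
    edges = set()
    for i in range(n):
        for j in range(i + 1, n):
            d = math.dist(points[i], points[j])
            if 0.0 < d <= dmax:
                edges.add(tuple(sorted((labels[i], labels[j]))))
    return edges


def _circumcircle(p, q, r):
    """Center and radius of the circle through three 2D points, or None."""
    ax, ay = p
    bx, by = q
    cx, cy = r
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if d == 0.0:
        return None
    ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay) + (cx**2 + cy**2) * (ay - by)) / d
    uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx) + (cx**2 + cy**2) * (bx - ax)) / d
    center = np.array([ux, uy])
    return center, math.dist(center, p)


def is_delaunay_edge_bruteforce(points: np.ndarray, i: int, j: int, tol: float = 1e-9) -> bool:
    """Empty-circumcircle membership test for the pair (i, j).

    The pair is a Delaunay edge iff some circle through both points contains
    no other point strictly inside.  It suffices to test the diametral
    circle and every circumcircle through a third point: an empty circle can
    always be shrunk/slid along the bisector until it hits one of these.
    """
    pi, pj = points[i], points[j]
    others = [k for k in range(len(points)) if k not in (i, j)]

    def empty(center, radius):
        return all(math.dist(points[k], center) >= radius - tol for k in others)

    center = (pi + pj) / 2.0
    if empty(center, math.dist(pi, pj) / 2.0):
        return True
    for k in others:
        cc = _circumcircle(pi, pj, points[k])
        if cc is not None and empty(*cc):
            return True
    return False


def rasterize_ellipse(a: float, b: float, angle_deg: float, pad: int = 5) -> np.ndarray:
    """Boolean mask of a filled ellipse with semi-axes a >= b rotated by angle.

    The rotation angle is measured from the x (column) axis, counterclockwise
    in conventional x/y coordinates (i.e. toward +y = increasing row index).
    """
    phi = math.radians(angle_deg)
    half = int(math.ceil(a)) + pad
    size = 2 * half + 1
    rows, cols = np.mgrid[0:size, 0:size]
    x = cols - half
    y = rows - half
    xr = x * math.cos(phi) + y * math.sin(phi)
    yr = -x * math.sin(phi) + y * math.cos(phi)
    return (xr / a) ** 2 + (yr / b) ** 2 <= 1.0


def pixel_moments_bruteforce(mask: np.ndarray, spacing=(1.0, 1.0)):
    """Eccentricity and major-axis angle from an explicit pixel-list covariance.

    Coordinates are built as (x, y) = (col * sx, row * sy); the covariance is
    accumulated with plain Python loops.
    """
    coords = [(c * spacing[1], r * spacing[0]) for r, c in zip(*np.nonzero(mask))]
    n = len(coords)
    mx = sum(p[0] for p in coords) / n
    my = sum(p[1] for p in coords) / n
    sxx = sum((p[0] - mx) ** 2 for p in coords) / n
    syy = sum((p[1] - my) ** 2 for p in coords) / n
    sxy = sum((p[0] - mx) * (p[1] - my) for p in coords) / n
    tr, det = sxx + syy, sxx * syy - sxy**2
    disc = math.sqrt(max(0.0, tr**2 / 4.0 - det))
    lam1, lam2 = tr / 2.0 + disc, tr / 2.0 - disc
    ecc = math.sqrt(max(0.0, 1.0 - lam2 / lam1)) if lam1 > 0 else 0.0
    if abs(sxy) < 1e-12 and sxx >= syy:
        theta = 0.0
    elif abs(sxy) < 1e-12:
        theta = math.pi / 2.0
    else:
        theta = math.atan2(lam1 - sxx, sxy)
    if theta > math.pi / 2:
        theta -= math.pi
    elif theta <= -math.pi / 2:
        theta += math.pi
    return ecc, theta


def clipped_ridge_lengths(generators: np.ndarray, extent) -> dict:
    """Length of each continuous Voronoi ridge clipped to the image rectangle.

    ``generators`` are 2D points in array-axis order; ``extent`` the physical
    image extents per axis.  Returns (label_i < label_j) -> clipped length
    (labels are generator index + 1).  Infinite ridges are extended far
    beyond the domain before clipping.
    """
    vor = Voronoi(generators)
    domain = box(0.0, 0.0, float(extent[0]), float(extent[1]))
    center = generators.mean(axis=0)
    span = float(np.ptp(generators, axis=0).max() * 10 + max(extent) * 10)
    out = {}
    for (p, q), verts in zip(vor.ridge_points, vor.ridge_vertices):
        if -1 in verts:
            fin = [v for v in verts if v != -1]
            if not fin:
                continue
            vfin = vor.vertices[fin[0]]
            t = generators[q] - generators[p]
            t = t / np.linalg.norm(t)
            normal = np.array([-t[1], t[0]])
            mid = generators[[p, q]].mean(axis=0)
            if np.dot(mid - center, normal) < 0:
                normal = -normal
            pts = [vfin, vfin + normal * span]
        else:
            pts = [vor.vertices[v] for v in verts]
        seg = LineString([tuple(pt) for pt in pts])
        key = tuple(sorted((p + 1, q + 1)))
        out[key] = float(seg.intersection(domain).length)
    return out


def hull_peel_bruteforce(points: np.ndarray) -> dict[int, int]:
    """Naive iterative convex-hull peeling; returns point index -> layer."""
    from scipy.spatial import ConvexHull, QhullError

    layers: dict[int, int] = {}
    remaining = list(range(len(points)))
    layer = 0
    dim = points.shape[1]
    while len(remaining) >= dim + 1:
        try:
            hull = ConvexHull(points[remaining])
        except QhullError:
            break
        on_hull = sorted(remaining[v] for v in hull.vertices)
        for idx in on_hull:
            layers[idx] = layer
            remaining.remove(idx)
        layer += 1
    for idx in remaining:
        layers[idx] = layer
    return layers


def flood_fill_clusters(nodes, edges, types) -> list[tuple[str, frozenset]]:
    """Same-type connected components by explicit flood fill."""
    adj: dict = {n: set() for n in nodes}
    for u, v in edges:
        if types[u] == types[v]:
            adj[u].add(v)
            adj[v].add(u)
    seen = set()
    clusters = []
    for start in nodes:
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            n = stack.pop()
            if n in comp:
                continue
            comp.add(n)
            stack.extend(adj[n] - comp)
        seen |= comp
        clusters.append((types[start], frozenset(comp)))
    return clusters
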