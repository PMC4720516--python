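"""Independent brute-force oracles shared across test modules."""

import itertools

import numpy as np


def brute_force_delaunay_edges(pts):
    """Edges of the Delaunay triangulation by exhaustive circumcircle checks.

    An edge (i, j) is Delaunay iff some circle through i, j and a third
    point contains no other point.  O(n^4): only for tiny instances.
    """
    n = len(pts)
    edges = set()
    for i, j, k in itertools.combinations(range(n), 3):
        a, b, c = pts[i], pts[j], pts[k]
        d = 2 * (a[0] * (b[1] - c[1]) + b[0] * (c[1] - a[1]) + c[0] * (a[1] - b[1]))
        if abs(d) < 1e-12:
            continue
        ux = (
            (a @ a) * (b[1] - c[1]) + (b @ b) * (c[1] - a[1]) + (c @ c) * (a[1] - b[1])
        ) / d
        uy = (
            (a @ a) * (c[0] - b[0]) + (b @ b) * (a[0] - c[0]) + (c @ c) * (b[0] - a[0])
        ) / d
        center = np.array([ux, uy])
        r = np.linalg.norm(a - center)
        empty = all(
            np.linalg.norm(pts[m] - center) >= r - 1e-9
            for m in range(n)
            if m not in (i, j, k)
        )
        if empty:
            edges.update({(i, j), (i, k), (j, k)})
    return {(min(e), max(e)) for e in edges}
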