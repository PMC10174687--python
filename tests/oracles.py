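"""Independent reference implementations used only to check the library.

These are deliberately naive: a dense ray-marching search for the
center-to-border distance, and an O(n^3) agglomerative complete-linkage
clustering built directly from the definition.  They share no code with
the implementations they validate.
"""

from __future__ import annotations

import numpy as np
import shapely
from shapely.geometry import Polygon


def ray_march_border(
    polygon: Polygon,
    center: np.ndarray,
    directions: np.ndarray,
    coarse_nm: float = 1.0,
    fine_nm: float = 0.01,
    r_max: float = 5000.0,
) -> np.ndarray:
    """Border distance by marching outward until point-in-polygon flips.

    Two-stage search: a coarse march locates the bracketing step, a fine
    march at *fine_nm* resolution (0.01 nm) pins the crossing down.
    """
    directions = np.atleast_2d(directions).astype(float)
    directions = directions / np.linalg.norm(directions, axis=1, keepdims=True)
    n = len(directions)
    coarse = np.arange(0.0, r_max, coarse_nm)
    out = np.empty(n)
    for i in range(n):
        pts = center + directions[i][None, :] * coarse[:, None]
        inside = shapely.contains_xy(polygon, pts[:, 0], pts[:, 1])
        first_out = np.argmin(inside)  # first False
        if inside[first_out]:
            raise ValueError("ray never left the polygon within r_max")
        lo = coarse[max(first_out - 1, 0)]
        fine = lo + np.arange(0.0, coarse_nm + fine_nm, fine_nm)
        pts = center + directions[i][None, :] * fine[:, None]
        inside = shapely.contains_xy(polygon, pts[:, 0], pts[:, 1])
        j = np.argmin(inside)
        out[i] = fine[j]
    return out


def complete_linkage_bruteforce(xy: np.ndarray, diameter: float) -> list[set[int]]:
    """Agglomerative complete-linkage clustering from first principles.

    Repeatedly merges the pair of clusters with the smallest complete
    linkage (maximum pairwise member distance), stopping when the smallest
    linkage exceeds *diameter*.  Ties are broken by the lexicographically
    smallest pair of minimum member indices, which makes the partition
    deterministic.
    """
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=2)
    clusters: list[set[int]] = [{i} for i in range(n)]
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                span = max(d[a, b] for a in clusters[i] for b in clusters[j])
                key = (span, min(clusters[i]), min(clusters[j]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        (span, _, _), i, j = best
        if span > diameter:
            break
        clusters[i] = clusters[i] | clusters[j]
        del clusters[j]
    return clusters
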