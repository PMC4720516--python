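"""Nuclear segmentation: foreground extraction, local clustering,
concavity-based splitting, and boundary shrinking.

The stage structure and the role of each parameter follow the original
pipeline's documented behaviour: a global foreground/background partition
seeded by the image mean with a noise-intensity prior (P5), mean-shift
clustering of foreground pixels in the joint spatial-intensity space with
bandwidths (P3, P3, P1), merging of objects smaller than the window size
(P2) into their nearest neighbour, recursive splitting of concave objects
against a threshold (P4; the larger the value, the less likely a cut), and
optional erosion of each object's boundary by ``shrink_level`` pixels.
Segmentation is strictly 2-D, per optical section; across sections only the
widest contour of a nucleus is kept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage import measure, morphology
from skimage.filters import threshold_isodata


@dataclass
class SegParams:
    """The five segmentation parameters plus the two shrink parameters.

    Ranges and defaults follow the documented parameter table; the
    single set used for whole-pipeline runs is available as
    :meth:`pipeline_defaults`.
    """

    intensity_range: int = 7  # P1 in [1, 20]
    window_size: int = 30  # P2 in [5, 250]
    spatial_range: int = 10  # P3 in [0, 20]
    concavity_threshold: int = 5  # P4 in [1, 20]
    noise_intensity: int = 30  # P5 in [1, 140]
    shrink: bool = True
    shrink_level: int = 4

    _RANGES = {
        "intensity_range": (1, 20),
        "window_size": (5, 250),
        "spatial_range": (0, 20),
        "concavity_threshold": (1, 20),
        "noise_intensity": (1, 140),
    }

    def __post_init__(self) -> None:
        for name, (lo, hi) in self._RANGES.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside documented range [{lo}, {hi}]")
        if self.shrink_level < 0:
            raise ValueError("shrink_level must be >= 0")

    @classmethod
    def pipeline_defaults(cls) -> "SegParams":
        """The single parameter set used for all layers in full runs."""
        return cls(
            intensity_range=6,
            window_size=30,
            spatial_range=3,
            concavity_threshold=5,
            noise_intensity=30,
            shrink=True,
            shrink_level=4,
        )


@dataclass
class SegmentedObject:
    """One candidate nucleus: integer label plus its pixel set."""

    label: int
    pixels: np.ndarray  # (n, 2) array of (row, col)
    shrink_failed: bool = False

    @property
    def area(self) -> int:
        return len(self.pixels)

    @property
    def centroid(self) -> Tuple[float, float]:
        """(x, y) = (col, row) centroid in pixels."""
        r, c = self.pixels.mean(axis=0)
        return float(c), float(r)

    def to_mask(self, shape: Tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.pixels[:, 0], self.pixels[:, 1]] = True
        return m

    @property
    def contour(self) -> np.ndarray:
        """Closed sub-pixel boundary contour, (n, 2) as (row, col)."""
        pts, offset = _boundary_contour(self.pixels)
        return pts + offset


def extract_foreground(image: np.ndarray, params: SegParams) -> np.ndarray:
    """Partition the image into background and nuclear foreground.

    The threshold is the ISODATA (iterative mean) split of the intensity
    histogram, floored at the noise prior P5: pixels at or below P5 are
    always background.  An image whose putative foreground covers most of
    the frame (inverted contrast) is rejected rather than segmented.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("extract_foreground expects a non-empty 2-D image")
    if image.max() <= params.noise_intensity:
        return np.zeros(image.shape, dtype=bool)
    try:
        thr = float(threshold_isodata(image))
    except ValueError:  # constant image above the prior
        thr = float(image.mean())
    thr = max(thr, float(params.noise_intensity))
    mask = image > thr
    if mask.mean() > 0.5:
        raise ValueError(
            "foreground covers most of the image — inverted contrast or "
            "saturated input"
        )
    return mask


def _mean_shift_modes(
    coords: np.ndarray, weights: np.ndarray, bandwidth: float, n_iter: int = 30
) -> np.ndarray:
    """Intensity-weighted spatial mean-shift; returns a mode label per pixel.

    Flat kernel of radius ``bandwidth``: each point iteratively moves to the
    intensity-weighted centroid of the original points within the radius, so
    points climb the local intensity surface and pool at its spatial modes.
    """
    from scipy.spatial.distance import cdist

    orig = coords.astype(float)
    cur = orig.copy()
    wx = weights * orig[:, 0]
    wy = weights * orig[:, 1]
    for _ in range(n_iter):
        within = cdist(cur, orig) <= bandwidth
        denom = within @ weights
        new = np.column_stack([within @ wx, within @ wy]) / denom[:, None]
        if np.max(np.abs(new - cur)) < 1e-3:
            cur = new
            break
        cur = new
    # group converged points whose modes are closer than half a bandwidth
    link = cdist(cur, cur) <= max(bandwidth / 2.0, 1.0)
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    _, labels = connected_components(csr_matrix(link), directed=False)
    return labels


def _adjacent_cluster_pairs(pix: np.ndarray, labels: np.ndarray) -> set:
    """Unordered pairs of cluster labels with 8-adjacent pixels."""
    rmin, cmin = pix.min(axis=0)
    local = pix - np.array([rmin, cmin]) + 1
    shape = tuple(local.max(axis=0) + 2)
    lab_img = np.full(shape, -1, dtype=int)
    lab_img[local[:, 0], local[:, 1]] = labels
    pairs = set()
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        a = lab_img[max(0, -dr) : shape[0] - max(0, dr), max(0, -dc) : shape[1] - max(0, dc)]
        b = lab_img[max(0, dr) :, max(0, dc) :] if dc >= 0 else lab_img[max(0, dr) :, : shape[1] + dc]
        both = (a >= 0) & (b >= 0) & (a != b)
        for x, y in zip(a[both].ravel(), b[both].ravel()):
            pairs.add((min(x, y), max(x, y)))
    return pairs


def cluster_foreground(
    mask: np.ndarray, image: np.ndarray, params: SegParams
) -> List[SegmentedObject]:
    """Partition foreground into candidate objects.

    Connected components (8-connectivity) are subdivided by
    intensity-weighted spatial mean-shift with bandwidth P3; adjacent
    subclusters are then re-merged when their mean intensities differ by no
    more than the P1-scaled similarity range (P1/20 of the foreground
    intensity spread), so raising P1 can only lower the object count.
    Finally any object smaller than ``window_size`` is merged into its
    nearest neighbour.
    """
    image = np.asarray(image, dtype=float)
    lbl, n_comp = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    fg = image[mask.astype(bool)]
    spread = float(fg.max() - fg.min()) if fg.size else 0.0
    sim_range = params.intensity_range / 20.0 * spread
    bandwidth = max(params.spatial_range, 1)
    objects: List[np.ndarray] = []
    for ci in range(1, n_comp + 1):
        rr, cc = np.nonzero(lbl == ci)
        pix = np.column_stack([rr, cc])
        if len(pix) < 8:
            objects.append(pix)
            continue
        sub = _mean_shift_modes(pix, image[rr, cc], bandwidth)
        groups = _merge_similar_adjacent(pix, sub, image, sim_range)
        objects.extend(groups)
    objects = _merge_small(objects, params.window_size)
    return [
        SegmentedObject(label=i + 1, pixels=p)
        for i, p in enumerate(objects)
        if len(p) > 0
    ]


def _merge_similar_adjacent(
    pix: np.ndarray, labels: np.ndarray, image: np.ndarray, sim_range: float
) -> List[np.ndarray]:
    """Union adjacent clusters whose mean intensities differ <= sim_range.

    A single union-find pass over a threshold-growing edge set: the edge set
    is monotone in the similarity range, so the number of resulting objects
    is non-increasing in P1.
    """
    uniq = np.unique(labels)
    if len(uniq) == 1:
        return [pix]
    dense = {k: i for i, k in enumerate(uniq)}
    lab = np.array([dense[k] for k in labels])
    means = np.array(
        [image[pix[lab == i, 0], pix[lab == i, 1]].mean() for i in range(len(uniq))]
    )
    parent = list(range(len(uniq)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in sorted(_adjacent_cluster_pairs(pix, lab)):
        if abs(means[i] - means[j]) <= sim_range:
            parent[find(i)] = find(j)
    roots = np.array([find(i) for i in lab])
    return [pix[roots == r] for r in np.unique(roots)]


def _merge_small(groups: List[np.ndarray], min_size: int) -> List[np.ndarray]:
    groups = [g for g in groups if len(g)]
    while len(groups) > 1:
        sizes = np.array([len(g) for g in groups])
        small = np.flatnonzero(sizes < min_size)
        if small.size == 0:
            break
        i = int(small[np.argmin(sizes[small])])
        cent = np.array([g.mean(axis=0) for g in groups])
        d = np.hypot(cent[:, 0] - cent[i, 0], cent[:, 1] - cent[i, 1])
        d[i] = np.inf
        j = int(np.argmin(d))
        groups[j] = np.vstack([groups[j], groups[i]])
        del groups[i]
    return groups


# ---------------------------------------------------------------------------
# concavity splitting


def _boundary_contour(pixels: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Closed sub-pixel contour of the pixel set (in local padded coords).

    Returns (contour points (n, 2) as (row, col), offset to map back).
    """
    rmin, cmin = pixels.min(axis=0)
    local = pixels - np.array([rmin, cmin]) + 2
    shape = tuple(local.max(axis=0) + 3)
    m = np.zeros(shape, dtype=float)
    m[local[:, 0], local[:, 1]] = 1.0
    contours = measure.find_contours(m, 0.5)
    if not contours:
        raise ValueError("object has no closed boundary")
    contour = max(contours, key=len)
    return contour, np.array([rmin - 2, cmin - 2], dtype=float)


def _hull_depths(contour: np.ndarray) -> np.ndarray:
    """Distance of each contour point to the convex hull boundary."""
    from scipy.spatial import ConvexHull

    hull = ConvexHull(contour)
    # hull.equations: rows (a, b, offset) with a*x + b*y + offset <= 0 inside
    d = contour @ hull.equations[:, :2].T + hull.equations[:, 2]
    return -d.max(axis=1)  # depth below the nearest hull facet


def split_concave_object(
    obj: SegmentedObject, concavity_threshold: int
) -> List[SegmentedObject]:
    """Recursively split an object along its deepest concavity chord.

    The two deepest, mutually distant concavity points define a candidate
    neck; the cut is made when the neck width is small relative to the
    object's equivalent diameter, with the acceptance fraction shrinking
    linearly in P4 (at P4 = 20 no cut is ever made).  Objects of fewer
    than 8 pixels are returned unsplit.
    """
    if obj.area < 8:
        return [obj]
    try:
        contour, offset = _boundary_contour(obj.pixels)
        depths = _hull_depths(contour)
    except Exception:
        return [obj]
    accept_frac = max(0.0, 1.0 - concavity_threshold / 20.0)
    if accept_frac == 0.0:
        return [obj]
    # candidate concavity points must be deeper than boundary pixelation
    # noise; the required depth grows with P4 (less likely to cut)
    depth_min = max(1.5, concavity_threshold / 2.5)
    cand = np.flatnonzero(depths >= depth_min)
    if cand.size < 2:
        return [obj]
    n = len(contour)
    order = cand[np.argsort(depths[cand])[::-1]]
    p1 = order[0]
    # deepest partner at least 15% of the contour away along the boundary
    p2 = None
    for idx in order[1:]:
        sep = abs(idx - p1)
        if min(sep, n - sep) >= 0.15 * n:
            p2 = idx
            break
    if p2 is None:
        return [obj]
    a, b = contour[p1], contour[p2]
    neck = float(np.hypot(*(a - b)))
    eq_diam = 2.0 * math.sqrt(obj.area / math.pi)
    if neck >= accept_frac * eq_diam:
        return [obj]
    # split pixels by the side of the chord through a-b
    pts = obj.pixels.astype(float) - offset
    v = b - a
    side = (pts[:, 0] - a[0]) * v[1] - (pts[:, 1] - a[1]) * v[0]
    left = obj.pixels[side >= 0]
    right = obj.pixels[side < 0]
    if len(left) == 0 or len(right) == 0:
        return [obj]
    out: List[SegmentedObject] = []
    for part in (left, right):
        out.extend(
            split_concave_object(
                SegmentedObject(label=obj.label, pixels=part), concavity_threshold
            )
        )
    return out


def shrink_contour(obj: SegmentedObject, shrink_level: int) -> SegmentedObject:
    """Erode the object's pixel set by ``shrink_level`` px (disc element).

    If erosion would remove the object entirely, the pre-shrink object is
    kept and flagged via ``shrink_failed``.
    """
    if shrink_level == 0:
        return obj
    rmin, cmin = obj.pixels.min(axis=0)
    local = obj.pixels - np.array([rmin, cmin]) + shrink_level
    shape = tuple(local.max(axis=0) + shrink_level + 1)
    m = np.zeros(shape, dtype=bool)
    m[local[:, 0], local[:, 1]] = True
    eroded = morphology.erosion(m, morphology.disk(shrink_level))
    rr, cc = np.nonzero(eroded)
    if rr.size == 0:
        return replace(obj, shrink_failed=True)
    pixels = np.column_stack([rr, cc]) + np.array([rmin, cmin]) - shrink_level
    return SegmentedObject(label=obj.label, pixels=pixels)


def select_widest_section(areas_by_section: Dict[int, float]) -> int:
    """Index of the optical section with the greatest nuclear contour.

    Ties break to the lower section index.
    """
    if not areas_by_section:
        raise ValueError("no sections given")
    best = max(sorted(areas_by_section), key=lambda s: (areas_by_section[s], -s))
    return best


def segment_image(
    image: np.ndarray, params: Optional[SegParams] = None
) -> List[SegmentedObject]:
    """Full 2-D segmentation of one optical section.

    foreground -> mean-shift clustering -> concavity splitting -> optional
    boundary shrink; final objects are relabelled 1..n in raster order of
    their centroids.
    """
    params = params or SegParams()
    mask = extract_foreground(image, params)
    if not mask.any():
        return []
    objects = cluster_foreground(mask, image, params)
    split: List[SegmentedObject] = []
    for obj in objects:
        split.extend(split_concave_object(obj, params.concavity_threshold))
    if params.shrink:
        split = [shrink_contour(o, params.shrink_level) for o in split]
    split.sort(key=lambda o: (o.centroid[1], o.centroid[0]))
    return [replace(o, label=i + 1) for i, o in enumerate(split)]
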