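"""Position-to-time conversion via the R8 lattice, and replicate alignment.

The morphogenetic furrow moves at constant velocity, founding one new
column of R8 photoreceptors per fixed interval (2 hr by default), and cells
do not migrate afterwards.  The mean x-distance mu between R8s of adjacent
columns therefore converts anterior-posterior position directly into
developmental time:

    t = hours_per_column / mu * (x - x_c1)

with x_c1 the x-coordinate of the first (anterior-most) R8 column, so time
zero is the initiation of R8 differentiation.  Adjacent-column R8 pairs are
found as Delaunay-triangulation links oriented 30-60 degrees from the
anterior-posterior axis; the x-component of each link (Pythagorean
decomposition) is the furrow's travel between the two columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import Delaunay, QhullError

logger = logging.getLogger(__name__)


@dataclass
class R8Network:
    """Delaunay network of R8 centroids with its column-pair subset."""

    nodes: np.ndarray  # (n, 2) centroids (x, y) px
    links: np.ndarray  # (m, 2) index pairs into nodes
    column_pairs: Optional[np.ndarray] = None  # (k, 2) of (x_ia, x_ib), x_ia > x_ib


@dataclass
class FurrowCalibration:
    """Conversion between pixels of furrow travel and hours of development."""

    mu_px: float
    x_c1_px: float
    hours_per_column: float = 2.0

    def __post_init__(self) -> None:
        if not self.mu_px > 0:
            raise ValueError("mu_px must be > 0")


def build_r8_network(r8_centroids: np.ndarray) -> R8Network:
    """Delaunay triangulation of R8 centroids; links are triangle edges."""
    pts = np.asarray(r8_centroids, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("need at least 3 R8 centroids of shape (n, 2)")
    try:
        tri = Delaunay(pts)
    except QhullError as e:
        raise ValueError(f"degenerate R8 geometry (collinear points?): {e}") from e
    edges = set()
    for simplex in tri.simplices:
        for i in range(3):
            a, b = int(simplex[i]), int(simplex[(i + 1) % 3])
            edges.add((min(a, b), max(a, b)))
    links = np.array(sorted(edges), dtype=int)
    return R8Network(nodes=pts, links=links)


def filter_column_links(network: R8Network) -> np.ndarray:
    """Keep links oriented 30-60 degrees from the anterior-posterior axis.

    Such links join R8s of adjacent columns in the staggered ommatidial
    packing; links at ~0 degrees join cells within a row and links at ~90
    degrees join cells within a column.  Each unordered pair is kept once,
    recorded as (x_ia, x_ib) with x_ia > x_ib.  The band is inclusive at
    both ends.
    """
    nodes, links = network.nodes, network.links
    dx = np.abs(nodes[links[:, 0], 0] - nodes[links[:, 1], 0])
    dy = np.abs(nodes[links[:, 0], 1] - nodes[links[:, 1], 1])
    ang = np.degrees(np.arctan2(dy, dx))
    keep = (ang >= 30.0) & (ang <= 60.0)
    if not keep.any():
        raise ValueError("no 30-60 degree links found — calibration impossible")
    xa = nodes[links[keep, 0], 0]
    xb = nodes[links[keep, 1], 0]
    pairs = np.column_stack([np.maximum(xa, xb), np.minimum(xa, xb)])
    network.column_pairs = pairs
    return pairs


def mean_column_spacing(column_pairs: np.ndarray) -> float:
    """mu = mean over pairs of |x_ia - x_ib| (pixels of furrow travel)."""
    pairs = np.asarray(column_pairs, dtype=float)
    if pairs.size == 0:
        raise ValueError("no column pairs — cannot estimate spacing")
    return float(np.mean(np.abs(pairs[:, 0] - pairs[:, 1])))


def detect_columns(x_coords: Sequence[float], mu_px: float) -> List[np.ndarray]:
    """1-D clustering of R8 x-coordinates into columns (gap > mu/2 splits)."""
    xs = np.sort(np.asarray(x_coords, dtype=float))
    if xs.size == 0:
        raise ValueError("no R8 x-coordinates")
    splits = np.flatnonzero(np.diff(xs) > mu_px / 2.0) + 1
    return np.split(xs, splits)


def first_column_x(r8_centroids: np.ndarray, mu_px: float) -> float:
    """x_c1: mean x of R8s in the anterior-most detected column."""
    cols = detect_columns(np.asarray(r8_centroids, dtype=float)[:, 0], mu_px)
    return float(np.mean(cols[0]))


def calibrate_furrow(
    r8_centroids: np.ndarray, hours_per_column: float = 2.0
) -> FurrowCalibration:
    """Full calibration: network -> column links -> mu -> x_c1."""
    network = build_r8_network(r8_centroids)
    pairs = filter_column_links(network)
    mu = mean_column_spacing(pairs)
    x_c1 = first_column_x(np.asarray(r8_centroids, dtype=float), mu)
    return FurrowCalibration(mu_px=mu, x_c1_px=x_c1, hours_per_column=hours_per_column)


def position_to_time(x_px, calibration: FurrowCalibration):
    """t = hours_per_column / mu * (x - x_c1); anterior cells get t < 0."""
    x = np.asarray(x_px, dtype=float)
    t = calibration.hours_per_column / calibration.mu_px * (x - calibration.x_c1_px)
    return float(t) if np.isscalar(x_px) else t


def align_samples(samples: Sequence, window_cells: int = 130, smooth_cells: int = 20):
    """Per-sample time offsets that register the induction midpoints.

    Each sample's progenitor profile (moving average) is fit with a Hill
    curve; the fitted half-maximal time k is the alignment anchor (a robust
    stand-in for the profile's inflection point).  Offsets shift every
    sample so its anchor coincides with the first sample's; the reference
    offset is exactly 0.
    """
    from furrow.dynamics import fit_hill, moving_average, FitError

    anchors = []
    for s in samples:
        prog = s.of_type("progenitor").sort_values("time_hr")
        if len(prog) < 5:
            raise ValueError(f"sample {s.disc_id}: too few progenitors to align")
        t = prog["time_hr"].to_numpy(dtype=float)
        y = prog["normalized_level"].to_numpy(dtype=float)
        w = min(window_cells, max(5, len(t) // 3))
        sm = min(smooth_cells, max(1, len(t) // 6))
        profile = moving_average(t, y, w, sm)
        try:
            fit = fit_hill(profile.times, profile.values)
        except FitError as e:
            raise ValueError(
                f"sample {s.disc_id}: no induction phase to anchor on"
            ) from e
        if fit.b < 1e-6:
            raise ValueError(f"sample {s.disc_id}: no induction phase (flat profile)")
        anchors.append(fit.k)
    offsets = [0.0] + [anchors[0] - a for a in anchors[1:]]
    logger.info("alignment anchors (hr): %s; offsets: %s", anchors, offsets)
    return offsets
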