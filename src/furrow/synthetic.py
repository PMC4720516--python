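"""Synthetic eye-disc generator with full ground truth.

Emulates the statistical structure the analysis assumes: a biphasic
(Hill-rise then exponential-fall) mean trajectory of the normalized
reporter level in progenitors, cell-type-specific decay onsets and time
constants in differentiating cells, transient windows of elevated
cell-to-cell variability ("noise spikes"), a staggered R8 lattice with
fixed inter-column spacing (one column of R8s per ``hours_per_column`` of
development), a positive dependence of R2/R5 levels on distance to the
nearest R8, constant-mean RFP with channel bleed-through into YFP at a
configurable fraction, and gene-copy-number scaling of the amplitude
parameters.

Conventions: x in pixels, anterior at low x, developmental time increasing
with x, time zero at the first R8 column.  Cell-to-cell noise is
multiplicative log-normal so that the coefficient of variation is
independent of the mean level and spike increments add directly in CV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from furrow.core import CELL_TYPES, DIFFERENTIATING_TYPES, DiscSample


class ConfigError(ValueError):
    """A SyntheticConfig field violates its invariant (message names it)."""


def _default_onsets() -> Dict[str, float]:
    # R8 first (defines time zero), R2/R5 earliest recruits, cones latest.
    # Numeric values are plumbing defaults, configurable, never asserted.
    return {
        "progenitor": 15.0,  # induction-to-decay changeover in progenitors
        "R8": 0.0,
        "R2R5": 8.0,
        "R3R4": 12.0,
        "R1R6": 16.0,
        "R7": 18.0,
        "C1C2": 22.0,
        "C3C4": 24.0,
    }


def _default_taus() -> Dict[str, float]:
    # Progenitor decay roughly twice as slow as differentiating neurons.
    return {
        "progenitor": 20.0,
        "R8": 10.0,
        "R2R5": 10.0,
        "R3R4": 10.0,
        "R1R6": 10.0,
        "R7": 10.0,
        "C1C2": 10.0,
        "C3C4": 10.0,
    }


def _default_spikes() -> Dict[str, List[Tuple[float, float, float]]]:
    # One transient heterogeneity spike per transiting population:
    # (center_hour, width_hours, extra_CV).
    return {
        "progenitor": [(15.0, 17.0, 0.3)],
        "R2R5": [(10.0, 17.0, 0.3)],
    }


def _default_cells_per_column(rows: int) -> Dict[str, int]:
    return {
        "progenitor": 5 * rows,
        "R2R5": 2 * rows,
        "R3R4": 2 * rows,
        "R1R6": 2 * rows,
        "R7": rows,
        "C1C2": 2 * rows,
        "C3C4": 2 * rows,
    }


@dataclass
class SyntheticConfig:
    """All knobs of the generator; defaults define the study conditions.

    ``hill_params = (a, b, k, n)`` parameterize the progenitor induction
    Y(t) = a + b t^n / (t^n + k^n); ``decay_params[cell_type] = (A, B, tau)``
    parameterize the post-onset decay Y(t) = A + B exp(-(t - onset)/tau).
    When ``decay_params`` is left ``None``, B is chosen per type so the decay
    branch joins the induction curve continuously at that type's onset.

    A spike ``(center, width, extra_cv)`` adds ``extra_cv`` to the baseline
    CV for |t - center| <= width/2; a non-finite width makes the elevation
    sustained for all t >= center.
    """

    n_columns: int = 14
    rows_per_column: int = 6
    column_spacing_px: float = 25.0
    row_spacing_px: float = 34.0  # taller than column spacing so adjacent-
    # column links sit inside the 30-60 degree band, as in the real packing
    lattice_jitter_px: float = 0.0
    hours_per_column: float = 2.0
    hill_params: Tuple[float, float, float, float] = (0.1, 1.0, 8.0, 4.0)
    decay_params: Optional[Dict[str, Tuple[float, float, float]]] = None
    onset_hours: Dict[str, float] = field(default_factory=_default_onsets)
    baseline_cv: float = 0.15
    noise_spikes: Dict[str, List[Tuple[float, float, float]]] = field(
        default_factory=_default_spikes
    )
    bleed_fraction: float = 0.05
    copy_number_scale: float = 1.0
    cells_per_column: Optional[Dict[str, int]] = None
    r8_distance_coeff: float = 0.03  # per px, on log R2/R5 level
    rfp_mean: float = 100.0
    rfp_cv: float = 0.10
    nuclear_size_mean_px: float = 120.0
    nuclear_size_cv: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()
        if self.cells_per_column is None:
            self.cells_per_column = _default_cells_per_column(self.rows_per_column)
        if self.decay_params is None:
            self.decay_params = self._continuous_decay_defaults()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if not self.column_spacing_px > 0:
            raise ConfigError("column_spacing_px must be > 0")
        if not self.row_spacing_px > 0:
            raise ConfigError("row_spacing_px must be > 0")
        if not self.hours_per_column > 0:
            raise ConfigError("hours_per_column must be > 0")
        if not 0.0 <= self.bleed_fraction <= 1.0:
            raise ConfigError("bleed_fraction must lie in [0, 1]")
        if self.lattice_jitter_px < 0:
            raise ConfigError("lattice_jitter_px must be >= 0")
        a, b, k, n = self.hill_params
        if min(a, b, k, n) < 0:
            raise ConfigError("hill_params must be nonnegative")
        if n < 1:
            raise ConfigError("hill_params: Hill coefficient n must be >= 1")
        if self.decay_params is not None:
            for ct, (A, B, tau) in self.decay_params.items():
                if min(A, B) < 0 or not tau > 0:
                    raise ConfigError(
                        f"decay_params[{ct!r}]: A, B must be >= 0 and tau > 0"
                    )
        if self.baseline_cv < 0:
            raise ConfigError("baseline_cv must be >= 0")
        if self.copy_number_scale <= 0:
            raise ConfigError("copy_number_scale must be > 0")
        if self.rfp_mean <= 0:
            raise ConfigError("rfp_mean must be > 0")

    # -- mean-trajectory machinery --------------------------------------
    def hill(self, t: np.ndarray) -> np.ndarray:
        """Induction branch; constant at ``a`` for t <= 0."""
        a, b, k, n = self.hill_params
        t = np.asarray(t, dtype=float)
        tp = np.clip(t, 0.0, None)
        with np.errstate(divide="ignore", invalid="ignore"):
            y = a + b * tp**n / (tp**n + k**n)
        return np.where(t <= 0, a, y)

    def _continuous_decay_defaults(self) -> Dict[str, Tuple[float, float, float]]:
        taus = _default_taus()
        out = {}
        for ct in CELL_TYPES:
            onset = self.onset_hours.get(ct, 0.0)
            level_at_onset = float(self.hill(np.array([onset]))[0])
            A = min(0.12, 0.9 * level_at_onset)
            out[ct] = (A, max(level_at_onset - A, 0.0), taus[ct])
        return out

    def mean_level(self, t: np.ndarray, cell_type: str) -> np.ndarray:
        """Expected normalized level (before bleed floor and noise)."""
        t = np.asarray(t, dtype=float)
        s = self.copy_number_scale
        if cell_type == "progenitor":
            onset = self.onset_hours["progenitor"]
            A, B, tau = self.decay_params["progenitor"]
            rise = self.hill(t)
            fall = A + B * np.exp(-(t - onset) / tau)
            return s * np.where(t <= onset, rise, fall)
        onset = self.onset_hours[cell_type]
        A, B, tau = self.decay_params[cell_type]
        return s * (A + B * np.exp(-np.clip(t - onset, 0.0, None) / tau))

    def cv_at(self, t: np.ndarray, cell_type: str) -> np.ndarray:
        """Coefficient of variation of the multiplicative noise at time t."""
        t = np.asarray(t, dtype=float)
        cv = np.full(t.shape, self.baseline_cv, dtype=float)
        for center, width, extra in self.noise_spikes.get(cell_type, []):
            if math.isfinite(width):
                inside = np.abs(t - center) <= width / 2.0
            else:
                inside = t >= center
            cv = cv + extra * inside
        return cv


@dataclass
class GroundTruth:
    """Per-cell generative truth, aligned with the cell table by cell_id."""

    table: pd.DataFrame  # cell_id, cell_type, true_time_hr, true_mean_level, true_cv
    r8_lattice: np.ndarray  # (n, 2) planted R8 centroids (x, y) px
    config: SyntheticConfig

    def for_cells(self, cell_ids: Sequence[int]) -> pd.DataFrame:
        return self.table.set_index("cell_id").loc[list(cell_ids)].reset_index()


def generate_r8_lattice(
    config: SyntheticConfig, rng: Optional[np.random.Generator] = None
) -> np.ndarray:
    """Staggered R8 lattice: alternate columns offset by half a row spacing.

    Returns an (n_columns * rows_per_column, 2) array of (x, y) centroids.
    """
    if config.n_columns < 2:
        raise ConfigError("n_columns must be >= 2 (no column spacing definable)")
    if config.rows_per_column < 2:
        raise ConfigError("rows_per_column must be >= 2")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    cols = np.arange(config.n_columns)
    rows = np.arange(config.rows_per_column)
    x0 = 3.0 * config.column_spacing_px  # anterior margin
    xs = x0 + cols * config.column_spacing_px
    pts = []
    for j, x in enumerate(xs):
        yoff = (j % 2) * config.row_spacing_px / 2.0
        for i in rows:
            pts.append((x, config.row_spacing_px * (i + 1) + yoff))
    pts = np.asarray(pts, dtype=float)
    if config.lattice_jitter_px > 0:
        pts = pts + rng.normal(0.0, config.lattice_jitter_px, size=pts.shape)
    return pts


def _lognormal_factors(rng: np.random.Generator, cv: np.ndarray) -> np.ndarray:
    """Unit-mean multiplicative log-normal factors with the given CV."""
    sigma = np.sqrt(np.log1p(np.square(cv)))
    return np.exp(rng.normal(0.0, 1.0, size=cv.shape) * sigma - sigma**2 / 2.0)


class _Occupancy:
    """Growing store of placed positions with fast nearest-distance checks."""

    def __init__(self, initial: np.ndarray, capacity: int):
        self.buf = np.empty((max(capacity, len(initial)) + 8, 2), dtype=float)
        self.n = len(initial)
        self.buf[: self.n] = initial

    def min_dist(self, p: np.ndarray) -> float:
        if self.n == 0:
            return np.inf
        a = self.buf[: self.n]
        return float(np.min(np.hypot(a[:, 0] - p[0], a[:, 1] - p[1])))

    def add(self, p: np.ndarray) -> None:
        if self.n >= len(self.buf):
            self.buf = np.vstack([self.buf, np.empty_like(self.buf)])
        self.buf[self.n] = p
        self.n += 1


def _scatter_positions(
    rng: np.random.Generator,
    n: int,
    x_range: Tuple[float, float],
    y_range: Tuple[float, float],
    min_sep: float,
    occupancy: "_Occupancy",
) -> np.ndarray:
    """Uniform positions with a minimum pairwise separation (dart throwing).

    Falls back to accepting the closest-legal draw after 40 attempts per
    point so generation always terminates; with the default densities the
    fallback is essentially never hit.
    """
    out = []
    for _ in range(n):
        best = None
        best_d = -1.0
        for _attempt in range(40):
            p = np.array(
                [rng.uniform(*x_range), rng.uniform(*y_range)], dtype=float
            )
            d = occupancy.min_dist(p)
            if d >= min_sep:
                best = p
                break
            if d > best_d:
                best, best_d = p, d
        occupancy.add(best)
        out.append(best)
    return np.asarray(out)


def generate_disc(
    config: SyntheticConfig, disc_id: str = "synthetic_0"
) -> Tuple[DiscSample, GroundTruth]:
    """Generate one disc's cell table plus its generative ground truth.

    The measured normalized level of each cell is
    ``mean_level(t) * noise_factor + bleed_fraction`` — the bleed floor is
    what a YFP-free nucleus would read because a fixed fraction of RFP
    fluorescence is detected in the yellow channel.  ``GroundTruth``
    records the expected (noise-free) value including the floor.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lattice = generate_r8_lattice(config, rng)
    n_rows = config.rows_per_column
    x_c1 = float(np.mean(lattice[:n_rows, 0]))
    hours_per_px = config.hours_per_column / config.column_spacing_px

    y_lo, y_hi = 0.5 * config.row_spacing_px, (n_rows + 1.0) * config.row_spacing_px
    x_max = float(np.max(lattice[:, 0])) + 0.5 * config.column_spacing_px
    min_sep = 0.35 * min(config.column_spacing_px, config.row_spacing_px)

    rows: List[dict] = []
    truth_rows: List[dict] = []
    cell_id = 0

    def emit(x: float, y: float, cell_type: str, r8_dist: float = np.nan) -> None:
        nonlocal cell_id
        t = hours_per_px * (x - x_c1)
        level = float(config.mean_level(np.array([t]), cell_type)[0])
        cv = float(config.cv_at(np.array([t]), cell_type)[0])
        if cell_type == "R2R5" and np.isfinite(r8_dist) and config.r8_distance_coeff:
            # positive dependence of the level on distance to the nearest R8,
            # centered so the population mean trend is unchanged
            level *= math.exp(config.r8_distance_coeff * (r8_dist - 11.0))
        noisy = level * float(_lognormal_factors(rng, np.array([cv]))[0])
        rfp = config.rfp_mean * float(
            _lognormal_factors(rng, np.array([config.rfp_cv]))[0]
        )
        size = max(
            8.0,
            config.nuclear_size_mean_px
            * float(_lognormal_factors(rng, np.array([config.nuclear_size_cv]))[0]),
        )
        yfp = noisy * rfp + config.bleed_fraction * rfp
        rows.append(
            dict(
                disc_id=disc_id,
                cell_id=cell_id,
                x_px=x,
                y_px=y,
                section=0,
                cell_type=cell_type,
                yfp_mean=yfp,
                rfp_mean=rfp,
                nuclear_size_px=size,
            )
        )
        truth_rows.append(
            dict(
                cell_id=cell_id,
                cell_type=cell_type,
                true_time_hr=t,
                true_mean_level=level + config.bleed_fraction,
                true_cv=cv,
            )
        )
        cell_id += 1

    # R8s sit exactly on the lattice
    for x, y in lattice:
        emit(float(x), float(y), "R8")

    # progenitors: uniform over the disc, extending anterior of column 1 so
    # the induction baseline and rise are both sampled
    n_prog = config.n_columns * config.cells_per_column["progenitor"]
    n_total_est = n_prog + len(lattice) * 16
    occupancy = _Occupancy(lattice, len(lattice) + n_total_est)
    x_lo = x_c1 - 3.0 * config.column_spacing_px
    prog_xy = _scatter_positions(
        rng, n_prog, (x_lo, x_max), (y_lo, y_hi), min_sep, occupancy
    )
    for x, y in prog_xy:
        emit(float(x), float(y), "progenitor")

    # differentiating cells: recruited around each R8 once the column's time
    # has passed the type's onset
    per_r8 = {
        ct: max(1, config.cells_per_column.get(ct, 0) // n_rows)
        for ct in DIFFERENTIATING_TYPES
    }
    def place_near(rx: float, ry: float) -> Tuple[float, float]:
        """Offset position near an R8, respecting the minimum separation."""
        best, best_d = None, -1.0
        for _attempt in range(40):
            radius = rng.uniform(4.0, 18.0)
            theta = rng.uniform(0.0, 2.0 * math.pi)
            p = np.array([rx + radius * math.cos(theta), ry + radius * math.sin(theta)])
            d = occupancy.min_dist(p)
            if d >= min_sep:
                best = p
                break
            if d > best_d:
                best, best_d = p, d
        occupancy.add(best)
        return float(best[0]), float(best[1])

    for ct in DIFFERENTIATING_TYPES:
        n_per = per_r8[ct]
        if config.cells_per_column.get(ct, 0) <= 0:
            continue
        for rx, ry in lattice:
            t_col = hours_per_px * (rx - x_c1)
            if t_col < config.onset_hours[ct]:
                continue
            for _ in range(n_per):
                x, y = place_near(float(rx), float(ry))
                d = float(
                    np.min(np.hypot(lattice[:, 0] - x, lattice[:, 1] - y))
                )
                emit(x, y, ct, r8_dist=d)

    cells = pd.DataFrame(rows)
    cells["normalized_level"] = cells["yfp_mean"] / cells["rfp_mean"]
    truth = pd.DataFrame(truth_rows)
    sample = DiscSample(disc_id=disc_id, cells=cells, meta={"config": asdict(config)})
    return sample, GroundTruth(table=truth, r8_lattice=lattice, config=config)


def render_image(
    sample: DiscSample,
    pixel_size: float = 1.0,
    psf_sigma: float = 2.0,
    background: float = 5.0,
    seed: int = 0,
    pad_px: int = 12,
    noise: bool = True,
    return_origin: bool = False,
) -> Tuple[np.ndarray, np.ndarray]:
    """Render a two-channel (RFP, YFP) image plus an integer label mask.

    Each nucleus becomes a uniform disk at its channel mean intensity,
    blurred by a Gaussian point-spread function of width ``psf_sigma``,
    with Poisson-like (variance = mean) noise on top of a constant
    background.  Mask disks are clipped to half the distance to the nearest
    neighbour so labels never overlap; two coincident nuclei are an error.

    Returns ``(image, mask)`` with ``image`` of shape (2, H, W), channel
    order (RFP, YFP), float32, and ``mask`` of shape (H, W), int32, one
    positive id per nucleus (ids are ``cell_id + 1``).  With
    ``return_origin`` the disc-frame coordinates of image pixel (0, 0) are
    appended, so image-frame centroids map back to disc coordinates.
    """
    cells = sample.cells
    if len(cells) == 0:
        raise ValueError("cannot render an empty sample")
    xy = cells[["x_px", "y_px"]].to_numpy(dtype=float) / pixel_size
    x0, y0 = xy.min(axis=0) - pad_px
    xy = xy - np.array([x0, y0])
    w = int(np.ceil(xy[:, 0].max())) + pad_px
    h = int(np.ceil(xy[:, 1].max())) + pad_px

    from scipy.ndimage import gaussian_filter
    from scipy.spatial import cKDTree

    if len(xy) > 1:
        tree = cKDTree(xy)
        dnn, _ = tree.query(xy, k=2)
        nearest = dnn[:, 1]
        if np.any(nearest < 2.0):
            raise ValueError("two nuclei coincide; cannot assign disjoint mask ids")
    else:
        nearest = np.full(1, np.inf)

    radii = np.sqrt(cells["nuclear_size_px"].to_numpy(dtype=float) / math.pi)
    radii = np.minimum(radii / pixel_size, 0.5 * (nearest - 1.0))

    rng = np.random.default_rng(seed)
    img = np.zeros((2, h, w), dtype=np.float64)
    mask = np.zeros((h, w), dtype=np.int32)
    amps = cells[["rfp_mean", "yfp_mean"]].to_numpy(dtype=float)
    for i in range(len(cells)):
        cx, cy = xy[i]
        r = radii[i]
        ext = int(math.ceil(r)) + 1
        lo_y, hi_y = max(0, int(cy) - ext), min(h, int(cy) + ext + 1)
        lo_x, hi_x = max(0, int(cx) - ext), min(w, int(cx) + ext + 1)
        sub_y, sub_x = np.mgrid[lo_y:hi_y, lo_x:hi_x]
        d2 = (sub_x - cx) ** 2 + (sub_y - cy) ** 2
        disk = d2 <= r**2
        for c in range(2):
            img[c, lo_y:hi_y, lo_x:hi_x] += amps[i, c] * disk
        region = mask[lo_y:hi_y, lo_x:hi_x]
        if np.any(region[disk] > 0):
            raise RuntimeError("overlapping mask ids — internal geometry error")
        region[disk] = int(cells["cell_id"].iloc[i]) + 1
    if psf_sigma > 0:
        for c in range(2):
            img[c] = gaussian_filter(img[c], psf_sigma)
    img += background
    if noise:
        # Poisson-like shot noise: gaussian with variance equal to the mean
        img = img + rng.normal(0.0, 1.0, size=img.shape) * np.sqrt(
            np.clip(img, 0.0, None)
        )
    if return_origin:
        return img.astype(np.float32), mask, (float(x0), float(y0))
    return img.astype(np.float32), mask
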