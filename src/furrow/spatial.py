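"""Distance-to-R8 spatial correlation of differentiating-cell levels.

To test whether R2/R5 expression depends on proximity to the R8 that
recruited them, log-transformed levels are first detrended in x (a proxy
for developmental time) with LOESS — local second-degree polynomials,
tri-cube weighted neighbourhoods, smoothing parameter (span) 0.5 — so that
any correlation with distance is not confounded by the shared time trend.
The residuals are then correlated with each cell's Euclidean distance to
its nearest R8 centroid inside sliding windows spanning 12.5 hr of
developmental time: Pearson product-moment r, a two-sided p-value from the
t-test t = r sqrt((n-2)/(1-r^2)) under an uncorrelated bivariate normal
null, and the explained variance R^2 of the corresponding linear fit.

Detrending and distance calculation are performed per disc, then residuals
are pooled across replicates for the windowed correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)


class LoessDetrender(TransformerMixin, BaseEstimator):
    """LOESS smoother: local polynomials with tri-cube distance weights.

    Parameters
    ----------
    span : float
        Fraction of the data in each local neighbourhood (0 < span <= 1).
    degree : int
        Degree of the local polynomial (2 = local quadratics).

    ``fit(x, y)`` stores the training data; ``predict(x)`` evaluates the
    local fit at new points; ``transform(x, y)`` (or fit_transform)
    returns detrending residuals ``y - predict(x)``.
    """

    def __init__(self, span: float = 0.5, degree: int = 2):
        self.span = span
        self.degree = degree

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        yv = np.asarray(y, dtype=float).reshape(-1)
        if x.shape != yv.shape:
            raise ValueError("X and y must have the same length")
        if len(x) < max(10, self.degree + 2):
            raise ValueError("need at least 10 points for LOESS")
        if not 0.0 < self.span <= 1.0:
            raise ValueError("span must lie in (0, 1]")
        order = np.argsort(x, kind="stable")
        self.x_ = x[order]
        self.y_ = yv[order]
        self.q_ = max(self.degree + 1, int(np.ceil(self.span * len(x))))
        return self

    def predict(self, X):
        x0s = np.asarray(X, dtype=float).reshape(-1)
        out = np.empty_like(x0s)
        for i, x0 in enumerate(x0s):
            d = np.abs(self.x_ - x0)
            nn = np.argpartition(d, self.q_ - 1)[: self.q_]
            dn = d[nn]
            dmax = dn.max()
            if dmax <= 0:
                out[i] = self.y_[nn].mean()
                continue
            w = (1.0 - (dn / dmax) ** 3) ** 3
            w = np.clip(w, 0.0, None)
            # weighted polynomial fit, centred at x0 for conditioning
            coef = np.polyfit(
                self.x_[nn] - x0, self.y_[nn], self.degree, w=np.sqrt(w)
            )
            out[i] = np.polyval(coef, 0.0)
        return out

    def transform(self, X, y=None):
        if y is None:
            raise ValueError("transform needs y to compute residuals")
        return np.asarray(y, dtype=float).reshape(-1) - self.predict(X)

    def fit_transform(self, X, y):
        return self.fit(X, y).transform(X, y)


def loess_detrend(times, log_levels=None, levels=None, span: float = 0.5) -> np.ndarray:
    """Residuals of LOESS detrending on log-transformed levels.

    Pass either ``log_levels`` (already transformed) or raw positive
    ``levels`` (natural log applied here; nonpositive values are an
    error, not silently offset).
    """
    if (log_levels is None) == (levels is None):
        raise ValueError("pass exactly one of log_levels / levels")
    if levels is not None:
        lv = np.asarray(levels, dtype=float)
        if np.any(lv <= 0):
            raise ValueError("levels must be positive before log transform")
        log_levels = np.log(lv)
    return LoessDetrender(span=span, degree=2).fit_transform(times, log_levels)


def nearest_r8_distance(cell_positions, r8_positions) -> np.ndarray:
    """Euclidean distance from each cell centroid to its nearest R8.

    Ties resolve to the lower R8 index (argmin convention), which makes the
    assignment deterministic; the distance itself is unique regardless.
    """
    cells = np.atleast_2d(np.asarray(cell_positions, dtype=float))
    r8s = np.atleast_2d(np.asarray(r8_positions, dtype=float))
    if r8s.size == 0:
        raise ValueError("no R8 positions given")
    d = cdist(cells, r8s)
    return d[np.arange(len(cells)), d.argmin(axis=1)]


@dataclass
class CorrelationWindow:
    """Pearson correlation of residual level vs R8 distance in one window."""

    center_time_hr: float
    half_span_hr: float
    r: float
    p_value: float
    explained_variance: float
    n_cells: int


def windowed_correlation(
    residuals,
    distances,
    times,
    window_span_hr: float = 12.5,
    step_hr: float = 1.0,
    min_cells: int = 3,
) -> List[CorrelationWindow]:
    """Sliding-window Pearson correlation along developmental time.

    Windows span ``window_span_hr`` (12.5 hr by default) and advance by
    ``step_hr``; windows with fewer than ``min_cells`` cells are skipped
    with a logged warning.  ``explained_variance`` is r^2, the R^2 of the
    simple linear fit of residuals on distances.
    """
    res = np.asarray(residuals, dtype=float)
    dist = np.asarray(distances, dtype=float)
    t = np.asarray(times, dtype=float)
    if not (res.shape == dist.shape == t.shape):
        raise ValueError("residuals, distances and times must align")
    half = window_span_hr / 2.0
    if t.max() - t.min() < window_span_hr:
        centers = np.array([(t.max() + t.min()) / 2.0])
    else:
        centers = np.arange(t.min() + half, t.max() - half + 1e-9, step_hr)
    out: List[CorrelationWindow] = []
    for c in centers:
        sel = (t >= c - half) & (t <= c + half)
        n = int(sel.sum())
        if n < min_cells:
            logger.warning(
                "window at %.2f hr skipped: %d cells (< %d)", c, n, min_cells
            )
            continue
        x, y = dist[sel], res[sel]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            logger.warning("window at %.2f hr skipped: degenerate variance", c)
            continue
        r, p = stats.pearsonr(x, y)
        out.append(
            CorrelationWindow(
                center_time_hr=float(c),
                half_span_hr=half,
                r=float(r),
                p_value=float(p),
                explained_variance=float(r) ** 2,
                n_cells=n,
            )
        )
    return out
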