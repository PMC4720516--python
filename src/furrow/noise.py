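"""Expression-noise statistics over sliding cell windows.

Two scale-free statistics of cell-to-cell heterogeneity, computed over
windows of consecutive (time-sorted) cells:

* coefficient of variation, CV = sigma / mean of the measured levels in
  the window;
* detrended fluctuation: the standard deviation of residuals to a fitted
  trend (Hill during induction, exponential during decay), divided by the
  mean of the fitted trend inside the window — robust to the trend itself
  and, unlike the CV, largely insensitive to window width.

Sample (n-1) standard deviation throughout.  Windows slide by one cell;
edge windows shorter than the window size are dropped, never padded.
Default window sizes: 280 cells for progenitors, 70 for differentiating
cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Optional, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

#: Analysis window sizes (cells) per class.
PROGENITOR_WINDOW = 280
DIFFERENTIATING_WINDOW = 70


@dataclass
class NoiseProfile:
    """Noise value per sliding window, as a time profile."""

    times: np.ndarray
    values: np.ndarray
    window_cells: int
    method: str  # "CV" or "detrended_fluctuation"
    cell_type: Optional[str] = None


def _sorted_windows(times, levels, window_cells):
    t = np.asarray(times, dtype=float)
    y = np.asarray(levels, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise ValueError("times and levels must be equal-length 1-D arrays")
    if window_cells < 2:
        raise ValueError("window_cells must be >= 2")
    if len(t) < window_cells:
        raise ValueError(f"need at least window_cells={window_cells} records")
    order = np.argsort(t, kind="stable")
    t, y = t[order], y[order]
    return (
        sliding_window_view(t, window_cells),
        sliding_window_view(y, window_cells),
        t,
        y,
    )


def cv_profile(times, levels, window_cells: int, cell_type: Optional[str] = None) -> NoiseProfile:
    """Sliding-window coefficient of variation of the measured levels."""
    tw, yw, _, _ = _sorted_windows(times, levels, window_cells)
    means = yw.mean(axis=1)
    if np.any(means <= 0):
        raise ValueError("window with nonpositive mean level — CV undefined")
    sds = yw.std(axis=1, ddof=1)
    return NoiseProfile(
        times=tw.mean(axis=1),
        values=sds / means,
        window_cells=window_cells,
        method="CV",
        cell_type=cell_type,
    )


def detrended_fluctuation_profile(
    times,
    levels,
    fitted_curve: Callable[[np.ndarray], np.ndarray],
    window_cells: int,
    cell_type: Optional[str] = None,
) -> NoiseProfile:
    """Sliding-window SD of residuals to the trend, over the trend's mean.

    ``fitted_curve`` must be evaluable at every record's time (e.g. a
    :class:`~furrow.dynamics.HillFit` or :class:`~furrow.dynamics.DecayFit`).
    """
    tw, _, t, y = _sorted_windows(times, levels, window_cells)
    curve_vals = np.asarray(fitted_curve(t), dtype=float)
    resid = y - curve_vals
    rw = sliding_window_view(resid, window_cells)
    cw = sliding_window_view(curve_vals, window_cells)
    cmeans = cw.mean(axis=1)
    if np.any(cmeans <= 0):
        raise ValueError("window with nonpositive trend mean — statistic undefined")
    return NoiseProfile(
        times=tw.mean(axis=1),
        values=rw.std(axis=1, ddof=1) / cmeans,
        window_cells=window_cells,
        method="detrended_fluctuation",
        cell_type=cell_type,
    )


@dataclass
class Spike:
    """One transient elevation of a noise profile.

    ``peak_time_hr`` is the midpoint of the half-prominence interval — for
    the plateau-shaped spikes that wide heterogeneity windows produce, the
    summit sample is an arbitrary point inside the plateau while the
    interval midpoint tracks the elevation's true centre.  ``summit_time_hr``
    keeps the raw argmax location.
    """

    peak_time_hr: float
    peak_value: float
    width_hr: float  # full width at half prominence over baseline
    summit_time_hr: float = float("nan")


def _half_prominence_interval(times, values, peak_idx, half_level):
    n = len(values)
    left = times[0]
    for i in range(peak_idx, 0, -1):
        if values[i - 1] < half_level:
            # linear interpolation of the crossing
            f = (half_level - values[i - 1]) / (values[i] - values[i - 1])
            left = times[i - 1] + f * (times[i] - times[i - 1])
            break
    right = times[-1]
    for i in range(peak_idx, n - 1):
        if values[i + 1] < half_level:
            f = (half_level - values[i + 1]) / (values[i] - values[i + 1])
            right = times[i + 1] - f * (times[i + 1] - times[i])
            break
    return float(left), float(right)


def spike_summary(
    profile: NoiseProfile, baseline_quantile: float = 0.25
) -> Tuple[Optional[Spike], List[Spike]]:
    """Locate the dominant noise spike and any secondary peaks.

    The baseline is the given quantile of the profile values; the default
    0.25 tolerates elevations covering up to about half the profile.  The
    profile is lightly mean-smoothed before peak finding so that the
    sampling noise of small windows cannot masquerade as a spike.  Returns
    ``(primary, ranked)`` where ``primary`` is the dominant elevation (None
    if nothing exceeds the baseline) with its full width at half
    prominence, and ``ranked`` lists all distinct peaks above baseline in
    decreasing height order (primary first).
    """
    if len(profile.values) < 10:
        raise ValueError("profile too short to summarise (need >= 10 points)")
    t = np.asarray(profile.times, dtype=float)
    v = np.asarray(profile.values, dtype=float)
    m = max(5, len(v) // 10)
    if len(v) > 2 * m:  # centred running mean with edge renormalisation
        kern = np.ones(m)
        v = np.convolve(v, kern, mode="same") / np.convolve(
            np.ones_like(v), kern, mode="same"
        )
    baseline = float(np.quantile(v, baseline_quantile))
    if v.max() <= baseline or np.isclose(v.max(), baseline):
        return None, []

    from scipy.signal import find_peaks

    idx, props = find_peaks(v, height=baseline, prominence=0.0)
    gmax = int(np.argmax(v))
    if gmax not in idx:  # plateau or boundary maximum missed by find_peaks
        idx = np.append(idx, gmax)
    spikes = []
    for i in idx:
        half = baseline + (v[i] - baseline) / 2.0
        left, right = _half_prominence_interval(t, v, int(i), half)
        spikes.append(
            Spike(
                peak_time_hr=(left + right) / 2.0,
                peak_value=float(v[i]),
                width_hr=right - left,
                summit_time_hr=float(t[i]),
            )
        )
    spikes.sort(key=lambda s: -s.peak_value)
    # collapse peaks sharing one half-prominence interval (one elevation
    # sampled at several local summits)
    distinct: List[Spike] = []
    for s in spikes:
        if all(abs(s.peak_time_hr - d.peak_time_hr) > d.width_hr / 4.0 for d in distinct):
            distinct.append(s)
    return distinct[0], distinct
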