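"""Capillary-fouling detection and integral baseline correction.

Radiation-induced deposition of sample on the measurement capillary adds a
slowly growing spurious signal that does not return to baseline after the
elution: each exposed frame deposits material in proportion γ to the sample
scattering during that frame, so the spurious baseline B(q, t) is the
running integral of the true signal.  Given the final steady-state level
I_BL(q) — the average over a late frame window where only buffer (plus
accumulated deposits) flows — the correction is computed per q by a
fixed-point iteration: estimate the signal above the current baseline,
rescale its running sum so that it ends at I_BL, repeat.

The steady-state window itself is found by two sliding-window indicators:
the average red-cluster size of the window's pairwise CorMap P-value map
(compared against the same statistic on buffer-only frames) and the
windowed cumulative low-q intensity (its flatness and sign decide whether
an integral correction is warranted at all).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cormap import PairwiseOptions, pairwise_pvalue_map, red_cluster_stats
from .core_data import Chromatogram, SECSAXSDataset

__all__ = [
    "SteadyStateRegion",
    "BlankReference",
    "BaselineResult",
    "steady_state_average",
    "blank_reference",
    "find_best_region",
    "gaussian_smooth",
    "integral_baseline",
    "apply_integral_baseline",
    "linear_baseline",
]


@dataclass
class SteadyStateRegion:
    """A chosen steady-state stretch plus the sliding-window indicators."""

    t_s1: int
    t_sm: int
    window: int = 20
    start_frames: np.ndarray | None = None
    red_cluster_indicator: np.ndarray | None = None  # indicator 1 per window
    cumulative_mean: np.ndarray | None = None  # indicator 2 mean per window
    cumulative_sd: np.ndarray | None = None
    candidate: np.ndarray | None = None
    suggestion: str = ""


@dataclass
class BlankReference:
    """Window statistics of the average red-cluster size on buffer frames."""

    mean: float
    sd: float
    window: int
    opts: PairwiseOptions
    per_window: np.ndarray | None = None


@dataclass
class BaselineResult:
    """Per-q integral baseline with its convergence record."""

    q: np.ndarray
    I_BL: np.ndarray
    B: np.ndarray  # n_q x n_t baseline series
    gamma: np.ndarray
    iterations: np.ndarray
    skipped: np.ndarray  # negative-integral guard flags ("0s")
    epsilon: float = 0.0


def steady_state_average(ds: SECSAXSDataset, t_s1: int, t_sm: int) -> np.ndarray:
    """Per-q mean intensity over the frame-ordinal window [t_s1, t_sm]."""
    sel = (ds.frames >= t_s1) & (ds.frames <= t_sm)
    n = int(np.count_nonzero(sel))
    if n == 0:
        raise ValueError("steady-state region outside dataset")
    if n < 10:
        import warnings

        warnings.warn(
            f"steady-state region holds only {n} frames; at least 10 "
            "are recommended for a reliable I_BL",
            stacklevel=2,
        )
    return ds.I[:, sel].mean(axis=1)


def _window_red_cluster_sizes(ds: SECSAXSDataset, window: int,
                              opts: PairwiseOptions,
                              start_positions) -> np.ndarray:
    out = np.empty(len(start_positions))
    for k, j in enumerate(start_positions):
        curves = [ds.I[:, jj] for jj in range(j, j + window)]
        pmap = pairwise_pvalue_map(curves, q=ds.q, opts=opts)
        out[k] = red_cluster_stats(pmap).average_red_cluster_size
    return out


def blank_reference(blanks: SECSAXSDataset, window: int = 20,
                    opts: PairwiseOptions | None = None) -> BlankReference:
    """Mean/s.d. of average red-cluster size over all same-size windows of
    a buffer-only dataset, computed with the sample analysis options."""
    opts = opts or PairwiseOptions()
    n = blanks.n_frames
    if n < window:
        raise ValueError("buffer dataset shorter than the window")
    starts = range(0, n - window + 1)
    vals = _window_red_cluster_sizes(blanks, window, opts, starts)
    return BlankReference(
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        window=window,
        opts=opts,
        per_window=vals,
    )


def find_best_region(ds: SECSAXSDataset, blanks: BlankReference,
                     opts: PairwiseOptions | None = None, window: int = 20,
                     scan_range: tuple[int, int] | None = None) -> SteadyStateRegion:
    """Locate the final steady-state window and suggest a correction mode.

    For each candidate start frame the window's average red-cluster size
    (indicator 1) is compared against the buffer reference (candidate when
    within mean + 1 s.d.); indicator 2 is the windowed mean ± s.d. of the
    per-frame cumulative intensity over q ≤ q_max_cutoff.  The chosen
    region is the latest contiguous run of candidate windows, within which
    the flattest-indicator-2 window wins.  The suggestion is "integral
    baseline" when the minimum windowed cumulative intensity stays above
    zero, else "none/linear".
    """
    opts = opts or blanks.opts
    if window != blanks.window:
        raise ValueError("window size must match the blank reference")
    frames = ds.frames
    if scan_range is None:
        lo_pos, hi_pos = 0, ds.n_frames - 1
    else:
        sel = np.flatnonzero((frames >= scan_range[0]) & (frames <= scan_range[1]))
        if sel.size == 0:
            raise ValueError("scan range outside dataset")
        lo_pos, hi_pos = int(sel[0]), int(sel[-1])
    if hi_pos - lo_pos + 1 < window:
        raise ValueError("scan range shorter than the window")
    starts = np.arange(lo_pos, hi_pos - window + 2)

    ind1 = _window_red_cluster_sizes(ds, window, opts, starts)
    q_sel = ds.q <= opts.q_max_cutoff
    cum = ds.I[q_sel].sum(axis=0)  # per-frame cumulative low-q intensity
    ind2_mean = np.array([cum[j : j + window].mean() for j in starts])
    ind2_sd = np.array([cum[j : j + window].std(ddof=1) for j in starts])

    candidate = ind1 <= blanks.mean + blanks.sd
    if not np.any(candidate):
        raise ValueError(
            "no window matches the buffer similarity level; cannot "
            "identify a steady-state region"
        )
    # latest contiguous run of candidate windows
    idx = np.flatnonzero(candidate)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_start = idx[breaks[-1] + 1] if breaks.size else idx[0]
    run = idx[idx >= run_start]
    best = run[np.argmin(ind2_sd[run])]

    suggestion = (
        "integral baseline" if np.min(ind2_mean) > 0 else "none/linear"
    )
    return SteadyStateRegion(
        t_s1=int(frames[starts[best]]),
        t_sm=int(frames[starts[best] + window - 1]),
        window=window,
        start_frames=frames[starts],
        red_cluster_indicator=ind1,
        cumulative_mean=ind2_mean,
        cumulative_sd=ind2_sd,
        candidate=candidate,
        suggestion=suggestion,
    )


def _gaussian_kernel(points: int) -> np.ndarray:
    # support of `points` samples covering +-3 sigma
    sigma = (points - 1) / 6.0 if points > 1 else 1.0
    x = np.arange(points) - (points - 1) / 2.0
    w = np.exp(-0.5 * (x / sigma) ** 2)
    return w / w.sum()


def gaussian_smooth(c: Chromatogram, points: int = 7) -> Chromatogram:
    """Gaussian smoothing of a chromatogram (default 7-point kernel).

    Edges are handled by kernel renormalisation over the available
    support; sigma is left untouched (the smoothed copy only feeds the
    baseline computation, never the subtraction itself).
    """
    if points < 3 or points % 2 == 0:
        raise ValueError("points must be odd and >= 3")
    n = c.intensity.size
    if points > n:
        raise ValueError("kernel support exceeds series length")
    w = _gaussian_kernel(points)
    num = np.convolve(c.intensity, w, mode="same")
    den = np.convolve(np.ones(n), w, mode="same")
    return Chromatogram(c.q_value, c.t.copy(), num / den, c.sigma.copy())


def integral_baseline(intensity: np.ndarray, I_BL_q: float,
                      region_end_pos: int, epsilon: float = 0.0,
                      max_iter: int = 5):
    """Iterative integral baseline for one chromatogram.

    ``intensity`` is the (smoothed) I_q(t) series; deposits accumulate
    over positions 0..region_end_pos (the start of the steady-state
    region); the baseline is held at I_BL for later frames.  Each
    iteration estimates the signal above the current baseline, sets
    γ_i = I_BL / Σ(signal) and rebuilds the baseline as the running sum
    of γ_i·signal; iteration stops when max|ΔB| ≤ ε (default 0, i.e. run
    to the cap unless the baseline repeats exactly) or after
    ``max_iter`` rounds.

    Returns ``(B, gamma, iterations, skipped)``.  A non-positive signal
    integral trips the negative-integral guard: the row is flagged
    skipped and a zero baseline returned (subtracting would add signal).
    """
    y = np.asarray(intensity, dtype=float)
    n = y.size
    B = np.zeros(n)
    if I_BL_q <= 0:
        return B, 0.0, 0, False
    k_end = int(region_end_pos)
    if not 1 <= k_end < n:
        raise ValueError("region end outside the series")
    gamma = 0.0
    iterations = 0
    for i in range(max_iter):
        signal = y - B
        # deposit at t_k is proportional to the signal at t_{k-1};
        # the total over the elution region must integrate to I_BL
        S = float(np.sum(signal[:k_end]))
        if S <= 0:
            return np.zeros(n), 0.0, iterations, True
        gamma = I_BL_q / S
        B_new = np.zeros(n)
        B_new[1 : k_end + 1] = gamma * np.cumsum(signal[:k_end])
        B_new[k_end + 1 :] = B_new[k_end]
        iterations = i + 1
        delta = float(np.max(np.abs(B_new - B)))
        B = B_new
        if delta <= epsilon:
            break
    return B, gamma, iterations, False


def apply_integral_baseline(ds: SECSAXSDataset, region: SteadyStateRegion,
                            epsilon: float = 0.0, max_iter: int = 5,
                            smooth_points: int = 7):
    """Integral baseline correction of every chromatogram of a dataset.

    The baseline is computed on a Gaussian-smoothed copy of each
    chromatogram but subtracted from the original data; sigma is
    unchanged.  Rows with I_BL ≤ 0 need no correction; rows tripping the
    negative-integral guard pass through unchanged and are flagged
    (the '0s' convention).  Returns (corrected dataset, BaselineResult).
    """
    I_BL = steady_state_average(ds, region.t_s1, region.t_sm)
    pos_s1 = int(np.flatnonzero(ds.frames >= region.t_s1)[0])
    n_q, n_t = ds.I.shape
    B = np.zeros((n_q, n_t))
    gamma = np.zeros(n_q)
    iters = np.zeros(n_q, dtype=int)
    skipped = np.zeros(n_q, dtype=bool)
    for i in range(n_q):
        c = ds.chromatogram(i)
        y = gaussian_smooth(c, smooth_points).intensity if smooth_points else c.intensity
        B[i], gamma[i], iters[i], skipped[i] = integral_baseline(
            y, float(I_BL[i]), pos_s1, epsilon=epsilon, max_iter=max_iter
        )
    corrected = ds.copy()
    corrected.I = ds.I - B
    corrected.meta = dict(ds.meta)
    corrected.meta["baseline"] = {
        "method": "integral",
        "region": [region.t_s1, region.t_sm],
        "skipped_q": ds.q[skipped].tolist(),
        "suffix": "0s" if np.any(skipped) else "",
    }
    result = BaselineResult(
        q=ds.q.copy(), I_BL=I_BL, B=B, gamma=gamma,
        iterations=iters, skipped=skipped, epsilon=epsilon,
    )
    return corrected, result


def linear_baseline(c: Chromatogram, anchor_start: tuple[int, int],
                    anchor_end: tuple[int, int]) -> Chromatogram:
    """Subtract the straight line through two anchor windows' means.

    Suitable for simple drifting, not for capillary fouling.  Each anchor
    is a (first, last) frame-ordinal pair; the line passes through the
    (mean t, mean I) point of each window.
    """
    t = np.asarray(c.t, dtype=float)

    def _mean_point(window):
        sel = (c.t >= window[0]) & (c.t <= window[1])
        if not np.any(sel):
            raise ValueError(f"anchor window {window} outside chromatogram")
        return t[sel].mean(), c.intensity[sel].mean()

    t1, y1 = _mean_point(anchor_start)
    t2, y2 = _mean_point(anchor_end)
    if t1 == t2:
        raise ValueError("anchor windows have identical mean time")
    slope = (y2 - y1) / (t2 - t1)
    line = y1 + slope * (t - t1)
    return Chromatogram(c.q_value, c.t.copy(), c.intensity - line, c.sigma.copy())
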