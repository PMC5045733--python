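"""Concentration-detector trace handling and band-broadening correction.

A UV (or RI) chromatogram recorded downstream of the column probes a
different volume than the SAXS cell, so it is time-shifted and band-
broadened relative to the SAXS chromatograms.  The treatment here: align
the trace onto the SAXS frame grid, decompose it with the SAXS-optimised
peak set (centers allowed only a ±2% excursion, widths fixed by default,
distortions and areas free), then *reshape* each concentration peak onto
the corresponding SAXS peak shape while conserving its fitted area.  The
reshaped peaks assign a concentration to every frame, which in turn
normalises the back-generated per-species frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .core_data import SAXSFrame
from .decomposition import DecompositionModel
from .peak_shapes import PeakKind, PeakModel

__all__ = [
    "ConcentrationTrace",
    "SpeciesProperties",
    "align_trace",
    "suggest_shift",
    "fit_concentration",
    "reshape_concentration",
    "frame_concentrations",
    "normalize_frames",
]


@dataclass
class ConcentrationTrace:
    """A detector trace (time base, signal) with alignment metadata."""

    t: np.ndarray
    signal: np.ndarray
    shift: float = 0.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.t.size != self.signal.size:
            raise ValueError("time and signal lengths differ")
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("trace time base must be strictly increasing")


@dataclass
class SpeciesProperties:
    """Per-family optical/volumetric constants for mass conversion."""

    extinction_coefficient: float  # ml mg^-1 cm^-1 (or dn/dc)
    partial_specific_volume: float = 0.736  # ml g^-1

    def __post_init__(self) -> None:
        if self.extinction_coefficient <= 0:
            raise ValueError("extinction coefficient must be positive")
        if self.partial_specific_volume <= 0:
            raise ValueError("partial specific volume must be positive")


def suggest_shift(trace: ConcentrationTrace, ref_t, ref_I,
                  max_lag: int | None = None) -> float:
    """Cross-correlation lag (frames) aligning the trace to a reference
    chromatogram; positive shift means the trace lags the SAXS signal."""
    ref_t = np.asarray(ref_t, dtype=float)
    ref_I = np.asarray(ref_I, dtype=float)
    sig = np.interp(ref_t, trace.t, trace.signal, left=0.0, right=0.0)
    a = ref_I - ref_I.mean()
    b = sig - sig.mean()
    corr = np.correlate(a, b, mode="full")
    lags = np.arange(-ref_t.size + 1, ref_t.size)
    if max_lag is not None:
        keep = np.abs(lags) <= max_lag
        corr, lags = corr[keep], lags[keep]
    return float(lags[np.argmax(corr)])


def align_trace(trace: ConcentrationTrace, ref_t, shift: float = 0.0,
                scale: float = 1.0, min_overlap: float = 0.5) -> ConcentrationTrace:
    """Shift the trace and interpolate it linearly onto the SAXS frame grid.

    ``scale`` only rescales for display; fits use the raw signal units.
    Fails when fewer than ``min_overlap`` of the grid points fall inside
    the shifted trace support.
    """
    ref_t = np.asarray(ref_t, dtype=float)
    t_shifted = trace.t + shift
    inside = (ref_t >= t_shifted[0]) & (ref_t <= t_shifted[-1])
    if np.count_nonzero(inside) < min_overlap * ref_t.size:
        raise ValueError("insufficient overlap between trace and frame grid")
    sig = np.interp(ref_t, t_shifted, trace.signal, left=0.0, right=0.0)
    return ConcentrationTrace(ref_t.copy(), sig, shift=shift, scale=scale)


def fit_concentration(trace: ConcentrationTrace, saxs_model: DecompositionModel,
                      center_tolerance: float = 0.02,
                      widths_fixed: bool = True,
                      max_nfev: int = 2000):
    """Decompose a concentration trace with the SAXS-optimised peak set.

    Centers may move at most ``center_tolerance`` (relative, default 2%)
    from the SAXS values; widths stay fixed by default (widths and
    distortions are strongly coupled, and the SAXS shapes are the
    reference), distortions and areas are free.  Traces usually carry no
    σ, so the fit is unweighted and residuals are reported on an
    absolute scale.  Returns (peaks, report).
    """
    sh = saxs_model.shapes
    N = sh.n
    kind = saxs_model.kind
    t = trace.t
    y = trace.signal

    n_d = {PeakKind.GAUSS: 0, PeakKind.EMG: 1, PeakKind.GMG: 1,
           PeakKind.EMG_GMG: 2}[kind]

    # parameter vector: centers (N) [+ widths (N) if free] + distortions
    # (n_d per family) ; areas solved linearly (non-negative)
    x0 = [sh.centers.copy()]
    lb = [sh.centers * (1 - center_tolerance)]
    ub = [sh.centers * (1 + center_tolerance)]
    if not widths_fixed:
        x0.append(sh.widths.copy())
        lb.append(np.full(N, 1e-6))
        ub.append(np.full(N, (t[-1] - t[0])))
    if n_d >= 1:
        x0.append(sh.dist1.copy())
        lb.append(np.full(N, -(t[-1] - t[0])))
        ub.append(np.full(N, (t[-1] - t[0])))
    if n_d == 2:
        x0.append(sh.dist2.copy())
        lb.append(np.full(N, -(t[-1] - t[0])))
        ub.append(np.full(N, (t[-1] - t[0])))
    x0 = np.concatenate(x0)
    lb, ub = np.concatenate(lb), np.concatenate(ub)

    def unpack(x):
        pos = 0
        centers = x[pos : pos + N]; pos += N
        if widths_fixed:
            widths = sh.widths
        else:
            widths = x[pos : pos + N]; pos += N
        d1 = x[pos : pos + N] if n_d >= 1 else np.zeros(N)
        pos += N if n_d >= 1 else 0
        d2 = x[pos : pos + N] if n_d == 2 else np.zeros(N)
        return centers, widths, d1, d2

    def design(x):
        centers, widths, d1, d2 = unpack(x)
        return np.column_stack([
            PeakModel(kind, 1.0, centers[k], widths[k], d1[k], d2[k])(t)
            for k in range(N)
        ])

    def residual(x):
        D = design(x)
        a, _ = optimize.nnls(D, y)
        return D @ a - y

    res = optimize.least_squares(residual, np.clip(x0, lb, ub),
                                 bounds=(lb, ub), max_nfev=max_nfev)
    centers, widths, d1, d2 = unpack(res.x)
    D = design(res.x)
    areas, _ = optimize.nnls(D, y)
    peaks = [PeakModel(kind, areas[k], centers[k], widths[k], d1[k], d2[k])
             for k in range(N)]
    report = {
        "success": bool(res.success),
        "cost": float(res.cost),
        "nfev": int(res.nfev),
        "residual_abs_max": float(np.max(np.abs(res.fun))),
        "message": res.message,
    }
    return peaks, report


def reshape_concentration(conc_peaks, saxs_model: DecompositionModel):
    """Reshape concentration peaks onto the SAXS-optimised shapes.

    Each concentration family takes the corresponding SAXS family's
    center, width and distortions but keeps its OWN fitted area — the
    band-broadening correction.  Returns (reshaped peaks, reshaped trace
    evaluator) where the evaluator sums the reshaped families on any
    time grid.
    """
    sh = saxs_model.shapes
    if len(conc_peaks) != sh.n:
        raise ValueError("family count mismatch between concentration fit "
                         "and SAXS model")
    reshaped = [
        PeakModel(saxs_model.kind, conc_peaks[k].a0, sh.centers[k],
                  sh.widths[k], sh.dist1[k], sh.dist2[k])
        for k in range(sh.n)
    ]

    def trace_eval(t):
        t = np.asarray(t, dtype=float)
        return sum(p(t) for p in reshaped)

    return reshaped, trace_eval


def frame_concentrations(reshaped_peaks, species_props, frames,
                         pathlength_cm: float = 1.0) -> np.ndarray:
    """Per-(family, frame) concentrations in mg·ml⁻¹.

    c(family, t) = family signal(t) / (E · pathlength) with the signal in
    absorbance units (the RI branch passes dn/dc in place of E).
    """
    frames = np.asarray(frames, dtype=float)
    if len(reshaped_peaks) != len(species_props):
        raise ValueError("need one SpeciesProperties per family")
    out = np.zeros((len(reshaped_peaks), frames.size))
    for k, (peak, props) in enumerate(zip(reshaped_peaks, species_props)):
        out[k] = peak(frames) / (props.extinction_coefficient * pathlength_cm)
    return out


def normalize_frames(frames, c):
    """Divide frames by their per-frame concentrations and average.

    Returns (normalized frames, inverse-variance-weighted average frame).
    Fails on non-positive concentrations.
    """
    c = np.asarray(c, dtype=float)
    if len(frames) != c.size:
        raise ValueError("one concentration per frame required")
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")
    normed = [
        SAXSFrame(fr.q.copy(), fr.intensity / ci, fr.sigma / ci,
                  time_index=fr.time_index)
        for fr, ci in zip(frames, c)
    ]
    w = np.array([1.0 / np.maximum(fr.sigma, 1e-300) ** 2 for fr in normed])
    I = np.array([fr.intensity for fr in normed])
    W = w.sum(axis=0)
    avg_I = (w * I).sum(axis=0) / W
    avg_S = 1.0 / np.sqrt(W)
    avg = SAXSFrame(normed[0].q.copy(), avg_I, avg_S)
    return normed, avg
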