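"""Multi-peak decomposition of SEC-SAXS chromatogram sets.

Poorly resolved elution peaks are decomposed into N component "families",
each described by one peak shape (Gaussian, EMG, GMG or EMG+GMG) whose
center, width and distortions are *shared across all q values*, while the
per-q amplitudes (areas) are free.  The physical picture: each eluting
species has one elution profile in time, and its scattering form factor
only scales that profile differently at different q.

The workflow mirrors interactive practice: an SVD of the frame matrix
suggests the number of components; a single low-q chromatogram is fitted
to get starting shapes; the shapes initialise a global fit over a subset
of chromatograms (amplitudes re-solved linearly at every step — a
variable-projection scheme); the accepted shapes are then frozen and
amplitudes fitted for every q; finally per-species frames are
back-generated with propagated uncertainties.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .cormap import PairwiseOptions, cormap_pvalue
from .core_data import Chromatogram, SAXSFrame, SECSAXSDataset
from .peak_shapes import PeakKind, PeakModel, eval_peak

__all__ = [
    "DecompositionModel",
    "FitReport",
    "svd_rank",
    "default_fit_limits",
    "fit_single",
    "init_global",
    "global_fit",
    "fit_all_amplitudes",
    "goodness_by_q",
    "back_generate_frames",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1


def svd_rank(ds: SECSAXSDataset, frame_range: tuple[int, int] | None = None,
             max_suggest: int = 10):
    """Singular spectrum of the I(q, t) matrix and a suggested rank.

    The suggestion is the ratio-gap knee — the index after which the
    singular values drop most steeply — and is advisory only: the
    spectrum is returned in full so the user decides.
    """
    if frame_range is None:
        M = ds.I
    else:
        sel = (ds.frames >= frame_range[0]) & (ds.frames <= frame_range[1])
        if np.count_nonzero(sel) < 2:
            raise ValueError("degenerate frame range for SVD")
        M = ds.I[:, sel]
    s = np.linalg.svd(M, compute_uv=False)
    if s[0] == 0:
        raise ValueError("degenerate (zero) matrix")
    k = min(max_suggest, s.size - 1)
    tail = s[:k]
    ratios = tail / np.maximum(s[1 : k + 1], np.finfo(float).tiny * s[0])
    suggested = int(np.argmax(ratios)) + 1
    return s, suggested


def default_fit_limits(n_frames: int, margin: float = 0.05) -> tuple[int, int]:
    """Positional fit window excluding the first/last 5% of frames."""
    lo = int(np.floor(margin * n_frames))
    hi = n_frames - 1 - lo
    return lo, max(hi, lo + 1)


# ---------------------------------------------------------------------------
# shared-parameter packing


@dataclass
class _ShapeParams:
    """Shared shape parameters of N families (everything except areas)."""

    kind: PeakKind
    centers: np.ndarray
    widths: np.ndarray
    dist1: np.ndarray  # per family (tied entries equal)
    dist2: np.ndarray
    common_distortion: bool = True

    @property
    def n(self) -> int:
        return self.centers.size

    def peak(self, k: int, area: float = 1.0) -> PeakModel:
        return PeakModel(self.kind, area, self.centers[k], self.widths[k],
                         self.dist1[k], self.dist2[k])

    def design(self, t: np.ndarray) -> np.ndarray:
        """n_t × N matrix of unit-area family shapes."""
        return np.column_stack([self.peak(k)(t) for k in range(self.n)])

    # --- flat vector packing for the optimiser ---------------------------
    def _dist_slots(self) -> int:
        per = {PeakKind.GAUSS: 0, PeakKind.EMG: 1, PeakKind.GMG: 1,
               PeakKind.EMG_GMG: 2}[self.kind]
        return per * (1 if self.common_distortion else self.n)

    def pack(self) -> np.ndarray:
        v = [self.centers, self.widths]
        if self.kind in (PeakKind.EMG, PeakKind.EMG_GMG):
            v.append(self.dist1[:1] if self.common_distortion else self.dist1)
        if self.kind is PeakKind.GMG:
            v.append(self.dist1[:1] if self.common_distortion else self.dist1)
        if self.kind is PeakKind.EMG_GMG:
            v.append(self.dist2[:1] if self.common_distortion else self.dist2)
        return np.concatenate(v)

    def unpack(self, x: np.ndarray) -> "_ShapeParams":
        n = self.n
        centers = x[:n]
        widths = x[n : 2 * n]
        pos = 2 * n
        dist1 = np.zeros(n)
        dist2 = np.zeros(n)
        if self.kind in (PeakKind.EMG, PeakKind.GMG, PeakKind.EMG_GMG):
            w = 1 if self.common_distortion else n
            dist1 = np.full(n, x[pos]) if w == 1 else x[pos : pos + n].copy()
            pos += w
        if self.kind is PeakKind.EMG_GMG:
            w = 1 if self.common_distortion else n
            dist2 = np.full(n, x[pos]) if w == 1 else x[pos : pos + n].copy()
            pos += w
        return _ShapeParams(self.kind, centers.copy(), widths.copy(),
                            dist1, dist2, self.common_distortion)

    def bounds(self, t_lo: float, t_hi: float,
               extra: dict | None = None):
        """Box bounds: centers confined to non-crossing intervals, widths
        positive, distortions loosely bounded by the time span."""
        n = self.n
        c = self.centers
        span = t_hi - t_lo
        mids = (c[:-1] + c[1:]) / 2.0
        lo_c = np.concatenate([[t_lo], mids])
        hi_c = np.concatenate([mids, [t_hi]])
        lo_w = np.full(n, 1e-3 * span / max(n, 1))
        hi_w = np.full(n, span)
        lo, hi = [lo_c, lo_w], [hi_c, hi_w]
        n_d = self._dist_slots()
        if n_d:
            lo.append(np.full(n_d, -span))
            hi.append(np.full(n_d, span))
        lo, hi = np.concatenate(lo), np.concatenate(hi)
        if extra:
            for idx, (l, h) in extra.items():
                lo[idx], hi[idx] = l, h
        return lo, hi


@dataclass
class DecompositionModel:
    """N peak families with shared shapes and per-q amplitudes."""

    kind: PeakKind
    shapes: _ShapeParams
    q: np.ndarray  # q values carrying amplitudes
    amplitudes: np.ndarray  # n_q x N, >= 0
    fit_limits: tuple[int, int]  # positional frame window
    common_distortion: bool = True
    meta: dict = field(default_factory=dict)

    @property
    def n_families(self) -> int:
        return self.shapes.n

    def peaks_for_q(self, i_q: int) -> list[PeakModel]:
        return [self.shapes.peak(k, self.amplitudes[i_q, k])
                for k in range(self.n_families)]

    def evaluate(self, i_q: int, t: np.ndarray) -> np.ndarray:
        D = self.shapes.design(np.asarray(t, dtype=float))
        return D @ self.amplitudes[i_q]

    def surface(self, t: np.ndarray) -> np.ndarray:
        """Full n_q × n_t model surface."""
        D = self.shapes.design(np.asarray(t, dtype=float))
        return self.amplitudes @ D.T


@dataclass
class FitReport:
    q: np.ndarray
    chi2: np.ndarray
    pvalues: np.ndarray
    cost: float = np.nan
    success: bool = True
    message: str = ""
    nfev: int = 0
    condition_number: float = np.nan


# ---------------------------------------------------------------------------
# fitting


def _solve_amplitudes(D: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Non-negative weighted linear solve for one chromatogram."""
    a, _ = optimize.nnls(D * w[:, None], y * w)
    return a


def fit_single(c: Chromatogram, n_peaks: int, kind: PeakKind | str,
               init_centers, common_distortion: bool = True,
               fit_limits: tuple[int, int] | None = None,
               init_widths=None, init_distortion: float = 0.0,
               max_nfev: int = 2000):
    """Weighted nonlinear least squares of one chromatogram.

    ``init_centers`` provides the N starting centers (user picks or
    automatic local maxima); distortions are tied across peaks unless
    released.  Returns (peaks, report); on non-convergence the
    best-so-far parameters are kept and reported.
    """
    kind = PeakKind(kind)
    init_centers = np.sort(np.asarray(init_centers, dtype=float))
    if n_peaks <= 0:
        raise ValueError("n_peaks must be positive")
    if init_centers.size != n_peaks:
        raise ValueError("need one initial center per peak")
    t = np.asarray(c.t, dtype=float)
    if fit_limits is None:
        fit_limits = default_fit_limits(t.size)
    lo, hi = fit_limits
    tt = t[lo : hi + 1]
    y = c.intensity[lo : hi + 1]
    sig = c.sigma[lo : hi + 1]
    w = np.where(sig > 0, 1.0 / sig, 1.0)

    if init_widths is None:
        span = tt[-1] - tt[0]
        init_widths = np.full(n_peaks, span / (6.0 * n_peaks))
    else:
        init_widths = np.asarray(init_widths, dtype=float)
    d0 = init_distortion if kind is not PeakKind.GAUSS else 0.0
    shapes0 = _ShapeParams(
        kind, init_centers, init_widths,
        np.full(n_peaks, d0), np.full(n_peaks, d0), common_distortion,
    )

    def residual(x):
        sp = shapes0.unpack(x)
        D = sp.design(tt)
        a = _solve_amplitudes(D, y, w)
        return (D @ a - y) * w

    x0 = shapes0.pack()
    lb, ub = shapes0.bounds(float(t[0]), float(t[-1]))
    # distortion starting exactly at a bound edge is fine; at 0 it must not
    # sit outside [lb, ub]
    x0 = np.clip(x0, lb, ub)
    res = optimize.least_squares(residual, x0, bounds=(lb, ub),
                                 x_scale="jac", max_nfev=max_nfev)
    shapes = shapes0.unpack(res.x)
    D = shapes.design(tt)
    a = _solve_amplitudes(D, y, w)
    peaks = [shapes.peak(k, a[k]) for k in range(n_peaks)]
    report = {
        "success": bool(res.success),
        "cost": float(res.cost),
        "nfev": int(res.nfev),
        "message": res.message,
        "fit_limits": fit_limits,
    }
    return peaks, report


def _model_from_peaks(peaks, q, fit_limits, common_distortion) -> DecompositionModel:
    kind = peaks[0].kind
    shapes = _ShapeParams(
        kind,
        np.array([p.a1 for p in peaks]),
        np.array([p.a2 for p in peaks]),
        np.array([p.a3 for p in peaks]),
        np.array([p.a4 for p in peaks]),
        common_distortion,
    )
    q = np.asarray(q, dtype=float)
    amps = np.zeros((q.size, len(peaks)))
    return DecompositionModel(kind, shapes, q, amps, fit_limits,
                              common_distortion)


def init_global(peaks, ds: SECSAXSDataset, q_indices=None,
                fit_limits: tuple[int, int] | None = None,
                common_distortion: bool = True) -> DecompositionModel:
    """Initialise a global model: shapes copied from a single-chromatogram
    fit, per-q amplitudes solved by (non-negative) linear least squares.

    ``q_indices`` selects the chromatogram subset (e.g. every fourth q);
    default is all rows.  A large design-matrix condition number —
    collinear peak shapes — is recorded in the model metadata.
    """
    if q_indices is None:
        q_indices = np.arange(ds.n_q)
    q_indices = np.asarray(q_indices, dtype=int)
    if fit_limits is None:
        fit_limits = default_fit_limits(ds.n_frames)
    model = _model_from_peaks(peaks, ds.q[q_indices], fit_limits,
                              common_distortion)
    lo, hi = fit_limits
    tt = ds.frames[lo : hi + 1].astype(float)
    D = model.shapes.design(tt)
    cond = float(np.linalg.cond(D))
    for row, i_q in enumerate(q_indices):
        y = ds.I[i_q, lo : hi + 1]
        sig = ds.S[i_q, lo : hi + 1]
        w = np.where(sig > 0, 1.0 / sig, 1.0)
        model.amplitudes[row] = _solve_amplitudes(D, y, w)
    model.meta["q_indices"] = q_indices.tolist()
    model.meta["design_condition_number"] = cond
    return model


def _stack_residuals(shapes: _ShapeParams, ds, q_indices, lo, hi):
    tt = ds.frames[lo : hi + 1].astype(float)
    D = shapes.design(tt)
    res = []
    amps = np.zeros((len(q_indices), shapes.n))
    for row, i_q in enumerate(q_indices):
        y = ds.I[i_q, lo : hi + 1]
        sig = ds.S[i_q, lo : hi + 1]
        w = np.where(sig > 0, 1.0 / sig, 1.0)
        a = _solve_amplitudes(D, y, w)
        amps[row] = a
        res.append((D @ a - y) * w)
    return np.concatenate(res), amps


def global_fit(model: DecompositionModel, ds: SECSAXSDataset,
               q_indices=None, bounds_override: dict | None = None,
               max_nfev: int = 200,
               distortion_starts=None,
               pvalue_opts: PairwiseOptions | None = None):
    """Joint weighted least squares over the selected chromatograms.

    Shared centers/widths (and distortions, tied across families by
    default) are optimised; amplitudes are re-solved linearly per q at
    every step, so the problem size stays that of the shared parameters
    (variable projection).  ``bounds_override`` maps packed-parameter
    index → (lo, hi) for user range constraints.

    The EMG+GMG hybrid has a known soft direction trading the two
    distortions against the widths; ``distortion_starts`` — an iterable
    of (a3, a4) (or (a3,)) initial values — runs one fit from each start
    deterministically and keeps the lowest-cost solution.  Default is a
    single fit from the model's own distortions.  Returns the refined
    model plus a per-q FitReport.
    """
    if q_indices is None:
        q_indices = np.asarray(model.meta.get("q_indices",
                                              np.arange(ds.n_q)), dtype=int)
    q_indices = np.asarray(q_indices, dtype=int)
    lo, hi = model.fit_limits

    shapes0 = model.shapes

    def residual(x):
        r, _ = _stack_residuals(shapes0.unpack(x), ds, q_indices, lo, hi)
        return r

    lb, ub = shapes0.bounds(float(ds.frames[0]), float(ds.frames[-1]),
                            extra=bounds_override)

    starts = [shapes0.pack()]
    if distortion_starts is not None:
        n = shapes0.n
        base = 2 * n  # distortion slots start here in the packed vector
        starts = []
        for d in distortion_starts:
            x = shapes0.pack()
            for k, v in enumerate(np.atleast_1d(np.asarray(d, dtype=float))):
                w = 1 if shapes0.common_distortion else n
                x[base + k * w : base + (k + 1) * w] = v
            starts.append(x)
    res = None
    for x0 in starts:
        r = optimize.least_squares(residual, np.clip(x0, lb, ub),
                                   bounds=(lb, ub), x_scale="jac",
                                   max_nfev=max_nfev)
        if res is None or r.cost < res.cost:
            res = r
    shapes = shapes0.unpack(res.x)
    _, amps = _stack_residuals(shapes, ds, q_indices, lo, hi)
    refined = DecompositionModel(
        model.kind, shapes, ds.q[q_indices].copy(), amps, model.fit_limits,
        model.common_distortion, dict(model.meta),
    )
    refined.meta["q_indices"] = q_indices.tolist()
    report = goodness_by_q(refined, ds, q_indices=q_indices,
                           opts=pvalue_opts)
    report.cost = float(res.cost)
    report.success = bool(res.success)
    report.message = res.message
    report.nfev = int(res.nfev)
    return refined, report


def fit_all_amplitudes(model: DecompositionModel,
                       ds: SECSAXSDataset) -> DecompositionModel:
    """Extend amplitude-only linear fits to every q of the dataset, using
    the shared shapes of a converged global fit."""
    full = init_global(
        [model.shapes.peak(k) for k in range(model.n_families)],
        ds, q_indices=np.arange(ds.n_q), fit_limits=model.fit_limits,
        common_distortion=model.common_distortion,
    )
    full.meta.update({k: v for k, v in model.meta.items()
                      if k not in full.meta})
    return full


def goodness_by_q(model: DecompositionModel, ds: SECSAXSDataset,
                  q_indices=None,
                  opts: PairwiseOptions | None = None) -> FitReport:
    """Per-q χ² and CorMap P value of data vs fit within the fit limits."""
    if q_indices is None:
        q_indices = np.asarray(model.meta.get("q_indices",
                                              np.arange(ds.n_q)), dtype=int)
    q_indices = np.asarray(q_indices, dtype=int)
    lo, hi = model.fit_limits
    tt = ds.frames[lo : hi + 1].astype(float)
    D = model.shapes.design(tt)
    chi2 = np.zeros(q_indices.size)
    pvals = np.zeros(q_indices.size)
    n_pts = tt.size
    for row, i_q in enumerate(q_indices):
        y = ds.I[i_q, lo : hi + 1]
        sig = ds.S[i_q, lo : hi + 1]
        fit = D @ model.amplitudes[row]
        w = np.where(sig > 0, 1.0 / sig, 1.0)
        dof = max(n_pts - model.n_families, 1)
        chi2[row] = float(np.sum(((y - fit) * w) ** 2) / dof)
        pvals[row] = cormap_pvalue(
            y, fit, opts=opts or PairwiseOptions(q_max_cutoff=np.inf)
        )
    return FitReport(q=ds.q[q_indices].copy(), chi2=chi2, pvalues=pvals)


def back_generate_frames(model: DecompositionModel, ds: SECSAXSDataset,
                         peak_index: int,
                         frame_range: tuple[int, int] | None = None,
                         fit_error_fraction: float = 0.0) -> list[SAXSFrame]:
    """Reconstruct per-species I_t(q) frames from a full-q model.

    For each frame t and q: intensity = family shape at t × that q's
    amplitude.  The original per-point σ is reassigned unchanged; with
    ``fit_error_fraction`` > 0, a fraction of the local data-vs-fit
    discrepancy — apportioned by the family's share of the total model
    intensity at that point — is added in quadrature.
    """
    if model.amplitudes.shape[0] != ds.n_q:
        raise ValueError("model must carry amplitudes for every q "
                         "(run fit_all_amplitudes first)")
    if not 0 <= peak_index < model.n_families:
        raise IndexError("peak index out of range")
    if frame_range is None:
        sel = np.arange(ds.n_frames)
    else:
        sel = np.flatnonzero((ds.frames >= frame_range[0])
                             & (ds.frames <= frame_range[1]))
    t = ds.frames.astype(float)
    D = model.shapes.design(t)  # n_t x N
    total = model.amplitudes @ D.T  # n_q x n_t
    fam = np.outer(model.amplitudes[:, peak_index], D[:, peak_index])
    frames = []
    for j in sel:
        inten = fam[:, j]
        sigma = ds.S[:, j].copy()
        if fit_error_fraction > 0:
            with np.errstate(divide="ignore", invalid="ignore"):
                share = np.where(total[:, j] > 0, inten / total[:, j], 0.0)
            extra = fit_error_fraction * np.abs(ds.I[:, j] - total[:, j]) * share
            sigma = np.sqrt(sigma**2 + extra**2)
        frames.append(SAXSFrame(ds.q.copy(), inten, sigma,
                                time_index=int(ds.frames[j])))
    return frames


# ---------------------------------------------------------------------------
# persistence


def save_model(model: DecompositionModel, path) -> None:
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "kind": model.kind.value,
        "common_distortion": model.common_distortion,
        "centers": model.shapes.centers.tolist(),
        "widths": model.shapes.widths.tolist(),
        "dist1": model.shapes.dist1.tolist(),
        "dist2": model.shapes.dist2.tolist(),
        "q": model.q.tolist(),
        "amplitudes": model.amplitudes.tolist(),
        "fit_limits": list(model.fit_limits),
        "meta": model.meta,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_model(path) -> DecompositionModel:
    with open(path) as fh:
        doc = json.load(fh)
    version = doc.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {version!r}")
    try:
        kind = PeakKind(doc["kind"])
    except ValueError:
        raise ValueError(f"unknown peak kind tag {doc['kind']!r}") from None
    centers = np.asarray(doc["centers"], dtype=float)
    shapes = _ShapeParams(
        kind,
        centers,
        np.asarray(doc["widths"], dtype=float),
        np.asarray(doc["dist1"], dtype=float),
        np.asarray(doc.get("dist2", np.zeros_like(centers)), dtype=float),
        doc["common_distortion"],
    )
    return DecompositionModel(
        kind, shapes,
        np.asarray(doc["q"], dtype=float),
        np.asarray(doc["amplitudes"], dtype=float),
        tuple(doc["fit_limits"]),
        doc["common_distortion"],
        doc.get("meta", {}),
    )
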