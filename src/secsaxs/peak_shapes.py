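"""Elution-peak shape functions for chromatogram decomposition.

Four peak shapes are supported, all parametrised so that ``a0`` is the peak
area, ``a1`` the center and ``a2`` the width (all on the frame-index axis):

* ``GAUSS`` — the classical symmetric Gaussian,
* ``EMG`` — the exponentially modified Gaussian, a Gaussian convolved with a
  one-sided exponential of time constant ``a3`` (sign selects tailing vs
  fronting),
* ``GMG`` — the half-Gaussian modified Gaussian, a Gaussian convolved with a
  half-Gaussian of width ``a3``,
* ``EMG_GMG`` — the equal-weight average of an EMG (distortion ``a3``) and a
  GMG (distortion ``a4``) sharing one (a0, a1, a2) triple.

The EMG and GMG closed forms follow the canonical chromatographic
convolution expressions; the EMG is evaluated through the scaled
complementary error function so that it stays finite far into the wings.
The EMG+GMG hybrid as an equal-weight average of the two kernels is a
convention choice (the common commercial-package one) and is documented as
such in the methods note.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import integrate, special

__all__ = [
    "PeakKind",
    "PeakModel",
    "eval_gaussian",
    "eval_emg",
    "eval_gmg",
    "eval_emg_gmg",
    "eval_peak",
    "peak_area",
    "save_peaks",
    "load_peaks",
]

_SQRT2 = math.sqrt(2.0)
_SQRT2PI = math.sqrt(2.0 * math.pi)

#: below this fraction of a2, an EMG distortion is numerically
#: indistinguishable from zero and the Gaussian limit is evaluated instead
EMG_DISTORTION_CUTOFF = 1e-4


class PeakKind(str, enum.Enum):
    GAUSS = "GAUSS"
    EMG = "EMG"
    GMG = "GMG"
    EMG_GMG = "EMG_GMG"

    @property
    def n_params(self) -> int:
        return {"GAUSS": 3, "EMG": 4, "GMG": 4, "EMG_GMG": 5}[self.value]


def _check_width(a2: float) -> None:
    if not a2 > 0:
        raise ValueError(f"peak width a2 must be > 0, got {a2}")


def eval_gaussian(t, a0: float, a1: float, a2: float):
    """Symmetric Gaussian of area ``a0``, center ``a1`` and width ``a2``."""
    _check_width(a2)
    t = np.asarray(t, dtype=float)
    z = (t - a1) / a2
    return a0 / (_SQRT2PI * a2) * np.exp(-0.5 * z * z)


def eval_emg(t, a0: float, a1: float, a2: float, a3: float):
    """Exponentially modified Gaussian.

    ``a3`` is the exponential time constant; ``a3 > 0`` produces a tailing
    peak, ``a3 < 0`` a fronting one (mirror image).  The first moment is
    ``a1 + a3``.  ``|a3| < EMG_DISTORTION_CUTOFF * a2`` routes to the
    Gaussian limit to avoid catastrophic cancellation.
    """
    _check_width(a2)
    t = np.asarray(t, dtype=float)
    if abs(a3) < EMG_DISTORTION_CUTOFF * a2:
        return eval_gaussian(t, a0, a1, a2)
    if a3 < 0:
        # fronting peak = mirror of the tailing one about the center
        return eval_emg(2.0 * a1 - t, a0, a1, a2, -a3)
    u = t - a1
    # z is the erfc argument of the standard EMG expression
    z = (a2 / a3 - u / a2) / _SQRT2
    out = np.empty_like(u)
    pos = z >= 0
    # stable branch: erfc(z) = erfcx(z) exp(-z^2) collapses the exponent
    # to the plain Gaussian one
    out[pos] = special.erfcx(z[pos]) * np.exp(-0.5 * (u[pos] / a2) ** 2)
    # for z < 0 the direct exponent is provably <= -a2^2/(2 a3^2): no overflow
    zn = z[~pos]
    out[~pos] = special.erfc(zn) * np.exp(
        0.5 * (a2 / a3) ** 2 - u[~pos] / a3
    )
    return a0 / (2.0 * a3) * out


def eval_gmg(t, a0: float, a1: float, a2: float, a3: float):
    """Half-Gaussian modified Gaussian (Gaussian ⊗ half-Gaussian).

    ``a3`` is the half-Gaussian width; its sign selects the tailing side.
    ``a3 = 0`` reduces exactly to the symmetric Gaussian.
    """
    _check_width(a2)
    t = np.asarray(t, dtype=float)
    if a3 == 0.0:
        return eval_gaussian(t, a0, a1, a2)
    u = t - a1
    s2 = a2 * a2 + a3 * a3
    core = a0 / math.sqrt(2.0 * math.pi * s2) * np.exp(-0.5 * u * u / s2)
    return core * (1.0 + special.erf(a3 * u / (_SQRT2 * a2 * math.sqrt(s2))))


def eval_emg_gmg(t, a0: float, a1: float, a2: float, a3: float, a4: float):
    """Hybrid EMG+GMG: ½·EMG(a0,a1,a2,a3) + ½·GMG(a0,a1,a2,a4)."""
    _check_width(a2)
    return 0.5 * (eval_emg(t, a0, a1, a2, a3) + eval_gmg(t, a0, a1, a2, a4))


@dataclass
class PeakModel:
    """One elution component: shape kind plus parameters a0..a4.

    a0 — area (intensity·frames); a1 — center (frames); a2 — width
    (frames, > 0); a3 — first distortion; a4 — second distortion
    (EMG_GMG only).
    """

    kind: PeakKind
    a0: float
    a1: float
    a2: float
    a3: float = 0.0
    a4: float = 0.0

    def __post_init__(self) -> None:
        self.kind = PeakKind(self.kind)
        _check_width(self.a2)

    @property
    def params(self) -> tuple[float, ...]:
        return (self.a0, self.a1, self.a2, self.a3, self.a4)[: self.kind.n_params]

    def __call__(self, t):
        return eval_peak(t, self.kind, *self.params)

    def unit(self) -> "PeakModel":
        """Same shape with unit area."""
        p = list(self.params)
        p[0] = 1.0
        return PeakModel(self.kind, *p)


def eval_peak(t, kind: PeakKind | str, *params: float):
    kind = PeakKind(kind)
    if kind is PeakKind.GAUSS:
        return eval_gaussian(t, *params)
    if kind is PeakKind.EMG:
        return eval_emg(t, *params)
    if kind is PeakKind.GMG:
        return eval_gmg(t, *params)
    return eval_emg_gmg(t, *params)


def peak_area(peak: PeakModel, support: tuple[float, float] | None = None):
    """Adaptive quadrature of a peak shape.

    Returns ``(area, relative deviation from a0)``.  The default support
    spans ±12 effective widths around the center, which is ample for every
    supported shape.
    """
    if support is None:
        w = peak.a2 + abs(peak.a3) + abs(peak.a4)
        support = (peak.a1 - 12.0 * w, peak.a1 + 12.0 * w)
    lo, hi = support
    span = hi - lo
    if span < 8.0 * peak.a2:
        raise ValueError("integration support must cover at least 8 widths")
    area, _ = integrate.quad(lambda x: float(peak(x)), lo, hi, limit=400)
    if not math.isfinite(area):
        raise FloatingPointError("non-finite peak evaluation in quadrature")
    rel = abs(area - peak.a0) / peak.a0 if peak.a0 else abs(area)
    return area, rel


def save_peaks(peaks: Sequence[PeakModel], path) -> None:
    """Write peaks as plain text, one per line: kind a0 a1 a2 [a3 [a4]]."""
    with open(path, "w") as fh:
        for p in peaks:
            vals = " ".join(repr(float(v)) for v in p.params)
            fh.write(f"{p.kind.value} {vals}\n")


def load_peaks(path) -> list[PeakModel]:
    peaks = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tok = line.split()
            kind = PeakKind(tok[0])
            vals = [float(v) for v in tok[1:]]
            if len(vals) != kind.n_params:
                raise ValueError(
                    f"{kind.value} expects {kind.n_params} parameters, "
                    f"got {len(vals)}"
                )
            peaks.append(PeakModel(kind, *vals))
    return peaks
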