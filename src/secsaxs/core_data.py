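"""Data model and I/O for SEC-SAXS frame series.

A SEC-SAXS experiment yields a time-ordered series of background-subtracted
1-D scattering profiles I_t(q), conventionally stored as 3-column ASCII
tables (q in Å⁻¹, intensity, standard deviation).  The central container is
:class:`SECSAXSDataset`, an n_q × n_t intensity matrix plus matching sigma
matrix on one shared q grid — the pivot between the *frame* view (columns,
one scattering curve per exposure) and the *chromatogram* view (rows, the
time profile of the intensity at one fixed q).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SAXSFrame",
    "SECSAXSDataset",
    "Chromatogram",
    "load_frames",
    "write_frames",
    "transpose_dataset",
    "trim_noise_chromatograms",
    "export_csv",
    "import_csv",
]

#: relative tolerance for declaring two q grids identical
Q_GRID_RTOL = 1e-8


def _validate_grid(q: np.ndarray) -> None:
    if q.ndim != 1 or q.size < 1:
        raise ValueError("q grid must be a non-empty 1-D array")
    if not np.all(np.diff(q) > 0):
        raise ValueError("non-monotone q")


@dataclass
class SAXSFrame:
    """One scattering curve I(q) with per-point standard deviations."""

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray
    time_index: int = 0
    time: float | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        _validate_grid(self.q)
        if not (len(self.q) == len(self.intensity) == len(self.sigma)):
            raise ValueError("q, intensity and sigma must have equal length")
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be non-negative")


@dataclass
class Chromatogram:
    """Time profile I_q(t) of the intensity at one fixed q."""

    q_value: float
    t: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (len(self.t) == len(self.intensity) == len(self.sigma)):
            raise ValueError("t, intensity and sigma must have equal length")


@dataclass
class SECSAXSDataset:
    """The I(q, t) matrix: shared q grid, frame ordinals, I and sigma."""

    q: np.ndarray
    frames: np.ndarray  # strictly increasing frame ordinals
    I: np.ndarray  # n_q x n_t
    S: np.ndarray  # n_q x n_t
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.frames = np.asarray(self.frames, dtype=int)
        self.I = np.asarray(self.I, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        _validate_grid(self.q)
        n_q, n_t = self.I.shape
        if self.S.shape != (n_q, n_t):
            raise ValueError("I and S shapes differ")
        if self.q.size != n_q or self.frames.size != n_t:
            raise ValueError("matrix shape inconsistent with q grid / frames")
        if self.frames.size > 1 and not np.all(np.diff(self.frames) > 0):
            raise ValueError("frame indices must be strictly increasing")

    @property
    def n_q(self) -> int:
        return self.q.size

    @property
    def n_frames(self) -> int:
        return self.frames.size

    def frame(self, t: int) -> SAXSFrame:
        """The frame with ordinal ``t`` (not positional index)."""
        (pos,) = np.where(self.frames == t)
        if pos.size == 0:
            raise KeyError(f"no frame with ordinal {t}")
        j = int(pos[0])
        return SAXSFrame(self.q, self.I[:, j], self.S[:, j], time_index=t)

    def chromatogram(self, i_q: int) -> Chromatogram:
        return Chromatogram(
            q_value=float(self.q[i_q]),
            t=self.frames.copy(),
            intensity=self.I[i_q].copy(),
            sigma=self.S[i_q].copy(),
        )

    def copy(self) -> "SECSAXSDataset":
        return SECSAXSDataset(
            self.q.copy(), self.frames.copy(), self.I.copy(), self.S.copy(),
            dict(self.meta),
        )


_TRAILING_INT = re.compile(r"(\d+)(?=\D*$)")


def _frame_ordinal(path: Path, fallback: int) -> int:
    m = _TRAILING_INT.search(path.stem)
    return int(m.group(1)) if m else fallback


def _read_frame_file(path: Path, sigma_fill: tuple[float, float] | None):
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] < 2:
        raise ValueError(f"{path}: fewer than 2 numeric columns")
    q = data[:, 0]
    I = data[:, 1]
    _validate_grid(q)
    if data.shape[1] >= 3:
        sigma = data[:, 2]
    elif sigma_fill is not None:
        k, floor = sigma_fill
        sigma = k * np.sqrt(np.maximum(I, floor))
    else:
        raise ValueError(
            f"{path}: no sigma column; pass sigma_fill=(k, floor) to fill "
            "with k*sqrt(max(I, floor))"
        )
    return q, I, sigma


def load_frames(paths, sigma_fill: tuple[float, float] | None = None,
                manifest_order: bool = False) -> SECSAXSDataset:
    """Load a series of 3-column frame files into one dataset.

    Frames are ordered by the trailing integer in each filename unless
    ``manifest_order`` keeps the list order as given.  Files whose q grid
    differs from the first one by more than a relative ``Q_GRID_RTOL``
    are rejected.  Missing sigma columns are an error unless a
    ``(k, floor)`` fill rule is supplied (sigma = k·sqrt(max(I, floor))).
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("no frame files given")
    if not manifest_order:
        paths = sorted(paths, key=lambda p: (_frame_ordinal(p, -1), p.name))
    q0 = None
    cols_I, cols_S, ordinals = [], [], []
    for k, path in enumerate(paths):
        q, I, sigma = _read_frame_file(path, sigma_fill)
        if q0 is None:
            q0 = q
        else:
            if q.shape != q0.shape or not np.allclose(
                q, q0, rtol=Q_GRID_RTOL, atol=0.0
            ):
                raise ValueError(f"{path}: inconsistent q grid")
        cols_I.append(I)
        cols_S.append(sigma)
        ordinals.append(_frame_ordinal(path, k))
    ordinals = np.asarray(ordinals)
    if np.unique(ordinals).size != ordinals.size:
        ordinals = np.arange(len(paths))
    order = np.argsort(ordinals, kind="stable")
    return SECSAXSDataset(
        q=q0,
        frames=ordinals[order],
        I=np.column_stack([cols_I[i] for i in order]),
        S=np.column_stack([cols_S[i] for i in order]),
        meta={"files": [str(paths[i]) for i in order]},
    )


def write_frames(ds: SECSAXSDataset, out_dir, prefix: str = "frame",
                 suffix: str = "") -> list[Path]:
    """Write each frame as a 3-column ASCII file; returns the paths.

    ``suffix`` is appended to the stem (used e.g. for the '0s'
    skipped-row marker convention of the baseline step).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    width = max(5, len(str(int(ds.frames.max()))))
    paths = []
    for j, t in enumerate(ds.frames):
        path = out_dir / f"{prefix}{suffix}_{t:0{width}d}.dat"
        np.savetxt(
            path,
            np.column_stack([ds.q, ds.I[:, j], ds.S[:, j]]),
            fmt="%.17g",
            header=f"q intensity sigma  (frame {t})",
        )
        paths.append(path)
    return paths


def transpose_dataset(ds: SECSAXSDataset) -> list[Chromatogram]:
    """Frame series → one chromatogram per q row (pure reindexing)."""
    return [ds.chromatogram(i) for i in range(ds.n_q)]


def trim_noise_chromatograms(ds: SECSAXSDataset, snr_threshold: float = 1.5):
    """Drop q rows whose mean signal-to-noise falls below the threshold.

    The per-row SNR is the mean over frames of I/σ.  Returns a new
    dataset (surviving rows in original order) plus a report dict listing
    the dropped q values.
    """
    if np.any(ds.S <= 0):
        raise ValueError("trimming requires strictly positive sigma")
    snr = np.mean(ds.I / ds.S, axis=1)
    keep = snr >= snr_threshold
    if not np.any(keep):
        raise ValueError("no usable chromatograms")
    report = {
        "snr_threshold": snr_threshold,
        "dropped_q": ds.q[~keep].tolist(),
        "kept_q": int(np.count_nonzero(keep)),
        "mean_snr": snr.tolist(),
    }
    trimmed = SECSAXSDataset(
        q=ds.q[keep].copy(),
        frames=ds.frames.copy(),
        I=ds.I[keep].copy(),
        S=ds.S[keep].copy(),
        meta=dict(ds.meta),
    )
    return trimmed, report


def export_csv(columns: dict, path) -> None:
    """Write named columns of equal length as an RFC-4180-style CSV."""
    lengths = {len(v) for v in columns.values()}
    if len(lengths) > 1:
        raise ValueError("ragged columns")
    df = pd.DataFrame({k: np.asarray(v) for k, v in columns.items()})
    # default str() formatting is shortest-round-trip: exact re-import
    df.to_csv(path, index=False)


def import_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")
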