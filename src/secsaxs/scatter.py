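"""Guinier analysis, molecular-mass estimates and curve-fit statistics.

Covers the per-frame structural readout of the pipeline: Guinier fits
(ln I vs q² weighted linear regression, with an automatic q_max·R_g
limit), the concentration-independent Rambo–Tainer molecular mass from
the volume of correlation V_c = I(0)/∫ q·I dq, the absolute-scale mass
from I(0)/c and the scattering contrast, the noise-level-free χ·r_σ
goodness-of-fit score, and non-negative least-squares combination of
model curves against a target frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .core_data import SAXSFrame

__all__ = [
    "GuinierResult",
    "FitStatistics",
    "guinier_fit",
    "guinier_scan",
    "mw_rambo_tainer",
    "mw_from_absolute_scale",
    "chi_and_rsigma",
    "nnls_combination",
]

# Rambo-Tainer protein calibration: M_w[Da] = (Q_R / RT_C1) ** RT_C2 with
# Q_R = V_c^2 / R_g (q in inverse Angstrom, R_g in Angstrom)
RT_C1 = 0.1231
RT_C2 = 1.0
RT_QMAX = 0.2  # A^-1, validated upper limit of the V_c integral

ELECTRON_RADIUS_CM = 2.8179403262e-13
AVOGADRO = 6.02214076e23
# electrons per gram of protein (~0.53 e per dalton)
PROTEIN_ELECTRONS_PER_GRAM = 3.22e23
WATER_ELECTRON_DENSITY_E_NM3 = 334.0


@dataclass
class GuinierResult:
    Rg: float
    Rg_sd: float
    I0: float
    I0_sd: float
    q_min: float
    q_max: float
    qmax_rg: float
    chi2: float
    n_points: int
    mw_rt: float | None = None
    mw_i0c: float | None = None
    warnings: list = field(default_factory=list)
    valid: bool = True


def _weighted_linefit(x, y, w):
    """Weighted least-squares line y = b + m x; returns b, m and their sd."""
    W = np.sum(w)
    xm = np.sum(w * x) / W
    ym = np.sum(w * y) / W
    sxx = np.sum(w * (x - xm) ** 2)
    m = np.sum(w * (x - xm) * (y - ym)) / sxx
    b = ym - m * xm
    # covariance of the weighted estimator with w = 1/sigma^2
    var_m = 1.0 / sxx
    var_b = 1.0 / W + xm * xm / sxx
    resid = y - (b + m * x)
    chi2 = float(np.sum(w * resid**2))
    return b, m, np.sqrt(var_b), np.sqrt(var_m), chi2


def guinier_fit(frame: SAXSFrame, q_range: tuple[float, float] | None = None,
                qmax_rg_limit: float = 1.3, max_auto_iter: int = 20) -> GuinierResult:
    """Guinier fit: weighted linear regression of ln I on q².

    With an explicit ``q_range`` the fit uses exactly that window; in
    automatic mode the upper limit starts from the full grid and is
    iterated until q_max·R_g ≤ ``qmax_rg_limit`` (default 1.3).  R_g =
    sqrt(−3·slope), I(0) = exp(intercept); parameter s.d. values come
    from the weighted-regression covariance with σ_lnI = σ/I.
    """
    q, I, S = frame.q, frame.intensity, frame.sigma
    warns: list[str] = []

    def _fit(mask):
        ok = mask & (I > 0)
        n = int(np.count_nonzero(ok))
        if n < 5:
            raise ValueError("fewer than 5 positive-intensity points in range")
        x = q[ok] ** 2
        y = np.log(I[ok])
        sig = np.where(S[ok] > 0, S[ok] / I[ok], 1.0)
        b, m, sb, sm, chi2 = _weighted_linefit(x, y, 1.0 / sig**2)
        return b, m, sb, sm, chi2, n, q[ok]

    if q_range is not None:
        mask = (q >= q_range[0]) & (q <= q_range[1])
        b, m, sb, sm, chi2, n, qs = _fit(mask)
    else:
        q_hi = float(q[-1])
        for _ in range(max_auto_iter):
            mask = q <= q_hi
            b, m, sb, sm, chi2, n, qs = _fit(mask)
            if m >= 0:
                break
            rg = np.sqrt(-3.0 * m)
            if q_hi * rg <= qmax_rg_limit * (1 + 1e-12):
                break
            q_hi = qmax_rg_limit / rg
    if m >= 0:
        warns.append("positive Guinier slope: R_g undefined (unphysical)")
        return GuinierResult(
            Rg=np.nan, Rg_sd=np.nan, I0=np.exp(b), I0_sd=np.exp(b) * sb,
            q_min=float(qs[0]), q_max=float(qs[-1]), qmax_rg=np.nan,
            chi2=chi2, n_points=n, warnings=warns, valid=False,
        )
    rg = float(np.sqrt(-3.0 * m))
    rg_sd = float(3.0 * sm / (2.0 * rg))
    i0 = float(np.exp(b))
    return GuinierResult(
        Rg=rg, Rg_sd=rg_sd, I0=i0, I0_sd=float(i0 * sb),
        q_min=float(qs[0]), q_max=float(qs[-1]),
        qmax_rg=float(qs[-1] * rg), chi2=chi2, n_points=n,
        warnings=warns,
    )


def guinier_scan(frames, drift_tol: float = 0.02, **kwargs):
    """Guinier fit of every frame in a series.

    Returns (results, flags); a frame is flagged when its R_g departs
    from the running median by more than ``drift_tol`` (relative) — the
    mixture indicator of unresolved co-eluting species.
    """
    results = []
    for fr in frames:
        try:
            results.append(guinier_fit(fr, **kwargs))
        except ValueError as exc:
            results.append(
                GuinierResult(
                    Rg=np.nan, Rg_sd=np.nan, I0=np.nan, I0_sd=np.nan,
                    q_min=np.nan, q_max=np.nan, qmax_rg=np.nan,
                    chi2=np.nan, n_points=0, warnings=[str(exc)], valid=False,
                )
            )
    rgs = np.array([r.Rg for r in results])
    ok = np.isfinite(rgs)
    flags = np.zeros(len(results), dtype=bool)
    if np.count_nonzero(ok) >= 3:
        med = np.median(rgs[ok])
        flags[ok] = np.abs(rgs[ok] - med) > drift_tol * med
    return results, flags


def mw_rambo_tainer(frame: SAXSFrame, guinier: GuinierResult,
                    q_integral_max: float = RT_QMAX):
    """Concentration-independent molecular mass (volume of correlation).

    V_c = I(0) / ∫₀^qmax q·I(q) dq with the unmeasured low-q gap filled
    by the fitted Guinier form from q = 0; Q_R = V_c²/R_g; M_w =
    (Q_R/0.1231)^1.0 Da, reported in kg·mol⁻¹ (protein calibration).
    Warnings are
    issued when the grid tops out below the validated 0.2 Å⁻¹ limit or
    when a non-default limit is requested.
    """
    warns = list(guinier.warnings)
    if not guinier.valid:
        raise ValueError("cannot compute M_w[RT] without a valid Guinier fit")
    if q_integral_max != RT_QMAX:
        warns.append(
            f"non-default V_c integration limit {q_integral_max} Å⁻¹; "
            "mass estimate may be unreliable"
        )
    q, I = frame.q, frame.intensity
    q_top = min(q_integral_max, float(q[-1]))
    if float(q[-1]) < q_integral_max:
        warns.append(
            f"q grid tops out at {q[-1]:.4g} Å⁻¹ < {q_integral_max} Å⁻¹; "
            "mass estimate may be unreliable"
        )
    # Guinier extrapolation over [0, q_min)
    q_gap = np.linspace(0.0, float(q[0]), 32, endpoint=False)
    I_gap = guinier.I0 * np.exp(-(q_gap**2) * guinier.Rg**2 / 3.0)
    sel = q <= q_top
    q_all = np.concatenate([q_gap, q[sel]])
    I_all = np.concatenate([I_gap, I[sel]])
    integral = float(np.trapezoid(q_all * I_all, q_all))
    if integral <= 0:
        raise ValueError("non-positive V_c integral")
    vc = guinier.I0 / integral
    qr = vc * vc / guinier.Rg
    mw_da = (qr / RT_C1) ** RT_C2
    return mw_da / 1e3, warns


def mw_from_absolute_scale(I0_abs: float, c: float, vbar: float = 0.735,
                           solvent_e_density: float = WATER_ELECTRON_DENSITY_E_NM3) -> float:
    """Molecular mass from absolute-scale forward scattering.

    M_w = I(0)[cm⁻¹] · N_A / (c · Δρ_M²), with the contrast per unit mass
    Δρ_M = r_e · (electrons per gram of protein − solvent electron
    density · v̄).  c in mg·ml⁻¹, v̄ in ml·g⁻¹, solvent electron density
    in e·nm⁻³; result in kg·mol⁻¹.
    """
    if c <= 0:
        raise ValueError("concentration must be positive")
    rho_s_cm3 = solvent_e_density * 1e21  # e/nm^3 -> e/cm^3
    drho_m = ELECTRON_RADIUS_CM * (
        PROTEIN_ELECTRONS_PER_GRAM - rho_s_cm3 * vbar
    )  # cm / g
    if drho_m <= 0:
        raise ValueError("non-positive scattering contrast")
    c_g_cm3 = c * 1e-3
    mw_g_mol = I0_abs * AVOGADRO / (c_g_cm3 * drho_m**2)
    return mw_g_mol / 1e3


@dataclass
class FitStatistics:
    chi: float
    r_sigma: float
    chi_r_sigma: float
    n: int
    scale: float


def chi_and_rsigma(I_exp, I_calc, sigma_exp, fit_scale: bool = True,
                   r_sigma_form: str = "rms") -> FitStatistics:
    """Goodness of fit between an experimental and a calculated curve.

    χ = sqrt(Σ((I_exp − s·I_calc)/σ)² / (n−1)) with the optional optimal
    multiplicative scale s (closed-form weighted solution); r_σ is the
    RMS of the experimental σ (``r_sigma_form="mean"`` uses the plain
    mean instead).  The product χ·r_σ is invariant under a global
    rescaling of σ, i.e. independent of the data set's noise level.
    """
    I_exp = np.asarray(I_exp, dtype=float)
    I_calc = np.asarray(I_calc, dtype=float)
    sigma = np.asarray(sigma_exp, dtype=float)
    if not (I_exp.size == I_calc.size == sigma.size):
        raise ValueError("curve lengths differ")
    n = I_exp.size
    if n < 2:
        raise ValueError("need at least 2 points")
    if np.any(sigma <= 0):
        raise ValueError("sigma must be strictly positive")
    w = 1.0 / sigma**2
    if fit_scale:
        denom = np.sum(w * I_calc**2)
        scale = float(np.sum(w * I_exp * I_calc) / denom) if denom > 0 else 1.0
    else:
        scale = 1.0
    chi = float(np.sqrt(np.sum(((I_exp - scale * I_calc) / sigma) ** 2) / (n - 1)))
    if r_sigma_form == "rms":
        r_sigma = float(np.sqrt(np.mean(sigma**2)))
    elif r_sigma_form == "mean":
        r_sigma = float(np.mean(sigma))
    else:
        raise ValueError("r_sigma_form must be 'rms' or 'mean'")
    return FitStatistics(chi=chi, r_sigma=r_sigma, chi_r_sigma=chi * r_sigma,
                         n=n, scale=scale)


def nnls_combination(target: SAXSFrame, model_curves, labels=None):
    """σ-weighted NNLS combination of model curves against a target frame.

    ``model_curves`` are intensity arrays on the target grid.  Returns a
    dict with the non-negative weights, their percentage shares, the
    combination's FitStatistics, and the single best curve (by χ·r_σ)
    among the basis.
    """
    y = target.intensity
    sigma = target.sigma
    if np.any(sigma <= 0):
        raise ValueError("target sigma must be strictly positive")
    curves = [np.asarray(c, dtype=float) for c in model_curves]
    if not curves:
        raise ValueError("empty model basis")
    for c in curves:
        if c.size != y.size:
            raise ValueError("model curve not on the target grid")
    A = np.column_stack(curves) / sigma[:, None]
    b = y / sigma
    weights, _ = optimize.nnls(A, b)
    combo = np.column_stack(curves) @ weights
    combo_stats = chi_and_rsigma(y, combo, sigma, fit_scale=False)
    total = weights.sum()
    percent = 100.0 * weights / total if total > 0 else np.zeros_like(weights)

    singles = [chi_and_rsigma(y, c, sigma, fit_scale=True) for c in curves]
    best = int(np.argmin([s.chi_r_sigma for s in singles]))
    if labels is None:
        labels = [f"model_{i}" for i in range(len(curves))]
    return {
        "weights": weights,
        "percent": percent,
        "labels": list(labels),
        "combination": combo_stats,
        "single_best_index": best,
        "single_best_label": labels[best],
        "single_best_stats": singles[best],
    }
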