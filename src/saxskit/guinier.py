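"""Guinier analysis, infinite-dilution extrapolation and state differences.

At small angles the scattering of a monodisperse solution follows

    I(S, C) = I(0, C) exp(-(4 pi^2 / 3) Rg^2(C) S^2),

so ln I is linear in S^2 with slope -(4 pi^2/3) Rg^2 (note the 4 pi^2/3
prefactor that goes with the S = 2 sin(theta)/lambda convention; in q
units the familiar -Rg^2/3 appears instead).  Both I(0, C) and Rg(C)
carry concentration dependence from interparticle interference:

    K C / I(0, C) = 1/Mw + 2 A2 C          (forward scattering)
    Rg^2(C)       = Rg^2(0) - Bif C        (apparent size)

Extrapolating a dilution series to C = 0 yields the apparent molecular
weight Mw, the second virial coefficient A2, the interference slope Bif
and the true Rg(0).  Linearity of all three relations is the standard
monodispersity diagnostic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from ._fitting import weighted_line_fit
from .types import ScatteringProfile, TWO_PI

logger = logging.getLogger("saxskit")

FOUR_PI2_OVER_3 = 4.0 * math.pi**2 / 3.0

__all__ = [
    "GuinierResult",
    "DilutionResult",
    "DifferenceResult",
    "guinier_fit",
    "extrapolate_dilution",
    "estimate_mw",
    "difference_profile",
]


@dataclass(frozen=True)
class GuinierResult:
    rg: float
    rg_err: float
    i0: float
    i0_err: float
    fit_window: Tuple[float, float]
    n_points: int
    r_squared: float

    @property
    def srg_max(self) -> float:
        """2 pi S_max * Rg of the accepted window (q*Rg in q units)."""
        return TWO_PI * self.fit_window[1] * self.rg


@dataclass(frozen=True)
class DilutionResult:
    mw_apparent: float
    mw_err: float
    rg0: float
    rg0_err: float
    a2: float
    a2_err: float
    bif: float
    bif_err: float
    k_const: float
    concentrations: Tuple[float, ...]
    guinier_results: Tuple[GuinierResult, ...]
    monodisperse: bool
    reasons: Tuple[str, ...]
    i0_fit_r2: float
    rg2_fit_r2: float


def _guinier_window_fit(s, i, sigma):
    """Weighted line fit of ln I vs S^2 on one window."""
    ln_i = np.log(i)
    ln_sigma = sigma / i if sigma is not None else None
    return weighted_line_fit(s**2, ln_i, ln_sigma)


def guinier_fit(profile: ScatteringProfile, srg_max: float = 1.3) -> GuinierResult:
    """Fit the low-angle Guinier region of one profile.

    The fit window is chosen iteratively: starting from the 10 smallest
    usable S points, Rg is estimated and the window extended or trimmed so
    that 2 pi S_max Rg <= srg_max, until self-consistent (at most 20
    rounds).  Points with non-positive intensity are unusable; when every
    sigma is positive the fit is error-weighted (with errors propagated
    onto ln I), otherwise unweighted.

    Raises ValueError when no window of >= 5 points gives a decreasing
    (negative-slope) Guinier line — e.g. for aggregating samples whose
    intensity rises at low angle.
    """
    usable = profile.intensity > 0
    s = profile.s_grid[usable]
    i = profile.intensity[usable]
    weighted = bool(np.all(profile.sigma[usable] > 0))
    e = profile.sigma[usable] if weighted else None
    if len(s) < 5:
        raise ValueError("fewer than 5 usable low-angle points")

    n = min(10, len(s))
    prev_n = -1
    fit = None
    rg = None
    for _ in range(20):
        fit = _guinier_window_fit(s[:n], i[:n], e[:n] if weighted else None)
        if fit.slope >= 0:
            raise ValueError("no Guinier region: intensity does not decay at low angle")
        rg = math.sqrt(-fit.slope / FOUR_PI2_OVER_3)
        n_new = int(np.searchsorted(s, srg_max / (TWO_PI * rg), side="right"))
        n_new = max(n_new, 5)
        n_new = min(n_new, len(s))
        if n_new == n or n_new == prev_n:
            n = n_new
            break
        prev_n, n = n, n_new
    fit = _guinier_window_fit(s[:n], i[:n], e[:n] if weighted else None)
    if fit.slope >= 0:
        raise ValueError("no Guinier region: intensity does not decay at low angle")
    rg = math.sqrt(-fit.slope / FOUR_PI2_OVER_3)
    rg_err = fit.slope_err / (2.0 * FOUR_PI2_OVER_3 * rg)
    i0 = math.exp(fit.intercept)
    i0_err = i0 * fit.intercept_err
    return GuinierResult(
        rg=rg,
        rg_err=rg_err,
        i0=i0,
        i0_err=i0_err,
        fit_window=(float(s[0]), float(s[n - 1])),
        n_points=n,
        r_squared=fit.r_squared,
    )


def extrapolate_dilution(
    results: Sequence[Tuple[float, GuinierResult]],
    k_const: float = 1.0,
    r2_threshold: float = 0.9,
    guinier_r2_threshold: float = 0.9,
) -> DilutionResult:
    """Extrapolate per-concentration Guinier results to infinite dilution.

    Fits K C / I(0, C) vs C (intercept 1/Mw, slope 2 A2) and Rg^2(C) vs C
    (intercept Rg^2(0), slope -Bif), both error-weighted via propagation
    from the Guinier parameter errors.  The monodispersity verdict is true
    iff both concentration fits and every Guinier fit reach the r^2
    thresholds.
    """
    if len(results) < 3:
        raise ValueError("need at least 3 concentrations")
    c = np.array([float(ci) for ci, _ in results])
    if len(np.unique(c)) < 3:
        raise ValueError("need at least 3 distinct concentrations")
    gs = [g for _, g in results]

    i0 = np.array([g.i0 for g in gs])
    i0_err = np.array([g.i0_err for g in gs])
    y1 = k_const * c / i0
    y1_err = k_const * c * i0_err / i0**2
    fit1 = weighted_line_fit(c, y1, y1_err if np.all(y1_err > 0) else None)
    if fit1.intercept <= 0:
        raise ValueError("non-positive 1/Mw intercept; series inconsistent with the dilution law")
    mw = 1.0 / fit1.intercept
    mw_err = fit1.intercept_err / fit1.intercept**2
    a2 = fit1.slope / 2.0
    a2_err = fit1.slope_err / 2.0

    rg = np.array([g.rg for g in gs])
    rg_err = np.array([g.rg_err for g in gs])
    y2 = rg**2
    y2_err = 2.0 * rg * rg_err
    fit2 = weighted_line_fit(c, y2, y2_err if np.all(y2_err > 0) else None)
    if fit2.intercept <= 0:
        raise ValueError("non-positive Rg^2(0) intercept")
    rg0 = math.sqrt(fit2.intercept)
    rg0_err = fit2.intercept_err / (2.0 * rg0)
    bif = -fit2.slope
    bif_err = fit2.slope_err

    reasons = []
    if fit1.r_squared < r2_threshold:
        reasons.append(f"C/I(0) vs C fit r^2 = {fit1.r_squared:.3f} < {r2_threshold}")
    if fit2.r_squared < r2_threshold:
        reasons.append(f"Rg^2 vs C fit r^2 = {fit2.r_squared:.3f} < {r2_threshold}")
    for ci, g in zip(c, gs):
        if g.r_squared < guinier_r2_threshold:
            reasons.append(f"Guinier fit at C = {ci:g} mg/mL has r^2 = {g.r_squared:.3f}")
    return DilutionResult(
        mw_apparent=mw,
        mw_err=mw_err,
        rg0=rg0,
        rg0_err=rg0_err,
        a2=a2,
        a2_err=a2_err,
        bif=bif,
        bif_err=bif_err,
        k_const=k_const,
        concentrations=tuple(c),
        guinier_results=tuple(gs),
        monodisperse=not reasons,
        reasons=tuple(reasons),
        i0_fit_r2=fit1.r_squared,
        rg2_fit_r2=fit2.r_squared,
    )


def estimate_mw(
    target_i0_over_c: float,
    reference: Tuple[float, float] = (14300.0, 1.0),
) -> float:
    """Molecular weight from forward scattering, against a calibrant.

    For equal contrast and partial specific volume (0.74 cm^3/g assumed
    for both proteins), I(0)/C is proportional to Mw, so

        Mw = Mw_ref * (I(0)/C)_target / (I(0)/C)_ref.

    ``reference`` defaults to hen egg-white lysozyme (14,300 Da); its
    measured I(0)/C must be supplied.  A contrast correction hook is not
    applied by default.
    """
    mw_ref, i0c_ref = reference
    if mw_ref <= 0 or i0c_ref <= 0 or target_i0_over_c <= 0:
        raise ValueError("all intensities and the reference Mw must be positive")
    return mw_ref * target_i0_over_c / i0c_ref


@dataclass(frozen=True)
class DifferenceResult:
    profile: ScatteringProfile
    max_rel_diff: float          # max |a-b|/a in the window
    max_rel_diff_s: float
    max_abs_diff: float          # max |a-b| in the window (on the, possibly
    max_abs_diff_s: float        # I(0)-normalized, intensity scale)
    window: Tuple[float, float]


def difference_profile(
    a: ScatteringProfile,
    b: ScatteringProfile,
    normalize: str = "none",
    interpolate: bool = False,
    s_window: Optional[Tuple[float, float]] = None,
) -> DifferenceResult:
    """Point-wise difference a - b between two states.

    normalize='i0' divides each curve by its Guinier I(0) first, so the
    difference reflects shape changes rather than concentration or
    exposure scale.  Errors are propagated in quadrature.  The relative
    difference (a - b)/a is summarised by its maximum magnitude over
    ``s_window`` (default: the full common range), together with the S at
    which it occurs.
    """
    if interpolate:
        lo = max(a.s_grid[0], b.s_grid[0])
        hi = min(a.s_grid[-1], b.s_grid[-1])
        if lo >= hi:
            raise ValueError("disjoint S ranges")
        keep = (a.s_grid >= lo) & (a.s_grid <= hi)
        s = a.s_grid[keep]
        ia, ea = a.intensity[keep], a.sigma[keep]
        ib = np.interp(s, b.s_grid, b.intensity)
        eb = np.interp(s, b.s_grid, b.sigma)
    else:
        if len(a) != len(b) or not np.allclose(a.s_grid, b.s_grid, rtol=0, atol=1e-12):
            raise ValueError("S grids differ; pass interpolate=True to resample b")
        s, ia, ea, ib, eb = a.s_grid, a.intensity, a.sigma, b.intensity, b.sigma

    if normalize == "i0":
        na = guinier_fit(a).i0
        nb = guinier_fit(b).i0
        ia, ea = ia / na, ea / na
        ib, eb = ib / nb, eb / nb
    elif normalize != "none":
        raise ValueError("normalize must be 'i0' or 'none'")

    diff = ia - ib
    err = np.sqrt(ea**2 + eb**2)
    window = s_window if s_window is not None else (float(s[0]), float(s[-1]))
    in_win = (s >= window[0]) & (s <= window[1])
    if not np.any(in_win):
        raise ValueError("no points in the requested S window")
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(ia != 0, diff / ia, 0.0)
    k = int(np.argmax(np.abs(rel[in_win])))
    ka = int(np.argmax(np.abs(diff[in_win])))
    s_win = s[in_win]
    prof = ScatteringProfile(
        s_grid=s,
        intensity=diff,
        sigma=err,
        concentration=a.concentration,
        label=f"{a.label}-{b.label}",
    )
    return DifferenceResult(
        profile=prof,
        max_rel_diff=float(np.abs(rel[in_win][k])),
        max_rel_diff_s=float(s_win[k]),
        max_abs_diff=float(np.abs(diff[in_win][ka])),
        max_abs_diff_s=float(s_win[ka]),
        window=window,
    )
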