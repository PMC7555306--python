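"""Dilution-series simulator with interparticle-interference structure.

Real solution SAXS at finite concentration deviates from the ideal
single-particle curve: the forward scattering follows

    K C / I(0, C) = 1/Mw + 2 A2 C

(A2 the second virial coefficient) and the apparent squared radius of
gyration follows

    Rg^2(C) = Rg^2(0) - Bif C

(Bif an empirical interference slope).  Rather than computing a
liquid-state structure factor, the simulator enforces both linear laws by
construction: the ideal Debye curve is multiplied by

    exp(+(4 pi^2 / 3) Bif C S^2) / (1 + 2 A2 Mw C)

and rescaled so that I(0, C) = K C Mw / (1 + 2 A2 Mw C).  In the noiseless
limit Guinier analysis of the simulated series therefore recovers
(Mw, A2, Bif, Rg(0)) exactly, which is what makes the concentration
extrapolation testable.  Gaussian noise with a relative, mildly
angle-dependent sigma(S) = noise_level * I(S) * (1 + S/S_max) is a
stand-in for counting statistics (true per-point counting errors of a
beamline reduction are not modelled).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .debye import debye_intensity, forward_intensity
from .types import BeadModel, ScatteringProfile

__all__ = ["SeriesSpec", "simulate_series", "default_s_grid"]

FOUR_PI2_OVER_3 = 4.0 * np.pi**2 / 3.0


def default_s_grid(n: int = 160, s_min: float = 0.002, s_max: float = 0.08) -> np.ndarray:
    """Default S grid (1/A) covering the usual protein solution-SAXS range."""
    return np.linspace(s_min, s_max, n)


@dataclass(frozen=True)
class SeriesSpec:
    """True parameters of a simulated dilution series.

    concentrations in mg/mL (>= 3 distinct values), mw_true in Da, a2_true
    in the units implied by the forward-scattering law above (so that
    2*a2_true*mw_true*C is dimensionless), bif_true in A^2 per mg/mL,
    noise_level as a relative sigma at low angle.
    """

    concentrations: Sequence[float] = (1.0, 2.5, 5.0)
    mw_true: float = 51000.0
    a2_true: float = 2.0e-7
    bif_true: float = 2.0
    noise_level: float = 0.01
    random_seed: int = 0
    k_const: float = 1.0

    def __post_init__(self):
        c = np.asarray(self.concentrations, dtype=float)
        if len(np.unique(c)) < 3 or np.any(c <= 0):
            raise ValueError("need >= 3 distinct positive concentrations")
        if self.mw_true <= 0 or self.noise_level < 0 or self.k_const <= 0:
            raise ValueError("mw_true and k_const must be positive, noise_level >= 0")


def _series_for_model(
    model: BeadModel,
    series: SeriesSpec,
    s_grid: np.ndarray,
    label: str,
    rng: np.random.Generator,
) -> List[ScatteringProfile]:
    i_ideal = debye_intensity(model, s_grid)
    i0_ideal = forward_intensity(model)
    s2 = s_grid**2
    out = []
    for c in series.concentrations:
        i0_target = series.k_const * c * series.mw_true / (1.0 + 2.0 * series.a2_true * series.mw_true * c)
        structure = np.exp(FOUR_PI2_OVER_3 * series.bif_true * c * s2)
        i = i_ideal * (i0_target / i0_ideal) * structure
        sigma = series.noise_level * i * (1.0 + s_grid / s_grid[-1])
        noisy = i + rng.standard_normal(len(i)) * sigma
        if series.noise_level == 0:
            sigma = np.zeros_like(i)
        out.append(
            ScatteringProfile(
                s_grid=s_grid,
                intensity=noisy,
                sigma=sigma,
                concentration=c,
                label=label,
            )
        )
    return out


def simulate_series(
    model_dark: BeadModel,
    model_light: Optional[BeadModel],
    series: SeriesSpec,
    s_grid=None,
) -> dict:
    """Simulate noisy dilution series for one or two conformational states.

    Returns ``{"dark": [profiles...], "light": [...]}`` (the "light" key is
    present only when a second model is given).  Output is bit-reproducible
    for a fixed ``series.random_seed``.
    """
    s = default_s_grid() if s_grid is None else np.asarray(s_grid, dtype=float)
    rng = np.random.default_rng(series.random_seed)
    result = {"dark": _series_for_model(model_dark, series, s, "dark", rng)}
    if model_light is not None:
        result["light"] = _series_for_model(model_light, series, s, "light", rng)
    return result
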