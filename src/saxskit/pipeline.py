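"""End-to-end per-specimen analysis.

For each conformational state (e.g. dark-adapted vs blue-light
irradiated) measured as a dilution series, the pipeline chains:
Guinier fits per concentration -> infinite-dilution extrapolation
(Mw, A2, Bif, Rg(0)) -> P(r)/Dmax on the lowest-concentration curve ->
multi-seed shape restoration -> ensemble classification.  Two states are
then compared through their extrapolated Rg(0) and a normalized
difference profile, whose signature for a hinge-type rearrangement is
concentrated at low angles.  A state measured after dark reversion can
be checked against the original dark state for photo-reversibility.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from . import io as skio
from .classify import ClassificationResult, classify_ensemble
from .config import RunConfig
from .distdist import DistanceDistribution, estimate_dmax, ift_pr
from .guinier import DilutionResult, difference_profile, extrapolate_dilution, guinier_fit
from .restore import RestorationResult, restore_shape
from .types import BeadModel, ScatteringProfile

logger = logging.getLogger("saxskit")

__all__ = ["PipelineError", "StateResult", "SpecimenReport", "run_pipeline", "reversion_check"]

VERSION = "0.1.0"


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name and partial results."""

    def __init__(self, stage: str, message: str, partial=None):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
        self.partial = partial


@dataclass
class StateResult:
    label: str
    dilution: DilutionResult
    pr: DistanceDistribution
    dmax: float
    restorations: Tuple[RestorationResult, ...]
    classification: Optional[ClassificationResult]
    lowest_c_profile: ScatteringProfile


@dataclass
class SpecimenReport:
    states: Dict[str, StateResult]
    delta_rg0: Optional[float]
    delta_rg0_err: Optional[float]
    max_diff_low_angle: Optional[float]
    max_diff_high_angle: Optional[float]
    low_angle_window: Tuple[float, float]
    seed: int
    config_hash: str
    version: str = VERSION

    def to_dict(self) -> dict:
        def state_dict(st: StateResult) -> dict:
            d = st.dilution
            return {
                "label": st.label,
                "mw_apparent": d.mw_apparent,
                "mw_err": d.mw_err,
                "rg0": d.rg0,
                "rg0_err": d.rg0_err,
                "a2": d.a2,
                "a2_err": d.a2_err,
                "bif": d.bif,
                "bif_err": d.bif_err,
                "monodisperse": d.monodisperse,
                "reasons": list(d.reasons),
                "dmax": st.dmax,
                "rg_from_pr": st.pr.rg_from_pr,
                "restoration_chi2": [r.fit.chi2 for r in st.restorations],
                "n_classes": st.classification.k if st.classification else None,
                "selected_classes": (list(st.classification.selected_classes)
                                     if st.classification else None),
            }

        return {
            "states": {k: state_dict(v) for k, v in self.states.items()},
            "delta_rg0": self.delta_rg0,
            "delta_rg0_err": self.delta_rg0_err,
            "max_diff_low_angle": self.max_diff_low_angle,
            "max_diff_high_angle": self.max_diff_high_angle,
            "low_angle_window": list(self.low_angle_window),
            "seed": self.seed,
            "config_hash": self.config_hash,
            "version": self.version,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


ManifestEntry = Union[ScatteringProfile, Tuple[Union[str, Path], float]]


def _load_state(entries: Sequence[ManifestEntry], label: str) -> List[ScatteringProfile]:
    profiles = []
    for e in entries:
        if isinstance(e, ScatteringProfile):
            profiles.append(e)
        else:
            path, conc = e
            profiles.append(skio.read_profile(path, concentration=conc, label=label))
    return sorted(profiles, key=lambda p: p.concentration)


def _analyze_state(
    label: str,
    profiles: List[ScatteringProfile],
    config: RunConfig,
    n_dr: int,
    replicates: int,
    classify: bool,
) -> StateResult:
    stage = "guinier"
    try:
        gs = [(p.concentration, guinier_fit(p, config.guinier_srg_max)) for p in profiles]
    except ValueError as exc:
        raise PipelineError(stage, str(exc)) from exc
    stage = "extrapolate"
    try:
        dilution = extrapolate_dilution(gs, k_const=config.k_const)
    except ValueError as exc:
        raise PipelineError(stage, str(exc)) from exc
    low = profiles[0]
    stage = "pr"
    try:
        rg = gs[0][1].rg
        dmax, _ = estimate_dmax(low, (2.0 * rg, 4.5 * rg), n_scan=8,
                                smoothness=config.ift_smoothness)
        pr = ift_pr(low, dmax, smoothness=config.ift_smoothness)
    except ValueError as exc:
        raise PipelineError(stage, str(exc), partial={"dilution": dilution}) from exc
    if replicates == 0:
        return StateResult(label=label, dilution=dilution, pr=pr, dmax=dmax,
                           restorations=(), classification=None, lowest_c_profile=low)
    stage = "restore"
    try:
        restorations = tuple(
            restore_shape(low, n_dr, dmax_hint=dmax, seed=(config.random_seed * 1000003 + r) % (2**31),
                          schedule=config.anneal)
            for r in range(replicates)
        )
    except ValueError as exc:
        raise PipelineError(stage, str(exc), partial={"dilution": dilution, "pr": pr}) from exc
    classification = None
    if classify and len(restorations) >= 3:
        stage = "classify"
        try:
            classification = classify_ensemble(
                [r.model for r in restorations], low,
                seed=config.random_seed, spacing=config.voxel_spacing,
            )
        except ValueError as exc:
            raise PipelineError(stage, str(exc),
                                partial={"dilution": dilution, "pr": pr}) from exc
    return StateResult(
        label=label,
        dilution=dilution,
        pr=pr,
        dmax=dmax,
        restorations=restorations,
        classification=classification,
        lowest_c_profile=low,
    )


def run_pipeline(
    manifest: Dict[str, Sequence[ManifestEntry]],
    config: Optional[RunConfig] = None,
    n_dr: int = 100,
    replicates: Optional[int] = None,
    classify: bool = True,
    outdir=None,
) -> SpecimenReport:
    """Run the full analysis for every state in the manifest.

    ``manifest`` maps state labels (conventionally "dark" first, then
    "light") to either ScatteringProfile objects or (path, concentration)
    pairs; each state needs >= 3 concentrations.  When two or more states
    are present, the first two are compared (delta Rg(0), normalized
    difference profile split at the configured low-angle window).  With
    ``outdir`` set, the JSON report and consensus models are written
    there; reruns with the same inputs, seed and config produce identical
    JSON.
    """
    config = config or RunConfig()
    replicates = config.restore_replicates if replicates is None else replicates
    states: Dict[str, StateResult] = {}
    for label, entries in manifest.items():
        profiles = _load_state(entries, label)
        if len({p.concentration for p in profiles}) < 3:
            raise PipelineError("extrapolate",
                                f"state '{label}' has fewer than 3 concentrations")
        states[label] = _analyze_state(label, profiles, config, n_dr, replicates, classify)

    delta_rg0 = delta_err = lo_diff = hi_diff = None
    window = (0.0, config.low_angle_s_max)
    labels = list(states)
    if len(labels) >= 2:
        a, b = states[labels[0]], states[labels[1]]
        delta_rg0 = b.dilution.rg0 - a.dilution.rg0
        delta_err = float(np.hypot(a.dilution.rg0_err, b.dilution.rg0_err))
        pa, pb = a.lowest_c_profile, b.lowest_c_profile
        # on the I(0)-normalized scale, a hinge-type rearrangement shows up
        # as an absolute intensity difference concentrated at low angles
        lo = difference_profile(pa, pb, normalize="i0", s_window=window)
        lo_diff = lo.max_abs_diff
        hi_window = (config.low_angle_s_max, float(pa.s_grid[-1]))
        hi = difference_profile(pa, pb, normalize="i0", s_window=hi_window)
        hi_diff = hi.max_abs_diff

    report = SpecimenReport(
        states=states,
        delta_rg0=delta_rg0,
        delta_rg0_err=delta_err,
        max_diff_low_angle=lo_diff,
        max_diff_high_angle=hi_diff,
        low_angle_window=window,
        seed=config.random_seed,
        config_hash=config.config_hash(),
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        report.to_json(outdir / "report.json")
        for label, st in states.items():
            if st.classification:
                for ci, avg in zip(st.classification.selected_classes,
                                   st.classification.class_averages):
                    skio.write_bead_model(avg, outdir / f"{label}_class{ci}_consensus.pdb")
    return report


def reversion_check(
    dark: StateResult,
    reversion: StateResult,
    tol: float = 0.02,
) -> dict:
    """Photo-reversibility verdict: does the reverted state match the dark one?

    "reversible" iff the maximum low-angle relative intensity difference
    (after I(0) normalization) is within ``tol`` and |delta Rg(0)| lies
    within twice the combined fit error.
    """
    pa, pb = dark.lowest_c_profile, reversion.lowest_c_profile
    diff = difference_profile(pa, pb, normalize="i0", s_window=(0.0, 0.012))
    d_rg = abs(reversion.dilution.rg0 - dark.dilution.rg0)
    rg_tol = 2.0 * float(np.hypot(dark.dilution.rg0_err, reversion.dilution.rg0_err))
    ok = diff.max_rel_diff <= tol and d_rg <= rg_tol
    return {
        "verdict": "reversible" if ok else "not reversible",
        "max_rel_diff": diff.max_rel_diff,
        "tol": tol,
        "delta_rg0": d_rg,
        "rg_tolerance": rg_tol,
    }
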