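"""Run configuration shared across the analysis stages."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple


@dataclass
class AnnealSchedule:
    """Simulated-annealing schedule for shape restoration.

    ``t0_factor`` sets the initial temperature as a multiple of the median
    |energy change| of a short probe batch of trial moves (so the starting
    acceptance ratio is insensitive to the objective's absolute scale);
    cooling is geometric with ``cooling`` applied every
    ``moves_per_bead * n_dr`` attempted moves; the run stops after
    ``max_levels`` temperature levels or ``patience`` levels without
    improvement of the best-ever objective.
    """

    t0_factor: float = 1.0
    cooling: float = 0.90
    moves_per_bead: int = 40
    max_levels: int = 50
    patience: int = 8

    def __post_init__(self):
        if not (0 < self.cooling < 1):
            raise ValueError("cooling must be in (0, 1)")
        if self.t0_factor <= 0 or self.moves_per_bead < 1 or self.max_levels < 1:
            raise ValueError("schedule parameters must be positive")


@dataclass
class RunConfig:
    """All tunables of the pipeline in one place.

    ``guinier_srg_max`` bounds the fit window through 2*pi*S_max*Rg
    (i.e. q*Rg in the other convention); 1.3 is the community default for
    globular particles.  ``mw_reference`` is (reference molecular weight in
    Da, reference I(0)/C), defaulting to hen egg-white lysozyme at
    14,300 Da with a unit intensity ratio placeholder that callers should
    replace with a measured value.  ``specific_volume`` is the protein
    partial specific volume in cm^3/g.
    """

    random_seed: int = 0
    guinier_srg_max: float = 1.3
    ift_smoothness: float = 3.0
    anneal: AnnealSchedule = field(default_factory=AnnealSchedule)
    voxel_spacing: float = 4.0
    mw_reference: Tuple[float, float] = (14300.0, 1.0)
    specific_volume: float = 0.74
    k_const: float = 1.0
    low_angle_s_max: float = 0.012
    restore_replicates: int = 10

    def __post_init__(self):
        if self.guinier_srg_max <= 0 or self.voxel_spacing <= 0:
            raise ValueError("guinier_srg_max and voxel_spacing must be positive")
        if self.ift_smoothness < 0:
            raise ValueError("ift_smoothness must be non-negative")
        if self.mw_reference[0] <= 0 or self.mw_reference[1] <= 0:
            raise ValueError("mw_reference values must be positive")
        if self.specific_volume <= 0 or self.k_const <= 0:
            raise ValueError("specific_volume and k_const must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        """Stable hash identifying this configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Parse a simple ``key = value`` configuration file.

        Unknown keys raise; anneal schedule fields use an ``anneal.``
        prefix; ``mw_reference`` takes two comma-separated numbers.
        """
        kwargs = {}
        anneal_kwargs = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {raw!r}")
            key, val = (t.strip() for t in line.split("=", 1))
            if key.startswith("anneal."):
                fname = key[len("anneal."):]
                ftype = {f.name: f.type for f in dataclasses.fields(AnnealSchedule)}
                if fname not in ftype:
                    raise ValueError(f"unknown config key: {key}")
                anneal_kwargs[fname] = int(val) if fname in ("moves_per_bead", "max_levels", "patience") else float(val)
            elif key == "mw_reference":
                a, b = (float(t) for t in val.split(","))
                kwargs[key] = (a, b)
            elif key in ("random_seed", "restore_replicates"):
                kwargs[key] = int(val)
            elif key in {f.name for f in dataclasses.fields(cls)}:
                kwargs[key] = float(val)
            else:
                raise ValueError(f"unknown config key: {key}")
        if anneal_kwargs:
            kwargs["anneal"] = AnnealSchedule(**anneal_kwargs)
        return cls(**kwargs)
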