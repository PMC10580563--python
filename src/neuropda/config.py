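"""Session configuration: one structured object holding every default.

Constants that operationalize the protocol (baseline 25 volumes, 2-SD
outlier pause, 10% radius shrink, 25% gain recalibration with the 3-5 hit
band, TR 1200 ms, 150-volume feedback runs, 0.008-0.09 Hz bandpass) live
here with their provenance tag; artifact-chosen values (grid size, noise
level, initial gain) are tagged accordingly so emitted configs are
self-documenting.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict

import yaml

from .bold_sim import AcquisitionParams, PhantomSpec, SignalSpec
from .feedback import ScenarioSpec
from .localizer import PreprocParams
from .postconn import CleaningParams


@dataclass
class SessionConfig:
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    signal: SignalSpec = field(default_factory=SignalSpec)
    scenario: ScenarioSpec = field(default_factory=ScenarioSpec)
    preproc: PreprocParams = field(default_factory=PreprocParams)
    cleaning: CleaningParams = field(default_factory=CleaningParams)
    dose: str = "min15"
    baseline_volumes: int = 25
    outlier_sd: float = 2.0
    radius_shrink: float = 0.10
    gain_up: float = 1.25
    gain_down: float = 0.75
    hit_band: tuple = (3, 5)
    initial_gain: float = 0.05
    radius_mode: str = "boundary"
    seed: int = 0

    #: which defaults are protocol constants vs artifact choices
    PROVENANCE = {
        "baseline_volumes": "protocol",
        "outlier_sd": "protocol",
        "radius_shrink": "protocol",
        "gain_up": "protocol",
        "gain_down": "protocol",
        "hit_band": "protocol",
        "initial_gain": "artifact-chosen",
        "radius_mode": "artifact-chosen",
        "seed": "artifact-chosen",
    }

    def to_dict(self) -> Dict:
        d = asdict(self)
        d["phantom"].pop("region_voxels", None)  # concrete voxels are bulky
        d["signal"]["outlier_volumes"] = sorted(d["signal"]["outlier_volumes"])
        d["provenance"] = dict(self.PROVENANCE)
        return d

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def load_config(path) -> SessionConfig:
    raw = yaml.safe_load(Path(path).read_text())
    raw.pop("provenance", None)
    kwargs = {}
    builders = {
        "phantom": PhantomSpec, "acquisition": AcquisitionParams,
        "signal": SignalSpec, "scenario": ScenarioSpec,
        "preproc": PreprocParams, "cleaning": CleaningParams,
    }
    for key, value in raw.items():
        if key in builders and isinstance(value, dict):
            if key == "phantom":
                value = {k: (tuple(v) if k == "grid_shape" else v)
                         for k, v in value.items()}
            if key == "signal" and "outlier_volumes" in value:
                value["outlier_volumes"] = frozenset(value["outlier_volumes"])
            if key == "cleaning" and "bandpass_hz" in value:
                value["bandpass_hz"] = tuple(value["bandpass_hz"])
            kwargs[key] = builders[key](**value)
        elif key == "hit_band":
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return SessionConfig(**kwargs)
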