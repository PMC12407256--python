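"""Run configuration: drugs, simulator settings, network hyperparameters.

Every stochastic stage derives its seed deterministically from the master
seed, so a config + seed pair pins down the whole run.  Configs round-trip
through YAML.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import yaml

from .simulate import (
    AcquisitionMode,
    CalibrationDesign,
    NoiseModel,
    ShapeDistribution,
)
from .unet import UNetConfig


@dataclass(frozen=True)
class DrugConfig:
    """Calibration range and fragment windows for one analyte.

    The fragment m/z values are placeholders (the real transition table is
    instrument-specific and not public); window position has no effect on any
    computed statistic.
    """

    name: str
    low: float
    high: float
    is_concentration: float = 100.0
    analyte_mz: float = 260.2
    is_mz: float = 266.2
    response_factor_analyte: float = 100.0
    response_factor_is: float = 100.0
    qc_high: float | None = None
    qc_low: float | None = None

    def design(self, replicates: int = 1, n_levels: int = 8) -> CalibrationDesign:
        return CalibrationDesign.doubling(
            self.low, self.high, n_levels=n_levels, replicates=replicates,
            is_concentration=self.is_concentration,
            response_factor_analyte=self.response_factor_analyte,
            response_factor_is=self.response_factor_is,
            analyte_mz=self.analyte_mz, is_mz=self.is_mz,
        )


def default_drugs() -> tuple:
    # therapeutic ranges: doubling series 10->1280 and 2.5->320 ng/mL
    return (
        DrugConfig(name="venlafaxine", low=10.0, high=1280.0,
                   analyte_mz=260.2, is_mz=266.2, qc_high=960.0, qc_low=60.0),
        DrugConfig(name="desvenlafaxine", low=10.0, high=1280.0,
                   analyte_mz=246.2, is_mz=252.2, qc_high=960.0, qc_low=60.0),
        DrugConfig(name="risperidone", low=2.5, high=320.0,
                   analyte_mz=191.1, is_mz=195.1, qc_high=240.0, qc_low=15.0),
        DrugConfig(name="hydroxyrisperidone", low=2.5, high=320.0,
                   analyte_mz=207.1, is_mz=211.1, qc_high=240.0, qc_low=15.0),
    )


@dataclass(frozen=True)
class RunConfig:
    drugs: tuple = field(default_factory=default_drugs)
    shape_dist: ShapeDistribution = field(default_factory=ShapeDistribution)
    noise: NoiseModel = field(default_factory=NoiseModel)
    mode: AcquisitionMode = AcquisitionMode.PARALLEL
    unet: UNetConfig = field(default_factory=UNetConfig)
    n_train: int = 300
    n_test: int = 100
    n_unknowns: int = 8
    n_clinical: int = 20
    calibration_replicates: int = 1
    seed: int = 1

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        ss = np.random.SeedSequence([self.seed, zlib.crc32(stage.encode())])
        return int(ss.generate_state(1, dtype=np.uint32)[0])

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["mode"] = AcquisitionMode(self.mode).value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        kw: dict = {}
        if "drugs" in d:
            kw["drugs"] = tuple(DrugConfig(**dd) for dd in d.pop("drugs"))
        for key, typ in (
            ("shape_dist", ShapeDistribution), ("noise", NoiseModel),
            ("unet", UNetConfig),
        ):
            if key in d:
                sub = d.pop(key)
                for k, v in list(sub.items()):
                    if isinstance(v, list):
                        sub[k] = tuple(v)
                kw[key] = typ(**sub)
        if "mode" in d:
            kw["mode"] = AcquisitionMode(d.pop("mode"))
        kw.update(d)
        return cls(**kw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_listify(self.to_dict()), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, seed=seed, unet=replace(self.unet, seed=seed))


def _listify(obj):
    """YAML-friendly copy: tuples -> lists, recursively."""
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_listify(v) for v in obj]
    return obj
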