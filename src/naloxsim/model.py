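"""The assembled, calibrated model: every constant the simulator needs."""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, Field

from .params import (
    BiophaseMap,
    FentanylPKParams,
    LigandSpec,
    NaloxonePKParams,
    ReceptorRates,
)

__all__ = ["CalibratedModel"]


class CalibratedModel(BaseModel):
    """Receptor rates, ligand specs, biophase maps and PK constants, plus
    provenance of the calibration that produced them.

    ``occupancy_definition`` selects the receptor pool the reported
    fentanyl occupancy refers to (``"total"`` includes internalized
    fentanyl-bound receptor; ``"surface"`` does not).
    """

    rates: ReceptorRates
    fentanyl: LigandSpec
    naloxone: LigandSpec
    biophase_f: BiophaseMap
    biophase_n: BiophaseMap
    naloxone_pk: NaloxonePKParams
    fentanyl_pk_defaults: dict = Field(
        default_factory=lambda: {"t_half_alpha": 13.0, "t_half_beta": 220.0, "frac_alpha": 0.6}
    )
    occupancy_definition: str = "total"
    #: per-anchor fit residuals in occupancy points (provenance)
    residuals: dict[str, float] = Field(default_factory=dict)
    #: anchors the calibration used (provenance)
    anchors_used: list[dict] = Field(default_factory=list)
    converged: bool = True

    def fentanyl_pk(self, C_peak: float) -> FentanylPKParams:
        return FentanylPKParams(C_peak=C_peak, **self.fentanyl_pk_defaults)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.model_dump(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "CalibratedModel":
        return cls.model_validate(json.loads(Path(path).read_text()))
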