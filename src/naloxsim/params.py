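"""Parameter and state containers for the mu-receptor competition model.

All receptor amounts are expressed as fractions of the baseline total
receptor pool; the absolute pool size (fmol/brain) is carried as metadata
for optional unit conversion only.  Concentrations at the receptor are in
nM, plasma concentrations in ng/ml, times in minutes.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, Field, model_validator

__all__ = [
    "FENTANYL_MW",
    "NALOXONE_MW",
    "LigandSpec",
    "ReceptorRates",
    "ReceptorState",
    "FentanylPKParams",
    "NaloxonePKParams",
    "BiophaseMap",
    "DoseEvent",
    "load_yaml_params",
]

#: Molecular weights (g/mol) used for ng/ml -> nM conversion.
FENTANYL_MW = 336.5
NALOXONE_MW = 327.4


def ngml_to_nm(c_ngml: float, mw: float) -> float:
    """Convert a plasma concentration from ng/ml to nM."""
    return c_ngml * 1000.0 / mw


class LigandSpec(BaseModel):
    """Binding and trafficking behaviour of one mu-receptor ligand.

    Parameters
    ----------
    name : str
        Ligand identifier (``"fentanyl"`` or ``"naloxone"``).
    Ki : float
        Equilibrium inhibition constant, nM.
    koff : float
        Dissociation rate, 1/min.  Only used in kinetic binding mode;
        the association rate is derived as ``kon = koff / Ki``.
    frac_internalized_30min : float
        Fraction of bound surface receptor internalized after 30 minutes,
        in [0, 1).
    """

    name: str
    Ki: float = Field(gt=0)
    koff: float = Field(default=1.0, gt=0)
    frac_internalized_30min: float = Field(ge=0, lt=1)

    @property
    def kon(self) -> float:
        """Association rate, 1/(nM*min), from ``koff / Ki``."""
        return self.koff / self.Ki


class ReceptorRates(BaseModel):
    """First-order rate constants of the receptor trafficking submodel.

    ``k_syn`` is zeroth order (fraction of baseline per minute); all others
    are first order (1/min).  At the ligand-free baseline steady state
    ``k_syn = k_deg_free * R_free_ss`` with ``R_free_ss = 1``.
    """

    k_syn: float = Field(ge=0)
    k_deg_free: float = Field(ge=0)
    k_deg_bound: float = Field(ge=0)
    k_int_f: float = Field(ge=0)
    k_int_n: float = Field(ge=0)
    k_rec: float = Field(ge=0)

    def with_(self, **kwargs: float) -> "ReceptorRates":
        return self.model_copy(update=kwargs)


class ReceptorState(BaseModel):
    """The six receptor pools, as fractions of baseline total receptor.

    Surface pools: free (``R_s``), fentanyl-bound (``RF_s``),
    naloxone-bound (``RN_s``); ``R_i``/``RF_i``/``RN_i`` are the
    corresponding internalized pools.
    """

    R_s: float = Field(ge=0)
    RF_s: float = Field(ge=0)
    RN_s: float = Field(ge=0)
    R_i: float = Field(ge=0)
    RF_i: float = Field(ge=0)
    RN_i: float = Field(ge=0)
    #: absolute baseline pool size, fmol/brain (metadata only)
    total_fmol: float = 2.37e7

    @classmethod
    def baseline(cls) -> "ReceptorState":
        """Ligand-free steady state: all receptor free at the surface."""
        return cls(R_s=1.0, RF_s=0.0, RN_s=0.0, R_i=0.0, RF_i=0.0, RN_i=0.0)

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.R_s, self.RF_s, self.RN_s, self.R_i, self.RF_i, self.RN_i]
        )

    @classmethod
    def from_array(cls, y: np.ndarray) -> "ReceptorState":
        return cls(
            R_s=max(y[0], 0.0), RF_s=max(y[1], 0.0), RN_s=max(y[2], 0.0),
            R_i=max(y[3], 0.0), RF_i=max(y[4], 0.0), RN_i=max(y[5], 0.0),
        )

    @property
    def total(self) -> float:
        return self.R_s + self.RF_s + self.RN_s + self.R_i + self.RF_i + self.RN_i


class FentanylPKParams(BaseModel):
    """Bi-exponential clearance-phase fentanyl plasma PK from peak.

    ``C(t) = C_peak * (f * 2^(-t/t_half_alpha) + (1-f) * 2^(-t/t_half_beta))``
    with ``t = 0`` at the plasma peak.
    """

    C_peak: float = Field(gt=0)
    t_half_alpha: float = Field(default=13.0, gt=0)
    t_half_beta: float = Field(default=220.0, gt=0)
    frac_alpha: float = Field(default=0.6, ge=0, le=1)


class NaloxonePKParams(BaseModel):
    """Naloxone plasma PK: first-order IM absorption into a two-compartment
    disposition model (linear).

    Volumes in L, clearances in L/min, ``ka`` in 1/min.  ``F_IM`` is the
    absolute IM bioavailability; IN dosing is handled by converting to an
    IM-equivalent dose with ``in_to_im_factor`` (~0.45 relative
    bioavailability of the IN route).
    """

    ka: float = Field(gt=0)
    V1: float = Field(gt=0)
    V2: float = Field(gt=0)
    CL: float = Field(gt=0)
    Q: float = Field(gt=0)
    F_IM: float = Field(gt=0, le=1)
    in_to_im_factor: float = Field(default=0.45, gt=0, le=1)


class BiophaseMap(BaseModel):
    """Calibrated mapping from plasma concentration to receptor-site (ISF)
    concentration.

    The steady-state target is a monotone function of the molar plasma
    concentration ``Cp`` (nM):

    * ``linear``: ``a * Cp`` — constant brain/plasma partition;
    * ``power``: ``a * Cp**b``;
    * ``hill``: ``a * Cp**b * (1 + (Cp/c50)**h)`` — power-law partition
      whose free receptor-site fraction rises as a saturable brain depot
      (nonspecific binding / efflux) with half-saturation ``c50`` and Hill
      coefficient ``h`` fills up.  Low-exposure behaviour is the plain
      power law; above ``c50`` the map steepens.

    The biophase state relaxes toward the target with first-order rate
    ``ke0``; the default ``ke0 = ln(100) ~ 4.6 /min`` puts the biophase at
    99% of a step target within one minute, matching the < 1 min appearance
    of both drugs in brain.
    """

    form: Literal["linear", "power", "hill"] = "linear"
    a: float = Field(gt=0)
    b: float = Field(default=1.0, gt=0)
    c50: float = Field(default=100.0, gt=0)
    h: float = Field(default=2.0, gt=0)
    ke0: float = Field(default=math.log(100.0), gt=0)
    mw: float = Field(gt=0)

    @model_validator(mode="after")
    def _monotone(self) -> "BiophaseMap":
        if self.form == "linear" and self.b != 1.0:
            raise ValueError("linear map must have b = 1")
        return self

    def target(self, c_plasma_ngml: float | np.ndarray) -> float | np.ndarray:
        """Steady-state biophase concentration (nM) for a plasma level (ng/ml)."""
        scalar = np.ndim(c_plasma_ngml) == 0
        if scalar:
            cp = c_plasma_ngml * 1000.0 / self.mw
            if self.form == "linear":
                return self.a * cp
            if self.form == "power":
                return self.a * cp ** self.b
            return self.a * cp ** self.b * (1.0 + (cp / self.c50) ** self.h)
        cp = np.asarray(c_plasma_ngml, dtype=float) * 1000.0 / self.mw
        if self.form == "linear":
            return self.a * cp
        if self.form == "power":
            return self.a * np.power(cp, self.b)
        return self.a * np.power(cp, self.b) * (1.0 + np.power(cp / self.c50, self.h))

    def scalar_target_fn(self):
        """A plain-float closure of :meth:`target` for ODE right-hand sides."""
        inv_mw = 1000.0 / self.mw
        a, b, c50, h, form = self.a, self.b, self.c50, self.h, self.form
        if form == "linear":
            return lambda c: a * (c * inv_mw)
        if form == "power":
            return lambda c: a * (c * inv_mw) ** b
        def hill(c):
            cp = c * inv_mw
            return a * cp ** b * (1.0 + (cp / c50) ** h)
        return hill


class DoseEvent(BaseModel):
    """A single dose, timed relative to the fentanyl plasma peak."""

    time: float = Field(ge=0)
    drug: str = "naloxone"
    amount: float = Field(ge=0)
    route: Literal["IM", "IN"] = "IM"


def load_yaml_params(path: str | Path) -> dict:
    """Load a YAML parameter file into a plain dict."""
    with open(path) as fh:
        return yaml.safe_load(fh)
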