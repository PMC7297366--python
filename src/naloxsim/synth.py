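"""Synthetic fixtures: occupancy traces with known crossing times,
anchor sets generated from a known model, and perturbed parameter
ensembles.

Every generator is deterministic under a fixed seed, so the test suite
needs no stored data files.  The additive Gaussian noise model (truncated
to [0, 1]) is a device for exercising the threshold-crossing estimator,
not a claim about any measurement process.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibrate import CalibrationAnchor, _equilibrium_occ
from .model import CalibratedModel
from .params import BiophaseMap, ReceptorRates

__all__ = ["SyntheticTrace", "make_trace", "make_anchor_set", "perturb_params"]


@dataclass
class SyntheticTrace:
    """An occupancy trace plus its analytically known 50%-crossing time."""

    trace: pd.DataFrame
    true_t50: float
    shape: str
    params: dict = field(default_factory=dict)
    seed: int | None = None


def make_trace(
    shape: str,
    *,
    occ0: float = 0.8,
    half_life: float = 5.0,
    occ_inf: float = 0.05,
    midpoint: float = 5.0,
    steepness: float = 1.0,
    horizon: float = 30.0,
    grid_step: float = 0.1,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SyntheticTrace:
    """Generate a synthetic fentanyl-occupancy trace with known t50.

    ``exponential-decay``: ``occ(t) = occ0 * 2**(-t/half_life)``.
    ``logistic-reversal``: a fall from ``occ0`` to ``occ_inf`` along a
    logistic in time centred at ``midpoint`` with rate ``steepness``.
    Gaussian noise of ``noise_sd`` occupancy *fraction* is added and the
    trace clipped to [0, 1]; the returned ``true_t50`` is the noise-free
    crossing time.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    t = np.arange(0.0, horizon + grid_step / 2, grid_step)
    if shape == "exponential-decay":
        occ = occ0 * np.exp2(-t / half_life)
        true_t50 = (half_life * math.log2(occ0 / 0.5)
                    if occ0 > 0.5 else 0.0)
        params = {"occ0": occ0, "half_life": half_life}
    elif shape == "logistic-reversal":
        occ = occ_inf + (occ0 - occ_inf) / (1.0 + np.exp(steepness * (t - midpoint)))
        if occ0 > 0.5 > occ_inf:
            frac = (occ0 - occ_inf) / (0.5 - occ_inf) - 1.0
            true_t50 = midpoint + math.log(frac) / steepness
        else:
            true_t50 = math.inf if occ_inf >= 0.5 else 0.0
        params = {"occ0": occ0, "occ_inf": occ_inf, "midpoint": midpoint,
                  "steepness": steepness}
    else:
        raise ValueError(f"unknown trace shape {shape!r}")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        occ = np.clip(occ + rng.normal(0.0, noise_sd, occ.shape), 0.0, 1.0)
    trace = pd.DataFrame({"time_min": t, "occ_f": occ})
    return SyntheticTrace(trace=trace, true_t50=true_t50, shape=shape,
                          params=params, seed=seed)


def make_anchor_set(
    true_map: BiophaseMap,
    true_rates: ReceptorRates,
    plasma_levels: list[float],
    Ki: float = 1.35,
    kinds: str | list[str] = "equilibrium_point",
    model_template: CalibratedModel | None = None,
) -> list[CalibrationAnchor]:
    """Generate calibration anchors by evaluating a known ground-truth
    model, for calibration-recovery tests.

    ``equilibrium_point`` anchors come from the closed-form competitive
    binding isotherm at the mapped biophase concentration (trafficking
    off); ``plateau`` anchors are simulated with the full scenario
    dynamics and require ``model_template``.
    """
    if isinstance(kinds, str):
        kinds = [kinds] * len(plasma_levels)
    anchors = []
    for c, kind in zip(plasma_levels, kinds):
        if kind == "equilibrium_point":
            occ = _equilibrium_occ(true_map, Ki, c)
        elif kind == "plateau":
            if model_template is None:
                raise ValueError("plateau anchors need a model_template")
            from .calibrate import _plateau_occ

            occ = _plateau_occ(
                c, true_map, true_rates,
                model_template.fentanyl, model_template.naloxone,
                model_template.occupancy_definition, model_template,
                grid_step=0.5, rtol=1e-8, atol=1e-10,
            )
        else:
            raise ValueError(f"unknown anchor kind {kind!r}")
        anchors.append(CalibrationAnchor(
            drug="fentanyl", plasma_conc=c, observed=occ, kind=kind))
    return anchors


#: model parameters eligible for ensemble perturbation
PERTURBABLE = ("k_rec", "k_int_f", "k_int_n", "biophase_f.a", "biophase_n.a")


def perturb_params(
    base: CalibratedModel,
    cv: float,
    n: int,
    seed: int = 0,
    which: tuple[str, ...] = PERTURBABLE,
) -> list[CalibratedModel]:
    """Log-normal multiplicative perturbation of selected parameters.

    Each ensemble member multiplies every selected (positive) parameter
    by an independent log-normal factor with coefficient of variation
    ``cv``.  ``cv = 0`` returns ``n`` copies of ``base``.  Deterministic
    under ``seed``.  This enables the between-subject sensitivity
    analysis the single-subject model itself does not attempt.
    """
    if cv < 0:
        raise ValueError("cv must be non-negative")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    members = []
    for _ in range(n):
        m = base.model_copy(deep=True)
        for name in which:
            factor = float(rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma))
            if "." in name:
                obj_name, attr = name.split(".")
                obj = getattr(m, obj_name)
                value = getattr(obj, attr)
                if value <= 0:
                    raise ValueError(f"cannot perturb non-positive {name}")
                setattr(m, obj_name, obj.model_copy(update={attr: value * factor}))
            else:
                value = getattr(m.rates, name)
                if value <= 0:
                    raise ValueError(f"cannot perturb non-positive {name}")
                m.rates = m.rates.model_copy(update={name: value * factor})
        members.append(m)
    return members
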