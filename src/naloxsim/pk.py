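"""Plasma pharmacokinetic forcing functions.

Fentanyl is modelled from its plasma peak: simulations do not resolve the
absorption route, they start at a stated overdose peak concentration and
follow a bi-exponential clearance phase.  Naloxone IM dosing uses
first-order absorption into a linear two-compartment disposition model;
the plasma concentration has the standard tri-exponential closed form, so
no ODE integration is needed for the forcing itself.

Receptor-site (biophase) concentrations relax toward a monotone function
of plasma concentration with first-order rate ``ke0`` (see
:class:`~naloxsim.params.BiophaseMap`); that single extra state per drug is
integrated alongside the receptor pools in the simulation engine.
"""

from __future__ import annotations

import numpy as np

from .params import DoseEvent, FentanylPKParams, NaloxonePKParams

__all__ = [
    "fentanyl_plasma",
    "naloxone_plasma_im",
    "naloxone_auc",
    "in_to_im_equivalent",
    "biophase_step_response",
]


def fentanyl_plasma(t: float | np.ndarray, p: FentanylPKParams) -> float | np.ndarray:
    """Fentanyl plasma concentration (ng/ml) at ``t`` minutes after peak.

    ``C(t) = C_peak * (f * 2^(-t/t_half_alpha) + (1-f) * 2^(-t/t_half_beta))``
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("fentanyl forcing is defined for t >= 0 (t=0 is the peak)")
    c = p.C_peak * (
        p.frac_alpha * np.exp2(-t_arr / p.t_half_alpha)
        + (1.0 - p.frac_alpha) * np.exp2(-t_arr / p.t_half_beta)
    )
    return float(c) if np.ndim(t) == 0 else c


def _two_compartment_rates(p: NaloxonePKParams) -> tuple[float, float, float, float, float]:
    """Micro-rate constants and hybrid disposition exponents (alpha, beta)."""
    k10 = p.CL / p.V1
    k12 = p.Q / p.V1
    k21 = p.Q / p.V2
    s = k10 + k12 + k21
    disc = np.sqrt(s * s - 4.0 * k10 * k21)
    alpha = 0.5 * (s + disc)
    beta = 0.5 * (s - disc)
    return k10, k12, k21, alpha, beta


def naloxone_plasma_im(
    t: float | np.ndarray, p: NaloxonePKParams, event: DoseEvent
) -> float | np.ndarray:
    """Naloxone plasma concentration (ng/ml) after a single IM (or
    IM-equivalent IN) dose.

    First-order absorption of the bioavailable dose ``F_IM * amount`` into
    the central compartment of a two-compartment model.  Zero before the
    dose time.  IN doses are converted with :func:`in_to_im_equivalent`.
    """
    if event.drug != "naloxone":
        raise ValueError(f"unsupported drug {event.drug!r}")
    if event.route == "IM":
        dose_mg = event.amount
    elif event.route == "IN":
        dose_mg = in_to_im_equivalent(event.amount, p.in_to_im_factor)
    else:
        raise ValueError(f"unsupported route {event.route!r}")

    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    tau = t_arr - event.time
    _, _, k21, alpha, beta = _two_compartment_rates(p)
    ka = p.ka
    # guard against coincident exponents (not hit with realistic parameters)
    for lam in (alpha, beta):
        if abs(ka - lam) < 1e-12:
            ka *= 1.0 + 1e-9
    dose_ng = p.F_IM * dose_mg * 1e6  # mg -> ng
    A = dose_ng * ka * (k21 - alpha) / (p.V1 * 1e3 * (ka - alpha) * (beta - alpha))
    B = dose_ng * ka * (k21 - beta) / (p.V1 * 1e3 * (ka - beta) * (alpha - beta))
    C = -(A + B)  # ensures C(0) = 0
    tau_pos = np.clip(tau, 0.0, None)
    conc = A * np.exp(-alpha * tau_pos) + B * np.exp(-beta * tau_pos) + C * np.exp(-ka * tau_pos)
    conc = np.where(tau < 0, 0.0, np.clip(conc, 0.0, None))
    return float(conc[0]) if np.ndim(t) == 0 else conc


def naloxone_auc(p: NaloxonePKParams, event: DoseEvent) -> float:
    """Closed-form AUC (ng*min/ml) over [dose time, inf): ``F*dose/CL``."""
    dose_mg = event.amount if event.route == "IM" else in_to_im_equivalent(
        event.amount, p.in_to_im_factor
    )
    return p.F_IM * dose_mg * 1e6 / (p.CL * 1e3)


def in_to_im_equivalent(dose_in_mg: float, factor: float = 0.45) -> float:
    """IM dose (mg) giving approximately the systemic exposure of an IN
    dose, via the ~45% relative bioavailability of the IN route."""
    if dose_in_mg < 0:
        raise ValueError(f"dose must be non-negative, got {dose_in_mg}")
    return factor * dose_in_mg


def biophase_step_response(t: float | np.ndarray, ke0: float) -> float | np.ndarray:
    """Fraction of a step change in the biophase target reached after
    ``t`` minutes: ``1 - exp(-ke0 * t)``."""
    return 1.0 - np.exp(-ke0 * np.asarray(t, dtype=float))
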