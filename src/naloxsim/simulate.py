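"""Scenario simulation: PK forcing + biophase + receptor trafficking ODEs,
with a naloxone dose event, and the derived outcome metrics.

A scenario starts at the fentanyl plasma peak (t = 0) and runs through
``dose_delay + horizon`` minutes.  The naloxone dose event is handled by
restarting the integrator at the event time, so the discontinuity in the
forcing derivative never crosses a solver step.  Reported metrics (time to
50% occupancy, occupancy at 10 min, ...) are measured on the time axis of
the figures, i.e. minutes since the naloxone dose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field
from scipy.integrate import solve_ivp

from .model import CalibratedModel
from .params import DoseEvent
from .pk import fentanyl_plasma, naloxone_plasma_im

__all__ = ["Scenario", "ScenarioResult", "run", "time_to_threshold", "occupancy_at",
           "NOT_REACHED"]

#: sentinel for a threshold never crossed within the horizon
NOT_REACHED = math.inf

RTOL = 1e-8
ATOL = 1e-10
GRID_STEP = 0.1  # minutes


class Scenario(BaseModel):
    """One dose-escalation experiment cell."""

    fentanyl_peak: float = Field(gt=0)
    naloxone_dose: float = Field(ge=0)
    naloxone_route: str = "IM"
    dose_delay: float = Field(default=5.0, ge=0)
    horizon: float = Field(default=60.0, gt=0)


@dataclass
class ScenarioResult:
    """Occupancy/concentration trace plus the derived outcome metrics.

    ``t50`` is minutes from the naloxone dose to the first downward
    crossing of 50% fentanyl occupancy (``NOT_REACHED`` if it never
    crosses); ``plateau_occ`` is the maximum fentanyl occupancy of the
    matching no-naloxone reference simulation.
    """

    scenario: Scenario
    trace: pd.DataFrame
    plateau_occ: float
    t50: float
    t50_already_below: bool = False
    occ_at: dict[float, float] = field(default_factory=dict)

    @property
    def reached_50(self) -> bool:
        return np.isfinite(self.t50)


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; carries the last valid state."""

    def __init__(self, message: str, t_last: float, y_last: np.ndarray):
        super().__init__(message)
        self.t_last = t_last
        self.y_last = y_last


def _solve(rhs, t0, t1, y0, t_eval, rtol=RTOL, atol=ATOL):
    sol = solve_ivp(
        rhs, (t0, t1), y0, method="LSODA", rtol=rtol, atol=atol,
        t_eval=t_eval, max_step=5.0,
    )
    if not sol.success:
        t_last = sol.t[-1] if sol.t.size else t0
        y_last = sol.y[:, -1] if sol.t.size else y0
        raise IntegrationError(f"ODE integration failed: {sol.message}", t_last, y_last)
    return sol


def _simulate_raw(
    scenario: Scenario,
    model: CalibratedModel,
    mode: str = "equilibrium",
    grid_step: float = GRID_STEP,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> pd.DataFrame:
    """Integrate one scenario and return the full trace DataFrame."""
    fpk = model.fentanyl_pk(scenario.fentanyl_peak)
    event = DoseEvent(
        time=scenario.dose_delay, amount=scenario.naloxone_dose,
        route=scenario.naloxone_route,
    )
    t_end = scenario.dose_delay + scenario.horizon

    # scalar closures (the vectorized pk functions are used for the output
    # trace; these run inside the ODE right-hand side)
    ln2 = math.log(2.0)
    cpk, fa = fpk.C_peak, fpk.frac_alpha
    la, lb = ln2 / fpk.t_half_alpha, ln2 / fpk.t_half_beta

    def c_f_plasma(t):
        return cpk * (fa * math.exp(-la * t) + (1.0 - fa) * math.exp(-lb * t))

    if scenario.naloxone_dose > 0:
        from .pk import _two_compartment_rates

        p = model.naloxone_pk
        _, _, k21, alpha, beta = _two_compartment_rates(p)
        ka = p.ka
        dose_mg = event.amount if event.route == "IM" else event.amount * p.in_to_im_factor
        dose_ng = p.F_IM * dose_mg * 1e6
        A = dose_ng * ka * (k21 - alpha) / (p.V1 * 1e3 * (ka - alpha) * (beta - alpha))
        B = dose_ng * ka * (k21 - beta) / (p.V1 * 1e3 * (ka - beta) * (alpha - beta))
        Cc = -(A + B)
        t_dose = event.time

        def c_n_plasma(t):
            tau = t - t_dose
            if tau <= 0.0:
                return 0.0
            c = A * math.exp(-alpha * tau) + B * math.exp(-beta * tau) + Cc * math.exp(-ka * tau)
            return c if c > 0.0 else 0.0
    else:
        def c_n_plasma(t):
            return 0.0

    lig_f, lig_n, rates = model.fentanyl, model.naloxone, model.rates
    map_f, map_n = model.biophase_f, model.biophase_n

    # hot loop: pre-extract every constant into plain floats
    Ki_f, Ki_n = lig_f.Ki, lig_n.Ki
    kon_f, koff_f = lig_f.kon, lig_f.koff
    kon_n, koff_n = lig_n.kon, lig_n.koff
    k_syn, k_df, k_db = rates.k_syn, rates.k_deg_free, rates.k_deg_bound
    k_if, k_in, k_rec = rates.k_int_f, rates.k_int_n, rates.k_rec
    ke0_f, ke0_n = map_f.ke0, map_n.ke0
    target_f, target_n = map_f.scalar_target_fn(), map_n.scalar_target_fn()

    if mode == "equilibrium":
        n_pool = 4
        def rhs(t, y):
            S, R_i, RF_i, RN_i, cbf, cbn = y
            x_f = cbf / Ki_f
            x_n = cbn / Ki_n
            denom = 1.0 + x_f + x_n
            R_s = S / denom
            RF_s = R_s * x_f
            RN_s = R_s * x_n
            recycle = k_rec * (R_i + RF_i + RN_i)
            dS = (k_syn - k_df * R_s - k_db * (RF_s + RN_s)
                  - k_if * RF_s - k_in * RN_s + recycle)
            dR_i = -(k_rec + k_df) * R_i
            dRF_i = k_if * RF_s - (k_rec + k_db) * RF_i
            dRN_i = k_in * RN_s - (k_rec + k_db) * RN_i
            dcbf = ke0_f * (target_f(c_f_plasma(t)) - cbf)
            dcbn = ke0_n * (target_n(c_n_plasma(t)) - cbn)
            return (dS, dR_i, dRF_i, dRN_i, dcbf, dcbn)
        y0_pools = np.array([1.0, 0.0, 0.0, 0.0])
    elif mode == "kinetic":
        n_pool = 6
        def rhs(t, y):
            R_s, RF_s, RN_s, R_i, RF_i, RN_i, cbf, cbn = y
            bind_f = kon_f * cbf * R_s - koff_f * RF_s
            bind_n = kon_n * cbn * R_s - koff_n * RN_s
            recycle = k_rec * (R_i + RF_i + RN_i)
            dR_s = k_syn - k_df * R_s - bind_f - bind_n + recycle
            dRF_s = bind_f - (k_if + k_db) * RF_s
            dRN_s = bind_n - (k_in + k_db) * RN_s
            dR_i = -(k_rec + k_df) * R_i
            dRF_i = k_if * RF_s - (k_rec + k_db) * RF_i
            dRN_i = k_in * RN_s - (k_rec + k_db) * RN_i
            dcbf = ke0_f * (target_f(c_f_plasma(t)) - cbf)
            dcbn = ke0_n * (target_n(c_n_plasma(t)) - cbn)
            return (dR_s, dRF_s, dRN_s, dR_i, dRF_i, dRN_i, dcbf, dcbn)
        y0_pools = np.array([1.0, 0.0, 0.0, 0.0, 0.0, 0.0])
    else:
        raise ValueError(f"unknown mode {mode!r}")

    # biophase pre-equilibrated to the fentanyl peak (exposure preceded t=0)
    y0 = np.concatenate([y0_pools, [map_f.target(scenario.fentanyl_peak), 0.0]])

    n1 = int(round(event.time / grid_step))
    t_grid1 = np.linspace(0.0, event.time, n1 + 1) if event.time > 0 else None
    n2 = int(round((t_end - event.time) / grid_step))
    t_grid2 = np.linspace(event.time, t_end, n2 + 1)

    segments = []
    if t_grid1 is not None:
        sol1 = _solve(rhs, 0.0, event.time, y0, t_grid1, rtol, atol)
        segments.append((sol1.t[:-1], sol1.y[:, :-1]))
        y0 = sol1.y[:, -1]
    sol2 = _solve(rhs, event.time, t_end, y0, t_grid2, rtol, atol)
    segments.append((sol2.t, sol2.y))

    t = np.concatenate([s[0] for s in segments])
    Y = np.concatenate([s[1] for s in segments], axis=1)

    cbf, cbn = Y[n_pool], Y[n_pool + 1]
    if mode == "equilibrium":
        S, R_i, RF_i, RN_i = Y[0], Y[1], Y[2], Y[3]
        x_f = cbf / lig_f.Ki
        x_n = cbn / lig_n.Ki
        denom = 1.0 + x_f + x_n
        R_s, RF_s, RN_s = S / denom, S * x_f / denom, S * x_n / denom
    else:
        R_s, RF_s, RN_s, R_i, RF_i, RN_i = Y[:6]

    total = R_s + RF_s + RN_s + R_i + RF_i + RN_i
    surface = R_s + RF_s + RN_s
    if model.occupancy_definition == "total":
        occ_f = (RF_s + RF_i) / total
        occ_n = (RN_s + RN_i) / total
    else:
        occ_f = RF_s / surface
        occ_n = RN_s / surface

    if scenario.naloxone_dose > 0:
        c_n_trace = naloxone_plasma_im(t, model.naloxone_pk, event)
    else:
        c_n_trace = np.zeros_like(t)
    return pd.DataFrame({
        "time_min": t,
        "C_f_plasma": fentanyl_plasma(t, fpk),
        "C_n_plasma": c_n_trace,
        "C_f_biophase": cbf,
        "C_n_biophase": cbn,
        "R_s": R_s, "RF_s": RF_s, "RN_s": RN_s,
        "R_i": R_i, "RF_i": RF_i, "RN_i": RN_i,
        "occ_f": occ_f, "occ_n": occ_n,
    })


def run(
    scenario: Scenario,
    model: CalibratedModel,
    mode: str = "equilibrium",
    grid_step: float = GRID_STEP,
    occ_at_times: tuple[float, ...] = (10.0,),
) -> ScenarioResult:
    """Run one scenario and compute its outcome metrics.

    The no-naloxone reference simulation of the same exposure and horizon
    supplies ``plateau_occ``; ``t50`` and ``occ_at`` are measured from the
    naloxone dose time.
    """
    trace = _simulate_raw(scenario, model, mode=mode, grid_step=grid_step)
    if scenario.naloxone_dose > 0:
        ref = _simulate_raw(
            scenario.model_copy(update={"naloxone_dose": 0.0}),
            model, mode=mode, grid_step=grid_step,
        )
    else:
        ref = trace
    plateau = float(ref["occ_f"].max())
    t50, already_below = time_to_threshold(trace, 0.5, origin=scenario.dose_delay)
    occ_at = {
        ta: occupancy_at(trace, ta, origin=scenario.dose_delay)
        for ta in occ_at_times
        if scenario.dose_delay + ta <= trace["time_min"].iloc[-1] + 1e-9
    }
    return ScenarioResult(
        scenario=scenario, trace=trace, plateau_occ=plateau,
        t50=t50, t50_already_below=already_below, occ_at=occ_at,
    )


def time_to_threshold(
    trace: pd.DataFrame, threshold: float = 0.5, origin: float = 0.0
) -> tuple[float, bool]:
    """First downward crossing of ``threshold`` by fentanyl occupancy.

    Returns ``(t_cross, already_below)`` with ``t_cross`` in minutes after
    ``origin`` (linear interpolation between bracketing samples),
    ``NOT_REACHED`` if the occupancy stays above threshold through the end
    of the trace, and ``(0.0, True)`` if the trace starts at or below the
    threshold.
    """
    t = trace["time_min"].to_numpy()
    occ = trace["occ_f"].to_numpy()
    mask = t >= origin - 1e-9
    t, occ = t[mask], occ[mask]
    if t.size == 0:
        raise ValueError("trace does not cover the requested origin")
    if occ[0] <= threshold:
        return 0.0, True
    below = np.nonzero(occ <= threshold)[0]
    if below.size == 0:
        return NOT_REACHED, False
    i = below[0]
    # linear interpolation between the bracketing samples
    frac = (occ[i - 1] - threshold) / (occ[i - 1] - occ[i])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]) - origin), False


def occupancy_at(trace: pd.DataFrame, t_post: float, origin: float = 0.0) -> float:
    """Fentanyl occupancy ``t_post`` minutes after ``origin``, linearly
    interpolated on the output grid."""
    t = trace["time_min"].to_numpy()
    t_abs = origin + t_post
    if t_abs < t[0] - 1e-9 or t_abs > t[-1] + 1e-9:
        raise ValueError(f"time {t_post} min post-origin is outside the trace span")
    return float(np.interp(t_abs, t, trace["occ_f"].to_numpy()))
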