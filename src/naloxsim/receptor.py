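"""Mu-receptor submodel: competitive binding, synthesis/degradation,
ligand-specific internalization and recycling.

Two binding modes are supported.  In *kinetic* mode the bound surface pools
are explicit states with association/dissociation fluxes
``kon*C*R_s - koff*RB_s`` (``kon = koff/Ki``).  In *equilibrium* mode the
surface pool is partitioned instantaneously among free, fentanyl-bound and
naloxone-bound receptor by the competitive-binding isotherm, and only the
(much slower) trafficking fluxes are integrated.  Equilibrium mode is the
default for scenario runs; kinetic mode converges to it as ``koff`` grows
at fixed ``Ki``.

Internalized bound receptor is assumed to release its ligand in the
endosome and recycle to the free surface pool at ``k_rec``.  Free receptor
degrades with a 12 h half-life and bound receptor (surface or internalized)
with a 7 h half-life; synthesis is zeroth order and balances free-receptor
degradation at the ligand-free baseline.
"""

from __future__ import annotations

import math
from typing import Callable, Literal

import numpy as np

from .params import LigandSpec, ReceptorRates, ReceptorState

__all__ = [
    "rate_from_halflife",
    "halflife_from_rate",
    "internalization_rate",
    "equilibrium_occupancy",
    "concentration_for_occupancy",
    "receptor_odes",
    "kinetic_rhs",
    "equilibrium_rhs",
    "fentanyl_occupancy_metric",
]

OccupancyDefinition = Literal["surface", "total"]


def rate_from_halflife(t_half: float) -> float:
    """First-order rate constant (1/min) from a half-life (min)."""
    if t_half <= 0:
        raise ValueError(f"half-life must be positive, got {t_half}")
    return math.log(2.0) / t_half


def halflife_from_rate(k: float) -> float:
    """Inverse of :func:`rate_from_halflife`."""
    if k <= 0:
        raise ValueError(f"rate must be positive, got {k}")
    return math.log(2.0) / k


def internalization_rate(frac_30: float, window: float = 30.0) -> float:
    """First-order internalization rate (1/min) that alone removes
    ``frac_30`` of the bound pool within ``window`` minutes.

    Recycling and degradation over the observation window are neglected,
    so the rate solves ``1 - exp(-k*window) = frac_30``.
    """
    if not 0.0 <= frac_30 < 1.0:
        raise ValueError(f"frac_30 must be in [0, 1), got {frac_30}")
    if window <= 0:
        raise ValueError(f"window must be positive, got {window}")
    return -math.log1p(-frac_30) / window


def equilibrium_occupancy(
    C_f: float, C_n: float, lig_f: LigandSpec, lig_n: LigandSpec
) -> tuple[float, float, float]:
    """Competitive-binding occupancy of surface receptor at equilibrium.

    Returns ``(occ_f, occ_n, free)``; the three fractions sum to 1 exactly:

    ``occ_f = (C_f/Ki_f) / (1 + C_f/Ki_f + C_n/Ki_n)``

    Parameters are receptor-site concentrations in nM.
    """
    if C_f < 0 or C_n < 0:
        raise ValueError(f"concentrations must be non-negative, got {C_f}, {C_n}")
    x_f = C_f / lig_f.Ki
    x_n = C_n / lig_n.Ki
    denom = 1.0 + x_f + x_n
    return x_f / denom, x_n / denom, 1.0 / denom


def concentration_for_occupancy(occ: float, Ki: float) -> float:
    """Invert the single-ligand binding isotherm: the concentration (nM)
    occupying fraction ``occ`` of receptor with no competitor present,
    ``C = Ki * occ / (1 - occ)``."""
    if not 0.0 <= occ < 1.0:
        raise ValueError(f"occupancy must be in [0, 1), got {occ}")
    return Ki * occ / (1.0 - occ)


def kinetic_rhs(
    y: np.ndarray,
    C_f: float,
    C_n: float,
    rates: ReceptorRates,
    lig_f: LigandSpec,
    lig_n: LigandSpec,
) -> np.ndarray:
    """Time derivative of the six pools with explicit binding kinetics.

    State order: ``[R_s, RF_s, RN_s, R_i, RF_i, RN_i]``.
    """
    R_s, RF_s, RN_s, R_i, RF_i, RN_i = y
    bind_f = lig_f.kon * C_f * R_s - lig_f.koff * RF_s
    bind_n = lig_n.kon * C_n * R_s - lig_n.koff * RN_s
    recycle = rates.k_rec * (R_i + RF_i + RN_i)
    dR_s = rates.k_syn - rates.k_deg_free * R_s - bind_f - bind_n + recycle
    dRF_s = bind_f - rates.k_int_f * RF_s - rates.k_deg_bound * RF_s
    dRN_s = bind_n - rates.k_int_n * RN_s - rates.k_deg_bound * RN_s
    dR_i = -rates.k_rec * R_i - rates.k_deg_free * R_i
    dRF_i = rates.k_int_f * RF_s - rates.k_rec * RF_i - rates.k_deg_bound * RF_i
    dRN_i = rates.k_int_n * RN_s - rates.k_rec * RN_i - rates.k_deg_bound * RN_i
    return np.array([dR_s, dRF_s, dRN_s, dR_i, dRF_i, dRN_i])


def partition_surface(
    S: float, C_f: float, C_n: float, lig_f: LigandSpec, lig_n: LigandSpec
) -> tuple[float, float, float]:
    """Split a total surface pool ``S`` into (free, fentanyl-bound,
    naloxone-bound) by the equilibrium isotherm."""
    occ_f, occ_n, free = equilibrium_occupancy(C_f, C_n, lig_f, lig_n)
    return S * free, S * occ_f, S * occ_n


def equilibrium_rhs(
    y: np.ndarray,
    C_f: float,
    C_n: float,
    rates: ReceptorRates,
    lig_f: LigandSpec,
    lig_n: LigandSpec,
) -> np.ndarray:
    """Trafficking-only derivative with instantaneous surface binding.

    Reduced state order: ``[S, R_i, RF_i, RN_i]`` where ``S`` is the total
    surface pool.  Surface binding is partitioned algebraically each
    instant, so only synthesis, degradation, internalization and recycling
    fluxes appear.
    """
    S, R_i, RF_i, RN_i = y
    R_s, RF_s, RN_s = partition_surface(S, C_f, C_n, lig_f, lig_n)
    dS = (
        rates.k_syn
        - rates.k_deg_free * R_s
        - rates.k_deg_bound * (RF_s + RN_s)
        - rates.k_int_f * RF_s
        - rates.k_int_n * RN_s
        + rates.k_rec * (R_i + RF_i + RN_i)
    )
    dR_i = -rates.k_rec * R_i - rates.k_deg_free * R_i
    dRF_i = rates.k_int_f * RF_s - rates.k_rec * RF_i - rates.k_deg_bound * RF_i
    dRN_i = rates.k_int_n * RN_s - rates.k_rec * RN_i - rates.k_deg_bound * RN_i
    return np.array([dS, dR_i, dRF_i, dRN_i])


def receptor_odes(
    state: ReceptorState,
    C_f: float | Callable[[float], float],
    C_n: float | Callable[[float], float],
    rates: ReceptorRates,
    lig_f: LigandSpec,
    lig_n: LigandSpec,
    mode: Literal["kinetic", "equilibrium"] = "kinetic",
    t: float = 0.0,
) -> ReceptorState:
    """Time derivative of the six receptor pools at time ``t``.

    ``C_f``/``C_n`` are receptor-site concentrations in nM, given either
    as constants or as callables of time.  In equilibrium mode the surface
    pools are first projected onto the instantaneous binding partition;
    the returned derivative then contains trafficking fluxes only.
    """
    cf = C_f(t) if callable(C_f) else C_f
    cn = C_n(t) if callable(C_n) else C_n
    if cf is None or cn is None or not np.isfinite(cf) or not np.isfinite(cn):
        raise ValueError(f"forcing undefined at t={t}")
    y = state.to_array()
    if mode == "kinetic":
        dy = kinetic_rhs(y, cf, cn, rates, lig_f, lig_n)
    elif mode == "equilibrium":
        S = y[0] + y[1] + y[2]
        d4 = equilibrium_rhs(np.array([S, y[3], y[4], y[5]]), cf, cn, rates, lig_f, lig_n)
        # report the surface derivative on the equilibrium partition
        frac = np.array(partition_surface(1.0, cf, cn, lig_f, lig_n))
        dy = np.concatenate([frac * d4[0], d4[1:]])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    # derivatives may be negative, so bypass the non-negativity validators
    return ReceptorState.model_construct(
        R_s=dy[0], RF_s=dy[1], RN_s=dy[2], R_i=dy[3], RF_i=dy[4], RN_i=dy[5],
        total_fmol=state.total_fmol,
    )


def fentanyl_occupancy_metric(
    state: ReceptorState, definition: OccupancyDefinition = "total"
) -> float:
    """Fraction of a receptor pool occupied by fentanyl.

    ``surface``: fentanyl-bound surface receptor over all surface receptor.
    ``total``: fentanyl-bound receptor (surface + internalized) over all
    six pools.  The ``total`` definition counts internalized fentanyl-bound
    receptor as occupied, reflecting that internalized receptor is not
    available for reversal until it recycles.
    """
    if definition == "surface":
        denom = state.R_s + state.RF_s + state.RN_s
        num = state.RF_s
    elif definition == "total":
        denom = state.total
        num = state.RF_s + state.RF_i
    else:
        raise ValueError(f"unknown occupancy definition {definition!r}")
    if denom <= 0:
        raise ValueError("occupancy undefined for an empty receptor pool")
    return num / denom
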