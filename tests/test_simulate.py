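"""Simulation engine: trajectory invariants, metric extraction, and the
dynamic oracles (kinetic -> equilibrium limit, closed-form binding)."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import solve_ivp

from naloxsim.receptor import equilibrium_occupancy, kinetic_rhs
from naloxsim.simulate import (
    NOT_REACHED,
    Scenario,
    _simulate_raw,
    occupancy_at,
    run,
    time_to_threshold,
)
from naloxsim.synth import make_trace

POOLS = ["R_s", "RF_s", "RN_s", "R_i", "RF_i", "RN_i"]


class TestTimeToThreshold:
    def test_exponential_decay_closed_form(self):
        st = make_trace("exponential-decay", occ0=0.8, half_life=5.0)
        t50, below = time_to_threshold(st.trace, 0.5)
        assert not below
        assert t50 == pytest.approx(st.true_t50, abs=0.01)  # 5*log2(1.6) = 3.39

    def test_never_crossing_trace(self):
        trace = pd.DataFrame({"time_min": np.arange(0, 30, 0.1),
                              "occ_f": np.full(300, 0.6)})
        t50, below = time_to_threshold(trace, 0.5)
        assert t50 == NOT_REACHED and not below

    def test_already_below_trace(self):
        trace = pd.DataFrame({"time_min": np.arange(0, 30, 0.1),
                              "occ_f": np.full(300, 0.4)})
        t50, below = time_to_threshold(trace, 0.5)
        assert t50 == 0.0 and below


class TestOccupancyAt:
    def test_on_grid_value_exact(self):
        st = make_trace("exponential-decay", occ0=0.8, half_life=5.0)
        idx = 50  # t = 5.0 min
        t = st.trace["time_min"].iloc[idx]
        assert occupancy_at(st.trace, t) == st.trace["occ_f"].iloc[idx]

    def test_beyond_horizon_rejected(self):
        st = make_trace("exponential-decay")
        with pytest.raises(ValueError):
            occupancy_at(st.trace, 1e4)


class TestTrajectoryInvariants:
    def test_nonnegative_pools_with_naloxone(self, uncalibrated_model):
        tr = _simulate_raw(Scenario(fentanyl_peak=50, naloxone_dose=10),
                           uncalibrated_model, mode="kinetic")
        assert (tr[POOLS].to_numpy() > -1e-12).all()

    def test_conservation_without_turnover_24h(self, uncalibrated_model):
        m = uncalibrated_model.model_copy(update={
            "rates": uncalibrated_model.rates.model_copy(
                update={"k_syn": 0.0, "k_deg_free": 0.0, "k_deg_bound": 0.0})})
        tr = _simulate_raw(Scenario(fentanyl_peak=50, naloxone_dose=2,
                                    horizon=24 * 60), m, mode="kinetic",
                           grid_step=1.0)
        total = tr[POOLS].sum(axis=1).to_numpy()
        assert np.max(np.abs(total - 1.0)) < 1e-8

    def test_ligand_free_steady_state_24h(self, uncalibrated_model):
        tr = _simulate_raw(Scenario(fentanyl_peak=1e-12, naloxone_dose=0,
                                    dose_delay=0, horizon=24 * 60),
                           uncalibrated_model, mode="kinetic", grid_step=5.0)
        drift = np.abs(tr[POOLS].to_numpy() - np.array([1, 0, 0, 0, 0, 0]))
        assert drift.max() < 1e-6

    def test_biophase_peak_lags_plasma_peak(self, uncalibrated_model):
        tr = _simulate_raw(Scenario(fentanyl_peak=50, naloxone_dose=2),
                           uncalibrated_model)
        t = tr["time_min"].to_numpy()
        t_plasma_peak = t[np.argmax(tr["C_n_plasma"].to_numpy())]
        t_bio_peak = t[np.argmax(tr["C_n_biophase"].to_numpy())]
        assert t_bio_peak >= t_plasma_peak


class TestBindingOracles:
    def test_kinetic_converges_to_equilibrium_mode(self, uncalibrated_model):
        """Max trace discrepancy falls monotonically as koff grows at fixed
        Ki; at koff = 100/min the two modes agree within 1% after 1 min."""
        sc = Scenario(fentanyl_peak=50, naloxone_dose=0, dose_delay=0)
        eq = _simulate_raw(sc, uncalibrated_model, mode="equilibrium")
        discs = []
        for koff in (1.0, 10.0, 100.0):
            m = uncalibrated_model.model_copy(update={
                "fentanyl": uncalibrated_model.fentanyl.model_copy(update={"koff": koff}),
                "naloxone": uncalibrated_model.naloxone.model_copy(update={"koff": koff}),
            })
            kin = _simulate_raw(sc, m, mode="kinetic")
            mask = kin["time_min"].to_numpy() > 1.0
            discs.append(np.max(np.abs(
                kin["occ_f"].to_numpy() - eq["occ_f"].to_numpy())[mask]))
        assert discs[0] > discs[1] > discs[2]
        assert discs[2] < 0.01

    def test_constant_forcing_matches_closed_form(self, uncalibrated_model):
        """With trafficking off, long-time kinetic surface occupancy equals
        the competitive-binding isotherm to 1e-6."""
        rates = uncalibrated_model.rates.model_copy(update={
            "k_syn": 0, "k_deg_free": 0, "k_deg_bound": 0,
            "k_int_f": 0, "k_int_n": 0, "k_rec": 0})
        lig_f, lig_n = uncalibrated_model.fentanyl, uncalibrated_model.naloxone
        C_f, C_n = 2.0, 1.5
        sol = solve_ivp(lambda t, y: kinetic_rhs(y, C_f, C_n, rates, lig_f, lig_n),
                        (0.0, 500.0), [1, 0, 0, 0, 0, 0], rtol=1e-10, atol=1e-12)
        occ_f, occ_n, _ = equilibrium_occupancy(C_f, C_n, lig_f, lig_n)
        assert abs(sol.y[1, -1] - occ_f) < 1e-6
        assert abs(sol.y[2, -1] - occ_n) < 1e-6


class TestScenarioMetrics:
    def test_vanishing_fentanyl_gives_zero_occupancy(self, uncalibrated_model):
        res = run(Scenario(fentanyl_peak=1e-9, naloxone_dose=2), uncalibrated_model)
        assert res.trace["occ_f"].max() < 1e-9
        assert res.t50_already_below

    def test_dose_monotonicity(self, calibrated_model, grid_table):
        """More naloxone: occupancy at 10 min never higher, t50 never later."""
        for f in (25.0, 50.0, 75.0):
            sub = grid_table[(grid_table.fentanyl_peak_ngml == f)
                             & (grid_table.naloxone_dose_mg > 0)]
            sub = sub.sort_values("naloxone_dose_mg")
            occ10 = sub["occ10_pct"].to_numpy()
            t50 = sub["t50_min"].to_numpy()
            assert np.all(np.diff(occ10) <= 1e-9)
            assert np.all(np.diff(t50) <= 1e-9)

    def test_exposure_monotonicity(self, grid_table):
        """More fentanyl at fixed dose: reversal never faster."""
        for d in (2.0, 5.0, 10.0):
            sub = grid_table[grid_table.naloxone_dose_mg == d]
            sub = sub.sort_values("fentanyl_peak_ngml")
            assert np.all(np.diff(sub["t50_min"].to_numpy()) >= -1e-9)

    def test_deterministic_rerun(self, calibrated_model):
        sc = Scenario(fentanyl_peak=50, naloxone_dose=5)
        r1 = run(sc, calibrated_model)
        r2 = run(sc, calibrated_model)
        assert r1.t50 == r2.t50
        assert r1.plateau_occ == r2.plateau_occ
        assert (r1.trace["occ_f"] == r2.trace["occ_f"]).all()

    def test_delayed_dosing_never_speeds_reversal_sustained_exposure(
            self, calibrated_model):
        """Under sustained fentanyl exposure, dosing later never shortens
        the reversal time (more receptor has internalized meanwhile).
        With a decaying plasma curve a later dose meets less fentanyl, so
        the property is specific to non-increasing *sustained* forcing."""
        m = calibrated_model.model_copy(deep=True)
        m.fentanyl_pk_defaults = dict(m.fentanyl_pk_defaults,
                                      t_half_alpha=1e6, t_half_beta=1e6)
        t50s = [run(Scenario(fentanyl_peak=50, naloxone_dose=5, dose_delay=dly),
                    m).t50
                for dly in (5.0, 10.0, 20.0)]
        assert t50s[0] <= t50s[1] <= t50s[2]

    def test_grid_refinement_stability(self, calibrated_model):
        """Halving the output grid step moves t50 by < 0.05 min."""
        sc = Scenario(fentanyl_peak=50, naloxone_dose=5)
        coarse = run(sc, calibrated_model, grid_step=0.1).t50
        fine = run(sc, calibrated_model, grid_step=0.05).t50
        assert abs(coarse - fine) < 0.05

    def test_plateau_insensitive_to_terminal_halflife(self, calibrated_model):
        """+/-50% on the fentanyl terminal half-life moves the no-naloxone
        plateau by well under a percentage point."""
        base = run(Scenario(fentanyl_peak=25, naloxone_dose=0), calibrated_model)
        for factor in (0.5, 1.5):
            m = calibrated_model.model_copy(deep=True)
            m.fentanyl_pk_defaults = dict(m.fentanyl_pk_defaults)
            m.fentanyl_pk_defaults["t_half_beta"] *= factor
            res = run(Scenario(fentanyl_peak=25, naloxone_dose=0), m)
            assert res.plateau_occ == pytest.approx(base.plateau_occ, abs=0.01)
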