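"""Rate derivation from the literature table and biophase calibration,
including parameter recovery on synthetic ground truth."""

import copy
import math

import numpy as np
import pytest

from naloxsim.calibrate import (
    CalibrationFailure,
    check_naloxone_occupancy,
    derive_rates,
    fit_biophase,
)
from naloxsim.params import BiophaseMap, FENTANYL_MW
from naloxsim.synth import make_anchor_set


class TestDeriveRates:
    def test_degradation_rates_from_halflives(self, table):
        rates = derive_rates(table)
        assert rates.k_deg_free == pytest.approx(9.627e-4, rel=1e-3)
        assert rates.k_deg_bound == pytest.approx(1.650e-3, rel=1e-3)

    def test_internalization_rates_from_30min_fractions(self, table):
        rates = derive_rates(table)
        assert rates.k_int_f == pytest.approx(0.05365, abs=1e-5)
        assert rates.k_int_n == pytest.approx(5.417e-3, abs=1e-6)

    def test_synthesis_balances_baseline(self, table):
        rates = derive_rates(table)
        assert rates.k_syn == pytest.approx(rates.k_deg_free * 1.0)

    def test_missing_row_names_the_row(self, table):
        broken = copy.deepcopy(table)
        del broken["receptor"]["unbound_halflife_h"]
        with pytest.raises(KeyError, match="unbound_halflife_h"):
            derive_rates(broken)


def _power_truth(table, a, b):
    ke0 = table["biophase"]["ke0_per_min"]
    return BiophaseMap(form="power", a=a, b=b, ke0=ke0, mw=FENTANYL_MW)


class TestParameterRecovery:
    @pytest.mark.parametrize("b_true", [1.0, 1.5, 2.0])
    def test_noise_free_power_map_recovery(self, table, uncalibrated_model, b_true):
        """Anchors generated from a known power map are fitted back to
        within 1% of the true (a, b)."""
        a_true = 0.048 / 14.86 ** (b_true - 1.0)  # keeps occupancies mid-range
        truth = _power_truth(table, a_true, b_true)
        rates = derive_rates(table)
        template = uncalibrated_model.model_copy(update={"biophase_f": truth})
        anchors = make_anchor_set(
            truth, rates, [5.0, 15.0, 40.0],
            kinds=["equilibrium_point", "equilibrium_point", "plateau"],
            model_template=template,
        )
        fitted = fit_biophase(anchors, table=table, map_form="power")
        assert not isinstance(fitted, CalibrationFailure), fitted
        assert fitted.biophase_f.a == pytest.approx(a_true, rel=0.01)
        assert fitted.biophase_f.b == pytest.approx(b_true, rel=0.01)

    def test_noisy_recovery_within_ten_percent(self, table, uncalibrated_model):
        """With 1 occupancy point of noise on the anchors, the recovered
        map parameters stay within 10% of truth (median of 20 replicates)."""
        b_true, a_true = 1.5, 0.048 / 14.86 ** 0.5
        truth = _power_truth(table, a_true, b_true)
        rates = derive_rates(table)
        template = uncalibrated_model.model_copy(update={"biophase_f": truth})
        base = make_anchor_set(
            truth, rates, [5.0, 15.0, 40.0],
            kinds=["equilibrium_point", "equilibrium_point", "plateau"],
            model_template=template,
        )
        rng = np.random.default_rng(2026)
        rec_a, rec_b = [], []
        for _ in range(20):
            noisy = [a.model_copy(update={
                "observed": float(np.clip(a.observed + rng.normal(0, 0.01),
                                          1e-3, 1 - 1e-3))})
                for a in base]
            fitted = fit_biophase(noisy, table=table, map_form="power",
                                  residual_tol_points=5.0)
            if isinstance(fitted, CalibrationFailure):
                continue
            rec_a.append(fitted.biophase_f.a)
            rec_b.append(fitted.biophase_f.b)
        assert len(rec_a) >= 15
        assert np.median(rec_a) == pytest.approx(a_true, rel=0.10)
        assert np.median(rec_b) == pytest.approx(b_true, rel=0.10)

    def test_fit_requires_both_anchor_kinds(self, table, uncalibrated_model):
        truth = _power_truth(table, 0.048, 1.0)
        anchors = make_anchor_set(truth, derive_rates(table), [5.0, 15.0])
        with pytest.raises(ValueError):
            fit_biophase(anchors, table=table)


class TestHeadlineCalibration:
    def test_anchor_residuals_within_tolerance(self, calibrated_model):
        """Every printed occupancy anchor is met within 2 points."""
        assert calibrated_model.residuals, "no residuals recorded"
        for name, res in calibrated_model.residuals.items():
            assert abs(res) <= 2.0, (name, res)

    def test_fit_is_deterministic(self, table, uncalibrated_model):
        truth = _power_truth(table, 0.048, 1.3)
        rates = derive_rates(table)
        template = uncalibrated_model.model_copy(update={"biophase_f": truth})
        anchors = make_anchor_set(
            truth, rates, [5.0, 40.0],
            kinds=["equilibrium_point", "plateau"], model_template=template)
        f1 = fit_biophase(anchors, table=table, map_form="power")
        f2 = fit_biophase(anchors, table=table, map_form="power")
        assert f1.biophase_f.a == f2.biophase_f.a
        assert f1.biophase_f.b == f2.biophase_f.b
        assert f1.rates.k_rec == f2.rates.k_rec

    def test_fitted_map_monotone_and_krec_finite(self, calibrated_model):
        c = np.linspace(0, 100, 400)
        target = calibrated_model.biophase_f.target(c)
        assert np.all(np.diff(target) >= 0)
        assert 0 < calibrated_model.rates.k_rec < math.inf

    def test_provenance_recorded(self, calibrated_model):
        kinds = {a.get("kind") for a in calibrated_model.anchors_used}
        assert "equilibrium_point" in kinds and "plateau" in kinds


class TestNaloxoneOccupancyCheck:
    def test_zero_dose_zero_occupancy(self, calibrated_model):
        tab = check_naloxone_occupancy(calibrated_model, [0.0, 1.0, 2.0])
        assert tab.iloc[0]["peak_occ_n"] == 0.0

    def test_strictly_increasing_in_dose(self, calibrated_model):
        tab = check_naloxone_occupancy(calibrated_model, [0.0, 0.5, 1, 2, 4, 8])
        occ = tab["peak_occ_n"].to_numpy()
        assert np.all(np.diff(occ) > 0)

    def test_concave_near_saturation(self, calibrated_model):
        """Doubling the dose less than doubles occupancy once well bound."""
        tab = check_naloxone_occupancy(calibrated_model, [4.0, 8.0])
        assert tab.iloc[1]["peak_occ_n"] < 2 * tab.iloc[0]["peak_occ_n"]
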