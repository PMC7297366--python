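import pytest

from naloxsim.calibrate import (
    build_calibrated_model,
    ligand_specs,
    load_naloxone_pk,
    load_table_params,
)
from naloxsim.grid import run_grid
from naloxsim.model import CalibratedModel
from naloxsim.params import BiophaseMap, FENTANYL_MW, NALOXONE_MW


@pytest.fixture(scope="session")
def table():
    return load_table_params()


@pytest.fixture(scope="session")
def ligands(table):
    return ligand_specs(table)


@pytest.fixture(scope="session")
def naloxone_pk():
    return load_naloxone_pk()


@pytest.fixture(scope="session")
def calibrated_model(table) -> CalibratedModel:
    """The headline calibrated model; computed once per session."""
    model = build_calibrated_model(table=table)
    assert isinstance(model, CalibratedModel), getattr(model, "message", model)
    return model


@pytest.fixture(scope="session")
def grid_table(calibrated_model):
    return run_grid(calibrated_model)


@pytest.fixture(scope="session")
def uncalibrated_model(table, ligands, naloxone_pk) -> CalibratedModel:
    """A hand-assembled model with plain linear biophase maps, for tests
    that do not depend on the calibration outcome."""
    from naloxsim.calibrate import derive_rates

    lig_f, lig_n = ligands
    ke0 = table["biophase"]["ke0_per_min"]
    return CalibratedModel(
        rates=derive_rates(table),
        fentanyl=lig_f,
        naloxone=lig_n,
        biophase_f=BiophaseMap(form="linear", a=0.016, ke0=ke0, mw=FENTANYL_MW),
        biophase_n=BiophaseMap(form="linear", a=1.0, ke0=ke0, mw=NALOXONE_MW),
        naloxone_pk=naloxone_pk,
    )
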