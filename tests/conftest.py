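import numpy as np
import pytest

from otomech import (
    CalibrationTable,
    GeometrySpec,
    MaterialTable,
    build_middle_ear_mesh,
)


@pytest.fixture(scope="session")
def geometry_spec():
    return GeometrySpec.default()


@pytest.fixture(scope="session")
def mesh(geometry_spec):
    return build_middle_ear_mesh(geometry_spec)


@pytest.fixture(scope="session")
def materials():
    return MaterialTable.default()


@pytest.fixture(scope="session")
def cal_table():
    return CalibrationTable.default()


@pytest.fixture(scope="session")
def calibrated(mesh, materials):
    """Calibrated materials + report, shared across the whole run."""
    from otomech.pipeline import calibrate_normal_model

    cal_mats, report = calibrate_normal_model(mesh, materials)
    return cal_mats, report


@pytest.fixture(scope="session")
def abg_of(mesh, calibrated, cal_table):
    """Simulated-ABG runner on the calibrated model (cached normals)."""
    from otomech.pathology import PathologySpec, simulate_abg

    cal_mats, _ = calibrated

    def run(*lesions, frequencies=None):
        from otomech.audiogram import FEM_FREQUENCIES_HZ

        spec = PathologySpec.of(*lesions)
        return simulate_abg(
            mesh, cal_mats, spec, cal_table, frequencies or FEM_FREQUENCIES_HZ
        )

    return run
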