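import numpy as np
import pytest

from brachykerma import (DwellPlan, Scheme, build_material_table,
                         build_phantom, load_calibration_curve,
                         load_ir192_spectrum, load_materials, run_simulation)


@pytest.fixture(scope="session")
def materials():
    return load_materials()


@pytest.fixture(scope="session")
def curve():
    return load_calibration_curve()


@pytest.fixture(scope="session")
def spectrum():
    return load_ir192_spectrum()


@pytest.fixture(scope="session")
def water_table(materials):
    return build_material_table(materials["water"])


@pytest.fixture(scope="session")
def air_table(materials):
    return build_material_table(materials["air"])


@pytest.fixture(scope="session")
def water_phantom():
    """Unbound water phantom, 111^3 voxels of 1 mm, centred on the origin."""
    hu = np.zeros((111, 111, 111))
    return build_phantom(hu, (1.0, 1.0, 1.0), (-55.0, -55.0, -55.0),
                         scheme=Scheme.WATER_UNBOUND)


@pytest.fixture(scope="session")
def single_dwell_plan():
    return DwellPlan(positions=[[0.0, 0.0, 0.0]], times=[10.0])


@pytest.fixture(scope="session")
def primary_water_dose(water_phantom, single_dwell_plan, spectrum):
    """Primary-only kerma per decay in unbound water, 1e6 histories."""
    return run_simulation(water_phantom, single_dwell_plan, spectrum,
                          1_000_000, n_batches=5, seed=17,
                          primary_only=True, per_decay=True)
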