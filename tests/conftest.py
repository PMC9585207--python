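import numpy as np
import pytest

from osmoforge import pk, sedem
from osmoforge.doe import build_design


@pytest.fixture(scope="session")
def design4():
    return build_design(4, seed=7)


@pytest.fixture(scope="session")
def disposition():
    """Literature two-compartment disposition set (70 kg)."""
    return pk.DispositionParams(Vc=1.4776, k12=0.4021, k21=0.0569, CL=0.00572,
                                body_weight=70.0)


@pytest.fixture(scope="session")
def drug_properties():
    return pk.DrugProperties()


@pytest.fixture
def simple_measurements():
    """10 g powder: bulk 20 ml, tapped 16 ml -> Da 0.5, Dc 0.625."""
    return sedem.PowderMeasurements(
        sample_mass_g=10.0, bulk_volume_ml=20.0, tapped_volume_ml=16.0,
        tablet_hardness_N=122.0, cone_height_cm=2.0, cone_diameter_cm=8.0,
        flow_time_s=7.0, loss_on_drying_pct=2.0, hygroscopicity_pct=2.0,
        fines_pct=10.0,
        sieve_fractions=((100.0, 60.0), (200.0, 40.0)),
    )


@pytest.fixture(scope="session")
def pk_sampling_times():
    """Dense design spanning absorption through the (very slow) terminal phase."""
    return np.concatenate([
        np.arange(0.1, 6.0, 0.1),
        np.arange(6.0, 48.0, 1.0),
        np.arange(48.0, 200.0, 8.0),
        np.geomspace(200.0, 8000.0, 40),
    ])
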