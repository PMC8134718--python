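import pytest

from oncodelay import Stratum, datasets, monthly_reduction


@pytest.fixture(scope="session")
def network_table():
    """Published network-level monthly totals of new patients."""
    return datasets.unicancer_network()


@pytest.fixture(scope="session")
def centers_table():
    """Per-center monthly new-patient counts with zone metadata."""
    return datasets.unicancer_centers()


@pytest.fixture(scope="session")
def network_series(network_table):
    """March-July reduction of the observation vs reference year."""
    return monthly_reduction(
        network_table, 2019, 2020, window=range(3, 8),
        stratum=Stratum(patient_status="new"),
    )
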