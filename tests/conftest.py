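import numpy as np
import pytest

import respdose as rd


@pytest.fixture(scope="session")
def worker():
    return rd.WorkerScenario.reference_worker()


@pytest.fixture(scope="session")
def aerosol_5um():
    return rd.AerosolSpec(amad=5.0)


@pytest.fixture(scope="session")
def s_pair():
    """Synthetic S-coefficient pair over the full source/target grid."""
    return rd.STablePair.from_synthetic(rd.generate_synthetic_s_table(seed=11))


@pytest.fixture(scope="session")
def reference_system(worker, aerosol_5um):
    """Full coupled I-131 system at reference parameters with its deposit vector."""
    regional = rd.polydisperse_deposition(aerosol_5um, worker)
    deposit = rd.apportion_deposit(regional)
    system, x0 = rd.build_full_system(deposit)
    return system, x0


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
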