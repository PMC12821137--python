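"""Shared fixtures: the synthetic molecule library and common parameter sets."""

import itertools

import numpy as np
import pytest

from cosmosac.core import ParameterSet
from cosmosac.fitting import IdacDataset, IdacRecord, predict_idac
from cosmosac.fixtures import fixture_library, library_specs
from cosmosac.sigma import build_profile

HB_CONSTANT_NAMES = (
    "C_HB", "C_HB2", "C_HB3", "C_HB4", "C_HB5", "C_HB6", "C_HB7", "C_HB8",
)


@pytest.fixture(scope="session")
def specs():
    return library_specs()


@pytest.fixture(scope="session")
def library():
    return fixture_library()


@pytest.fixture(scope="session")
def hb2_params():
    return ParameterSet.from_preset("HB2-FINE")


@pytest.fixture(scope="session")
def sac_params():
    return ParameterSet.from_preset("COSMO-SAC-FINE")


@pytest.fixture(scope="session")
def profiles_split(library, hb2_params):
    """HB-class-split sigma-profiles of the fixture library at the HB2-FINE r_avg."""
    return {
        name: build_profile(mol, hb2_params.r_avg, split_hb=True)
        for name, mol in library.items()
    }


@pytest.fixture(scope="session")
def generating_params():
    """Conditions used to synthesize IDAC data for recovery experiments:
    single-HB-constant model with an active hydrogen-bond channel on the
    fixture surfaces."""
    return ParameterSet(
        variant="cosmosac2002", f_pol=0.90, r_avg=1.2, r_eff=1.20,
        sigma_hb=0.0070, c_hb=4000.0,
    )


@pytest.fixture(scope="session")
def idac_dataset(library, generating_params):
    """Noiseless synthetic IDAC data: all ordered fixture pairs at three
    temperatures, labels generated by the model itself."""
    recs = [
        (a, b, T)
        for a, b in itertools.permutations(library, 2)
        for T in (298.15, 323.15, 348.15)
    ]
    blank = IdacDataset(
        [IdacRecord(a, b, T, 0.0) for a, b, T in recs], library, split_hb=False
    )
    truth = predict_idac(blank, generating_params)
    return IdacDataset(
        [IdacRecord(a, b, T, float(v)) for (a, b, T), v in zip(recs, truth)],
        library,
        split_hb=False,
    )
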