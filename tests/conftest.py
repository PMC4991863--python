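import pytest
from hypothesis import HealthCheck, settings

from isopka import (
    ConvergenceTier,
    EnergyRecord,
    FreeEnergyModel,
    Method,
    SolventModel,
    State,
    load_reference_library,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_record(
    molecule_id="mol",
    state=State.ACID,
    conformer_id="c01",
    method=Method.PM6,
    solvent_model=SolventModel.COSMO,
    delta_hf=0.0,
    dg_solv=0.0,
    g_rrho=None,
    n_imaginary=0,
    convergence_tier=ConvergenceTier.DEFAULT,
    excluded=False,
):
    return EnergyRecord(
        molecule_id=molecule_id,
        state=state,
        conformer_id=conformer_id,
        method=method,
        solvent_model=solvent_model,
        delta_hf=delta_hf,
        dg_solv=dg_solv,
        g_rrho=g_rrho,
        n_imaginary=n_imaginary,
        convergence_tier=convergence_tier,
        excluded=excluded,
    )


@pytest.fixture(scope="session")
def library():
    return load_reference_library()


@pytest.fixture
def model_no_rrho():
    return FreeEnergyModel.from_parts(Method.PM6, SolventModel.COSMO, include_rrho=False)


@pytest.fixture
def model_with_rrho():
    return FreeEnergyModel.from_parts(Method.PM6, SolventModel.COSMO, include_rrho=True)
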