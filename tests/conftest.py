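import numpy as np
import pytest

from refkin.synthetic_data import (
    InputFunction,
    RegionTruth,
    default_schedule_av45,
    default_schedule_av1451,
    generate_reference_tac,
    generate_target_tac,
)
from refkin.tac_io import RegionalTACSet


@pytest.fixture(scope="session")
def av45_schedule():
    return default_schedule_av45()


@pytest.fixture(scope="session")
def av1451_schedule():
    return default_schedule_av1451()


@pytest.fixture(scope="session")
def bolus_if():
    return InputFunction()


@pytest.fixture(scope="session")
def ref_tac_fast(bolus_if, av45_schedule):
    """Noiseless fast-tracer reference TAC (cerebellum-like kinetics)."""
    return generate_reference_tac(bolus_if, K1_ref=0.5, k2_ref=0.17,
                                  schedule=av45_schedule)


@pytest.fixture(scope="session")
def ref_tac_slow(av1451_schedule):
    return generate_reference_tac(
        InputFunction(tail_rates=(0.04, 0.005)), K1_ref=0.5, k2_ref=0.06,
        schedule=av1451_schedule,
    )


@pytest.fixture(scope="session")
def target_tac_fast(ref_tac_fast):
    """Noiseless fast-kinetics target TAC with known truth."""
    truth = RegionTruth("target", R1=1.2, k2=0.10, BP_ND=2.0)
    return generate_target_tac(ref_tac_fast, truth), truth


def make_tac_set(ref, targets, subject="sub-01", tracer="amyloid"):
    tacs = {"cerebellum-grey": ref, **targets}
    ref.region = "cerebellum-grey"
    return RegionalTACSet(subject, tracer, tacs, "cerebellum-grey")
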