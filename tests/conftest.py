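import pytest
from hypothesis import settings as hypothesis_settings

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")

from ringtrial.quantification import (
    Condition,
    Cycle,
    Medium,
    PlateObservation,
    Role,
    Strain,
)
from ringtrial.synthetic_data import main_wash_config


@pytest.fixture
def plate():
    """Factory for plate observations with sensible defaults."""

    def make(
        cfu,
        d=1.0,
        role=Role.NA,
        strain=Strain.PA,
        medium=Medium.TSA,
        volume=0.4,
        lab="L1",
        condition=Condition.A,
        run=1,
        carrier=1,
        cycle=Cycle.MAIN_WASH,
    ):
        return PlateObservation(
            lab_id=lab,
            cycle=cycle,
            condition=condition,
            run_index=run,
            role=role,
            medium=medium,
            strain=strain if role in (Role.N0, Role.NA) else None,
            carrier=carrier,
            cfu=cfu,
            dilution_factor=d,
            plated_volume_ml=volume,
        )

    return make


@pytest.fixture
def noiseless_window_config():
    """Noiseless design whose implied plate counts all sit comfortably in
    the countable window, so requantification error is pure count rounding."""
    means = {}
    for ep in ("LR-PA", "LR-EC", "LR-SA", "LR-EH", "LR-CA"):
        means[(Condition.A, ep)] = 4.0
    means[(Condition.A, "RI-TSA")] = 3.0
    means[(Condition.A, "RI-MEA")] = 3.0
    means[(Condition.A, "WW-TSA")] = 2.0
    means[(Condition.A, "WW-MEA")] = 2.0
    return main_wash_config(
        conditions=(Condition.A,),
        endpoint_means=means,
        sigma_B=0.0,
        sigma_r=0.0,
        poisson_layer=False,
        seed=0,
    )
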