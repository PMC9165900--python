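"""Plate-count quantification: countable window, dilution-weighted counts,
detection-limit censoring and log reductions."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from ringtrial.quantification import (
    Condition,
    DetectionLimits,
    Medium,
    OrganismClass,
    Role,
    Strain,
    UncountableHighError,
    InvalidPlateGroupError,
    QuantificationError,
    apply_detection_limit,
    carrier_count,
    log_reduction,
    plate_admissible,
    records_from_plates,
    validate_inoculum,
    wash_water_count,
)


@pytest.mark.parametrize(
    "cfu,expected",
    [(14, True), (330, True), (13, False), (331, False), (0, False), (100, True)],
)
def test_countable_window_is_inclusive(plate, cfu, expected):
    assert plate_admissible(plate(cfu)) is expected


class TestCarrierCount:
    def test_single_dilution_duplicates(self, plate):
        q = carrier_count([plate(120, d=1e-2), plate(80, d=1e-2)])
        assert q.count_per_carrier == pytest.approx(25_000)
        assert (q.n1, q.n2) == (2, 0)
        assert not q.censored

    def test_two_consecutive_dilutions_weighted(self, plate):
        q = carrier_count(
            [plate(300, d=0.1), plate(280, d=0.1), plate(30, d=0.01), plate(28, d=0.01)]
        )
        # c=638 over n1=2 plates at d=0.1 plus n2=2 at d=0.01
        assert q.count_per_carrier == pytest.approx(638 / (0.4 * 2.2 * 0.1))
        assert (q.n1, q.n2) == (2, 2)

    def test_only_higher_dilution_countable(self, plate):
        # overgrown at d=0.1, countable at d=0.01: the countable level is
        # treated as the sole dilution
        q = carrier_count([plate(400, d=0.1), plate(40, d=0.01)])
        assert q.count_per_carrier == pytest.approx(40 / (0.4 * 1 * 0.01))
        assert (q.n1, q.n2) == (1, 0)

    def test_duplicates_at_censoring_count(self, plate):
        q = carrier_count([plate(14, d=1.0), plate(14, d=1.0)])
        assert q.count_per_carrier == pytest.approx(35.0)
        assert round(q.log10_count, 2) == 1.54
        assert not q.censored  # 14 cfu is countable

    def test_below_floor_censors_at_constant(self, plate):
        q = carrier_count([plate(5, d=1.0), plate(3, d=1.0)])
        assert q.censored
        assert q.log10_count == 1.54  # bit-exact constant
        assert q.count_per_carrier == pytest.approx(35.0)  # 14 cfu/plate

    def test_all_zero_censors(self, plate):
        q = carrier_count([plate(0, d=1.0), plate(0, d=1.0)])
        assert q.censored and q.log10_count == 1.54

    def test_uncountable_high_is_error(self, plate):
        with pytest.raises(UncountableHighError):
            carrier_count([plate(500, d=1e-4), plate(480, d=1e-4)])

    def test_non_consecutive_countable_dilutions_rejected(self, plate):
        with pytest.raises(InvalidPlateGroupError):
            carrier_count([plate(300, d=1.0), plate(30, d=0.01)])

    def test_control_below_floor_is_error_not_censored(self, plate):
        with pytest.raises(QuantificationError):
            carrier_count([plate(3, d=1.0, role=Role.N0)])

    def test_empty_group_rejected(self):
        with pytest.raises(InvalidPlateGroupError):
            carrier_count([])

    def test_custom_detection_limit(self, plate):
        limits = DetectionLimits(carrier=2.0, wash_water=1.5)
        q = carrier_count([plate(5, d=1.0)], limits)
        assert q.log10_count == 2.0 and q.censored


class TestWashWater:
    def test_mean_over_five_plates(self, plate):
        q = wash_water_count(
            [plate(c, role=Role.WW, volume=2.0) for c in (20, 22, 18, 20, 20)]
        )
        assert q.count_per_plate == pytest.approx(20.0)
        assert q.log10_count == pytest.approx(math.log10(20), abs=1e-12)
        assert q.n_plates == 5

    def test_all_at_censoring_count(self, plate):
        q = wash_water_count([plate(14, role=Role.WW, volume=2.0)] * 5)
        assert q.count_per_plate == pytest.approx(14.0)
        assert round(q.log10_count, 2) == 1.15

    def test_all_zero_censors_at_constant(self, plate):
        q = wash_water_count([plate(0, role=Role.WW, volume=2.0)] * 5)
        assert q.censored and q.log10_count == 1.15

    def test_empty_rejected(self):
        with pytest.raises(InvalidPlateGroupError):
            wash_water_count([])

    def test_diluted_plates_rejected(self, plate):
        with pytest.raises(InvalidPlateGroupError):
            wash_water_count([plate(20, d=0.1, role=Role.WW, volume=2.0)])


@pytest.mark.parametrize(
    "raw,role,expected",
    [
        (None, Role.NA, (1.54, True)),
        (None, Role.RI, (1.54, True)),
        (None, Role.WW, (1.15, True)),
        (1.00, Role.WW, (1.15, True)),
        (3.20, Role.RI, (3.20, False)),
        (1.54, Role.NA, (1.54, False)),  # at-limit passes through uncensored
    ],
)
def test_apply_detection_limit(raw, role, expected):
    assert apply_detection_limit(raw, role) == expected


def test_apply_detection_limit_rejects_control_role():
    with pytest.raises(ValueError):
        apply_detection_limit(3.0, Role.N0)


@pytest.mark.parametrize(
    "n0,na,expected",
    [(6.50, 1.54, 4.96), (4.0, 4.0, 0.0), (7.00, 2.00, 5.00)],
)
def test_log_reduction(n0, na, expected):
    assert log_reduction(n0, na) == pytest.approx(expected)


@pytest.mark.parametrize(
    "n0,cls,expected",
    [
        (6.15, OrganismClass.BACTERIA, True),
        (8.15, OrganismClass.BACTERIA, True),
        (6.14, OrganismClass.BACTERIA, False),
        (9.0, OrganismClass.BACTERIA, False),
        (5.15, OrganismClass.YEAST, True),
        (7.15, OrganismClass.YEAST, True),
        (5.00, OrganismClass.YEAST, False),
    ],
)
def test_inoculum_validity_window(n0, cls, expected):
    assert validate_inoculum(n0, cls) is expected


# --- properties ------------------------------------------------------------

@given(
    counts=st.lists(st.integers(14, 110), min_size=1, max_size=4),
    k=st.integers(1, 3),
    dexp=st.integers(0, 4),
)
@settings(max_examples=100, deadline=None)
def test_carrier_count_homogeneous_in_counts(counts, k, dexp):
    """Scaling every countable plate count by k scales N by k."""
    d = 10.0 ** (-dexp)
    base = _plates(counts, d)
    scaled = _plates([c * k for c in counts], d)
    assert carrier_count(scaled).count_per_carrier == pytest.approx(
        k * carrier_count(base).count_per_carrier
    )


@given(
    counts=st.lists(st.integers(14, 330), min_size=1, max_size=4),
    dexp=st.integers(0, 3),
)
@settings(max_examples=100, deadline=None)
def test_carrier_count_inverse_in_dilution(counts, dexp):
    """Identical counts at a 10x higher dilution give a 10x larger N."""
    d = 10.0 ** (-dexp)
    n_lo = carrier_count(_plates(counts, d)).count_per_carrier
    n_hi = carrier_count(_plates(counts, d / 10.0)).count_per_carrier
    assert n_hi == pytest.approx(10.0 * n_lo)


@given(count=st.integers(14, 330), dexp=st.integers(0, 5))
@settings(max_examples=100, deadline=None)
def test_noiseless_roundtrip_exact(count, dexp):
    """Counts laid down from a true concentration recover it exactly."""
    d = 10.0 ** (-dexp)
    conc = count / (0.4 * d)
    q = carrier_count(_plates([count, count], d))
    assert q.count_per_carrier == pytest.approx(conc, rel=1e-12)


def _plates(counts, d):
    from ringtrial.quantification import Cycle, PlateObservation

    return [
        PlateObservation(
            lab_id="L1", cycle=Cycle.MAIN_WASH, condition=Condition.A,
            run_index=1, role=Role.NA, medium=Medium.TSA, strain=Strain.PA,
            cfu=c, dilution_factor=d,
        )
        for c in counts
    ]


def test_records_from_plates_assembles_endpoints(plate):
    plates = [
        # N0 for PA: duplicates of 100 at 1e-5 -> 2.5e7 cfu -> 7.39794
        plate(100, d=1e-5, role=Role.N0, strain=Strain.PA),
        plate(100, d=1e-5, role=Role.N0, strain=Strain.PA),
        # Na for PA: duplicates of 20 direct -> 50 cfu -> 1.69897
        plate(20, d=1.0, role=Role.NA, strain=Strain.PA),
        plate(20, d=1.0, role=Role.NA, strain=Strain.PA),
        # RI on TSA: two carriers, duplicates of 40 at 0.1 -> 1000 cfu -> 3.0
        plate(40, d=0.1, role=Role.RI, carrier=1),
        plate(40, d=0.1, role=Role.RI, carrier=1),
        plate(40, d=0.1, role=Role.RI, carrier=2),
        plate(40, d=0.1, role=Role.RI, carrier=2),
    ] + [plate(20, role=Role.WW, volume=2.0) for _ in range(5)]

    (rec,) = records_from_plates(plates)
    assert rec.endpoints["LR-PA"] == pytest.approx(
        math.log10(2.5e7) - math.log10(50)
    )
    assert rec.endpoints["RI-TSA"] == pytest.approx(3.0)
    assert rec.endpoints["WW-TSA"] == pytest.approx(math.log10(20))
    assert rec.endpoints["LR-EC"] is None  # no plates for that strain
    assert rec.endpoints["RI-MEA"] is None
    assert not rec.censor_flags["LR-PA"]


def test_records_from_plates_censored_na_flags_lr(plate):
    plates = [
        plate(100, d=1e-5, role=Role.N0, strain=Strain.PA),
        plate(100, d=1e-5, role=Role.N0, strain=Strain.PA),
        plate(2, d=1.0, role=Role.NA, strain=Strain.PA),
        plate(2, d=1.0, role=Role.NA, strain=Strain.PA),
    ]
    (rec,) = records_from_plates(plates)
    # LR computed against the detection-limit constant
    assert rec.endpoints["LR-PA"] == pytest.approx(math.log10(2.5e7) - 1.54)
    assert rec.censor_flags["LR-PA"]
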