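"""Plate-count quantification for carrier-based laundry disinfection tests.

Raw agar-plate counts from a ring-trial run are converted into per-carrier
microbial loads (weighted over up to two consecutive ten-fold dilutions),
wash-water counts (mean over five direct-plated aliquots), and log-reduction
values, applying the method's countable-range rule (14-330 cfu per plate)
and detection-limit censoring (1.54 log10 for carrier eluates, 1.15 log10
for wash water).
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Cycle",
    "Condition",
    "Strain",
    "Medium",
    "Role",
    "OrganismClass",
    "DetectionLimits",
    "PlateObservation",
    "CarrierQuantification",
    "WashWaterQuantification",
    "RunRecord",
    "QuantificationError",
    "UncountableHighError",
    "InvalidPlateGroupError",
    "ENDPOINTS",
    "LR_ENDPOINTS",
    "MIN_COUNTABLE",
    "MAX_COUNTABLE",
    "CARRIER_PLATE_VOLUME_ML",
    "plate_admissible",
    "count_admissible",
    "carrier_count",
    "wash_water_count",
    "apply_detection_limit",
    "log_reduction",
    "validate_inoculum",
    "records_from_plates",
]

# Countable window for a single agar plate; counts outside it are discarded.
MIN_COUNTABLE = 14
MAX_COUNTABLE = 330

# Volume plated per dilution-series plate for carrier eluates (ml).
CARRIER_PLATE_VOLUME_ML = 0.4


class Cycle(str, Enum):
    MAIN_WASH = "main_wash"
    RINSE = "rinse"


class Condition(str, Enum):
    """Test condition: A-C main wash, D-F rinse cycle."""

    A = "A"
    B = "B"
    C = "C"
    D = "D"
    E = "E"
    F = "F"


class Strain(str, Enum):
    PA = "PA"  # Pseudomonas aeruginosa
    EC = "EC"  # Escherichia coli
    SA = "SA"  # Staphylococcus aureus
    EH = "EH"  # Enterococcus hirae
    CA = "CA"  # Candida albicans


class Medium(str, Enum):
    TSA = "TSA"
    MEA = "MEA"


class Role(str, Enum):
    N0 = "N0"  # untreated control carrier
    NA = "Na"  # contaminated carrier after laundering
    RI = "RI"  # initially sterile carrier (cross-contamination)
    WW = "WW"  # wash water


class OrganismClass(str, Enum):
    BACTERIA = "bacteria"
    YEAST = "yeast"


#: Inoculum validity window (log10 cfu/carrier) per organism class.
INOCULUM_RANGES: Mapping[OrganismClass, tuple[float, float]] = {
    OrganismClass.BACTERIA: (6.15, 8.15),
    OrganismClass.YEAST: (5.15, 7.15),
}

#: Which organism class each strain belongs to (C. albicans is the yeast).
STRAIN_CLASS: Mapping[Strain, OrganismClass] = {
    Strain.PA: OrganismClass.BACTERIA,
    Strain.EC: OrganismClass.BACTERIA,
    Strain.SA: OrganismClass.BACTERIA,
    Strain.EH: OrganismClass.BACTERIA,
    Strain.CA: OrganismClass.YEAST,
}

#: Growth medium used for each strain's dilution series.
STRAIN_MEDIUM: Mapping[Strain, Medium] = {
    Strain.PA: Medium.TSA,
    Strain.EC: Medium.TSA,
    Strain.SA: Medium.TSA,
    Strain.EH: Medium.TSA,
    Strain.CA: Medium.MEA,
}

LR_ENDPOINTS = ("LR-PA", "LR-EC", "LR-SA", "LR-EH", "LR-CA")

#: The nine log-scale endpoints of one run, in report order.
ENDPOINTS = LR_ENDPOINTS + ("RI-TSA", "RI-MEA", "WW-TSA", "WW-MEA")

ENDPOINT_FOR_STRAIN: Mapping[Strain, str] = {s: f"LR-{s.value}" for s in Strain}


class QuantificationError(ValueError):
    """Raw plate data cannot be quantified."""


class UncountableHighError(QuantificationError):
    """Every supplied plate exceeds the countable maximum; no substitute
    value exists for overgrown plates, so this is an error, not censoring."""


class InvalidPlateGroupError(QuantificationError):
    """Plates supplied to a single quantification are inconsistent
    (mixed roles, non-consecutive dilutions, empty group, ...)."""


@dataclass(frozen=True)
class DetectionLimits:
    """Censoring constants on the log10 scale.

    ``carrier`` applies to Na and RI (1.54 = log10 of 14 cfu in duplicate
    0.4-ml direct plating), ``wash_water`` to WW (1.15 = log10 of 14
    cfu/plate).  Configurable so other plated volumes remain usable; the
    defaults reproduce the standard method.
    """

    carrier: float = 1.54
    wash_water: float = 1.15

    def limit_for(self, role: Role) -> float:
        if role in (Role.NA, Role.RI):
            return self.carrier
        if role is Role.WW:
            return self.wash_water
        raise ValueError(f"no detection limit defined for role {role!r}")


DEFAULT_LIMITS = DetectionLimits()


@dataclass(frozen=True)
class PlateObservation:
    """One agar-plate count with its dilution and context keys.

    ``carrier`` distinguishes replicate carriers of the same strain and role
    within a run (eluates are quantified separately before pooling).
    """

    lab_id: str
    cycle: Cycle
    condition: Condition
    run_index: int
    role: Role
    medium: Medium
    cfu: int
    dilution_factor: float = 1.0
    plated_volume_ml: float = CARRIER_PLATE_VOLUME_ML
    strain: Strain | None = None
    carrier: int = 1

    def __post_init__(self) -> None:
        if self.cfu < 0:
            raise ValueError(f"cfu must be >= 0, got {self.cfu}")
        if not 0 < self.dilution_factor <= 1:
            raise ValueError(
                f"dilution_factor must lie in (0, 1], got {self.dilution_factor}"
            )
        if self.plated_volume_ml <= 0:
            raise ValueError("plated_volume_ml must be positive")
        if self.run_index < 1:
            raise ValueError("run_index must be >= 1")


@dataclass(frozen=True)
class CarrierQuantification:
    """Per-carrier count (N0, Na or RI) with censoring state.

    ``n1``/``n2`` are the numbers of countable plates retained at the lower
    (less dilute) and higher dilution respectively.
    """

    role: Role
    count_per_carrier: float
    log10_count: float
    censored: bool
    n1: int
    n2: int = 0


@dataclass(frozen=True)
class WashWaterQuantification:
    """Wash-water count, cfu per directly plated 2-ml aliquot."""

    count_per_plate: float
    log10_count: float
    censored: bool
    n_plates: int


@dataclass
class RunRecord:
    """One lab x condition x run row with its nine log-scale endpoints.

    ``endpoints`` maps endpoint name to a log10 value, or ``None`` when the
    endpoint could not be determined; ``censor_flags`` marks endpoints whose
    value sits at a detection limit.
    """

    lab_id: str
    cycle: Cycle
    condition: Condition
    run_index: int
    endpoints: dict[str, float | None] = field(default_factory=dict)
    censor_flags: dict[str, bool] = field(default_factory=dict)

    def value(self, endpoint: str) -> float | None:
        return self.endpoints.get(endpoint)


def count_admissible(cfu: int) -> bool:
    """Countable-range rule for a single plate: 14 <= cfu <= 330."""
    return MIN_COUNTABLE <= cfu <= MAX_COUNTABLE


def plate_admissible(obs: PlateObservation) -> bool:
    """Whether a plate's count falls in the countable window (inclusive)."""
    return count_admissible(obs.cfu)


def apply_detection_limit(
    raw_log10: float | None,
    role: Role,
    limits: DetectionLimits = DEFAULT_LIMITS,
) -> tuple[float, bool]:
    """Censor a log10 value at the role's detection limit.

    Undefined or below-limit values are replaced by the limit constant and
    flagged as censored; values at or above the limit pass through.
    """
    if isinstance(role, str):
        role = Role(role)
    limit = limits.limit_for(role)
    if raw_log10 is None or raw_log10 < limit:
        return limit, True
    return raw_log10, False


def _check_group(plates: Sequence[PlateObservation], expected_role: set[Role]) -> None:
    if not plates:
        raise InvalidPlateGroupError("no plates supplied")
    roles = {p.role for p in plates}
    if not roles <= expected_role:
        raise InvalidPlateGroupError(f"unexpected roles {roles} in plate group")
    strains = {p.strain for p in plates}
    if len(strains) > 1:
        raise InvalidPlateGroupError(f"mixed strains {strains} in plate group")


def carrier_count(
    plates: Sequence[PlateObservation],
    limits: DetectionLimits = DEFAULT_LIMITS,
) -> CarrierQuantification:
    """Quantify one carrier eluate from its dilution-series plates.

    The count per carrier is ``N = c / (V * (n1 + 0.1*n2) * d)`` where ``c``
    sums the countable plates over at most two consecutive ten-fold
    dilutions, ``n1``/``n2`` count the plates retained at the lower/higher
    dilution, ``d`` is the lower (less dilute) dilution factor and ``V`` the
    plated volume (0.4 ml).  A full dilution ladder may be supplied; the
    least dilute level holding any countable plate is chosen, together with
    its ten-fold neighbour when that is countable too.

    With no countable plate anywhere: if the direct-dilution counts are all
    below 14 the carrier is censored at the role's detection limit (Na/RI
    set to 14 cfu/plate); if every plate is overgrown (> 330) the eluate is
    uncountable-high, which is an error.
    """
    _check_group(plates, {Role.N0, Role.NA, Role.RI})
    role = plates[0].role
    volumes = {p.plated_volume_ml for p in plates}
    if len(volumes) > 1:
        raise InvalidPlateGroupError(f"non-uniform plated volumes {volumes}")
    volume = volumes.pop()

    admissible = [p for p in plates if plate_admissible(p)]
    if not admissible:
        direct = [p for p in plates if p.dilution_factor == 1.0]
        if direct and all(p.cfu < MIN_COUNTABLE for p in direct):
            if role is Role.N0:
                raise QuantificationError(
                    "control carrier below countable range; no detection limit "
                    "is defined for N0"
                )
            # Na/RI set to 14 cfu/plate in the direct dilution.
            n1 = len(direct)
            count = MIN_COUNTABLE * n1 / (volume * n1 * 1.0)
            return CarrierQuantification(
                role=role,
                count_per_carrier=count,
                log10_count=limits.limit_for(role),
                censored=True,
                n1=n1,
                n2=0,
            )
        if all(p.cfu > MAX_COUNTABLE for p in plates):
            raise UncountableHighError(
                "all plates exceed the countable maximum of "
                f"{MAX_COUNTABLE} cfu"
            )
        raise QuantificationError(
            "no countable plate and no direct-dilution plates below the "
            "countable minimum; eluate cannot be quantified"
        )

    # d = least dilute (largest) factor with a countable plate.
    d1 = max(p.dilution_factor for p in admissible)
    d2 = d1 / 10.0
    at_d1 = [p for p in admissible if math.isclose(p.dilution_factor, d1, rel_tol=1e-9)]
    at_d2 = [p for p in admissible if math.isclose(p.dilution_factor, d2, rel_tol=1e-9)]
    stray = [p for p in admissible if p not in at_d1 and p not in at_d2]
    if stray:
        raise InvalidPlateGroupError(
            "countable plates span non-consecutive dilutions: "
            f"{sorted({p.dilution_factor for p in admissible}, reverse=True)}"
        )

    n1, n2 = len(at_d1), len(at_d2)
    c = sum(p.cfu for p in at_d1) + sum(p.cfu for p in at_d2)
    count = c / (volume * (n1 + 0.1 * n2) * d1)
    log10_count = math.log10(count)
    censored = False
    if role is not Role.N0:
        log10_count, censored = apply_detection_limit(log10_count, role, limits)
    return CarrierQuantification(
        role=role,
        count_per_carrier=count,
        log10_count=log10_count,
        censored=censored,
        n1=n1,
        n2=n2,
    )


def wash_water_count(
    plates: Sequence[PlateObservation],
    limits: DetectionLimits = DEFAULT_LIMITS,
) -> WashWaterQuantification:
    """Quantify a wash-water sample from its five direct-plated aliquots.

    ``WW = c / n`` over the countable plates (cfu per plate).  If every
    plate is below the countable floor the sample is censored at the
    wash-water detection limit (14 cfu/plate, 1.15 log10); fully overgrown
    samples are uncountable-high.
    """
    if not plates:
        raise InvalidPlateGroupError("no wash-water plates supplied")
    if any(p.role is not Role.WW for p in plates):
        raise InvalidPlateGroupError("wash_water_count accepts only WW plates")
    if any(p.dilution_factor != 1.0 for p in plates):
        raise InvalidPlateGroupError("wash-water plates must be direct dilution")

    admissible = [p for p in plates if plate_admissible(p)]
    if not admissible:
        if all(p.cfu < MIN_COUNTABLE for p in plates):
            return WashWaterQuantification(
                count_per_plate=float(MIN_COUNTABLE),
                log10_count=limits.wash_water,
                censored=True,
                n_plates=len(plates),
            )
        raise UncountableHighError(
            "all countable-range checks failed with at least one overgrown "
            "wash-water plate"
        )
    ww = sum(p.cfu for p in admissible) / len(admissible)
    log10_count, censored = apply_detection_limit(math.log10(ww), Role.WW, limits)
    return WashWaterQuantification(
        count_per_plate=ww,
        log10_count=log10_count,
        censored=censored,
        n_plates=len(admissible),
    )


def log_reduction(n0_log10: float, na_log10: float) -> float:
    """Log reduction LR = N0 - Na, both on the log10 scale.

    ``na_log10`` must already be censoring-resolved: for below-limit Na the
    detection limit constant is subtracted from N0.
    """
    return n0_log10 - na_log10


def validate_inoculum(n0_log10: float, organism_class: OrganismClass | str) -> bool:
    """Whether a control-carrier load lies in the method's validity window.

    Bacteria must recover between 6.15 and 8.15 log10 per carrier, yeast
    between 5.15 and 7.15 (inclusive bounds).
    """
    organism_class = OrganismClass(organism_class)
    low, high = INOCULUM_RANGES[organism_class]
    return low <= n0_log10 <= high


def _mean(values: Sequence[float]) -> float:
    return sum(values) / len(values)


def records_from_plates(
    plates: Iterable[PlateObservation],
    limits: DetectionLimits = DEFAULT_LIMITS,
) -> list[RunRecord]:
    """Assemble RunRecords (nine endpoints each) from raw plate observations.

    Plates are grouped per lab/cycle/condition/run.  Carrier eluates are
    quantified individually; replicate carriers of the same strain and role
    are pooled by averaging their log10 counts before the log reduction is
    taken.  Endpoints whose plates are missing or unquantifiable are left
    as ``None``.
    """
    runs: dict[tuple, list[PlateObservation]] = defaultdict(list)
    for p in plates:
        runs[(p.lab_id, p.cycle, p.condition, p.run_index)].append(p)

    records = []
    for (lab_id, cycle, condition, run_index), group in sorted(
        runs.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2], kv[0][3])
    ):
        record = RunRecord(lab_id=lab_id, cycle=cycle, condition=condition,
                           run_index=run_index)
        for name in ENDPOINTS:
            record.endpoints[name] = None
            record.censor_flags[name] = False

        # carrier roles: quantify each (role, strain/medium, carrier) eluate
        carrier_logs: dict[tuple, list[CarrierQuantification]] = defaultdict(list)
        for key, sub in _group_carriers(group).items():
            try:
                carrier_logs[key[:2]].append(carrier_count(sub, limits))
            except QuantificationError:
                continue

        for strain in Strain:
            n0s = carrier_logs.get((Role.N0, strain), [])
            nas = carrier_logs.get((Role.NA, strain), [])
            if not n0s or not nas:
                continue
            n0_log = _mean([q.log10_count for q in n0s])
            na_log = _mean([q.log10_count for q in nas])
            name = ENDPOINT_FOR_STRAIN[strain]
            record.endpoints[name] = log_reduction(n0_log, na_log)
            record.censor_flags[name] = any(q.censored for q in nas)

        for medium in Medium:
            ris = carrier_logs.get((Role.RI, medium), [])
            if ris:
                name = f"RI-{medium.value}"
                record.endpoints[name] = _mean([q.log10_count for q in ris])
                record.censor_flags[name] = any(q.censored for q in ris)

        ww_plates: dict[Medium, list[PlateObservation]] = defaultdict(list)
        for p in group:
            if p.role is Role.WW:
                ww_plates[p.medium].append(p)
        for medium, sub in ww_plates.items():
            try:
                q = wash_water_count(sub, limits)
            except QuantificationError:
                continue
            name = f"WW-{medium.value}"
            record.endpoints[name] = q.log10_count
            record.censor_flags[name] = q.censored

        records.append(record)
    return records


def _group_carriers(
    group: Sequence[PlateObservation],
) -> dict[tuple, list[PlateObservation]]:
    """Split a run's carrier-role plates into individual eluates.

    N0/Na eluates key on (role, strain, carrier); RI eluates, which carry no
    strain, key on (role, medium, carrier).
    """
    out: dict[tuple, list[PlateObservation]] = defaultdict(list)
    for p in group:
        if p.role in (Role.N0, Role.NA):
            out[(p.role, p.strain, p.carrier)].append(p)
        elif p.role is Role.RI:
            out[(p.role, p.medium, p.carrier)].append(p)
    return out
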