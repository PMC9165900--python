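"""Synthetic ring-trial data with the structure the analysis assumes.

Endpoint values follow the one-way random-effects model: each laboratory
draws a systematic effect B_i ~ N(0, sigma_B) per endpoint (optionally
shared across endpoints) and each run adds residual noise
e_ij ~ N(0, sigma_r).  Censoring is applied on the Na/RI/WW level — a
simulated survivor load that falls below its detection limit is recorded at
the limit, so low-mean conditions reproduce the pile-up of identical
censored values (zero spread) seen in effective-disinfectant tests.

An optional plate-count layer turns true log10 loads into Poisson-noised
(or deterministically rounded) colony counts across a ten-fold dilution
ladder, so the whole quantification pipeline can be exercised end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .quantification import (
    CARRIER_PLATE_VOLUME_ML,
    Condition,
    Cycle,
    DetectionLimits,
    ENDPOINTS,
    ENDPOINT_FOR_STRAIN,
    LR_ENDPOINTS,
    Medium,
    PlateObservation,
    Role,
    RunRecord,
    Strain,
    STRAIN_MEDIUM,
)

__all__ = [
    "SimulationConfig",
    "default_endpoint_means",
    "main_wash_config",
    "rinse_config",
    "simulate_endpoints",
    "simulate_plate_counts",
    "make_fixture_spreadsheet",
]

#: Default control-carrier loads (log10 cfu/carrier): midpoints of the
#: method's inoculum validity windows.
DEFAULT_N0_MEANS: Mapping[Strain, float] = {
    Strain.PA: 7.15,
    Strain.EC: 7.15,
    Strain.SA: 7.15,
    Strain.EH: 7.15,
    Strain.CA: 6.15,
}


def default_endpoint_means(cycle: Cycle) -> dict[tuple[Condition, str], float]:
    """Per-endpoint mean presets taken from the published ring-trial report.

    These make synthetic tables visually comparable with the published
    ones; they are presets, not ground truth.
    """
    from .io import load_reference_table

    table = load_reference_table()
    sub = table[table["cycle"] == Cycle(cycle).value]
    return {
        (Condition(row.condition), row.endpoint): float(row.mean)
        for row in sub.itertuples()
    }


@dataclass
class SimulationConfig:
    """Full parameterization of a synthetic ring trial.

    Defaults reproduce the study design: 7 laboratories (6 for the rinse
    cycle), 3 runs, 3 conditions per cycle, endpoint means from the
    published report, lab effect sigma_B = 0.45 and repeatability
    sigma_r = 0.40 on the log10 scale (central tendency of the published
    S_R/S_r panel).
    """

    cycle: Cycle = Cycle.MAIN_WASH
    n_labs: int = 7
    n_runs: int = 3
    conditions: tuple[Condition, ...] = (Condition.A, Condition.B, Condition.C)
    endpoint_means: dict[tuple[Condition, str], float] = field(default_factory=dict)
    sigma_B: float = 0.45
    sigma_r: float = 0.40
    n0_means: dict[Strain, float] = field(
        default_factory=lambda: dict(DEFAULT_N0_MEANS))
    detection_limits: DetectionLimits = field(default_factory=DetectionLimits)
    shared_lab_effect: bool = False
    poisson_layer: bool = False
    # Ten-fold ladder; extends to 1e-6 so control carriers at the top of the
    # inoculum validity window (8.15 log10) still yield countable plates.
    dilution_scheme: tuple[float, ...] = (1.0, 1e-1, 1e-2, 1e-3, 1e-4, 1e-5, 1e-6)
    plates_per_dilution: int = 2
    n0_replicates: int = 3
    na_carriers_per_strain: int = 1
    ri_carriers_per_medium: int = 2
    ww_plates: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_B < 0 or self.sigma_r < 0:
            raise ValueError("sigma_B and sigma_r must be non-negative")
        if self.n_labs < 2 or self.n_runs < 2:
            raise ValueError("the design needs at least 2 labs and 2 runs")
        self.cycle = Cycle(self.cycle)
        self.conditions = tuple(Condition(c) for c in self.conditions)
        if not self.endpoint_means:
            self.endpoint_means = {
                k: v for k, v in default_endpoint_means(self.cycle).items()
                if k[0] in self.conditions
            }

    @property
    def lab_ids(self) -> tuple[str, ...]:
        return tuple(f"L{i + 1}" for i in range(self.n_labs))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cycle"] = self.cycle.value
        d["conditions"] = [c.value for c in self.conditions]
        d["endpoint_means"] = {
            f"{cond.value}:{ep}": mu
            for (cond, ep), mu in self.endpoint_means.items()
        }
        d["n0_means"] = {s.value: v for s, v in self.n0_means.items()}
        d["detection_limits"] = {
            "carrier": self.detection_limits.carrier,
            "wash_water": self.detection_limits.wash_water,
        }
        return d


def main_wash_config(**overrides) -> SimulationConfig:
    """Study-design preset for the main wash: 7 labs, conditions A-C."""
    overrides.setdefault("cycle", Cycle.MAIN_WASH)
    overrides.setdefault("n_labs", 7)
    overrides.setdefault("conditions", (Condition.A, Condition.B, Condition.C))
    return SimulationConfig(**overrides)


def rinse_config(**overrides) -> SimulationConfig:
    """Study-design preset for the rinse cycle: 6 labs, conditions D-F."""
    overrides.setdefault("cycle", Cycle.RINSE)
    overrides.setdefault("n_labs", 6)
    overrides.setdefault("conditions", (Condition.D, Condition.E, Condition.F))
    return SimulationConfig(**overrides)


def _latent_endpoint_values(
    config: SimulationConfig, rng: np.random.Generator
) -> dict[tuple[Condition, str, str, int], float]:
    """Raw (uncensored) endpoint values keyed by (condition, lab, endpoint, run)."""
    out: dict[tuple[Condition, str, str, int], float] = {}
    for condition in config.conditions:
        shared = {lab: rng.normal(0.0, config.sigma_B)
                  for lab in config.lab_ids}
        for endpoint in ENDPOINTS:
            mu = config.endpoint_means.get((condition, endpoint))
            if mu is None:
                continue
            for lab in config.lab_ids:
                b = shared[lab] if config.shared_lab_effect else rng.normal(
                    0.0, config.sigma_B)
                for run in range(1, config.n_runs + 1):
                    eps = rng.normal(0.0, config.sigma_r)
                    out[(condition, lab, endpoint, run)] = mu + b + eps
    return out


def _censor_endpoint(
    config: SimulationConfig, endpoint: str, raw: float
) -> tuple[float, bool]:
    """Apply detection-limit censoring on the survivor level.

    LR endpoints censor through the implied Na = N0 - LR; RI/WW endpoints
    censor directly.
    """
    limits = config.detection_limits
    if endpoint in LR_ENDPOINTS:
        strain = Strain(endpoint.split("-")[1])
        n0 = config.n0_means[strain]
        na = n0 - raw
        if na < limits.carrier:
            return n0 - limits.carrier, True
        return raw, False
    limit = limits.carrier if endpoint.startswith("RI") else limits.wash_water
    if raw < limit:
        return limit, True
    return raw, False


def simulate_endpoints(config: SimulationConfig) -> list[RunRecord]:
    """Draw RunRecords from the one-way random-effects model.

    Deterministic for a fixed seed.  Endpoints without a configured mean
    are left missing.
    """
    rng = np.random.default_rng(config.seed)
    latent = _latent_endpoint_values(config, rng)
    records: list[RunRecord] = []
    for condition in config.conditions:
        for lab in config.lab_ids:
            for run in range(1, config.n_runs + 1):
                rec = RunRecord(lab_id=lab, cycle=config.cycle,
                                condition=condition, run_index=run)
                for endpoint in ENDPOINTS:
                    key = (condition, lab, endpoint, run)
                    if key not in latent:
                        rec.endpoints[endpoint] = None
                        rec.censor_flags[endpoint] = False
                        continue
                    value, censored = _censor_endpoint(
                        config, endpoint, latent[key])
                    rec.endpoints[endpoint] = value
                    rec.censor_flags[endpoint] = censored
                records.append(rec)
    return records


# Plates whose expected count exceeds this are skipped: they would be lawn
# growth, uncountable anyway, and enormous Poisson draws are pointless.
_LAMBDA_CAP = 1e6


def _plates_for_load(
    rng: np.random.Generator,
    config: SimulationConfig,
    log10_load: float,
    *,
    lab: str,
    condition: Condition,
    run: int,
    role: Role,
    medium: Medium,
    strain: Strain | None,
    carrier: int,
) -> list[PlateObservation]:
    """Dilution-series plates for one carrier eluate at a true log10 load."""
    plates = []
    concentration = 10.0 ** log10_load
    for d in config.dilution_scheme:
        lam = concentration * CARRIER_PLATE_VOLUME_ML * d
        if lam > _LAMBDA_CAP:
            continue
        for _ in range(config.plates_per_dilution):
            count = (int(rng.poisson(lam)) if config.poisson_layer
                     else int(round(lam)))
            plates.append(PlateObservation(
                lab_id=lab, cycle=config.cycle, condition=condition,
                run_index=run, role=role, medium=medium, strain=strain,
                carrier=carrier, cfu=count, dilution_factor=d,
                plated_volume_ml=CARRIER_PLATE_VOLUME_ML,
            ))
    return plates


def simulate_plate_counts(config: SimulationConfig) -> list[PlateObservation]:
    """Forward-simulate raw plate counts down from latent true loads.

    True endpoint values are drawn from the same random-effects model as
    :func:`simulate_endpoints` (uncensored); each implied survivor load is
    turned into plate counts — Poisson(lambda) when ``poisson_layer`` is
    on, round(lambda) otherwise, with lambda = 10^y * 0.4 * d per carrier
    plate and lambda = 10^y per wash-water plate.  Requantifying these
    plates with the pipeline recovers the latent values up to counting
    noise and detection-limit censoring.
    """
    rng = np.random.default_rng(config.seed)
    latent = _latent_endpoint_values(config, rng)
    plates: list[PlateObservation] = []
    for condition in config.conditions:
        for lab in config.lab_ids:
            for run in range(1, config.n_runs + 1):
                # control carriers, one load per strain
                for strain in Strain:
                    lr_key = (condition, lab, ENDPOINT_FOR_STRAIN[strain], run)
                    if lr_key not in latent:
                        continue
                    n0 = config.n0_means[strain]
                    medium = STRAIN_MEDIUM[strain]
                    for carrier in range(1, config.n0_replicates + 1):
                        plates.extend(_plates_for_load(
                            rng, config, n0, lab=lab, condition=condition,
                            run=run, role=Role.N0, medium=medium,
                            strain=strain, carrier=carrier))
                    na_true = max(n0 - latent[lr_key], -2.0)
                    for carrier in range(1, config.na_carriers_per_strain + 1):
                        plates.extend(_plates_for_load(
                            rng, config, na_true, lab=lab, condition=condition,
                            run=run, role=Role.NA, medium=medium,
                            strain=strain, carrier=carrier))
                for medium in Medium:
                    ri_key = (condition, lab, f"RI-{medium.value}", run)
                    if ri_key in latent:
                        for carrier in range(1, config.ri_carriers_per_medium + 1):
                            plates.extend(_plates_for_load(
                                rng, config, latent[ri_key], lab=lab,
                                condition=condition, run=run, role=Role.RI,
                                medium=medium, strain=None, carrier=carrier))
                    ww_key = (condition, lab, f"WW-{medium.value}", run)
                    if ww_key in latent:
                        lam = min(10.0 ** latent[ww_key], _LAMBDA_CAP)
                        for _ in range(config.ww_plates):
                            count = (int(rng.poisson(lam))
                                     if config.poisson_layer
                                     else int(round(lam)))
                            plates.append(PlateObservation(
                                lab_id=lab, cycle=config.cycle,
                                condition=condition, run_index=run,
                                role=Role.WW, medium=medium, strain=None,
                                carrier=1, cfu=count, dilution_factor=1.0,
                                plated_volume_ml=2.0,
                            ))
    return plates


def make_fixture_spreadsheet(config: SimulationConfig, path: str | Path) -> Path:
    """Write a raw-data CSV in the collection-spreadsheet dialect.

    A companion ``<path>.config.json`` records the generating configuration
    and seed for provenance.  Returns the CSV path.
    """
    from .io import write_raw_data

    path = Path(path)
    plates = simulate_plate_counts(config)
    try:
        write_raw_data(plates, path)
        with open(path.with_suffix(path.suffix + ".config.json"), "w",
                  encoding="utf-8") as fh:
            json.dump(config.to_dict(), fh, indent=2)
    except OSError as exc:
        raise OSError(f"failed writing fixture spreadsheet to {path}: {exc}"
                      ) from exc
    return path
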