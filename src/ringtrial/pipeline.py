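"""End-to-end orchestration: raw plates -> precision report -> summary.

``run_pipeline`` chains quantification, per-cycle precision tables,
Cochran/Grubbs screening with re-analysis, and the cross-table summary
statistics, writing every artefact to an output directory.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

from .io import (
    read_raw_data,
    render_precision_table,
    write_precision_table,
    write_run_records,
)
from .outliers import ScreeningResult, screen_and_reanalyze
from .precision import EstimationMethod, PrecisionRow, RatioClass
from .quantification import Cycle, DetectionLimits, PlateObservation, \
    RunRecord, records_from_plates, plate_admissible
from .synthetic_data import SimulationConfig, simulate_plate_counts

__all__ = ["SummaryStats", "summarize", "run_pipeline", "PipelineResult"]

logger = logging.getLogger("ringtrial")


@dataclass(frozen=True)
class SummaryStats:
    """Cross-table summary of a precision report.

    Percentages follow the report conventions: ratio-class shares to one
    decimal, the share of RSD values below 30% to the nearest integer.
    "Below 30%" and the maxima use strict comparisons on the rendered
    (2-decimal) statistics.
    """

    n_rows: int
    pct_minor: float
    pct_clear: float
    pct_considerable: float
    n_considerable: int
    pct_rsd_below_30: float
    max_rsd: float
    max_s_R: float
    max_s_r: float


def summarize(rows: Sequence[PrecisionRow]) -> SummaryStats:
    """Summary statistics over precision rows (both cycles pooled)."""
    valid = [r for r in rows if not math.isnan(r.s_R)]
    if not valid:
        raise ValueError("summarize requires at least one non-missing row")
    n = len(valid)
    counts = {cls: sum(1 for r in valid if r.ratio_class is cls)
              for cls in RatioClass}
    below30 = sum(1 for r in valid if r.rsd_percent < 30.0)
    return SummaryStats(
        n_rows=n,
        pct_minor=round(100.0 * counts[RatioClass.MINOR] / n, 1),
        pct_clear=round(100.0 * counts[RatioClass.CLEAR] / n, 1),
        pct_considerable=round(100.0 * counts[RatioClass.CONSIDERABLE] / n, 1),
        n_considerable=counts[RatioClass.CONSIDERABLE],
        pct_rsd_below_30=round(100.0 * below30 / n),
        max_rsd=max(r.rsd_percent for r in valid),
        max_s_R=max(r.s_R for r in valid),
        max_s_r=max(r.s_r for r in valid),
    )


def format_summary(stats: SummaryStats) -> str:
    return "\n".join([
        f"rows analysed:                 {stats.n_rows}",
        f"minor lab differences:         {stats.pct_minor}%",
        f"clear lab differences:         {stats.pct_clear}%",
        f"considerable lab differences:  {stats.pct_considerable}% "
        f"({stats.n_considerable} comparison(s))",
        f"RSD below 30%:                 {stats.pct_rsd_below_30:.0f}%",
        f"max RSD:                       {stats.max_rsd:.2f}%",
        f"max S_R:                       {stats.max_s_R:.2f}",
        f"max S_r:                       {stats.max_s_r:.2f}",
    ])


@dataclass
class PipelineResult:
    records: list[RunRecord]
    screening: dict[Cycle, ScreeningResult]
    summary_before: SummaryStats
    summary_after: SummaryStats
    outdir: Path | None


def run_pipeline(
    raw_path: str | Path | None = None,
    config: SimulationConfig | None = None,
    outdir: str | Path | None = None,
    method: EstimationMethod | str = EstimationMethod.ANOVA_MOM,
    alpha: float = 0.05,
    limits: DetectionLimits = DetectionLimits(),
) -> PipelineResult:
    """Run quantification -> precision -> screening -> summary.

    Input is either a raw-data CSV (``raw_path``) or a simulation config
    whose plate counts are generated in memory.  With ``outdir`` set, all
    report tables plus a machine-readable ``results.json`` are written.
    """
    if (raw_path is None) == (config is None):
        raise ValueError("provide exactly one of raw_path or config")
    if raw_path is not None:
        plates = read_raw_data(raw_path)
        logger.info("read %d plate observations from %s", len(plates), raw_path)
    else:
        plates = simulate_plate_counts(config)
        logger.info("simulated %d plate observations (seed=%d)",
                    len(plates), config.seed)

    n_inadmissible = sum(1 for p in plates if not plate_admissible(p))
    logger.info("%d of %d plates outside the countable window",
                n_inadmissible, len(plates))

    records = records_from_plates(plates, limits)
    n_censored = sum(1 for r in records for f in r.censor_flags.values() if f)
    logger.info("%d run records; %d censored endpoint values",
                len(records), n_censored)

    cycles = sorted({r.cycle for r in records}, key=lambda c: c.value)
    screening: dict[Cycle, ScreeningResult] = {}
    rows_before: list[PrecisionRow] = []
    rows_after: list[PrecisionRow] = []
    for cycle in cycles:
        sub = [r for r in records if r.cycle == cycle]
        result = screen_and_reanalyze(sub, alpha=alpha, method=method)
        screening[cycle] = result
        rows_before.extend(result.table_before)
        rows_after.extend(result.table_after)
        n_removed = sum(rep.n_removed for rep in result.reports)
        logger.info("cycle %s: %d outlying value(s) removed", cycle.value,
                    n_removed)

    summary_before = summarize(rows_before)
    summary_after = summarize(rows_after)

    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        write_run_records(records, out / "run_records.csv")
        for cycle in cycles:
            res = screening[cycle]
            write_precision_table(
                res.table_before, out / f"precision_{cycle.value}_before.csv")
            write_precision_table(
                res.table_after, out / f"precision_{cycle.value}_after.csv")
        _write_outlier_report(screening, out / "outlier_report.csv")
        (out / "summary.txt").write_text(
            "Before outlier removal\n" + format_summary(summary_before)
            + "\n\nAfter outlier removal\n" + format_summary(summary_after)
            + "\n", encoding="utf-8")
        with open(out / "results.json", "w", encoding="utf-8") as fh:
            json.dump({
                "summary_before": asdict(summary_before),
                "summary_after": asdict(summary_after),
                "n_plates": len(plates),
                "n_inadmissible_plates": n_inadmissible,
                "n_run_records": len(records),
                "n_censored_endpoints": n_censored,
                "n_outliers_removed": sum(
                    rep.n_removed for res in screening.values()
                    for rep in res.reports),
            }, fh, indent=2)

    return PipelineResult(
        records=records,
        screening=screening,
        summary_before=summary_before,
        summary_after=summary_after,
        outdir=out,
    )


def _write_outlier_report(screening: dict[Cycle, ScreeningResult],
                          path: Path) -> None:
    import pandas as pd

    rows = []
    for cycle, res in screening.items():
        for rep in res.reports:
            rows.append({
                "cycle": cycle.value,
                "condition": rep.condition.value,
                "endpoint": rep.endpoint,
                "cochran_C": rep.cochran_C,
                "cochran_critical": rep.cochran_critical,
                "cochran_flagged_lab": rep.cochran_flagged_lab or "",
                "grubbs_G": rep.grubbs_G,
                "grubbs_critical": rep.grubbs_critical,
                "grubbs_flagged": (
                    f"{rep.grubbs_flagged_value[0]}:run{rep.grubbs_flagged_value[1]}"
                    if rep.grubbs_flagged_value else ""),
                "alpha": rep.alpha,
                "n_removed": rep.n_removed,
                "notes": "; ".join(rep.notes),
            })
    pd.DataFrame(rows).to_csv(path, index=False)
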