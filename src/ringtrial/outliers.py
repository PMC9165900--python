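"""Cochran and Grubbs screening for interlaboratory endpoint data.

The Cochran test flags a laboratory whose within-lab variance is abnormally
large relative to the other laboratories; the Grubbs test flags a single
outlying observation.  Screening runs per endpoint x condition, removes
flagged data (a whole laboratory for Cochran, one observation per pass for
Grubbs, at most two passes) and recomputes the precision table so the
before/after reports can be compared.
"""

from __future__ import annotations

import copy
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .precision import (
    EstimationMethod,
    PrecisionRow,
    precision_table,
)
from .quantification import Condition, ENDPOINTS, RunRecord

__all__ = [
    "CochranResult",
    "GrubbsResult",
    "OutlierReport",
    "ScreeningResult",
    "cochran_critical",
    "cochran_test",
    "grubbs_critical",
    "grubbs_test",
    "screen_and_reanalyze",
]


def cochran_critical(p: int, n: int, alpha: float = 0.05) -> float:
    """Critical value of Cochran's C for p groups of n replicates.

    Uses the exact closed form C = 1 / (1 + (p-1)/F) with F the upper
    alpha/p quantile of the F distribution on (n-1, (p-1)(n-1)) degrees of
    freedom, which reproduces the classical printed tables.
    """
    if p < 2 or n < 2:
        raise ValueError("Cochran's test needs p >= 2 groups of n >= 2 replicates")
    fq = float(stats.f.ppf(1.0 - alpha / p, n - 1, (p - 1) * (n - 1)))
    return 1.0 / (1.0 + (p - 1) / fq)


@dataclass(frozen=True)
class CochranResult:
    C: float
    critical: float
    flagged_lab: str | None
    note: str | None = None


@dataclass(frozen=True)
class GrubbsResult:
    G: float
    critical: float
    flagged_index: int | None


def cochran_test(
    lab_variances: Sequence[tuple[str, float, int]],
    alpha: float = 0.05,
) -> CochranResult:
    """Cochran's test of variance homogeneity across laboratories.

    ``lab_variances`` holds (lab_id, s2, n_reps) per laboratory.  C is the
    largest variance divided by the variance total; the lab attaining it is
    flagged when C exceeds the critical value.  Unequal replication falls
    back on the critical value for the largest n (slightly liberal), with a
    note.  All-zero variances leave C undefined and nothing flagged.
    """
    if len(lab_variances) < 3:
        raise ValueError("Cochran's test requires at least 3 laboratories")
    labs = [str(l) for l, _, _ in lab_variances]
    s2 = np.array([float(v) for _, v, _ in lab_variances])
    reps = [int(n) for _, _, n in lab_variances]
    if np.any(s2 < 0):
        raise ValueError("variances must be non-negative")
    total = float(s2.sum())
    if total == 0.0:
        return CochranResult(math.nan, math.nan, None,
                             note="all laboratory variances are zero")
    note = None
    n_crit = reps[0]
    if len(set(reps)) > 1:
        n_crit = max(reps)
        note = (f"unequal replication {sorted(set(reps))}; critical value "
                f"taken at n = {n_crit}")
    c = float(s2.max()) / total
    critical = cochran_critical(len(labs), n_crit, alpha)
    flagged = labs[int(np.argmax(s2))] if c > critical else None
    return CochranResult(c, critical, flagged, note)


def grubbs_critical(n: int, alpha: float = 0.05) -> float:
    """Two-sided single-outlier Grubbs critical value for sample size n."""
    if n < 3:
        raise ValueError("Grubbs' test requires n >= 3")
    t = float(stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2))
    return (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))


def grubbs_test(values: Sequence[float], alpha: float = 0.05) -> GrubbsResult:
    """Two-sided Grubbs test for a single outlying observation.

    G = max|x_i - mean| / s; the extreme observation is flagged when G
    exceeds the critical value.  Degenerate samples (s = 0) are untestable.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        raise ValueError("Grubbs' test requires at least 3 observations")
    s = float(arr.std(ddof=1))
    if s == 0.0:
        raise ValueError("Grubbs' test is undefined for zero sample spread")
    dev = np.abs(arr - arr.mean())
    idx = int(np.argmax(dev))
    g = float(dev[idx]) / s
    critical = grubbs_critical(arr.size, alpha)
    return GrubbsResult(g, critical, idx if g > critical else None)


@dataclass
class OutlierReport:
    """Screening outcome for one endpoint under one condition."""

    endpoint: str
    condition: Condition
    alpha: float
    cochran_C: float = math.nan
    cochran_critical: float = math.nan
    cochran_flagged_lab: str | None = None
    grubbs_G: float = math.nan
    grubbs_critical: float = math.nan
    grubbs_flagged_value: tuple[str, int] | None = None
    n_removed: int = 0
    notes: list[str] = field(default_factory=list)


@dataclass
class ScreeningResult:
    reports: list[OutlierReport]
    cleaned_records: list[RunRecord]
    table_before: list[PrecisionRow]
    table_after: list[PrecisionRow]


def screen_and_reanalyze(
    records: Sequence[RunRecord],
    alpha: float = 0.05,
    method: EstimationMethod | str = EstimationMethod.ANOVA_MOM,
    max_passes: int = 2,
) -> ScreeningResult:
    """Screen every endpoint x condition, remove flagged data, re-analyse.

    Per pass: Cochran first (removing the flagged laboratory's runs for
    that endpoint, unless that would leave fewer than 2 laboratories), then
    Grubbs (removing at most one observation).  A pass with no flag stops
    the screening.  Returns the outlier reports, cleaned records and the
    precision tables before and after removal.
    """
    table_before = precision_table(records, method)
    cleaned = copy.deepcopy(list(records))
    reports: list[OutlierReport] = []
    conditions = sorted({r.condition for r in cleaned}, key=lambda c: c.value)

    for condition in conditions:
        for endpoint in ENDPOINTS:
            report = OutlierReport(endpoint=endpoint, condition=condition,
                                   alpha=alpha)
            for _pass in range(max_passes):
                flagged_any = False
                present = [
                    r for r in cleaned
                    if r.condition == condition
                    and r.endpoints.get(endpoint) is not None
                ]
                by_lab: dict[str, list[RunRecord]] = {}
                for r in present:
                    by_lab.setdefault(r.lab_id, []).append(r)

                lab_variances = [
                    (lab, float(np.var([r.endpoints[endpoint] for r in rs],
                                       ddof=1)), len(rs))
                    for lab, rs in sorted(by_lab.items())
                    if len(rs) >= 2
                ]
                if len(lab_variances) >= 3:
                    cres = cochran_test(lab_variances, alpha)
                    report.cochran_C = cres.C
                    report.cochran_critical = cres.critical
                    if cres.note:
                        report.notes.append(f"cochran: {cres.note}")
                    if cres.flagged_lab is not None:
                        if len(by_lab) - 1 >= 2:
                            report.cochran_flagged_lab = cres.flagged_lab
                            removed = _mask(cleaned, condition, endpoint,
                                            lab=cres.flagged_lab)
                            report.n_removed += removed
                            flagged_any = True
                        else:
                            report.notes.append(
                                "cochran flag ignored: removal would leave "
                                "fewer than 2 laboratories"
                            )

                present = [
                    r for r in cleaned
                    if r.condition == condition
                    and r.endpoints.get(endpoint) is not None
                ]
                values = [float(r.endpoints[endpoint]) for r in present]
                if len(values) >= 3 and float(np.std(values, ddof=1)) > 0:
                    gres = grubbs_test(values, alpha)
                    report.grubbs_G = gres.G
                    report.grubbs_critical = gres.critical
                    if gres.flagged_index is not None:
                        victim = present[gres.flagged_index]
                        labs_left = {
                            r.lab_id for r in present if r is not victim
                        }
                        if len(labs_left) >= 2:
                            report.grubbs_flagged_value = (
                                victim.lab_id, victim.run_index
                            )
                            victim.endpoints[endpoint] = None
                            report.n_removed += 1
                            flagged_any = True
                        else:
                            report.notes.append(
                                "grubbs flag ignored: removal would leave "
                                "fewer than 2 laboratories"
                            )
                if not flagged_any:
                    break
            reports.append(report)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table_after = precision_table(cleaned, method)
    return ScreeningResult(
        reports=reports,
        cleaned_records=cleaned,
        table_before=table_before,
        table_after=table_after,
    )


def _mask(records: list[RunRecord], condition: Condition, endpoint: str,
          lab: str) -> int:
    """Drop one laboratory's values for one endpoint; returns count removed."""
    removed = 0
    for r in records:
        if (r.condition == condition and r.lab_id == lab
                and r.endpoints.get(endpoint) is not None):
            r.endpoints[endpoint] = None
            removed += 1
    return removed
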