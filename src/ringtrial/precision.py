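"""Repeatability and reproducibility statistics for interlaboratory data.

Each endpoint is modelled with the one-way random-effects model

    Y_ij = mu + B_i + e_ij,   B_i ~ N(0, sigma_B),  e_ij ~ N(0, sigma_r),

where i indexes laboratories and j runs within a laboratory.  The
reproducibility variance decomposes as sigma_R^2 = sigma_B^2 + sigma_r^2.
Components are estimated either by ANOVA method-of-moments (OLS sums of
squares, with the between-lab component truncated at zero) or by REML with
a non-negativity constraint; the two coincide on balanced data whenever the
moment estimate is interior.

Laboratory agreement is summarised by S_R/S_r: ratios below 2 indicate
minor systematic differences between laboratories, 2-4 clear but acceptable
differences, and above 4 considerable differences.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

from .quantification import Condition, Cycle, ENDPOINTS, RunRecord

__all__ = [
    "EstimationMethod",
    "RatioClass",
    "RATIO_CLASS_LABELS",
    "VarianceComponents",
    "PrecisionInput",
    "PrecisionRow",
    "InsufficientDesignError",
    "variance_components",
    "rsd",
    "classify_ratio",
    "mean_ci",
    "precision_table",
]


class EstimationMethod(str, Enum):
    ANOVA_MOM = "anova_mom"
    REML = "reml"


class RatioClass(str, Enum):
    MINOR = "minor"
    CLEAR = "clear"
    CONSIDERABLE = "considerable"


#: Report strings for the three S_R/S_r classes, as printed in method reports.
RATIO_CLASS_LABELS = {
    RatioClass.MINOR: "S_R<2·S_r",
    RatioClass.CLEAR: "4·S_r>S_R>2·S_r",
    RatioClass.CONSIDERABLE: "S_R>4·S_r",
}

_LABEL_TO_CLASS = {v: k for k, v in RATIO_CLASS_LABELS.items()}


class InsufficientDesignError(ValueError):
    """The design cannot support a between-laboratory variance estimate."""


@dataclass(frozen=True)
class VarianceComponents:
    """Estimated variance components of the one-way random model.

    ``sigma2_R`` is always exactly ``sigma2_B + sigma2_r``.  ``p_lab_effect``
    is the ANOVA F-test p-value for H0: sigma_B^2 = 0 (reported for both
    estimation methods).
    """

    sigma2_B: float
    sigma2_r: float
    method: EstimationMethod
    p_lab_effect: float
    sigma2_R: float = field(init=False)

    def __post_init__(self) -> None:
        if self.sigma2_B < 0 or self.sigma2_r < 0:
            raise ValueError("variance components must be non-negative")
        object.__setattr__(self, "sigma2_R", self.sigma2_B + self.sigma2_r)

    @property
    def s_R(self) -> float:
        return math.sqrt(self.sigma2_R)

    @property
    def s_r(self) -> float:
        return math.sqrt(self.sigma2_r)


@dataclass(frozen=True)
class PrecisionInput:
    """Log-scale observations of one endpoint under one condition."""

    endpoint: str
    condition: Condition
    values: tuple[tuple[str, int, float], ...]  # (lab_id, run_index, y)

    @classmethod
    def from_arrays(
        cls,
        endpoint: str,
        condition: Condition,
        labs: Sequence[str],
        y: Sequence[float],
        runs: Sequence[int] | None = None,
    ) -> "PrecisionInput":
        if runs is None:
            seen: dict[str, int] = {}
            runs = []
            for l in labs:
                seen[l] = seen.get(l, 0) + 1
                runs.append(seen[l])
        return cls(
            endpoint=endpoint,
            condition=Condition(condition),
            values=tuple((str(l), int(r), float(v)) for l, r, v in zip(labs, runs, y)),
        )


@dataclass(frozen=True)
class PrecisionRow:
    """One line of a precision report: endpoint x condition statistics."""

    endpoint: str
    condition: Condition
    n: int
    mean: float
    ci95: tuple[float, float]
    s_R: float
    s_r: float
    rsd_percent: float
    ratio_class: RatioClass

    @property
    def ratio_label(self) -> str:
        return RATIO_CLASS_LABELS[self.ratio_class]


def _group_by_lab(
    values: Iterable[tuple[str, int, float]]
) -> dict[str, list[float]]:
    groups: dict[str, list[float]] = {}
    for lab, _run, y in values:
        groups.setdefault(lab, []).append(float(y))
    return groups


def _anova_sums(groups: dict[str, list[float]]):
    """One-way sums of squares: returns (N, p, ni, ssw, ssb, grand mean)."""
    ni = np.array([len(v) for v in groups.values()], dtype=float)
    means = np.array([float(np.mean(v)) for v in groups.values()])
    n_total = ni.sum()
    grand = sum(sum(v) for v in groups.values()) / n_total
    ssw = sum(float(np.sum((np.asarray(v) - m) ** 2))
              for v, m in zip(groups.values(), means))
    ssb = float(np.sum(ni * (means - grand) ** 2))
    return n_total, len(ni), ni, ssw, ssb, grand


def variance_components(
    data: PrecisionInput,
    method: EstimationMethod | str = EstimationMethod.ANOVA_MOM,
) -> VarianceComponents:
    """Estimate (sigma_B^2, sigma_r^2) for one endpoint under one condition.

    ``anova_mom``: sigma_r^2 = MS_within; sigma_B^2 = max(0,
    (MS_between - MS_within)/n0), with n0 the per-lab replication when
    balanced and the effective replication n0 = (N - sum(n_i^2)/N)/(p-1)
    otherwise.  ``reml``: restricted maximum likelihood with the
    between-component profiled on [0, inf).

    Both methods report ``p_lab_effect`` from the one-way ANOVA F-test.
    Zero total variance returns all-zero components with p = 1.
    """
    method = EstimationMethod(method)
    groups = _group_by_lab(data.values)
    if len(groups) < 2:
        raise InsufficientDesignError("at least 2 laboratories are required")
    if all(len(v) < 2 for v in groups.values()):
        raise InsufficientDesignError(
            "at least one laboratory must contribute replicate runs"
        )

    n_total, p, ni, ssw, ssb, _ = _anova_sums(groups)
    df_b = p - 1
    df_w = n_total - p
    if df_w <= 0:
        raise InsufficientDesignError("no within-laboratory degrees of freedom")

    # exact degenerate case (e.g. every value pinned at a detection limit);
    # the range check avoids rounding dust in the sums of squares
    all_values = [v for vs in groups.values() for v in vs]
    if ssw + ssb <= 0.0 or max(all_values) == min(all_values):
        return VarianceComponents(0.0, 0.0, method, 1.0)

    msw = ssw / df_w
    msb = ssb / df_b
    if msw == 0.0:
        p_lab = 0.0 if msb > 0 else 1.0
    else:
        p_lab = float(stats.f.sf(msb / msw, df_b, df_w))

    if method is EstimationMethod.ANOVA_MOM:
        if np.all(ni == ni[0]):
            n0 = float(ni[0])
        else:
            n0 = (n_total - float(np.sum(ni**2)) / n_total) / df_b
        sigma2_r = msw
        sigma2_b = max(0.0, (msb - msw) / n0)
        return VarianceComponents(sigma2_b, sigma2_r, method, p_lab)

    sigma2_b, sigma2_r = _reml_oneway(groups)
    return VarianceComponents(sigma2_b, sigma2_r, method, p_lab)


def _reml_oneway(groups: dict[str, list[float]]) -> tuple[float, float]:
    """REML for the one-way random model via the profiled variance ratio.

    For lambda = sigma_B^2/sigma_r^2 the residual variance has the closed
    form sigma_r^2(lambda) = Q(lambda)/(N-1), so only a bounded scalar
    search over lambda is needed.
    """
    ni = np.array([len(v) for v in groups.values()], dtype=float)
    ybar = np.array([float(np.mean(v)) for v in groups.values()])
    ssw = sum(float(np.sum((np.asarray(v) - m) ** 2))
              for v, m in zip(groups.values(), ybar))
    n_total = float(ni.sum())

    def neg2_profile(lam: float) -> float:
        w = ni / (1.0 + ni * lam)
        mu = float(np.sum(w * ybar) / np.sum(w))
        q = ssw + float(np.sum(w * (ybar - mu) ** 2))
        if q <= 0:
            return -math.inf  # degenerate: likelihood unbounded, handled below
        return (
            (n_total - 1.0) * math.log(q)
            + float(np.sum(np.log1p(ni * lam)))
            + math.log(float(np.sum(w)))
        )

    # Bracket on log-ish grid; the objective is smooth and unimodal in
    # practice, a bounded Brent search refines the best grid cell.
    grid = np.concatenate(([0.0], np.geomspace(1e-8, 1e6, 57)))
    vals = np.array([neg2_profile(l) for l in grid])
    k = int(np.argmin(vals))
    lo = grid[max(0, k - 1)]
    hi = grid[min(len(grid) - 1, k + 1)]
    if hi > lo:
        res = optimize.minimize_scalar(
            neg2_profile, bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-12},
        )
        lam = float(res.x) if res.fun <= vals[k] else float(grid[k])
    else:
        lam = float(grid[k])
    if neg2_profile(0.0) <= neg2_profile(lam):
        lam = 0.0

    w = ni / (1.0 + ni * lam)
    mu = float(np.sum(w * ybar) / np.sum(w))
    q = ssw + float(np.sum(w * (ybar - mu) ** 2))
    sigma2_r = q / (n_total - 1.0)
    return lam * sigma2_r, sigma2_r


def rsd(mean: float, s_R: float) -> float:
    """Relative standard deviation, RSD = 100 * S_R / mean (percent).

    Defined for positive means only (log-scale endpoint means here are
    positive by construction).
    """
    if mean <= 0:
        raise ValueError(f"RSD requires a positive mean, got {mean}")
    return 100.0 * s_R / mean


def classify_ratio(s_R: float, s_r: float) -> RatioClass:
    """Classify between-laboratory systematic differences from S_R/S_r.

    minor: S_R < 2*S_r; clear: 2*S_r <= S_R <= 4*S_r; considerable:
    S_R > 4*S_r.  Degenerate repeatability (S_r = 0) maps to minor when
    S_R = 0 and considerable otherwise.
    """
    if s_R < 0 or s_r < 0:
        raise ValueError("standard deviations must be non-negative")
    if s_r == 0.0:
        return RatioClass.MINOR if s_R == 0.0 else RatioClass.CONSIDERABLE
    ratio = s_R / s_r
    if ratio < 2.0:
        return RatioClass.MINOR
    if ratio <= 4.0:
        return RatioClass.CLEAR
    return RatioClass.CONSIDERABLE


def ratio_class_from_label(label: str) -> RatioClass:
    """Inverse of :data:`RATIO_CLASS_LABELS` (accepts enum values too)."""
    if label in _LABEL_TO_CLASS:
        return _LABEL_TO_CLASS[label]
    return RatioClass(label)


def mean_ci(
    values: Sequence[float], level: float = 0.95
) -> tuple[float, float, float]:
    """Arithmetic mean with a t-based confidence interval.

    Returns ``(mean, low, high)``.  A single observation yields a collapsed
    interval with a warning; zero spread collapses the interval to the mean.
    """
    if len(values) == 0:
        raise ValueError("mean_ci requires at least one value")
    arr = np.asarray(values, dtype=float)
    m = float(arr.mean())
    n = arr.size
    if n == 1:
        warnings.warn("confidence interval from a single observation collapses "
                      "to the point estimate", stacklevel=2)
        return m, m, m
    s = float(arr.std(ddof=1))
    # identical values collapse exactly (std of n copies of x carries
    # rounding dust from the mean)
    if s == 0.0 or float(arr.max()) == float(arr.min()):
        return m, m, m
    half = float(stats.t.ppf(0.5 + level / 2.0, n - 1)) * s / math.sqrt(n)
    return m, m - half, m + half


def precision_table(
    records: Sequence[RunRecord],
    method: EstimationMethod | str = EstimationMethod.ANOVA_MOM,
) -> list[PrecisionRow]:
    """Build the per-endpoint precision report from run records.

    One row per condition x endpoint (report order: conditions sorted, the
    nine endpoints in standard order).  Endpoints with no data produce a
    missing-marker row (NaN statistics) and a warning.
    """
    method = EstimationMethod(method)
    conditions = sorted({r.condition for r in records}, key=lambda c: c.value)
    rows: list[PrecisionRow] = []
    for condition in conditions:
        cond_records = [r for r in records if r.condition == condition]
        for endpoint in ENDPOINTS:
            triples = [
                (r.lab_id, r.run_index, r.endpoints[endpoint])
                for r in cond_records
                if r.endpoints.get(endpoint) is not None
            ]
            if not triples:
                warnings.warn(
                    f"endpoint {endpoint} under condition {condition.value} "
                    "has no observations; emitting missing row",
                    stacklevel=2,
                )
                rows.append(PrecisionRow(
                    endpoint=endpoint, condition=condition, n=0,
                    mean=math.nan, ci95=(math.nan, math.nan),
                    s_R=math.nan, s_r=math.nan, rsd_percent=math.nan,
                    ratio_class=RatioClass.MINOR,
                ))
                continue
            y = [t[2] for t in triples]
            m, lo, hi = mean_ci(y)
            data = PrecisionInput(endpoint=endpoint, condition=condition,
                                  values=tuple(triples))
            try:
                vc = variance_components(data, method)
            except InsufficientDesignError as exc:
                warnings.warn(
                    f"endpoint {endpoint} under condition {condition.value}: "
                    f"{exc}; emitting missing row", stacklevel=2)
                rows.append(PrecisionRow(
                    endpoint=endpoint, condition=condition, n=len(y),
                    mean=m, ci95=(lo, hi), s_R=math.nan, s_r=math.nan,
                    rsd_percent=math.nan, ratio_class=RatioClass.MINOR,
                ))
                continue
            rsd_pct = rsd(m, vc.s_R) if m > 0 else math.nan
            rows.append(PrecisionRow(
                endpoint=endpoint, condition=condition, n=len(y),
                mean=m, ci95=(lo, hi), s_R=vc.s_R, s_r=vc.s_r,
                rsd_percent=rsd_pct,
                ratio_class=classify_ratio(vc.s_R, vc.s_r),
            ))
    return rows
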