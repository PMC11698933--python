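"""Deterministic drinking-water exposure algebra (USEPA 1989 intake model).

For a contaminant concentration ``C`` (mg/L) ingested at rate ``IR`` (L/day)
over an exposure frequency ``EF`` (days/year) and duration ``ED`` (years),
averaged over ``AT`` days by a receptor of body weight ``BW`` (kg):

    TDI = C * IR                          (total daily intake, mg/day)
    CDI = C * IR * EF * ED / (BW * AT)    (chronic daily intake, mg/kg/day)
    HQ  = CDI / RfD                       (hazard quotient, dimensionless)

``RfD`` is the reference dose (mg/kg/day); HQ > 1 flags a potential
non-carcinogenic risk. When ``EF * ED == AT`` (true for all default cohorts)
the CDI collapses to ``C * IR / BW``.

The module works on :class:`SiteRecord` objects (one sampling location with
replicate concentrations and/or a min/max/mean/std summary) and
:class:`AgeGroupParams` cohorts, and produces per-(site, cohort)
:class:`ExposureResult` rows plus district-level summaries.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import DomainError, UsageError, ValidationWarning

__all__ = [
    "AgeGroupParams",
    "SiteSummary",
    "SiteRecord",
    "ExposureResult",
    "DistrictSummary",
    "DEFAULT_COHORTS",
    "round_half_up",
    "compute_tdi",
    "compute_cdi",
    "compute_hq",
    "exposure_table",
    "district_summary",
    "mean_hq_by_cohort",
]

#: Concentration variants carried through every exposure table.
VARIANTS = ("min", "mean", "max")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero (matches hand-tabulated values).

    Python's builtin ``round`` is banker's rounding; published exposure
    tables are conventionally rounded half-up, so reproduction tests use
    this helper.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _require_positive(value: float, name: str) -> None:
    if not (math.isfinite(value) and value > 0):
        raise DomainError(f"{name} must be a positive finite number, got {value!r}")


def _require_nonnegative(value: float, name: str) -> None:
    if not (math.isfinite(value) and value >= 0):
        raise DomainError(f"{name} must be a non-negative finite number, got {value!r}")


@dataclass(frozen=True)
class AgeGroupParams:
    """Exposure parameters for one receptor cohort.

    Units: AT days; EF days/year; ED years; BW kg; IR L/day; RfD mg/kg/day.
    All default cohorts satisfy ``EF * ED == AT``; a deviation is legal but
    triggers a :class:`ValidationWarning` since it usually indicates a typo.
    """

    name: str
    AT: float
    EF: float
    ED: float
    BW: float
    IR: float
    RfD: float

    def __post_init__(self) -> None:
        for field in ("AT", "EF", "ED", "BW", "IR", "RfD"):
            _require_positive(getattr(self, field), f"{self.name or 'cohort'}.{field}")
        if self.EF > 366:
            raise DomainError(
                f"{self.name}.EF={self.EF} exceeds 366 days/year"
            )
        if not math.isclose(self.EF * self.ED, self.AT, rel_tol=1e-9):
            warnings.warn(
                f"cohort {self.name!r}: EF*ED = {self.EF * self.ED} differs from "
                f"AT = {self.AT}; intake will not collapse to C*IR/BW",
                ValidationWarning,
                stacklevel=2,
            )


#: Default cohorts (children 2-6, teenagers 7-18, adults 18-62).
DEFAULT_COHORTS: tuple[AgeGroupParams, ...] = (
    AgeGroupParams("children", AT=1460, EF=365, ED=4, BW=15, IR=0.78, RfD=0.06),
    AgeGroupParams("teenagers", AT=4745, EF=365, ED=13, BW=50, IR=2.0, RfD=0.06),
    AgeGroupParams("adults", AT=14600, EF=365, ED=40, BW=78, IR=2.5, RfD=0.06),
)


@dataclass(frozen=True)
class SiteSummary:
    """Min/max/mean/std of the fluoride concentration at one site (mg/L)."""

    min: float
    max: float
    mean: float
    std: float

    def __post_init__(self) -> None:
        for field in ("min", "max", "mean", "std"):
            _require_nonnegative(getattr(self, field), f"summary.{field}")
        if not (self.min <= self.mean <= self.max):
            raise DomainError(
                f"summary requires min <= mean <= max, got "
                f"({self.min}, {self.mean}, {self.max})"
            )


def summarize_samples(samples: Sequence[float]) -> SiteSummary:
    """Summary statistics of replicate concentrations (sample std, ddof=1)."""
    arr = np.asarray(samples, dtype=float)
    if arr.size == 0:
        raise UsageError("cannot summarize an empty replicate list")
    std = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return SiteSummary(float(arr.min()), float(arr.max()), float(arr.mean()), std)


@dataclass(frozen=True)
class SiteRecord:
    """One sampling location: replicate concentrations and/or their summary."""

    site_id: str
    location_name: str
    samples: tuple[float, ...] | None
    summary: SiteSummary

    def __post_init__(self) -> None:
        if self.samples is not None:
            if len(self.samples) == 0:
                raise DomainError(f"{self.site_id}: empty replicate list")
            for c in self.samples:
                _require_nonnegative(c, f"{self.site_id} concentration")
            recomputed = summarize_samples(self.samples)
            # Supplied summaries are typically rounded to 2 decimals; the
            # std is additionally only loosely constrained by 5 replicates.
            tol = 5.05e-3
            for field in ("min", "max", "mean"):
                if abs(getattr(recomputed, field) - getattr(self.summary, field)) > tol:
                    raise DomainError(
                        f"{self.site_id}: supplied summary {field}="
                        f"{getattr(self.summary, field)} disagrees with replicates "
                        f"({getattr(recomputed, field):.4f})"
                    )

    @classmethod
    def from_samples(
        cls, site_id: str, location_name: str, samples: Iterable[float]
    ) -> "SiteRecord":
        samples = tuple(float(c) for c in samples)
        return cls(site_id, location_name, samples, summarize_samples(samples))

    @classmethod
    def from_summary(
        cls, site_id: str, location_name: str, summary: SiteSummary
    ) -> "SiteRecord":
        return cls(site_id, location_name, None, summary)


@dataclass(frozen=True)
class ExposureResult:
    """TDI/CDI/HQ for one (site, cohort) pair at min/mean/max concentration.

    ``tdi_*`` in mg/day, ``cdi_*`` in mg/kg/day, ``hq_*`` dimensionless.
    """

    site_id: str
    cohort: str
    tdi_min: float
    tdi_mean: float
    tdi_max: float
    cdi_min: float
    cdi_mean: float
    cdi_max: float
    hq_min: float
    hq_mean: float
    hq_max: float

    def tdi(self, variant: str) -> float:
        return getattr(self, f"tdi_{variant}")

    def cdi(self, variant: str) -> float:
        return getattr(self, f"cdi_{variant}")

    def hq(self, variant: str) -> float:
        return getattr(self, f"hq_{variant}")


@dataclass(frozen=True)
class DistrictSummary:
    """Dataset-level concentration summary.

    ``mean_of_means`` is the unweighted mean of the site means;
    ``exceedance_pct`` is the share of *site means* strictly above the
    threshold (replicate-level exceedance is reported when replicates
    exist, else ``None``).
    """

    threshold: float
    n_sites: int
    minimum: float
    maximum: float
    mean_of_means: float
    n_exceeding: int
    exceedance_pct: float
    exceeding_sites: tuple[str, ...]
    n_samples: int
    sample_exceedance_pct: float | None


def compute_tdi(C: float, IR: float) -> float:
    """Total daily intake ``C * IR`` in mg/day."""
    _require_nonnegative(C, "C")
    _require_positive(IR, "IR")
    return C * IR


def compute_cdi(C: float, params: AgeGroupParams) -> float:
    """Chronic daily intake ``C*IR*EF*ED / (BW*AT)`` in mg/kg/day."""
    _require_nonnegative(C, "C")
    if not isinstance(params, AgeGroupParams):
        params = AgeGroupParams(**params)  # type: ignore[arg-type]
    return C * params.IR * params.EF * params.ED / (params.BW * params.AT)


def compute_hq(C: float, params: AgeGroupParams) -> float:
    """Hazard quotient ``CDI / RfD`` (dimensionless)."""
    return compute_cdi(C, params) / params.RfD


def exposure_table(
    sites: Sequence[SiteRecord], cohorts: Sequence[AgeGroupParams]
) -> list[ExposureResult]:
    """One :class:`ExposureResult` per (site, cohort), site-major order.

    The min/mean/max variants are driven by the site's min/mean/max
    concentration. Pure function of its inputs.
    """
    if len(sites) == 0:
        raise UsageError("exposure_table requires at least one site")
    if len(cohorts) == 0:
        raise UsageError("exposure_table requires at least one cohort")
    results: list[ExposureResult] = []
    for site in sites:
        conc = {v: getattr(site.summary, v if v != "mean" else "mean") for v in VARIANTS}
        for cohort in cohorts:
            values: dict[str, float] = {}
            for variant in VARIANTS:
                c = conc[variant]
                values[f"tdi_{variant}"] = compute_tdi(c, cohort.IR)
                values[f"cdi_{variant}"] = compute_cdi(c, cohort)
                values[f"hq_{variant}"] = values[f"cdi_{variant}"] / cohort.RfD
            results.append(ExposureResult(site.site_id, cohort.name, **values))
    return results


def district_summary(
    sites: Sequence[SiteRecord], threshold: float = 1.5
) -> DistrictSummary:
    """District-wide concentration summary with threshold exceedance."""
    if len(sites) == 0:
        raise UsageError("district_summary requires at least one site")
    _require_positive(threshold, "threshold")
    minima = [s.summary.min for s in sites]
    maxima = [s.summary.max for s in sites]
    means = [s.summary.mean for s in sites]
    exceeding = tuple(s.site_id for s in sites if s.summary.mean > threshold)
    all_samples = [c for s in sites if s.samples for c in s.samples]
    sample_pct = (
        100.0 * sum(c > threshold for c in all_samples) / len(all_samples)
        if all_samples
        else None
    )
    return DistrictSummary(
        threshold=threshold,
        n_sites=len(sites),
        minimum=min(minima),
        maximum=max(maxima),
        mean_of_means=float(np.mean(means)),
        n_exceeding=len(exceeding),
        exceedance_pct=100.0 * len(exceeding) / len(sites),
        exceeding_sites=exceeding,
        n_samples=len(all_samples),
        sample_exceedance_pct=sample_pct,
    )


def mean_hq_by_cohort(results: Sequence[ExposureResult]) -> dict[str, float]:
    """Arithmetic mean over sites of the mean-concentration HQ, per cohort."""
    if len(results) == 0:
        raise UsageError("mean_hq_by_cohort requires at least one result")
    by_cohort: dict[str, list[float]] = {}
    for r in results:
        by_cohort.setdefault(r.cohort, []).append(r.hq_mean)
    return {name: float(np.mean(v)) for name, v in by_cohort.items()}
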