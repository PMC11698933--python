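"""Fluorosis endpoint classification and prevalence.

A site is counted toward an endpoint's prevalence when its mean-concentration
hazard quotient strictly exceeds the endpoint threshold (default 1.0, the
conventional no-risk boundary). Endpoint-specific reference doses can be
supplied as overrides; only the dental endpoint ships with defaults, since
reference doses for bone and skeletal fluorosis endpoints are not part of
this package's parameter set and must come from the user.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .errors import DomainError, UsageError
from .exposure import AgeGroupParams, ExposureResult, compute_cdi, round_half_up

__all__ = [
    "EndpointConfig",
    "CohortPrevalence",
    "PrevalenceReport",
    "DENTAL",
    "classify_sites",
    "endpoint_hq",
]


@dataclass(frozen=True)
class EndpointConfig:
    """One fluorosis endpoint: name, HQ threshold, optional RfD override."""

    name: str
    hq_threshold: float = 1.0
    rfd_override: float | None = None  # mg/kg/day

    def __post_init__(self) -> None:
        if not self.hq_threshold > 0:
            raise DomainError(f"hq_threshold must be > 0, got {self.hq_threshold}")
        if self.rfd_override is not None and not self.rfd_override > 0:
            raise DomainError(f"rfd_override must be > 0, got {self.rfd_override}")


#: Dental fluorosis: HQ computed with the cohort's own RfD, threshold 1.
DENTAL = EndpointConfig("dental")


@dataclass(frozen=True)
class CohortPrevalence:
    """Exceedance summary for one cohort under one endpoint."""

    cohort: str
    n_total: int
    n_exceeding: int
    fraction_pct: float          # unrounded percentage
    fraction_pct_display: int    # rounded half-up to the nearest integer
    exceeding_sites: tuple[str, ...]


@dataclass(frozen=True)
class PrevalenceReport:
    endpoint: str
    hq_threshold: float
    cohorts: Mapping[str, CohortPrevalence]


def endpoint_hq(C: float, params: AgeGroupParams, config: EndpointConfig) -> float:
    """HQ against an endpoint, honoring its RfD override when present."""
    rfd = config.rfd_override if config.rfd_override is not None else params.RfD
    return compute_cdi(C, params) / rfd


def _endpoint_hq_from_result(r: ExposureResult, config: EndpointConfig) -> float:
    if config.rfd_override is not None:
        return r.cdi_mean / config.rfd_override
    return r.hq_mean


def classify_sites(
    results: Sequence[ExposureResult], config: EndpointConfig = DENTAL
) -> PrevalenceReport:
    """Per-cohort fraction of sites whose mean-variant HQ exceeds the threshold.

    Exceedance is strict (HQ == threshold does not count). Each (site, cohort)
    pair may appear once.
    """
    if len(results) == 0:
        raise UsageError("classify_sites requires at least one exposure result")
    seen: set[tuple[str, str]] = set()
    by_cohort: dict[str, list[ExposureResult]] = {}
    for r in results:
        if not r.cohort:
            raise UsageError("exposure results must carry cohort labels")
        key = (r.site_id, r.cohort)
        if key in seen:
            raise UsageError(f"duplicate (site, cohort) pair {key}")
        seen.add(key)
        by_cohort.setdefault(r.cohort, []).append(r)
    cohorts: dict[str, CohortPrevalence] = {}
    for name, rows in by_cohort.items():
        exceeding = tuple(
            r.site_id
            for r in rows
            if _endpoint_hq_from_result(r, config) > config.hq_threshold
        )
        pct = 100.0 * len(exceeding) / len(rows)
        cohorts[name] = CohortPrevalence(
            cohort=name,
            n_total=len(rows),
            n_exceeding=len(exceeding),
            fraction_pct=pct,
            fraction_pct_display=int(round_half_up(pct, 0)),
            exceeding_sites=exceeding,
        )
    return PrevalenceReport(config.name, config.hq_threshold, cohorts)
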