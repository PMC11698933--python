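"""Readers and writers for the package's plain-text interchange formats.

Site CSVs come in two dialects (UTF-8, comma-separated, dot decimal, header
mandatory):

* replicate mode: ``site_id,location_name,sample_1,...,sample_k``
* summary mode:   ``site_id,location_name,min,max,mean[,std]``

Cohort parameters and distribution specs are YAML (or JSON, which YAML
parses). Numeric outputs are emitted unrounded alongside display-rounded
twins; every JSON report carries a ``meta`` block with the package version,
seed and a hash of the effective configuration.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from .endpoints import EndpointConfig, PrevalenceReport
from .errors import UsageError
from .exposure import (
    VARIANTS,
    AgeGroupParams,
    DistrictSummary,
    ExposureResult,
    SiteRecord,
    SiteSummary,
    round_half_up,
)
from .montecarlo import DistributionSpec, RiskDistribution, SensitivityReport

__all__ = [
    "read_sites_csv",
    "write_sites_csv",
    "read_cohorts",
    "read_endpoint",
    "read_specs",
    "exposure_frame",
    "district_summary_dict",
    "prevalence_dict",
    "prevalence_frame",
    "risk_dict",
    "tornado_frame",
    "meta_block",
    "write_json",
]

_SUMMARY_COLS = {"min", "max", "mean"}


def read_sites_csv(path: str | Path) -> list[SiteRecord]:
    """Read a site CSV in replicate or summary mode (auto-detected)."""
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # includes empty files and parse errors
        raise UsageError(f"{path}: cannot parse CSV ({exc})") from exc
    cols = list(frame.columns)
    if "site_id" not in cols or "location_name" not in cols:
        raise UsageError(
            f"{path}: header must contain site_id and location_name, got {cols}"
        )
    sample_cols = [c for c in cols if c.startswith("sample_")]
    records: list[SiteRecord] = []
    if sample_cols:
        for i, row in frame.iterrows():
            values = [row[c] for c in sample_cols if pd.notna(row[c])]
            if not values:
                raise UsageError(f"{path}: row {i + 2} ({row['site_id']}): no samples")
            try:
                records.append(
                    SiteRecord.from_samples(
                        str(row["site_id"]), str(row["location_name"]),
                        [float(v) for v in values],
                    )
                )
            except (TypeError, ValueError) as exc:
                raise UsageError(f"{path}: row {i + 2}: {exc}") from exc
    elif _SUMMARY_COLS.issubset(cols):
        for i, row in frame.iterrows():
            try:
                summary = SiteSummary(
                    float(row["min"]), float(row["max"]), float(row["mean"]),
                    float(row["std"]) if "std" in cols and pd.notna(row["std"]) else 0.0,
                )
                records.append(
                    SiteRecord.from_summary(
                        str(row["site_id"]), str(row["location_name"]), summary
                    )
                )
            except (TypeError, ValueError) as exc:
                raise UsageError(f"{path}: row {i + 2}: {exc}") from exc
    else:
        raise UsageError(
            f"{path}: need either sample_1..sample_k or min/max/mean columns, "
            f"got {cols}"
        )
    if not records:
        raise UsageError(f"{path}: no site rows")
    return records


def write_sites_csv(records: Sequence[SiteRecord], path: str | Path) -> None:
    """Write sites in replicate mode (falls back to summary mode if any
    record lacks replicates)."""
    path = Path(path)
    if all(r.samples is not None for r in records):
        k = max(len(r.samples) for r in records)
        rows = []
        for r in records:
            row: dict[str, Any] = {"site_id": r.site_id, "location_name": r.location_name}
            for j in range(k):
                row[f"sample_{j + 1}"] = r.samples[j] if j < len(r.samples) else None
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        rows = [
            {"site_id": r.site_id, "location_name": r.location_name,
             "min": r.summary.min, "max": r.summary.max,
             "mean": r.summary.mean, "std": r.summary.std}
            for r in records
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


def read_cohorts(path: str | Path) -> list[AgeGroupParams]:
    """Read cohort parameter sets from a YAML/JSON document keyed by name."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping) or not doc:
        raise UsageError(f"{path}: expected a mapping of cohort name -> parameters")
    cohorts = []
    for name, params in doc.items():
        try:
            cohorts.append(
                AgeGroupParams(
                    name=str(name),
                    AT=float(params["AT"]), EF=float(params["EF"]),
                    ED=float(params["ED"]), BW=float(params["BW"]),
                    IR=float(params["IR"]), RfD=float(params["RfD"]),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise UsageError(f"{path}: cohort {name!r}: {exc}") from exc
    return cohorts


def read_endpoint(path: str | Path) -> EndpointConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping) or "name" not in doc:
        raise UsageError(f"{path}: expected a mapping with at least a 'name'")
    return EndpointConfig(
        name=str(doc["name"]),
        hq_threshold=float(doc.get("hq_threshold", 1.0)),
        rfd_override=(
            float(doc["rfd_override"]) if doc.get("rfd_override") is not None else None
        ),
    )


def _spec_from_dict(d: Mapping[str, Any]) -> DistributionSpec:
    family = d.get("family")
    if family == "mixture":
        return DistributionSpec.mixture(
            [_spec_from_dict(c) for c in d["components"]], d.get("weights")
        )
    return DistributionSpec(
        family=str(family),
        params=tuple(float(p) for p in d.get("params", ())),
        low=float(d["low"]) if d.get("low") is not None else None,
        high=float(d["high"]) if d.get("high") is not None else None,
    )


def read_specs(path: str | Path) -> dict[str, DistributionSpec]:
    """Read a mapping of input name -> distribution spec from YAML/JSON."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping) or not doc:
        raise UsageError(f"{path}: expected a mapping of input -> distribution spec")
    try:
        return {str(name): _spec_from_dict(d) for name, d in doc.items()}
    except (KeyError, TypeError, ValueError) as exc:
        raise UsageError(f"{path}: {exc}") from exc


# -- tidy output assembly ---------------------------------------------------

def exposure_frame(results: Sequence[ExposureResult]) -> pd.DataFrame:
    """One row per site x cohort x variant, raw values plus rounded twins
    (TDI 3 decimals, HQ 2 decimals)."""
    rows = []
    for r in results:
        for variant in VARIANTS:
            rows.append(
                {
                    "site_id": r.site_id,
                    "cohort": r.cohort,
                    "variant": variant,
                    "tdi_mg_day": r.tdi(variant),
                    "cdi_mg_kg_day": r.cdi(variant),
                    "hq": r.hq(variant),
                    "tdi_3dp": round_half_up(r.tdi(variant), 3),
                    "hq_2dp": round_half_up(r.hq(variant), 2),
                }
            )
    return pd.DataFrame(rows)


def district_summary_dict(summary: DistrictSummary) -> dict[str, Any]:
    return {
        "threshold_mg_L": summary.threshold,
        "n_sites": summary.n_sites,
        "min_mg_L": summary.minimum,
        "max_mg_L": summary.maximum,
        "mean_of_site_means_mg_L": summary.mean_of_means,
        "mean_of_site_means_2dp": round_half_up(summary.mean_of_means, 2),
        "n_exceeding": summary.n_exceeding,
        "exceedance_pct": summary.exceedance_pct,
        "exceedance_pct_1dp": round_half_up(summary.exceedance_pct, 1),
        "exceeding_sites": list(summary.exceeding_sites),
        "n_samples": summary.n_samples,
        "sample_exceedance_pct": summary.sample_exceedance_pct,
    }


def prevalence_dict(report: PrevalenceReport) -> dict[str, Any]:
    return {
        "endpoint": report.endpoint,
        "hq_threshold": report.hq_threshold,
        "cohorts": {
            name: {
                "n_total": p.n_total,
                "n_exceeding": p.n_exceeding,
                "fraction_pct": p.fraction_pct,
                "fraction_pct_display": p.fraction_pct_display,
                "exceeding_sites": list(p.exceeding_sites),
            }
            for name, p in report.cohorts.items()
        },
    }


def prevalence_frame(report: PrevalenceReport) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"endpoint": report.endpoint, "cohort": name,
             "fraction_pct": p.fraction_pct, "n_exceed": p.n_exceeding,
             "n_total": p.n_total}
            for name, p in report.cohorts.items()
        ]
    )


def risk_dict(dist: RiskDistribution) -> dict[str, Any]:
    return {
        "cohort": dist.cohort,
        "n_iterations": dist.n_iterations,
        "seed": dist.seed,
        "mean": dist.mean,
        "variance": dist.variance,
        "percentiles": {f"P{int(q)}": v for q, v in dist.percentiles.items()},
        "P95_2dp": round_half_up(dist.percentiles[95.0], 2),
    }


def tornado_frame(reports: Sequence[SensitivityReport]) -> pd.DataFrame:
    rows = []
    for rep in reports:
        for name in rep.ordering:
            rows.append(
                {"cohort": rep.cohort, "input": name,
                 "rho": rep.rho[name], "contribution_pct": rep.contribution_pct[name]}
            )
    return pd.DataFrame(rows)


def meta_block(seed: int | None, config: Mapping[str, Any]) -> dict[str, Any]:
    """Provenance block recorded in every JSON output."""
    from . import __version__

    canon = json.dumps(config, sort_keys=True, default=str)
    return {
        "package": "fluorisk",
        "version": __version__,
        "seed": seed,
        "config_hash": hashlib.sha256(canon.encode()).hexdigest()[:16],
    }


def write_json(payload: Mapping[str, Any], path: str | Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
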