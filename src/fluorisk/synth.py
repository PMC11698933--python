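"""Synthetic study generation: replicates that honor published site summaries.

Field campaigns of this shape report, per sampling site, only min/max/mean/std
of a handful of replicate measurements. To make every downstream stage
(deterministic HQ, Monte Carlo, surrogate training) runnable without raw
data, this module reconstructs replicate vectors that

* attain the target min and max exactly,
* match the target mean to within 0.005 mg/L (in practice exactly, up to
  float rounding), and
* approach the target std as closely as the fixed extremes allow.

The construction fixes the two extremes, places the interior replicates at
the value that balances the mean, then adds a seeded zero-sum perturbation
whose amplitude is solved in closed form to hit the target variance —
capped so no replicate leaves [min, max]. The mean constraint is therefore
never traded away; std is matched approximately (the extremes already spend
three of the few degrees of freedom).

The default 17-site district configuration ships as a packaged CSV and is
the study every example and test runs on.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np

from .errors import GenerationError
from .exposure import AgeGroupParams, DEFAULT_COHORTS, SiteRecord, SiteSummary
from .surrogate import SurrogateDataset, build_dataset

__all__ = [
    "SiteSpec",
    "default_site_specs",
    "generate_site_replicates",
    "generate_study",
    "generate_surrogate_dataset",
]

DEFAULT_N_REPLICATES = 5


@dataclass(frozen=True)
class SiteSpec:
    """Target summary for one site's synthetic replicates (mg/L)."""

    site_id: str
    location_name: str
    min: float
    max: float
    mean: float
    std: float
    n_replicates: int = DEFAULT_N_REPLICATES

    def __post_init__(self) -> None:
        if not (0 <= self.min <= self.mean <= self.max):
            raise GenerationError(
                f"{self.site_id}: need 0 <= min <= mean <= max, got "
                f"({self.min}, {self.mean}, {self.max})"
            )
        if self.std < 0:
            raise GenerationError(f"{self.site_id}: std must be >= 0")
        if self.std > 0 and self.n_replicates < 2:
            raise GenerationError(
                f"{self.site_id}: std > 0 needs at least 2 replicates"
            )
        if self.n_replicates < 1:
            raise GenerationError(f"{self.site_id}: need at least 1 replicate")


def default_site_specs() -> list[SiteSpec]:
    """The packaged 17-site district configuration."""
    import pandas as pd

    with resources.files("fluorisk.data").joinpath("kasganj_sites.csv").open() as fh:
        frame = pd.read_csv(fh)
    return [
        SiteSpec(r.site_id, r.location_name, r.min, r.max, r.mean, r.std)
        for r in frame.itertuples()
    ]


def generate_site_replicates(spec: SiteSpec, seed: int = 0) -> np.ndarray:
    """Replicate concentrations meeting the spec's constraints (sorted)."""
    n = spec.n_replicates
    rng = np.random.default_rng(seed)
    if spec.min == spec.max:
        return np.full(n, spec.mean)
    if n == 2:
        if abs((spec.min + spec.max) / 2 - spec.mean) > 5e-3:
            raise GenerationError(
                f"{spec.site_id}: with 2 replicates the mean is pinned to "
                f"(min+max)/2 = {(spec.min + spec.max) / 2}"
            )
        return np.array([spec.min, spec.max])
    n_int = n - 2
    interior_sum = n * spec.mean - spec.min - spec.max
    if not (n_int * spec.min - 1e-12 <= interior_sum <= n_int * spec.max + 1e-12):
        raise GenerationError(
            f"{spec.site_id}: no {n} values in [{spec.min}, {spec.max}] "
            f"can average {spec.mean}"
        )
    m = interior_sum / n_int
    # Zero-sum seeded direction for the interior perturbation.
    d = rng.standard_normal(n_int)
    d -= d.mean()
    if np.allclose(d, 0):
        d = np.zeros(n_int)
    # Variance is var0 + a^2 * sum(d^2)/(n-1): solve a for the target std.
    base = np.array([spec.min, spec.max] + [m] * n_int)
    var0 = base.var(ddof=1)
    sum_d2 = float((d**2).sum())
    if sum_d2 == 0:
        a = 0.0
    else:
        need = max(spec.std**2 - var0, 0.0) * (n - 1) / sum_d2
        a = float(np.sqrt(need))
        # Cap the amplitude so every interior value stays inside [min, max].
        pos = d > 0
        neg = d < 0
        caps = []
        if pos.any():
            caps.append((spec.max - m) / d[pos].max())
        if neg.any():
            caps.append((spec.min - m) / d[neg].min())
        if caps:
            a = min(a, max(0.0, min(caps)))
    values = np.concatenate(([spec.min, spec.max], m + a * d))
    return np.sort(values)


def generate_study(
    specs: Sequence[SiteSpec] | None = None, seed: int = 0
) -> list[SiteRecord]:
    """Generate replicate-backed :class:`SiteRecord` objects for a study.

    Defaults to the packaged 17-site × 5-replicate district configuration.
    Site summaries are recomputed from the generated replicates, so records
    are internally consistent under any seed.
    """
    if specs is None:
        specs = default_site_specs()
    seeds = np.random.SeedSequence(seed).spawn(len(specs))
    return [
        SiteRecord.from_samples(
            spec.site_id,
            spec.location_name,
            generate_site_replicates(spec, seed=int(ss.generate_state(1)[0] % 2**31)),
        )
        for spec, ss in zip(specs, seeds)
    ]


def generate_surrogate_dataset(
    study: Sequence[SiteRecord],
    cohorts: Sequence[AgeGroupParams] = DEFAULT_COHORTS,
    seed: int = 0,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
) -> SurrogateDataset:
    """Surrogate training table for a generated study (85 rows by default)."""
    return build_dataset(study, cohorts, fractions=fractions, seed=seed)
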