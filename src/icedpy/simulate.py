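"""Synthetic two-timepoint, multi-site, multi-region datasets with known components.

The generator emulates the structure of a large multi-site developmental MRI
cohort: S testing sites (each tied to one scanner manufacturer), R cortical
regions, three structural measures, and two scans roughly two years apart.
Values follow the generative model

    value_t = mu_r + delta_r * 1[t=2] + b_i + s_i * 1[t=2] + e_it

with b_i ~ N(0, sigma_b2[region]), an optional per-subject random change
s_i ~ N(0, slope_sd^2) that emulates individual differences in the rate of
change (which a two-timepoint model cannot separate from error), and
e_it ~ N(0, sigma_e2[site, region] * ratio_t) where ratio_1 = 1 and
ratio_2 = ``error_timepoint_ratio``.  With slope_sd = 0 and ratio = 1 the
population covariance of (T1, T2) is exactly the compound-symmetric matrix
[[sigma_b2 + sigma_e2, sigma_b2], [sigma_b2, sigma_b2 + sigma_e2]].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "SimulationConfig",
    "generate_dataset",
    "assign_scanners",
    "small_config",
    "abcd_like_config",
    "DATASET_COLUMNS",
]

DATASET_COLUMNS = (
    "participant_id",
    "site",
    "scanner",
    "measure",
    "region",
    "value_t1",
    "value_t2",
)

#: default manufacturer mix: 13/3/5 sites out of 21
DEFAULT_SCANNER_BLOCKS: dict[str, int] = {"Siemens": 13, "Philips": 3, "GE": 5}

VarianceMap = Union[float, Mapping]


def _lookup(value: VarianceMap, site: str, region: str, what: str) -> float:
    """Resolve a scalar or a map keyed by (site, region), site, or region."""
    if isinstance(value, Mapping):
        for key in ((site, region), site, region):
            if key in value:
                return float(value[key])
        raise ConfigurationError(f"{what} has no entry for site={site!r}, region={region!r}")
    return float(value)


def _lookup_region(value: VarianceMap, region: str, what: str) -> float:
    if isinstance(value, Mapping):
        if region in value:
            return float(value[region])
        raise ConfigurationError(f"{what} has no entry for region={region!r}")
    return float(value)


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for a synthetic multi-site two-timepoint dataset.

    ``sigma_b2`` may be a scalar or a map region -> variance; ``sigma_e2`` a
    scalar or a map keyed by (site, region), site, or region.  All variances
    are in squared measure units.
    """

    n_sites: int = 5
    n_per_site: Union[int, Sequence[int]] = 400
    regions: Sequence[str] = tuple(f"region{i:02d}" for i in range(1, 9))
    measures: Sequence[str] = ("thickness", "area", "volume")
    sigma_b2: VarianceMap = 1.0
    sigma_e2: VarianceMap = 1.0
    grand_mean: VarianceMap = 0.0
    mean_change: VarianceMap = 0.0
    slope_sd: float = 0.0
    error_timepoint_ratio: float = 1.0
    scanner_blocks: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SCANNER_BLOCKS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ConfigurationError("n_sites must be >= 1")
        for n in self.per_site_counts():
            if n < 2:
                raise ConfigurationError("n_per_site must be >= 2")
        if self.slope_sd < 0:
            raise ConfigurationError("slope_sd must be >= 0")
        if self.error_timepoint_ratio <= 0:
            raise ConfigurationError("error_timepoint_ratio must be > 0")
        if not self.regions:
            raise ConfigurationError("regions must be non-empty")
        if not self.measures:
            raise ConfigurationError("measures must be non-empty")
        for name, value, allow_zero in (
            ("sigma_b2", self.sigma_b2, True),
            ("sigma_e2", self.sigma_e2, True),
        ):
            vals = value.values() if isinstance(value, Mapping) else [value]
            for v in vals:
                if float(v) < 0:
                    raise ConfigurationError(f"{name} must be non-negative, got {v}")

    def per_site_counts(self) -> list[int]:
        if isinstance(self.n_per_site, (int, np.integer)):
            return [self.n_per_site] * self.n_sites
        counts = list(self.n_per_site)
        if len(counts) != self.n_sites:
            raise ConfigurationError(
                f"n_per_site list length {len(counts)} != n_sites {self.n_sites}"
            )
        return counts

    def site_labels(self) -> list[str]:
        return [f"site{i:02d}" for i in range(1, self.n_sites + 1)]


def assign_scanners(
    site_labels: Sequence[str],
    blocks: Mapping[str, int] = None,
) -> dict[str, str]:
    """Map each site to one scanner manufacturer in contiguous blocks.

    Block sizes are scaled proportionally (largest-remainder rounding) when the
    number of sites differs from the block total, so the default 13/3/5 mix is
    preserved approximately at any scale.
    """
    blocks = dict(blocks or DEFAULT_SCANNER_BLOCKS)
    n = len(site_labels)
    total = sum(blocks.values())
    if total <= 0:
        raise ConfigurationError("scanner blocks must sum to a positive count")
    exact = {k: v * n / total for k, v in blocks.items()}
    counts = {k: int(np.floor(x)) for k, x in exact.items()}
    shortfall = n - sum(counts.values())
    for k in sorted(exact, key=lambda k: exact[k] - counts[k], reverse=True)[:shortfall]:
        counts[k] += 1
    mapping: dict[str, str] = {}
    i = 0
    for manufacturer, c in counts.items():
        for site in site_labels[i : i + c]:
            mapping[site] = manufacturer
        i += c
    return mapping


def generate_dataset(config: SimulationConfig) -> pd.DataFrame:
    """Simulate a tidy dataset: one row per participant x measure x region.

    Output columns are exactly ``DATASET_COLUMNS``; with a fixed seed the
    output is bit-identical across runs.  Random effects are drawn
    independently per (participant, measure, region).
    """
    rng = np.random.default_rng(config.seed)
    sites = config.site_labels()
    counts = config.per_site_counts()
    scanner_of = assign_scanners(sites, config.scanner_blocks)

    frames = []
    pid_offset = 0
    for site, n_s in zip(sites, counts):
        ids = np.array([f"sub{pid_offset + j:06d}" for j in range(n_s)])
        pid_offset += n_s
        for measure in config.measures:
            for region in config.regions:
                mu = _lookup_region(config.grand_mean, region, "grand_mean")
                delta = _lookup_region(config.mean_change, region, "mean_change")
                sb2 = _lookup_region(config.sigma_b2, region, "sigma_b2")
                se2 = _lookup(config.sigma_e2, site, region, "sigma_e2")
                b = rng.normal(0.0, np.sqrt(sb2), n_s)
                e1 = rng.normal(0.0, np.sqrt(se2), n_s)
                e2 = rng.normal(
                    0.0, np.sqrt(se2 * config.error_timepoint_ratio), n_s
                )
                if config.slope_sd > 0:
                    s = rng.normal(0.0, config.slope_sd, n_s)
                else:
                    s = 0.0
                frames.append(
                    pd.DataFrame(
                        {
                            "participant_id": ids,
                            "site": site,
                            "scanner": scanner_of[site],
                            "measure": measure,
                            "region": region,
                            "value_t1": mu + b + e1,
                            "value_t2": mu + delta + b + s + e2,
                        }
                    )
                )
    out = pd.concat(frames, ignore_index=True)
    return out[list(DATASET_COLUMNS)]


def small_config(**overrides) -> SimulationConfig:
    """Desk-scale profile: 5 sites x 400 participants, 8 regions, 3 measures."""
    base = SimulationConfig()
    return replace(base, **overrides) if overrides else base


def abcd_like_config(**overrides) -> SimulationConfig:
    """ABCD-scale profile: 21 sites x ~350 participants, 68 cortical regions."""
    base = SimulationConfig(
        n_sites=21,
        n_per_site=350,
        regions=tuple(
            f"{hemi}_region{i:02d}" for hemi in ("lh", "rh") for i in range(1, 35)
        ),
    )
    return replace(base, **overrides) if overrides else base
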