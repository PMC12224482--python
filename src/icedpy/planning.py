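"""Decision-study calculators: timepoints needed, attenuation, and power.

These translate fitted variance components into study-design answers:

* How many repeated measurements N are needed so that the construct-level
  reliability ICC2 = sigma_b2 / (sigma_b2 + sigma_e2 / N) exceeds a target?
  Rearranging gives the strict bound N > (target / (1 - target)) * sigma_e2 / sigma_b2.
* How attenuated is an observed correlation under imperfect reliability?
  Spearman: r_observed = r_true * sqrt(rel_x) * sqrt(rel_y).
* What sample size detects an (attenuated) correlation at given power and
  alpha?  Fisher z: sqrt(n - 3) * atanh(r) = z_{1-alpha/2} + z_{power}.

Sample sizes report the integer part of the Fisher-z solution by default; a
conservative ``ceil`` mode is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd
from scipy import stats

from .core import VarianceComponents
from .errors import ConfigurationError

__all__ = [
    "DesignQuery",
    "AttenuationQuery",
    "required_timepoints",
    "attenuated_correlation",
    "sample_size_for_correlation",
    "attenuation_power_report",
]


@dataclass(frozen=True)
class DesignQuery:
    """Either a single-measure ICC or an explicit component pair, plus a target ICC2."""

    icc: Optional[float] = None
    sigma_b2: Optional[float] = None
    sigma_e2: Optional[float] = None
    target_icc2: float = 0.9

    def __post_init__(self) -> None:
        has_icc = self.icc is not None
        has_pair = self.sigma_b2 is not None and self.sigma_e2 is not None
        if has_icc == has_pair:
            raise ConfigurationError(
                "supply exactly one of icc or (sigma_b2, sigma_e2)"
            )
        if has_icc and not 0 < self.icc <= 1:
            raise ConfigurationError("icc must be in (0, 1]")
        if has_pair and (self.sigma_b2 < 0 or self.sigma_e2 < 0):
            raise ConfigurationError("variance components must be non-negative")
        if not 0 < self.target_icc2 < 1:
            raise ConfigurationError("target_icc2 must be in (0, 1)")

    def error_to_between_ratio(self) -> float:
        """sigma_e2 / sigma_b2; from an ICC this is (1 - ICC) / ICC."""
        if self.icc is not None:
            return (1.0 - self.icc) / self.icc
        if self.sigma_b2 == 0:
            return math.inf
        return self.sigma_e2 / self.sigma_b2


@dataclass(frozen=True)
class AttenuationQuery:
    r_true: float
    rel_x: float
    rel_y: float
    power: float = 0.80
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not -1 < self.r_true < 1:
            raise ConfigurationError("r_true must be in (-1, 1)")
        for name, rel in (("rel_x", self.rel_x), ("rel_y", self.rel_y)):
            if not 0 < rel <= 1:
                raise ConfigurationError(f"{name} must be in (0, 1]")
        if not 0 < self.power < 1:
            raise ConfigurationError("power must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")


def required_timepoints(query: DesignQuery) -> float:
    """Smallest integer N with N strictly greater than (t/(1-t)) * sigma_e2/sigma_b2.

    For the default target of .9 the bound is N > 9 * sigma_e2 / sigma_b2.
    Error-free measures need a single timepoint; a measure with no
    between-subjects variance can never reach the target (returns ``inf``).
    """
    ratio = query.error_to_between_ratio()
    if math.isinf(ratio):
        return math.inf
    t = query.target_icc2
    bound = (t / (1.0 - t)) * ratio
    nearest = round(bound)
    if abs(bound - nearest) < 1e-9 * max(1.0, abs(bound)):
        bound = float(nearest)  # guard float noise at exact-integer bounds
    n = int(math.floor(bound)) + 1  # strict inequality: equality forces one more
    return max(n, 1)


def attenuated_correlation(r_true: float, rel_x: float, rel_y: float) -> float:
    """Spearman attenuation: r_observed = r_true * sqrt(rel_x) * sqrt(rel_y)."""
    q = AttenuationQuery(r_true=r_true, rel_x=rel_x, rel_y=rel_y)
    return q.r_true * math.sqrt(q.rel_x) * math.sqrt(q.rel_y)


def sample_size_for_correlation(
    r: float,
    power: float = 0.80,
    alpha: float = 0.05,
    rounding: str = "floor",
) -> float:
    """Sample size for a two-sided test of a Pearson correlation (Fisher z).

    Solves sqrt(n - 3) * atanh(|r|) = z_{1-alpha/2} + z_{power} and reports
    the integer part of n (``rounding="ceil"`` for the conservative choice).
    r = 0 is undetectable and returns ``inf``.
    """
    if not -1 < r < 1:
        raise ConfigurationError("r must be in (-1, 1)")
    if not 0 < power < 1 or not 0 < alpha < 1:
        raise ConfigurationError("power and alpha must be in (0, 1)")
    if r == 0:
        return math.inf
    z = stats.norm.ppf(1 - alpha / 2) + stats.norm.ppf(power)
    n = 3.0 + (z / math.atanh(abs(r))) ** 2
    if rounding == "floor":
        n_int = int(math.floor(n))
    elif rounding == "ceil":
        n_int = int(math.ceil(n))
    else:
        raise ConfigurationError("rounding must be 'floor' or 'ceil'")
    return max(n_int, 4)


def attenuation_power_report(
    queries: Sequence[AttenuationQuery],
    labels: Optional[Sequence[str]] = None,
    rounding: str = "floor",
    r_decimals: Optional[int] = 2,
) -> pd.DataFrame:
    """Per-region attenuated correlations, required n, and percent extra participants.

    Attenuated correlations are rounded to ``r_decimals`` places before the
    power step — the usual reporting convention for correlation-based power
    figures (pass ``None`` for full precision).  ``pct_extra`` is relative to
    the least demanding region (smallest n), so the best region reads 0%.
    """
    if not queries:
        raise ConfigurationError("need at least one query")
    if labels is None:
        labels = [f"query{i + 1}" for i in range(len(queries))]
    if len(labels) != len(queries):
        raise ConfigurationError("labels and queries must have equal length")
    rows = []
    for label, q in zip(labels, queries):
        r_obs = attenuated_correlation(q.r_true, q.rel_x, q.rel_y)
        r_pow = round(r_obs, r_decimals) if r_decimals is not None else r_obs
        n = sample_size_for_correlation(r_pow, q.power, q.alpha, rounding=rounding)
        rows.append({
            "label": label, "r_true": q.r_true,
            "rel_x": q.rel_x, "rel_y": q.rel_y,
            "r_observed": r_obs, "n_required": n,
        })
    table = pd.DataFrame(rows)
    n_best = table["n_required"].min()
    table["pct_extra"] = (table["n_required"] / n_best - 1.0) * 100.0
    return table


def components_to_query(
    vc: VarianceComponents, target_icc2: float = 0.9
) -> DesignQuery:
    """Convenience: build a DesignQuery from fitted variance components."""
    return DesignQuery(
        sigma_b2=vc.sigma_b2, sigma_e2=vc.sigma_e2, target_icc2=target_icc2
    )
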