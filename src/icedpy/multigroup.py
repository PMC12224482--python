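"""Multigroup ICED models across sites (or scanner manufacturers).

Four nested models localise where stability differs between groups:

1. ``constrained``      — sigma_b2 and sigma_e2 equal across groups (p = 2)
2. ``b_varying``        — sigma_b2 free per group, sigma_e2 shared (p = G + 1)
3. ``e_varying``        — sigma_e2 free per group, sigma_b2 shared (p = G + 1)
4. ``unconstrained``    — both free per group (p = 2G)

Each group contributes 3 observed moments (two variances, one covariance), so
df = 3G - p.  The error variances at the two occasions are always equal
within a group.  The total discrepancy sum_g (n_g - 1) F_g is minimized
jointly; the CFI baseline is the sum of per-group independence models
(df = G).  Five delta-CFI comparisons (A-E), oriented toward the less
constrained model, diagnose whether group differences live in the
between-subjects or the error component:

    A constrained -> b_varying        C constrained -> e_varying
    B b_varying  -> unconstrained     D e_varying  -> unconstrained
    E constrained -> unconstrained
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .core import (
    CovarianceSummary,
    FitIndices,
    ModelSpec,
    VarianceComponents,
    compute_cfi,
    fit_iced,
    summarize_two_timepoint,
)
from .errors import InsufficientDataError

__all__ = [
    "MULTIGROUP_MODELS",
    "COMPARISONS",
    "MultigroupFit",
    "ComparisonResult",
    "ComparisonGrid",
    "fit_multigroup",
    "model_comparison_series",
    "comparison_grid",
]

logger = logging.getLogger(__name__)

MULTIGROUP_MODELS = ("constrained", "b_varying", "e_varying", "unconstrained")
COMPARISONS = ("A", "B", "C", "D", "E")

# comparison -> (less constrained, more constrained)
_COMPARISON_PAIRS = {
    "A": ("b_varying", "constrained"),
    "B": ("unconstrained", "b_varying"),
    "C": ("e_varying", "constrained"),
    "D": ("unconstrained", "e_varying"),
    "E": ("unconstrained", "constrained"),
}


@dataclass
class MultigroupFit:
    model_id: str
    per_group: dict[str, VarianceComponents]
    indices: FitIndices
    n_groups: int
    groups: list[str]
    excluded: list[str] = field(default_factory=list)
    converged: bool = True

    @property
    def chisq(self) -> float:
        return self.indices.chisq

    @property
    def df(self) -> int:
        return self.indices.df

    @property
    def cfi(self) -> float:
        return self.indices.cfi


@dataclass
class ComparisonResult:
    delta_cfi: dict[str, Optional[float]]
    flags: dict[str, Optional[bool]]
    cfis: dict[str, float]
    threshold: float
    groups: list[str]


@dataclass
class ComparisonGrid:
    table: pd.DataFrame
    flag_fractions: dict[str, float]
    threshold: float


def _group_summaries(
    dataset_slice: pd.DataFrame, grouping: str, min_n: int = 3
) -> tuple[dict[str, CovarianceSummary], list[str]]:
    summaries: dict[str, CovarianceSummary] = {}
    excluded: list[str] = []
    for label, sub in dataset_slice.groupby(grouping, sort=True, observed=True):
        if len(sub) < min_n:
            excluded.append(str(label))
            continue
        summaries[str(label)] = summarize_two_timepoint(sub)
    if excluded:
        warnings.warn(
            f"excluded groups below n={min_n}: {excluded}", stacklevel=2
        )
    if not summaries:
        raise InsufficientDataError("no group has enough complete cases")
    return summaries, excluded


def _weighted_objective(summaries: Sequence[CovarianceSummary]):
    """Build joint discrepancy sum_g w_g F_g and its gradient factory."""
    mats = [s.matrix() for s in summaries]
    ws = np.array([s.n - 1 for s in summaries], dtype=float)
    logdets = [float(np.linalg.slogdet(m)[1]) for m in mats]

    def total_f(thetas: np.ndarray) -> float:
        # thetas: (G, 2) array of (sigma_b2, sigma_e2) per group
        acc = 0.0
        for (b, e), S, w, ld in zip(thetas, mats, ws, logdets):
            sigma = np.array([[b + e, b], [b, b + e]])
            sign, logdet = np.linalg.slogdet(sigma)
            if sign <= 0:
                return 1e12
            inv = np.linalg.inv(sigma)
            acc += w * (logdet + (S * inv).sum() - ld - 2.0)
        return acc

    def group_grads(thetas: np.ndarray) -> np.ndarray:
        # rows of (dF/db, dF/de) * w_g per group
        out = np.zeros((len(mats), 2))
        for g, ((b, e), S, w) in enumerate(zip(thetas, mats, ws)):
            sigma = np.array([[b + e, b], [b, b + e]])
            sign, _ = np.linalg.slogdet(sigma)
            if sign <= 0:
                continue
            inv = np.linalg.inv(sigma)
            m = inv - inv @ S @ inv
            out[g] = w * np.array([m.sum(), np.trace(m)])
        return out

    return total_f, group_grads, ws


def _expand(model_id: str, params: np.ndarray, G: int) -> np.ndarray:
    """Map the model's free-parameter vector to per-group (b, e) rows."""
    if model_id == "constrained":
        return np.tile(params, (G, 1))
    if model_id == "b_varying":
        return np.column_stack([params[:G], np.full(G, params[G])])
    if model_id == "e_varying":
        return np.column_stack([np.full(G, params[0]), params[1:]])
    raise ValueError(f"unknown model_id {model_id!r}")


def _collapse_grad(model_id: str, grads: np.ndarray, G: int) -> np.ndarray:
    if model_id == "constrained":
        return grads.sum(axis=0)
    if model_id == "b_varying":
        return np.concatenate([grads[:, 0], [grads[:, 1].sum()]])
    if model_id == "e_varying":
        return np.concatenate([[grads[:, 0].sum()], grads[:, 1]])
    raise ValueError(f"unknown model_id {model_id!r}")


def _starting_values(model_id: str, summaries: Sequence[CovarianceSummary]) -> np.ndarray:
    ws = np.array([s.n - 1 for s in summaries], dtype=float)
    bs = np.array([s.s12 for s in summaries])
    es = np.array([s.mean_variance - s.s12 for s in summaries])
    b_pool = float(np.average(bs, weights=ws))
    e_pool = float(np.average(es, weights=ws))
    if model_id == "constrained":
        return np.array([b_pool, e_pool])
    if model_id == "b_varying":
        return np.concatenate([bs, [e_pool]])
    if model_id == "e_varying":
        return np.concatenate([[b_pool], es])
    raise ValueError(f"unknown model_id {model_id!r}")


def _multigroup_baseline(summaries: dict[str, CovarianceSummary]) -> FitIndices:
    chisq = 0.0
    for s in summaries.values():
        r2 = s.correlation**2
        chisq += (s.n - 1) * (float("inf") if r2 >= 1 else -math.log1p(-r2))
    return FitIndices(loglik=float("nan"), chisq=chisq, df=len(summaries))


def fit_multigroup(
    dataset_slice: pd.DataFrame,
    grouping: str,
    model_id: str,
    min_n: int = 3,
) -> MultigroupFit:
    """Fit one of the four multigroup models to a single measure x region slice.

    Groups are the distinct values of ``grouping`` (e.g. ``site`` or
    ``scanner``); groups below ``min_n`` complete cases are excluded with a
    warning.  The unconstrained model factorizes into independent per-group
    equal-error ICED fits.
    """
    if model_id not in MULTIGROUP_MODELS:
        raise ValueError(f"model_id must be one of {MULTIGROUP_MODELS}")
    summaries, excluded = _group_summaries(dataset_slice, grouping, min_n)
    labels = sorted(summaries)
    ordered = [summaries[g] for g in labels]
    G = len(labels)

    if model_id == "unconstrained":
        chisq = 0.0
        per_group = {}
        converged = True
        for g, s in zip(labels, ordered):
            f = fit_iced(s, ModelSpec(constrained_error=True), ci=False)
            per_group[g] = f.components
            chisq += f.indices.chisq
            converged &= f.status in ("ok", "degenerate")
        indices = FitIndices(loglik=float("nan"), chisq=chisq, df=G)
    else:
        total_f, group_grads, ws = _weighted_objective(ordered)
        w_total = float(ws.sum())  # scale so gradients are O(1) regardless of n

        def fun(params):
            return total_f(_expand(model_id, params, G)) / w_total

        def jac(params):
            thetas = _expand(model_id, params, G)
            return _collapse_grad(model_id, group_grads(thetas), G) / w_total

        x0 = _starting_values(model_id, ordered)
        res = optimize.minimize(
            fun, x0, jac=jac, method="BFGS",
            options={"gtol": 1e-10, "maxiter": 1000},
        )
        params, fmin = res.x, float(res.fun)
        converged = bool(np.linalg.norm(jac(params)) < 1e-7)
        if not converged:
            res2 = optimize.minimize(
                fun, params, method="Nelder-Mead",
                options={"xatol": 1e-12, "fatol": 1e-15, "maxiter": 5000},
            )
            if res2.fun <= fmin:
                params, fmin = res2.x, float(res2.fun)
            converged = bool(np.linalg.norm(jac(params)) < 1e-6)
        fmin *= w_total
        thetas = _expand(model_id, params, G)
        per_group = {
            g: VarianceComponents(sigma_b2=float(b), sigma_e2=float(e))
            for g, (b, e) in zip(labels, thetas)
        }
        p = {"constrained": 2, "b_varying": G + 1, "e_varying": G + 1}[model_id]
        indices = FitIndices(
            loglik=float("nan"), chisq=max(0.0, fmin), df=3 * G - p
        )
    indices.cfi = compute_cfi(indices, _multigroup_baseline(summaries))
    return MultigroupFit(
        model_id=model_id,
        per_group=per_group,
        indices=indices,
        n_groups=G,
        groups=labels,
        excluded=excluded,
        converged=converged,
    )


def model_comparison_series(
    dataset_slice: pd.DataFrame,
    grouping: str,
    threshold: float = 0.02,
    min_n: int = 3,
) -> ComparisonResult:
    """Fit all four multigroup models and compute the five delta-CFI comparisons.

    delta-CFI is oriented toward the less constrained model; values above
    ``threshold`` flag a meaningful fit difference.  A non-convergent member
    renders its comparisons unavailable (None) while the rest are reported.
    """
    fits = {
        m: fit_multigroup(dataset_slice, grouping, m, min_n=min_n)
        for m in MULTIGROUP_MODELS
    }
    cfis = {m: f.cfi for m, f in fits.items()}
    delta: dict[str, Optional[float]] = {}
    flags: dict[str, Optional[bool]] = {}
    for comp, (less, more) in _COMPARISON_PAIRS.items():
        if fits[less].converged and fits[more].converged:
            d = cfis[less] - cfis[more]
            delta[comp] = d
            flags[comp] = d > threshold
        else:
            delta[comp] = None
            flags[comp] = None
    return ComparisonResult(
        delta_cfi=delta,
        flags=flags,
        cfis=cfis,
        threshold=threshold,
        groups=fits["constrained"].groups,
    )


def comparison_grid(
    dataset: pd.DataFrame,
    grouping: str,
    threshold: float = 0.02,
    min_n: int = 3,
) -> ComparisonGrid:
    """Run the five-comparison series for every measure x region in the dataset.

    Per-cell failures are logged and skipped; the grid always completes.  The
    summary reports, per comparison, the fraction of fitted cells whose
    delta-CFI exceeded the threshold.
    """
    rows = []
    measures = sorted(dataset["measure"].unique())
    for measure in measures:
        dm = dataset[dataset["measure"] == measure]
        for region in sorted(dm["region"].unique()):
            cell = dm[dm["region"] == region]
            try:
                res = model_comparison_series(
                    cell, grouping, threshold=threshold, min_n=min_n
                )
            except Exception as exc:  # noqa: BLE001 - batch must complete
                logger.warning(
                    "comparison failed for measure=%s region=%s: %s",
                    measure, region, exc,
                )
                continue
            row = {"measure": measure, "region": region}
            for comp in COMPARISONS:
                row[f"delta_cfi_{comp}"] = res.delta_cfi[comp]
                row[f"flag_{comp}"] = res.flags[comp]
            rows.append(row)
    columns = ["measure", "region"] + [
        f"{kind}_{comp}" for comp in COMPARISONS for kind in ("delta_cfi", "flag")
    ]
    table = pd.DataFrame(rows, columns=columns if not rows else None)
    fractions = {}
    for comp in COMPARISONS:
        col = f"flag_{comp}"
        if len(table) and col in table:
            valid = table[col].dropna()
            fractions[comp] = float(valid.mean()) if len(valid) else float("nan")
        else:
            fractions[comp] = float("nan")
    return ComparisonGrid(table=table, flag_fractions=fractions, threshold=threshold)
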