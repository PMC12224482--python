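"""Batch ICED fits across measures, regions, and groups; map-level summaries.

Produces the long "stability table" (one fitted model per measure x region x
group), per-measure mean/range summaries, a dispersion decomposition that
asks whether estimate heterogeneity lives on the region axis or the site
axis, Shrout-Fleiss rank-order ICCs of the resulting estimate maps, and
lobe-level aggregation of region tables.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import ModelSpec, fit_iced, summarize_two_timepoint
from .errors import ConfigurationError, InsufficientDataError

__all__ = [
    "STABILITY_COLUMNS",
    "fit_region_map",
    "summarize_map",
    "AxisDispersion",
    "DispersionReport",
    "dispersion_decomposition",
    "build_estimate_matrix",
    "rank_order_stability",
    "aggregate_lobes",
    "load_lobe_mapping",
    "apply_rescaling",
    "split_holdout",
]

logger = logging.getLogger(__name__)

STABILITY_COLUMNS = (
    "measure", "region", "group", "n",
    "sigma_b2", "sigma_e2", "icc", "icc2",
    "ci_low", "ci_high", "chisq", "df", "cfi", "status",
)

#: measures aggregated by averaging (everything else is summed) at lobe level
MEAN_AGGREGATED_MEASURES = ("thickness",)


def apply_rescaling(
    dataset: pd.DataFrame,
    measures: Sequence[str] = ("area", "volume"),
    constant: float = 0.001,
) -> pd.DataFrame:
    """Multiply selected measures by a constant so variances are comparable.

    Surface area and volume live on much larger numeric scales than cortical
    thickness; rescaling by an arbitrary constant (default .001) equalizes the
    scales without affecting ICC, ICC2, chi-square, or CFI (the model is scale
    equivariant).
    """
    if constant <= 0:
        raise ConfigurationError("rescale constant must be > 0")
    out = dataset.copy()
    mask = out["measure"].isin(measures)
    out.loc[mask, ["value_t1", "value_t2"]] *= constant
    return out


def split_holdout(
    dataset: pd.DataFrame, n_holdout: int, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Withhold a random exploratory subset of participants.

    Returns (analysis, holdout) frames; the holdout can be used for model
    tuning while final fits run on the remainder.
    """
    participants = np.sort(dataset["participant_id"].unique())
    if n_holdout < 0 or n_holdout >= len(participants):
        raise ConfigurationError(
            f"n_holdout must be in [0, {len(participants)})"
        )
    rng = np.random.default_rng(seed)
    held = set(rng.choice(participants, size=n_holdout, replace=False))
    mask = dataset["participant_id"].isin(held)
    return dataset[~mask].copy(), dataset[mask].copy()


def _fit_row(cell: pd.DataFrame, measure: str, region: str, group: str,
             constrained: bool, ci: bool, ci_level: float) -> dict:
    row = {
        "measure": measure, "region": region, "group": group, "n": len(cell),
        "sigma_b2": np.nan, "sigma_e2": np.nan, "icc": np.nan, "icc2": np.nan,
        "ci_low": np.nan, "ci_high": np.nan,
        "chisq": np.nan, "df": np.nan, "cfi": np.nan, "status": "ok",
    }
    try:
        summary = summarize_two_timepoint(cell)
    except InsufficientDataError:
        row["status"] = "insufficient_data"
        return row
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_iced(
            summary, ModelSpec(constrained_error=constrained),
            ci=ci, ci_level=ci_level,
        )
    row.update(
        sigma_b2=fit.components.sigma_b2,
        sigma_e2=fit.components.sigma_e2,
        icc=fit.icc, icc2=fit.icc2,
        chisq=fit.indices.chisq, df=fit.indices.df, cfi=fit.indices.cfi,
        status=fit.status,
    )
    if fit.icc_ci is not None:
        row.update(ci_low=fit.icc_ci.low, ci_high=fit.icc_ci.high)
    return row


def fit_region_map(
    dataset: pd.DataFrame,
    measure: Optional[str] = None,
    grouping: str = "pooled",
    constrained: bool = True,
    ci: bool = True,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Fit the ICED model for every measure x region x group combination.

    ``grouping`` is ``"pooled"`` (one fit per region over everyone) or a
    column name such as ``"site"`` or ``"scanner"``.  Per-slice failures are
    downgraded to status codes so the batch always completes.
    """
    measures = [measure] if measure is not None else sorted(dataset["measure"].unique())
    rows = []
    for m in measures:
        dm = dataset[dataset["measure"] == m]
        if dm.empty:
            raise ConfigurationError(f"measure {m!r} not present in dataset")
        for region in sorted(dm["region"].unique()):
            cell = dm[dm["region"] == region]
            if grouping == "pooled":
                groups = [("pooled", cell)]
            else:
                groups = [
                    (str(g), sub)
                    for g, sub in cell.groupby(grouping, sort=True, observed=True)
                ]
            for gname, sub in groups:
                rows.append(
                    _fit_row(sub, m, region, gname, constrained, ci, ci_level)
                )
    return pd.DataFrame(rows, columns=list(STABILITY_COLUMNS))


def summarize_map(table: pd.DataFrame) -> pd.DataFrame:
    """Per-measure mean and range of ICC and ICC2 over successfully fitted rows."""
    rows = []
    for measure, sub in table.groupby("measure", sort=True):
        ok = sub[sub["status"] == "ok"]
        if ok.empty:
            warnings.warn(f"no successful fits for measure {measure!r}", stacklevel=2)
            continue
        rows.append({
            "measure": measure,
            "n_fits": len(ok),
            "icc_mean": ok["icc"].mean(),
            "icc_min": ok["icc"].min(),
            "icc_max": ok["icc"].max(),
            "icc2_mean": ok["icc2"].mean(),
            "icc2_min": ok["icc2"].min(),
            "icc2_max": ok["icc2"].max(),
        })
    return pd.DataFrame(rows)


@dataclass
class AxisDispersion:
    """Spread of median component estimates along one axis of the map."""

    var_between: float
    var_error: float

    @property
    def ratio_between_over_error(self) -> float:
        return self.var_between / self.var_error if self.var_error > 0 else float("nan")

    @property
    def ratio_error_over_between(self) -> float:
        return self.var_error / self.var_between if self.var_between > 0 else float("nan")


@dataclass
class DispersionReport:
    by_region: AxisDispersion
    by_site: AxisDispersion


def dispersion_decomposition(table: pd.DataFrame) -> DispersionReport:
    """Quantify whether estimate heterogeneity is region-driven or site-driven.

    From a site-grouped stability table: take per-region medians (over sites)
    of sigma_b2 and sigma_e2 and compute their variances across regions; then
    per-site medians (over regions) and their variances across sites.  A large
    between-over-error ratio on the region axis means regions differ mostly in
    true between-subjects variance; a large error-over-between ratio on the
    site axis means sites differ mostly in measurement error.
    """
    ok = table[table["status"] == "ok"]
    if ok["region"].nunique() < 2 or ok["group"].nunique() < 2:
        raise InsufficientDataError(
            "dispersion decomposition needs >= 2 regions and >= 2 groups"
        )

    def axis(by: str) -> AxisDispersion:
        med = ok.groupby(by)[["sigma_b2", "sigma_e2"]].median()
        return AxisDispersion(
            var_between=float(med["sigma_b2"].var(ddof=1)),
            var_error=float(med["sigma_e2"].var(ddof=1)),
        )

    return DispersionReport(by_region=axis("region"), by_site=axis("group"))


def build_estimate_matrix(
    table: pd.DataFrame,
    estimate: str = "icc",
    targets: str = "region",
) -> pd.DataFrame:
    """Pivot a stability table into a targets x raters estimate matrix.

    ``targets="region"`` puts regions in rows and groups (sites) in columns —
    "how stable are regional estimates across sites?"; ``targets="group"``
    transposes the question.  Incomplete rows are deleted with a logged count.
    """
    if targets not in ("region", "group"):
        raise ValueError("targets must be 'region' or 'group'")
    raters = "group" if targets == "region" else "region"
    ok = table[table["status"] == "ok"]
    matrix = ok.pivot_table(index=targets, columns=raters, values=estimate,
                            aggfunc="first")
    complete = matrix.dropna()
    dropped = len(matrix) - len(complete)
    if dropped:
        logger.warning("dropped %d incomplete rows from estimate matrix", dropped)
    return complete


def rank_order_stability(matrix) -> tuple[float, float]:
    """Shrout-Fleiss single-rater ICCs of an estimate matrix: (ICC(2,1), ICC(3,1)).

    Rows are targets, columns raters.  From two-way ANOVA mean squares
    (BMS between targets, JMS between raters, EMS residual):

        ICC(3,1) = (BMS - EMS) / (BMS + (k-1) EMS)                 consistency
        ICC(2,1) = (BMS - EMS) / (BMS + (k-1) EMS + k(JMS-EMS)/n)  absolute

    ICC(3,1) ignores systematic rater offsets; ICC(2,1) penalizes them.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("matrix must be 2-dimensional")
    if np.isnan(x).any():
        keep = ~np.isnan(x).any(axis=1)
        logger.warning("dropping %d rows with missing cells", int((~keep).sum()))
        x = x[keep]
    n, k = x.shape
    if n < 2 or k < 2:
        raise InsufficientDataError("need >= 2 targets and >= 2 raters")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    bms = k * ((row_means - grand) ** 2).sum() / (n - 1)
    jms = n * ((col_means - grand) ** 2).sum() / (k - 1)
    ss_total = ((x - grand) ** 2).sum()
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ems = (ss_total - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    if bms <= 0:
        return float("nan"), float("nan")
    icc31 = (bms - ems) / (bms + (k - 1) * ems)
    icc21 = (bms - ems) / (bms + (k - 1) * ems + k * (jms - ems) / n)
    return float(icc21), float(icc31)


def load_lobe_mapping(path=None) -> dict[str, str]:
    """Load a region -> lobe mapping from YAML (default: bundled 5-lobe grouping).

    The bundled file maps the 34 standard cortical parcellation labels per
    hemisphere (``lh_``/``rh_`` prefixes) to five lobes per hemisphere; it is
    editable data, not code.
    """
    if path is None:
        text = (resources.files("icedpy") / "data" / "dk_lobes.yaml").read_text()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    mapping: dict[str, str] = {}
    for hemi in ("lh", "rh"):
        for lobe, regions in raw["lobes"].items():
            for region in regions:
                mapping[f"{hemi}_{region}"] = f"{hemi}_{lobe}"
    return mapping


def aggregate_lobes(
    dataset: pd.DataFrame,
    mapping: Mapping[str, str],
    mean_measures: Sequence[str] = MEAN_AGGREGATED_MEASURES,
) -> pd.DataFrame:
    """Aggregate a region-level dataset to lobe resolution.

    Thickness-like measures (``mean_measures``) are averaged (unweighted) over
    member regions; everything else (area, volume) is summed, per participant
    per timepoint.  Hemispheres stay separate through the mapping labels.
    Regions absent from the mapping are rejected with the offending labels.
    """
    present = set(dataset["region"].unique())
    unmapped = sorted(present - set(mapping))
    if unmapped:
        raise ConfigurationError(f"regions missing from lobe mapping: {unmapped}")
    out = dataset.copy()
    out["region"] = out["region"].map(mapping)
    keys = ["participant_id", "site", "scanner", "measure", "region"]
    parts = []
    for how, rows in (
        ("mean", out[out["measure"].isin(mean_measures)]),
        ("sum", out[~out["measure"].isin(mean_measures)]),
    ):
        if rows.empty:
            continue
        agg = rows.groupby(keys, sort=True, observed=True)[
            ["value_t1", "value_t2"]
        ].agg(how).reset_index()
        parts.append(agg)
    result = pd.concat(parts, ignore_index=True)
    return result.sort_values(keys, ignore_index=True)[list(dataset.columns)]
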