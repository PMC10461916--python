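"""Relative growth rates from selection sequencing count trajectories.

Each mutant's log2 frequency relative to WT, anchored at t=0, is fit by a
count-weighted linear regression over the selection timepoints; the slope,
scaled by the bulk (turbidostat) growth rate, gives a WT-relative growth
rate.  Mutants that drop out of the counts within the first three
timepoints are classified as Null and carry no rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.linear_model import LinearRegression

from .counts import CountTable

__all__ = [
    "FrequencyTrace",
    "threshold_counts",
    "frequency_trace",
    "fit_relative_growth",
    "normalize_growth",
    "aggregate_replicates",
    "infer_growth_rates",
    "RelativeGrowthEstimator",
]


@dataclass
class FrequencyTrace:
    """log2 relative-frequency trajectory of one mutant in one replicate.

    f(t) = log2(N_t^mut / N_t^WT) - log2(N_0^mut / N_0^WT); timepoints
    where the (thresholded) mutant count is zero are excluded, not
    imputed.  ``weights`` are the mutant's own counts at the retained
    timepoints.
    """

    mutant: str
    times: np.ndarray
    f: np.ndarray
    weights: np.ndarray
    null: bool


def threshold_counts(table: CountTable, min_count: int = 10) -> CountTable:
    """Zero out counts below ``min_count`` (default 10) to reduce noise."""
    data = table.data.copy()
    data["count"] = np.where(data["count"] < min_count, 0, data["count"])
    return CountTable(data)


def frequency_trace(
    pivot: pd.DataFrame,
    mutant: str,
    n_null_timepoints: int = 3,
) -> FrequencyTrace:
    """Build the log2 relative-frequency trace for one mutant.

    ``pivot`` is a mutants x timepoints count table for a single replicate
    (must contain a "WT" row).  The mutant is Null when its count is zero
    at any of the first ``n_null_timepoints`` timepoints (absence at t=0
    leaves f undefined and is Null as well).
    """
    times = np.asarray(pivot.columns, dtype=float)
    order = np.argsort(times)
    times = times[order]
    n_mut = pivot.loc[mutant].to_numpy(dtype=float)[order]
    n_wt = pivot.loc["WT"].to_numpy(dtype=float)[order]
    if np.any(n_wt <= 0):
        raise ValueError("WT reference counts must be positive at all timepoints")
    null = bool(np.any(n_mut[:n_null_timepoints] <= 0))
    defined = n_mut > 0
    with np.errstate(divide="ignore"):
        ratio = np.where(defined, n_mut, np.nan) / n_wt
    f = np.log2(ratio)
    if defined[0]:
        f = f - f[0]
    return FrequencyTrace(
        mutant=mutant,
        times=times[defined],
        f=f[defined],
        weights=n_mut[defined],
        null=null,
    )


def fit_relative_growth(trace: FrequencyTrace) -> float | None:
    """Count-weighted least-squares slope of f(t) (log2 units/hour).

    Returns None for Null traces.  Individual points are weighted by the
    mutant's own counts, down-weighting poorly sampled late timepoints.
    """
    if trace.null:
        return None
    reg = LinearRegression().fit(
        trace.times.reshape(-1, 1), trace.f, sample_weight=trace.weights
    )
    return float(reg.coef_[0])


def normalize_growth(slope: float, bulk_rate: float) -> float:
    """WT-relative growth from a log2-frequency slope.

    The WT lineage grows at the bulk rate (doublings/hour), so a mutant
    with slope m doubles at bulk + m and its relative rate is
    1 + m / bulk.  A slope of 0 maps to exactly 1 (the WT anchor); a
    slope of -bulk maps to 0 (non-dividing).
    """
    if not bulk_rate > 0:
        raise ValueError("bulk rate must be positive")
    return 1.0 + slope / bulk_rate


def aggregate_replicates(
    rates: list[float | None], min_replicates_for_sem: int = 2
) -> tuple[float, float, bool]:
    """Mean and SEM across replicate relative rates; any-Null => Null."""
    if any(r is None for r in rates):
        return np.nan, np.nan, True
    arr = np.asarray(rates, dtype=float)
    mean = float(arr.mean())
    if arr.size >= min_replicates_for_sem:
        sem = float(arr.std(ddof=1) / np.sqrt(arr.size))
    else:
        sem = np.nan
    return mean, sem, False


def infer_growth_rates(
    table: CountTable,
    bulk_rates: Mapping,
    min_count: int = 10,
    n_null_timepoints: int = 3,
    background: str | None = None,
) -> pd.DataFrame:
    """Full counts-to-growth pipeline for one selection experiment.

    Thresholds the counts, fits a count-weighted slope per mutant and
    replicate, normalizes by each vial's bulk growth rate (doublings/h),
    and aggregates replicates into mean +/- SEM with Null propagation.

    Returns a DataFrame with columns mutant, position, aa, rel_growth,
    sem, null_flag, replicate_rates (list), background.
    """
    for rep in table.replicates:
        if rep not in bulk_rates:
            raise ValueError(f"missing bulk rate for replicate {rep!r}")
    thresholded = threshold_counts(table, min_count=min_count)
    meta = (
        thresholded.data.drop_duplicates("mutant")
        .set_index("mutant")[["position", "aa"]]
        .to_dict("index")
    )
    pivots = {rep: thresholded.pivot(rep) for rep in thresholded.replicates}
    rows = []
    mutants = ["WT"] + thresholded.mutants
    for mutant in mutants:
        rep_rates: list[float | None] = []
        for rep, pivot in pivots.items():
            if mutant not in pivot.index:
                rep_rates.append(None)
                continue
            trace = frequency_trace(pivot, mutant, n_null_timepoints)
            slope = fit_relative_growth(trace)
            rep_rates.append(
                None if slope is None else normalize_growth(slope, bulk_rates[rep])
            )
        mean, sem, null = aggregate_replicates(rep_rates)
        rows.append(
            {
                "mutant": mutant,
                "position": meta.get(mutant, {}).get("position"),
                "aa": meta.get(mutant, {}).get("aa"),
                "rel_growth": mean,
                "sem": sem,
                "null_flag": null,
                "replicate_rates": rep_rates,
                "background": background,
            }
        )
    return pd.DataFrame(rows)


class RelativeGrowthEstimator(BaseEstimator):
    """Estimator wrapper over the counts-to-growth pipeline.

    Parameters mirror :func:`infer_growth_rates`; after ``fit`` the
    per-mutant records are available as ``records_``.
    """

    def __init__(self, min_count: int = 10, n_null_timepoints: int = 3):
        self.min_count = min_count
        self.n_null_timepoints = n_null_timepoints

    def fit(self, table: CountTable, bulk_rates: Mapping, background: str | None = None):
        self.records_ = infer_growth_rates(
            table,
            bulk_rates,
            min_count=self.min_count,
            n_null_timepoints=self.n_null_timepoints,
            background=background,
        )
        return self
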