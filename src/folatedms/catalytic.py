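"""Monte-Carlo inference of DHFR catalytic parameters from growth rates.

Given a mutant's relative growth rate in each TYMS background, (kcat, Km)
candidates are drawn log-uniformly and accepted when the model reproduces
every observed growth within tolerance.  Three growth measurements cannot
pin down kcat and Km separately -- the steady state depends on kinetics
mainly through V = [E]*kcat and Km/fol_tot, so the acceptance region is
elongated along rays of constant kcat/Km -- but the log10 catalytic power
kcat/Km is well constrained and is what the solution set summarizes.
Fully neutral mutants saturate the growth law and only bound power from
below; they are flagged rather than given a point estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .core_model import EnzymeKinetics, ModelParams, _predict_growth_arrays

__all__ = [
    "GrowthTriplet",
    "KineticsSolutionSet",
    "sample_consistent_kinetics",
    "summarize_catalytic_power",
    "CatalyticPowerEstimator",
    "reproject_growth_epistasis",
    "position_average_power",
    "DHFR_WT",
]

#: reference (WT) DHFR kinetics used to center the sampling bounds
DHFR_WT = EnzymeKinetics(kcat=13.0, km=20.0)


@dataclass
class GrowthTriplet:
    """One mutant's growth rate (+/- SEM) across TYMS backgrounds."""

    mutant: str
    growth: Mapping[str, float]
    sem: Mapping[str, float]

    def __post_init__(self) -> None:
        if len(self.growth) < 2:
            raise ValueError("need growth in >= 2 backgrounds")
        if any(s < 0 for s in self.sem.values()):
            raise ValueError("SEMs must be >= 0")


@dataclass
class KineticsSolutionSet:
    """Accepted (kcat, Km) samples for one mutant.

    ``saturated`` marks mutants whose acceptance region is unbounded
    above in catalytic power (growth-law plateau); their summary is a
    lower bound.  An empty set is a valid, flagged outcome.
    """

    mutant: str
    kcat: np.ndarray
    km: np.ndarray
    n_proposed: int
    tolerance: Mapping[str, float]
    saturated: bool
    flags: list[str] = field(default_factory=list)
    ray_km_min: float | None = None

    @property
    def n_accepted(self) -> int:
        return int(self.kcat.size)

    @property
    def is_empty(self) -> bool:
        return self.n_accepted == 0

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / self.n_proposed if self.n_proposed else 0.0

    @property
    def log10_power(self) -> np.ndarray:
        return np.log10(self.kcat / self.km)

    @property
    def ray_log10_power(self) -> np.ndarray:
        """Power of accepted samples on the degenerate constant-power ray.

        Restricted to Km >= ray_km_min (the folate pool size), the regime
        where the steady state depends on kinetics only through kcat/Km;
        low-Km samples lie off the ray and are excluded from the summary.
        Falls back to all samples when the ray is unpopulated.
        """
        if self.ray_km_min is None or self.is_empty:
            return self.log10_power
        on_ray = self.km >= self.ray_km_min
        if not on_ray.any():
            return self.log10_power
        return np.log10(self.kcat[on_ray] / self.km[on_ray])


def _triplet_tolerance(
    triplet: GrowthTriplet, tolerance_floor: float
) -> dict[str, float]:
    """Acceptance tolerance per background: max(2*SEM, floor)."""
    return {
        bg: max(2.0 * triplet.sem.get(bg, 0.0), tolerance_floor)
        for bg in triplet.growth
    }


def sample_consistent_kinetics(
    triplet: GrowthTriplet,
    params: ModelParams,
    n_samples: int = 2000,
    tolerance_floor: float = 0.035,
    bounds_decades: float = 3.0,
    wt_kinetics: EnzymeKinetics = DHFR_WT,
    seed: int | None = 0,
) -> KineticsSolutionSet:
    """Rejection-sample DHFR (kcat, Km) consistent with a growth triplet.

    Candidates are log-uniform over ``10**(+/-bounds_decades)`` times the
    WT kcat and Km; a candidate is accepted iff the predicted WT-relative
    growth (model prediction divided by the WT variant's prediction in
    the same background, matching the observation scale) in every
    background lies within max(2*SEM, ``tolerance_floor``) of the
    observation.  Reproducible under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    tol = _triplet_tolerance(triplet, tolerance_floor)
    lo_k, hi_k = np.log10(wt_kinetics.kcat) - bounds_decades, np.log10(
        wt_kinetics.kcat
    ) + bounds_decades
    lo_m, hi_m = np.log10(wt_kinetics.km) - bounds_decades, np.log10(
        wt_kinetics.km
    ) + bounds_decades
    kcat = 10.0 ** rng.uniform(lo_k, hi_k, n_samples)
    km = 10.0 ** rng.uniform(lo_m, hi_m, n_samples)
    accept = np.ones(n_samples, dtype=bool)
    hi_corner_ok = True  # max-power corner consistent => unbounded above
    lo_corner_ok = True  # min-power corner consistent => unbounded below
    for bg, g_obs in triplet.growth.items():
        g_wt = float(
            _predict_growth_arrays(
                np.array([wt_kinetics.kcat]), np.array([wt_kinetics.km]), bg, params
            )[0]
        )
        pred = _predict_growth_arrays(kcat, km, bg, params) / g_wt
        accept &= np.abs(pred - g_obs) <= tol[bg]
        g_hi = (
            float(
                _predict_growth_arrays(
                    np.array([10.0**hi_k]), np.array([10.0**lo_m]), bg, params
                )[0]
            )
            / g_wt
        )
        g_lo = (
            float(
                _predict_growth_arrays(
                    np.array([10.0**lo_k]), np.array([10.0**hi_m]), bg, params
                )[0]
            )
            / g_wt
        )
        hi_corner_ok &= abs(g_hi - g_obs) <= tol[bg]
        lo_corner_ok &= abs(g_lo - g_obs) <= tol[bg]
    flags = []
    if hi_corner_ok:
        flags.append("lower_bound")
    if lo_corner_ok:
        flags.append("upper_bound")
    if not accept.any():
        flags.append("empty")
    else:
        on_ray = km[accept] >= params.fol_tot
        lp = np.log10(kcat[accept] / km[accept])
        lp_ray = lp[on_ray] if on_ray.any() else lp
        # an acceptance region spanning decades of power only brackets the
        # mutant; a point summary would be prior-driven, so flag it
        if np.percentile(lp_ray, 97.5) - np.percentile(lp_ray, 2.5) > 2.0:
            flags.append("interval")
    return KineticsSolutionSet(
        mutant=triplet.mutant,
        kcat=kcat[accept],
        km=km[accept],
        n_proposed=n_samples,
        tolerance=tol,
        saturated=hi_corner_ok,
        flags=flags,
        ray_km_min=params.fol_tot,
    )


def summarize_catalytic_power(
    solutions: KineticsSolutionSet | Sequence[KineticsSolutionSet],
) -> dict:
    """Summarize log10(kcat/Km) from one or several inference repeats.

    For a single solution set: median of accepted samples with their SD.
    For repeats (the default protocol runs 50 independent inferences):
    mean of per-repeat medians, SD across repeats.  Saturated mutants are
    reported as lower bounds; an empty set yields a NaN sentinel.
    """
    sets = (
        [solutions] if isinstance(solutions, KineticsSolutionSet) else list(solutions)
    )
    medians = [
        float(np.median(s.ray_log10_power)) for s in sets if not s.is_empty
    ]
    lower = any("lower_bound" in s.flags for s in sets)
    upper = any("upper_bound" in s.flags for s in sets)
    interval = any("interval" in s.flags for s in sets)
    n_accepted = int(sum(s.n_accepted for s in sets))
    if not medians:
        return {
            "log10_power": float("nan"),
            "sd": float("nan"),
            "n_accepted": 0,
            "flag": "empty",
        }
    est = float(np.mean(medians))
    sd = float(np.std(medians, ddof=1)) if len(medians) > 1 else 0.0
    if lower and upper:
        flag = "unbounded"
    elif lower:
        flag = "lower_bound"
    elif upper:
        flag = "upper_bound"
    elif interval:
        flag = "interval"
    else:
        flag = "ok"
    return {
        "log10_power": est,
        "sd": sd,
        "n_accepted": n_accepted,
        "flag": flag,
    }


def _triplets_from_frame(X: pd.DataFrame) -> list[GrowthTriplet]:
    """Build triplets from a long table (mutant, background, rel_growth, sem)."""
    triplets = []
    for mutant, grp in X.groupby("mutant", sort=True):
        growth = dict(zip(grp["background"], grp["rel_growth"]))
        sem = dict(zip(grp["background"], grp["sem"].fillna(0.0)))
        triplets.append(GrowthTriplet(mutant=str(mutant), growth=growth, sem=sem))
    return triplets


class CatalyticPowerEstimator(BaseEstimator):
    """Per-mutant Monte-Carlo estimation of log10 catalytic power.

    ``fit`` consumes a long-format growth table (columns mutant,
    background, rel_growth, sem) and runs ``n_repeats`` independent
    rejection-sampling inferences per mutant (default 50), each with
    ``n_samples`` proposals.  Results land in ``results_`` with one row
    per mutant: log10_power, sd (across repeats), n_accepted, flag.
    """

    def __init__(
        self,
        model_params: ModelParams | None = None,
        n_samples: int = 2000,
        n_repeats: int = 50,
        tolerance_floor: float = 0.035,
        bounds_decades: float = 3.0,
        wt_kinetics: EnzymeKinetics = DHFR_WT,
        random_state: int | None = 0,
    ):
        self.model_params = model_params
        self.n_samples = n_samples
        self.n_repeats = n_repeats
        self.tolerance_floor = tolerance_floor
        self.bounds_decades = bounds_decades
        self.wt_kinetics = wt_kinetics
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None):
        if self.model_params is None:
            raise ValueError("model_params must be supplied")
        triplets = _triplets_from_frame(X)
        ss = np.random.SeedSequence(self.random_state)
        rows = []
        self.solution_sets_: dict[str, list[KineticsSolutionSet]] = {}
        for triplet, child in zip(triplets, ss.spawn(len(triplets))):
            seeds = child.generate_state(self.n_repeats) % (2**31)
            sets = [
                sample_consistent_kinetics(
                    triplet,
                    self.model_params,
                    n_samples=self.n_samples,
                    tolerance_floor=self.tolerance_floor,
                    bounds_decades=self.bounds_decades,
                    wt_kinetics=self.wt_kinetics,
                    seed=int(s),
                )
                for s in seeds
            ]
            self.solution_sets_[triplet.mutant] = sets
            summary = summarize_catalytic_power(sets)
            summary["mutant"] = triplet.mutant
            rows.append(summary)
        self.results_ = pd.DataFrame(rows)[
            ["mutant", "log10_power", "sd", "n_accepted", "flag"]
        ]
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Inferred log10 power aligned to the mutants appearing in X."""
        lookup = self.results_.set_index("mutant")["log10_power"]
        mutants = list(dict.fromkeys(X["mutant"]))
        return lookup.reindex(mutants).to_numpy(float)


def reproject_growth_epistasis(
    results: pd.DataFrame,
    params: ModelParams,
    backgrounds: Sequence[str],
    wt_background: str = "WT",
    km: float | None = None,
) -> pd.DataFrame:
    """Predicted growth and epistasis tables from inferred catalytic power.

    Along the degenerate (kcat, Km) ray each mutant is represented at the
    reference Km (WT's by default) with kcat = power * Km, then pushed
    back through the model for every background; predictions are
    WT-normalized to match the experimental growth-record scale.  Mutants
    with empty solution sets propagate as missing rows (NaN), never
    imputed.
    """
    km = DHFR_WT.km if km is None else km
    g_wt = {
        bg: float(
            _predict_growth_arrays(
                np.array([DHFR_WT.kcat]), np.array([DHFR_WT.km]), bg, params
            )[0]
        )
        for bg in backgrounds
    }
    rows = []
    for row in results.itertuples(index=False):
        power = row.log10_power
        if not np.isfinite(power):
            preds = {bg: np.nan for bg in backgrounds}
        else:
            kcat = 10.0**power * km
            preds = {
                bg: float(
                    _predict_growth_arrays(np.array([kcat]), np.array([km]), bg, params)[0]
                )
                / g_wt[bg]
                for bg in backgrounds
            }
        for bg in backgrounds:
            rows.append(
                {
                    "mutant": row.mutant,
                    "background": bg,
                    "pred_growth": preds[bg],
                    "pred_eps": preds[bg] - preds[wt_background]
                    if np.isfinite(power)
                    else np.nan,
                }
            )
    return pd.DataFrame(rows)


def position_average_power(
    results: pd.DataFrame, protein_length: int | None = None
) -> pd.DataFrame:
    """Arithmetic mean of log10 power over measured mutants per position.

    ``results`` needs position and log10_power columns; positions without
    any measured mutant are flagged with NaN when ``protein_length`` is
    given.
    """
    scored = results.dropna(subset=["position", "log10_power"])
    means = (
        scored.groupby("position")["log10_power"].mean().rename("mean_log10_power")
    )
    if protein_length is not None:
        means = means.reindex(range(1, protein_length + 1))
    out = means.reset_index()
    out["measured"] = out["mean_log10_power"].notna()
    return out
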