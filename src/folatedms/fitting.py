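"""Least-squares parameterization of the velocity-to-growth model.

Three estimators cover the fitting stages used in practice: the Hill growth
law against measured THF abundance (:class:`GrowthLawRegressor`), the
steady-state concentrations against metabolomics data
(:class:`SteadyStateModelRegressor`), and the joint model against growth
rates (:class:`GrowthModelRegressor`).  Resampling controls (jackknife,
bootstrap, catalytic-parameter shuffling) operate generically on any of
them.  All positive scale parameters are fit in log space with a seeded
multi-start bounded nonlinear least squares (scipy ``least_squares``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin, clone

from .core_model import (
    EnzymeKinetics,
    GrowthLaw,
    ModelParams,
    _gk_fraction,
    growth_from_thf,
)

__all__ = [
    "ObservationSet",
    "FitResult",
    "GrowthLawRegressor",
    "SteadyStateModelRegressor",
    "GrowthModelRegressor",
    "fit_growth_law",
    "fit_steady_state_model",
    "fit_joint_model",
    "jackknife_uncertainty",
    "bootstrap_fit",
    "shuffle_control",
    "r_squared",
]

_REQUIRED_COLUMNS = [
    "dhfr_variant",
    "tyms_variant",
    "dhfr_kcat",
    "dhfr_km",
    "tyms_kcat",
    "tyms_km",
    "growth",
    "growth_sem",
]


def r_squared(y_true, y_pred) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    ss_res = np.sum((y_true - y_pred) ** 2)
    ss_tot = np.sum((y_true - np.mean(y_true)) ** 2)
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else -np.inf
    return float(1.0 - ss_res / ss_tot)


@dataclass
class ObservationSet:
    """Table of paired kinetics/growth (and optional THF) observations.

    One row per DHFR-variant x TYMS-background combination, carrying the
    in-vitro kinetics of both enzymes, the measured relative growth rate
    with its replicate SEM, and optionally a THF-abundance readout.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"ObservationSet missing columns: {missing}")
        if (self.data["growth_sem"].fillna(0) < 0).any():
            raise ValueError("growth_sem must be >= 0")
        self.data = self.data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def has_thf(self) -> bool:
        return "thf_abundance" in self.data.columns and (
            self.data["thf_abundance"].notna().all()
        )

    @classmethod
    def from_csv(cls, path) -> "ObservationSet":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


@dataclass
class FitResult:
    """Outcome of a model fit: parameters, residuals, fit quality."""

    params: ModelParams
    residual_norm: float
    r2: float
    residuals: np.ndarray
    n_obs: int
    uncertainty: Mapping[str, float] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


def _multistart_least_squares(
    residual_fn: Callable[[np.ndarray], np.ndarray],
    theta0: np.ndarray,
    bounds: tuple[np.ndarray, np.ndarray],
    n_restarts: int,
    rng: np.random.Generator,
    perturb_sd: float = 0.5,
):
    """Bounded least squares with seeded random restarts; best fit wins."""
    lo, hi = bounds
    best = None
    starts = [theta0]
    for _ in range(max(0, n_restarts - 1)):
        pert = theta0 + rng.normal(0.0, perturb_sd, size=theta0.size)
        starts.append(np.clip(pert, lo, hi))
    for start in starts:
        try:
            sol = least_squares(
                residual_fn, np.clip(start, lo, hi), bounds=(lo, hi), method="trf"
            )
        except Exception:  # pragma: no cover - optimizer pathologies
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("all least-squares starts failed")
    return best


class GrowthLawRegressor(RegressorMixin, BaseEstimator):
    """Fit the four-parameter Hill growth law g(THF).

    X is the THF abundance readout (1d array or single column), y the
    measured growth rate.  g_min is constrained non-negative and the
    amplitude g_max - g_min positive; K and n are fit in log space.

    Attributes
    ----------
    law_ : GrowthLaw
    r2_ : float
    residual_norm_ : float
    degenerate_ : bool
        True when the response is flat (g_max ~= g_min) making K and n
        unidentifiable.
    """

    def __init__(self, n_restarts: int = 10, random_state: int | None = 0):
        self.n_restarts = n_restarts
        self.random_state = random_state

    def fit(self, X, y):
        thf = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if thf.size != y.size:
            raise ValueError("X and y length mismatch")
        if np.unique(thf).size < 4 or thf.size < 4:
            raise ValueError(
                "growth-law fit needs >= 4 observations with distinct THF values"
            )
        rng = np.random.default_rng(self.random_state)
        span = float(np.ptp(y))
        flat = span < 1e-12
        g_min0 = max(float(np.min(y)), 0.0)
        dg0 = max(span, 1e-6)
        k0 = float(np.median(thf[thf > 0])) if np.any(thf > 0) else 1.0

        # theta = [g_min, log10(dg), log10(K), log10(n)]
        def resid(theta):
            g_min, dg, k, n = theta[0], 10 ** theta[1], 10 ** theta[2], 10 ** theta[3]
            with np.errstate(divide="ignore"):
                ratio = np.where(thf > 0, k / np.where(thf > 0, thf, 1.0), np.inf)
            pred = g_min + dg / (1.0 + ratio**n)
            pred = np.where(thf == 0, g_min, pred)
            return pred - y

        theta0 = np.array([g_min0, np.log10(dg0), np.log10(k0), np.log10(2.0)])
        lo = np.array([0.0, np.log10(dg0) - 6, np.log10(k0) - 4, -1.0])
        hi = np.array(
            [max(np.max(y), 1e-6), np.log10(dg0) + 2, np.log10(k0) + 4, 1.0]
        )
        sol = _multistart_least_squares(resid, theta0, (lo, hi), self.n_restarts, rng)
        g_min, dg = sol.x[0], 10 ** sol.x[1]
        self.law_ = GrowthLaw(
            g_max=g_min + dg, g_min=g_min, K=10 ** sol.x[2], n=10 ** sol.x[3]
        )
        self.degenerate_ = bool(flat or dg < 1e-3 * max(span, 1e-12) or flat)
        pred = resid(sol.x) + y
        self.residual_norm_ = float(np.linalg.norm(pred - y))
        self.r2_ = r_squared(y, pred)
        return self

    def predict(self, X):
        thf = np.asarray(X, dtype=float).reshape(-1)
        return np.asarray(growth_from_thf(thf, self.law_))

    def fitted_param_dict(self) -> dict[str, float]:
        law = self.law_
        return {"g_max": law.g_max, "g_min": law.g_min, "K": law.K, "n": law.n}


def _row_tyms_kinetics(X: pd.DataFrame, params: ModelParams):
    """Per-row TYMS (kcat, km): explicit columns win over registered ones."""
    if "tyms_kcat" in X.columns and X["tyms_kcat"].notna().all():
        return X["tyms_kcat"].to_numpy(float), X["tyms_km"].to_numpy(float)
    kcat = np.empty(len(X))
    km = np.empty(len(X))
    for i, bg in enumerate(X["tyms_variant"]):
        kin = params.tyms_kinetics[bg]
        kcat[i], km[i] = kin.kcat, kin.km
    return kcat, km


def _predict_thf_abundance(X: pd.DataFrame, params: ModelParams) -> np.ndarray:
    t_kcat, t_km = _row_tyms_kinetics(X, params)
    conc = np.array([params.tyms_concs[bg] for bg in X["tyms_variant"]])
    frac = _gk_fraction(
        params.dhfr_conc * X["dhfr_kcat"].to_numpy(float),
        conc * t_kcat,
        X["dhfr_km"].to_numpy(float) / params.fol_tot,
        t_km / params.fol_tot,
    )
    return params.thf_scale * params.fol_tot * np.asarray(frac)


def _predict_growth(X: pd.DataFrame, params: ModelParams) -> np.ndarray:
    return np.asarray(
        growth_from_thf(_predict_thf_abundance(X, params), params.growth_law)
    )


class SteadyStateModelRegressor(RegressorMixin, BaseEstimator):
    """Fit intracellular concentrations + folate pool to THF metabolomics.

    X carries per-observation kinetics (``dhfr_kcat``, ``dhfr_km``,
    ``tyms_kcat``, ``tyms_km``) and the TYMS background label
    (``tyms_variant``); y is the measured THF-abundance readout (linear
    units).  Free parameters are fol_tot, [DHFR], one [TYMS] per unique
    background, and the abundance scale factor; the fit target is log10
    abundance.  The scale factor and fol_tot are jointly degenerate with
    the abundance units; recovery is therefore up to that scale.
    """

    def __init__(
        self,
        fol_tot0: float = 20.0,
        conc0: float = 1.0,
        thf_scale0: float = 1.0,
        span_decades: float = 3.0,
        n_restarts: int = 10,
        random_state: int | None = 0,
    ):
        self.fol_tot0 = fol_tot0
        self.conc0 = conc0
        self.thf_scale0 = thf_scale0
        self.span_decades = span_decades
        self.n_restarts = n_restarts
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y):
        y = np.asarray(y, dtype=float).reshape(-1)
        if np.any(y <= 0):
            raise ValueError("THF abundances must be positive")
        backgrounds = list(dict.fromkeys(X["tyms_variant"]))
        names = ["fol_tot", "dhfr_conc", "thf_scale"] + [
            f"tyms_conc:{bg}" for bg in backgrounds
        ]
        n_free = len(names)
        if len(X) < n_free:
            raise ValueError(
                f"under-determined: {len(X)} observations < {n_free} parameters"
            )
        self.flags_ = []
        if len(backgrounds) < 2:
            self.flags_.append(
                "single TYMS background: [TYMS] and [DHFR] only jointly identifiable"
            )
        log_y = np.log10(y)
        rng = np.random.default_rng(self.random_state)
        theta0 = np.log10(
            np.array(
                [self.fol_tot0, self.conc0, self.thf_scale0]
                + [self.conc0] * len(backgrounds)
            )
        )
        lo = theta0 - self.span_decades
        hi = theta0 + self.span_decades

        def build(theta) -> ModelParams:
            vals = 10.0**theta
            return ModelParams(
                growth_law=GrowthLaw(1.0, 0.0, 1.0, 1.0),  # unused here
                dhfr_conc=vals[1],
                tyms_concs={bg: vals[3 + i] for i, bg in enumerate(backgrounds)},
                fol_tot=vals[0],
                thf_scale=vals[2],
            )

        def resid(theta):
            return np.log10(_predict_thf_abundance(X, build(theta))) - log_y

        sol = _multistart_least_squares(resid, theta0, (lo, hi), self.n_restarts, rng)
        vals = 10.0**sol.x
        self.fol_tot_ = float(vals[0])
        self.dhfr_conc_ = float(vals[1])
        self.thf_scale_ = float(vals[2])
        self.tyms_concs_ = {bg: float(vals[3 + i]) for i, bg in enumerate(backgrounds)}
        self._params = build(sol.x)
        pred = np.log10(_predict_thf_abundance(X, self._params))
        self.residual_norm_ = float(np.linalg.norm(pred - log_y))
        self.r2_ = r_squared(log_y, pred)
        return self

    def predict(self, X: pd.DataFrame):
        """Predicted THF abundance in the measured (linear) units."""
        return _predict_thf_abundance(X, self._params)

    def fitted_param_dict(self) -> dict[str, float]:
        out = {
            "fol_tot": self.fol_tot_,
            "dhfr_conc": self.dhfr_conc_,
            "thf_scale": self.thf_scale_,
        }
        out.update({f"tyms_conc:{bg}": c for bg, c in self.tyms_concs_.items()})
        return out


class GrowthModelRegressor(RegressorMixin, BaseEstimator):
    """Joint fit of the velocity-to-growth model against growth rates.

    X carries ``dhfr_kcat``, ``dhfr_km`` and ``tyms_variant`` (plus
    optionally explicit ``tyms_kcat``/``tyms_km`` overriding the kinetics
    registered in ``base_params``); y is relative growth.  ``free`` names
    the parameters to optimize, any of: ``g_max``, ``g_min``, ``K``,
    ``n``, ``dhfr_conc``, ``fol_tot``, ``thf_scale``,
    ``tyms_conc:<BACKGROUND>``.  An empty list yields an evaluation-only
    fit (residuals of the supplied parameters).
    """

    def __init__(
        self,
        base_params: ModelParams | None = None,
        free: Sequence[str] | None = None,
        span_decades: float = 3.0,
        n_restarts: int = 10,
        random_state: int | None = 0,
    ):
        self.base_params = base_params
        self.free = free
        self.span_decades = span_decades
        self.n_restarts = n_restarts
        self.random_state = random_state

    # -- parameter vector plumbing -------------------------------------
    def _get_value(self, params: ModelParams, name: str) -> float:
        if name in ("g_max", "g_min", "K", "n"):
            law = params.growth_law
            return {"g_max": law.g_max, "g_min": law.g_min, "K": law.K, "n": law.n}[
                name
            ]
        if name in ("dhfr_conc", "fol_tot", "thf_scale"):
            return getattr(params, name)
        if name.startswith("tyms_conc:"):
            return params.tyms_concs[name.split(":", 1)[1]]
        raise ValueError(f"unknown parameter {name!r}")

    def _apply(self, params: ModelParams, values: Mapping[str, float]) -> ModelParams:
        law = params.growth_law
        law_kw = {"g_max": law.g_max, "g_min": law.g_min, "K": law.K, "n": law.n}
        concs = dict(params.tyms_concs)
        other = {
            "dhfr_conc": params.dhfr_conc,
            "fol_tot": params.fol_tot,
            "thf_scale": params.thf_scale,
        }
        for name, v in values.items():
            if name in law_kw:
                law_kw[name] = v
            elif name in other:
                other[name] = v
            elif name.startswith("tyms_conc:"):
                concs[name.split(":", 1)[1]] = v
            else:
                raise ValueError(f"unknown parameter {name!r}")
        if law_kw["g_max"] < law_kw["g_min"]:
            law_kw["g_max"] = law_kw["g_min"]
        return ModelParams(
            growth_law=GrowthLaw(**law_kw),
            dhfr_conc=other["dhfr_conc"],
            tyms_concs=concs,
            fol_tot=other["fol_tot"],
            thf_scale=other["thf_scale"],
            tyms_kinetics=params.tyms_kinetics,
        )

    def fit(self, X: pd.DataFrame, y, sample_weight=None):
        if self.base_params is None:
            raise ValueError("base_params must be supplied")
        y = np.asarray(y, dtype=float).reshape(-1)
        free = list(self.free or [])
        w = (
            np.ones_like(y)
            if sample_weight is None
            else np.sqrt(np.asarray(sample_weight, dtype=float))
        )
        if free and len(X) < len(free):
            raise ValueError(
                f"under-determined: {len(X)} observations < {len(free)} parameters"
            )
        if not free:
            self.params_ = self.base_params
        else:
            rng = np.random.default_rng(self.random_state)
            # g_min is fit linearly (it may be 0); all others in log10 space
            linear = [f for f in free if f == "g_min"]
            logged = [f for f in free if f != "g_min"]

            def unpack(theta) -> dict[str, float]:
                vals = {}
                for i, name in enumerate(logged):
                    vals[name] = 10.0 ** theta[i]
                for j, name in enumerate(linear):
                    vals[name] = theta[len(logged) + j]
                return vals

            theta0 = np.array(
                [np.log10(self._get_value(self.base_params, f)) for f in logged]
                + [self._get_value(self.base_params, f) for f in linear]
            )
            lo = np.concatenate(
                [theta0[: len(logged)] - self.span_decades, np.zeros(len(linear))]
            )
            g_cap = max(float(np.max(y)) * 2.0, 1e-3)
            hi = np.concatenate(
                [
                    theta0[: len(logged)] + self.span_decades,
                    np.full(len(linear), g_cap),
                ]
            )

            def resid(theta):
                params = self._apply(self.base_params, unpack(theta))
                return w * (_predict_growth(X, params) - y)

            sol = _multistart_least_squares(
                resid, theta0, (lo, hi), self.n_restarts, rng
            )
            self.params_ = self._apply(self.base_params, unpack(sol.x))
        pred = _predict_growth(X, self.params_)
        self.residuals_ = pred - y
        self.residual_norm_ = float(np.linalg.norm(w * self.residuals_))
        self.r2_ = r_squared(y, pred)
        self.result_ = FitResult(
            params=self.params_,
            residual_norm=self.residual_norm_,
            r2=self.r2_,
            residuals=self.residuals_,
            n_obs=len(y),
        )
        return self

    def predict(self, X: pd.DataFrame):
        return _predict_growth(X, self.params_)

    def fitted_param_dict(self) -> dict[str, float]:
        p = self.params_
        out = {
            "g_max": p.growth_law.g_max,
            "g_min": p.growth_law.g_min,
            "K": p.growth_law.K,
            "n": p.growth_law.n,
            "dhfr_conc": p.dhfr_conc,
            "fol_tot": p.fol_tot,
            "thf_scale": p.thf_scale,
        }
        out.update({f"tyms_conc:{bg}": c for bg, c in p.tyms_concs.items()})
        return out


# ---------------------------------------------------------------------------
# thin functional wrappers over the estimators


def fit_growth_law(obs: ObservationSet, **kwargs) -> GrowthLaw:
    """Fit the Hill growth law to (THF abundance, growth) observations."""
    if not obs.has_thf:
        raise ValueError("ObservationSet lacks thf_abundance values")
    est = GrowthLawRegressor(**kwargs).fit(
        obs.data["thf_abundance"].to_numpy(float), obs.data["growth"].to_numpy(float)
    )
    return est.law_


def fit_steady_state_model(obs: ObservationSet, **kwargs) -> SteadyStateModelRegressor:
    """Fit concentrations + fol_tot (+ scale) to THF metabolomics data."""
    if not obs.has_thf:
        raise ValueError("ObservationSet lacks thf_abundance values")
    return SteadyStateModelRegressor(**kwargs).fit(
        obs.data, obs.data["thf_abundance"].to_numpy(float)
    )


def fit_joint_model(
    obs: ObservationSet,
    base_params: ModelParams,
    free: Sequence[str],
    **kwargs,
) -> FitResult:
    """Joint model fit against growth rates; returns a FitResult."""
    est = GrowthModelRegressor(base_params=base_params, free=free, **kwargs)
    est.fit(obs.data, obs.data["growth"].to_numpy(float))
    return est.result_


# ---------------------------------------------------------------------------
# resampling controls


@dataclass
class JackknifeResult:
    predictions: np.ndarray  # (n_fits, n_obs)
    pred_sd: np.ndarray
    pred_sem: np.ndarray
    n_fits: int
    failures: list[int]


def jackknife_uncertainty(estimator, X, y) -> JackknifeResult:
    """Leave-one-out refits; SD/SEM of predictions across the N refits.

    Exactly one refit per observation; failed sub-fits are recorded by
    index, never silently dropped.
    """
    y = np.asarray(y, dtype=float).reshape(-1)
    n = len(y)
    if n < 3:
        raise ValueError("jackknife needs >= 3 observations")
    is_frame = isinstance(X, pd.DataFrame)
    preds, failures = [], []
    for i in range(n):
        keep = np.arange(n) != i
        Xi = X.iloc[keep] if is_frame else np.asarray(X)[keep]
        try:
            est = clone(estimator).fit(Xi, y[keep])
            preds.append(np.asarray(est.predict(X)).reshape(-1))
        except Exception:
            failures.append(i)
    P = np.vstack(preds) if preds else np.empty((0, n))
    sd = P.std(axis=0, ddof=1) if len(preds) > 1 else np.zeros(n)
    return JackknifeResult(
        predictions=P,
        pred_sd=sd,
        pred_sem=sd / np.sqrt(max(len(preds), 1)),
        n_fits=len(preds),
        failures=failures,
    )


@dataclass
class BootstrapResult:
    param_samples: pd.DataFrame  # (B, n_params)
    param_sd: pd.Series
    pred_sd: np.ndarray
    n_resamples: int


def bootstrap_fit(estimator, X, y, B: int = 1000, seed: int | None = 0) -> BootstrapResult:
    """Observation-level bootstrap (resampling with replacement) of a fit.

    Default B = 1000 resamples.  SDs use ddof=0 so a single resample
    yields zero spread.  Reproducible under a fixed seed.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    y = np.asarray(y, dtype=float).reshape(-1)
    n = len(y)
    rng = np.random.default_rng(seed)
    is_frame = isinstance(X, pd.DataFrame)
    rows, preds = [], []
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        Xi = X.iloc[idx] if is_frame else np.asarray(X)[idx]
        est = clone(estimator).fit(Xi, y[idx])
        rows.append(est.fitted_param_dict())
        preds.append(np.asarray(est.predict(X)).reshape(-1))
    samples = pd.DataFrame(rows)
    return BootstrapResult(
        param_samples=samples,
        param_sd=samples.std(ddof=0),
        pred_sd=np.vstack(preds).std(axis=0, ddof=0),
        n_resamples=B,
    )


@dataclass
class ShuffleControlResult:
    true_r2: float
    shuffled_r2: np.ndarray
    scope: str


def _permute_variant_kinetics(
    data: pd.DataFrame, enzyme: str, rng: np.random.Generator
) -> pd.DataFrame:
    """Permute (kcat, Km) pairs jointly among the unique variants of one enzyme."""
    var_col = f"{enzyme}_variant"
    kcat_col, km_col = f"{enzyme}_kcat", f"{enzyme}_km"
    variants = list(dict.fromkeys(data[var_col]))
    table = {
        v: (
            float(data.loc[data[var_col] == v, kcat_col].iloc[0]),
            float(data.loc[data[var_col] == v, km_col].iloc[0]),
        )
        for v in variants
    }
    perm = rng.permutation(len(variants))
    mapping = {variants[i]: table[variants[perm[i]]] for i in range(len(variants))}
    out = data.copy()
    out[kcat_col] = [mapping[v][0] for v in data[var_col]]
    out[km_col] = [mapping[v][1] for v in data[var_col]]
    return out


def shuffle_control(
    estimator,
    obs: ObservationSet,
    n_shuffles: int = 50,
    scope: str = "both",
    seed: int | None = 0,
) -> ShuffleControlResult:
    """Overfitting control: shuffle catalytic parameters and refit.

    Each shuffle permutes (kcat, Km) pairs jointly among variants of the
    scoped enzyme(s) ('dhfr', 'tyms' or 'both'), refits all free
    parameters and records the R^2 against growth; the true-data R^2 is
    reported alongside.  Default 50 shuffles.
    """
    if scope not in ("dhfr", "tyms", "both"):
        raise ValueError("scope must be 'dhfr', 'tyms' or 'both'")
    data = obs.data
    y = data["growth"].to_numpy(float)
    rng = np.random.default_rng(seed)
    true_est = clone(estimator).fit(data, y)
    true_r2 = r_squared(y, true_est.predict(data))
    r2s = np.empty(n_shuffles)
    for s in range(n_shuffles):
        shuffled = data
        if scope in ("dhfr", "both"):
            shuffled = _permute_variant_kinetics(shuffled, "dhfr", rng)
        if scope in ("tyms", "both"):
            shuffled = _permute_variant_kinetics(shuffled, "tyms", rng)
        est = clone(estimator).fit(shuffled, y)
        r2s[s] = r_squared(y, est.predict(shuffled))
    return ShuffleControlResult(true_r2=true_r2, shuffled_r2=r2s, scope=scope)
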