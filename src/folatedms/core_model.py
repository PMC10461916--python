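"""Velocity-to-growth model for the DHFR/TYMS two-enzyme folate cycle.

DHFR reduces dihydrofolate (DHF) to tetrahydrofolate (THF); TYMS oxidizes
THF back to DHF.  Treating both as Michaelis--Menten reactions on a conserved
folate pool of size ``fol_tot`` gives a rate equation whose steady state is
the Goldbeter--Koshland zero-order form.  Growth rate is then a Hill function
of steady-state THF abundance.  This module holds the closed-form model, an
ODE right-hand side used as an independent oracle, and the landscape
simulations (growth/epistasis grids, mutational-tolerance grids) built on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "EnzymeKinetics",
    "PathwayContext",
    "GKInputs",
    "GrowthLaw",
    "ModelParams",
    "thf_ode_rhs",
    "steady_state_thf_fraction",
    "growth_from_thf",
    "predict_relative_growth",
    "growth_and_epistasis_grid",
    "neutral_fraction_grid",
]

#: clip bound protecting the downstream Hill evaluation from log(0)
_FRACTION_EPS = 1e-12


@dataclass(frozen=True)
class EnzymeKinetics:
    """Steady-state catalytic parameters of one enzyme variant.

    Parameters
    ----------
    kcat : float
        Turnover number (1/s).  Non-negative; a near-inactive variant is
        represented by an arbitrarily small ``kcat`` and large ``km``,
        never by zeros.
    km : float
        Michaelis constant (µM), strictly positive.
    """

    kcat: float
    km: float

    def __post_init__(self) -> None:
        if not self.kcat >= 0:
            raise ValueError(f"kcat must be >= 0, got {self.kcat}")
        if not self.km > 0:
            raise ValueError(f"km must be > 0, got {self.km}")

    @property
    def log10_power(self) -> float:
        """log10 catalytic power, log10(kcat/Km)."""
        return float(np.log10(self.kcat / self.km))


#: sentinel kinetics for near-inactive variants (R166Q-like): arbitrarily
#: low kcat and high Km, keeping every model expression well defined
NEAR_INACTIVE = EnzymeKinetics(kcat=1e-4, km=1e4)


@dataclass(frozen=True)
class PathwayContext:
    """Intracellular concentrations shared by a model evaluation (µM)."""

    dhfr_conc: float
    tyms_conc: float
    fol_tot: float

    def __post_init__(self) -> None:
        for name in ("dhfr_conc", "tyms_conc", "fol_tot"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class GKInputs:
    """Reduced inputs of the Goldbeter--Koshland steady state.

    ``v1 = [DHFR]*kcat_DHFR`` and ``v2 = [TYMS]*kcat_TYMS`` are maximal
    velocities (µM/s); ``km1_hat = Km_DHFR/fol_tot`` and
    ``km2_hat = Km_TYMS/fol_tot`` are Michaelis constants scaled by the
    total folate pool (dimensionless).
    """

    v1: float
    v2: float
    km1_hat: float
    km2_hat: float

    def __post_init__(self) -> None:
        for name in ("v1", "v2", "km1_hat", "km2_hat"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")

    @classmethod
    def from_kinetics(
        cls, dhfr: EnzymeKinetics, tyms: EnzymeKinetics, ctx: PathwayContext
    ) -> "GKInputs":
        return cls(
            v1=ctx.dhfr_conc * dhfr.kcat,
            v2=ctx.tyms_conc * tyms.kcat,
            km1_hat=dhfr.km / ctx.fol_tot,
            km2_hat=tyms.km / ctx.fol_tot,
        )


@dataclass(frozen=True)
class GrowthLaw:
    """Hill relation between THF abundance and growth rate.

    g(THF) = g_min + (g_max - g_min) / (1 + (K/THF)^n)

    ``K`` is the THF abundance giving half-maximal growth (in the units of
    the measured THF readout) and ``n`` the Hill coefficient.
    """

    g_max: float
    g_min: float
    K: float
    n: float

    def __post_init__(self) -> None:
        if not (self.g_max >= self.g_min >= 0):
            raise ValueError("require g_max >= g_min >= 0")
        if not self.K > 0:
            raise ValueError("K must be > 0")
        if not self.n > 0:
            raise ValueError("n must be > 0")

    def __call__(self, thf_abundance):
        return growth_from_thf(thf_abundance, self)


@dataclass(frozen=True)
class ModelParams:
    """Full parameter set of the fitted velocity-to-growth model.

    ``tyms_concs`` maps TYMS background labels (e.g. ``"WT"``, ``"Q33S"``,
    ``"R166Q"``) to intracellular concentrations; ``tyms_kinetics`` carries
    the catalytic parameters of each background's TYMS variant so that a
    background label suffices to evaluate the model.  ``thf_scale`` maps the
    model's [THF]ss (µM) to the units of the measured THF readout the growth
    law was fit in.
    """

    growth_law: GrowthLaw
    dhfr_conc: float
    tyms_concs: Mapping[str, float]
    fol_tot: float
    thf_scale: float = 1.0
    tyms_kinetics: Mapping[str, EnzymeKinetics] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.dhfr_conc > 0 or not self.fol_tot > 0 or not self.thf_scale > 0:
            raise ValueError("concentrations and thf_scale must be > 0")
        for name, c in self.tyms_concs.items():
            if not c > 0:
                raise ValueError(f"tyms_concs[{name!r}] must be > 0")

    def context(self, tyms_name: str) -> PathwayContext:
        if tyms_name not in self.tyms_concs:
            raise KeyError(
                f"unknown TYMS background {tyms_name!r}; "
                f"known: {sorted(self.tyms_concs)}"
            )
        return PathwayContext(
            dhfr_conc=self.dhfr_conc,
            tyms_conc=self.tyms_concs[tyms_name],
            fol_tot=self.fol_tot,
        )

    def with_updates(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


def thf_ode_rhs(
    thf: float,
    dhfr: EnzymeKinetics,
    tyms: EnzymeKinetics,
    ctx: PathwayContext,
) -> float:
    """d[THF]/dt (µM/s) of the two-enzyme cycle.

    Production by DHFR acting on DHF = fol_tot - THF minus consumption by
    TYMS acting on THF.  Used directly as the numerical-integration oracle
    for the closed-form steady state.
    """
    thf = float(thf)
    if not (0.0 <= thf <= ctx.fol_tot):
        raise ValueError(f"thf={thf} outside [0, fol_tot={ctx.fol_tot}]")
    dhf = ctx.fol_tot - thf
    production = ctx.dhfr_conc * dhfr.kcat / (1.0 + dhfr.km / dhf) if dhf > 0 else 0.0
    consumption = ctx.tyms_conc * tyms.kcat / (1.0 + tyms.km / thf) if thf > 0 else 0.0
    return production - consumption


def _gk_fraction(v1, v2, km1_hat, km2_hat):
    """Vectorized Goldbeter--Koshland steady-state THF fraction.

    Stable root of the quadratic (r-1)x^2 + (1 + j1 + r*j2 - r)x - r*j2 = 0
    with r = v1/v2, written as x = 2q / (b + sqrt(b^2 + 4(r-1)q)), q = r*j2.
    This form is continuous through r = 1 (where the quadratic degenerates
    to a linear equation) and numerically stable for extreme r.
    """
    r = np.asarray(v1, dtype=float) / np.asarray(v2, dtype=float)
    j1 = np.asarray(km1_hat, dtype=float)
    j2 = np.asarray(km2_hat, dtype=float)
    q = r * j2
    b = 1.0 + j1 + q - r
    disc = b * b + 4.0 * (r - 1.0) * q
    x = 2.0 * q / (b + np.sqrt(disc))
    return np.clip(x, _FRACTION_EPS, 1.0 - _FRACTION_EPS)


def steady_state_thf_fraction(gk: GKInputs) -> float:
    """Steady-state THF fraction [THF]ss/fol_tot in (0, 1).

    Equals the stable root of :func:`thf_ode_rhs` = 0; the V1 = V2
    degeneracy of the printed quadratic is handled by an algebraically
    equivalent form that attains the analytic limit continuously.
    """
    return float(_gk_fraction(gk.v1, gk.v2, gk.km1_hat, gk.km2_hat))


def growth_from_thf(thf_abundance, law: GrowthLaw):
    """Growth rate from THF abundance via the Hill growth law.

    Monotone non-decreasing, bounded in [g_min, g_max]; zero abundance
    returns g_min exactly (limit convention).
    """
    thf = np.asarray(thf_abundance, dtype=float)
    if np.any(thf < 0):
        raise ValueError("thf_abundance must be >= 0")
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(thf > 0, law.K / np.where(thf > 0, thf, 1.0), np.inf)
        g = law.g_min + (law.g_max - law.g_min) / (1.0 + ratio**law.n)
    g = np.where(thf == 0, law.g_min, g)
    return float(g) if g.ndim == 0 else g


def _predict_growth_arrays(kcat, km, tyms_name: str, params: ModelParams):
    """Vectorized growth prediction for arrays of DHFR (kcat, Km)."""
    if tyms_name not in params.tyms_kinetics:
        raise KeyError(
            f"no TYMS kinetics registered for background {tyms_name!r}; "
            f"known: {sorted(params.tyms_kinetics)}"
        )
    tyms = params.tyms_kinetics[tyms_name]
    ctx = params.context(tyms_name)
    frac = _gk_fraction(
        ctx.dhfr_conc * np.asarray(kcat, dtype=float),
        ctx.tyms_conc * tyms.kcat,
        np.asarray(km, dtype=float) / ctx.fol_tot,
        tyms.km / ctx.fol_tot,
    )
    thf_abundance = params.thf_scale * ctx.fol_tot * frac
    return growth_from_thf(thf_abundance, params.growth_law)


def predict_relative_growth(
    dhfr: EnzymeKinetics,
    tyms_name: str,
    params: ModelParams,
    tyms: EnzymeKinetics | None = None,
) -> float:
    """Relative growth rate of a DHFR variant in a named TYMS background.

    Composes the Goldbeter--Koshland steady state with the growth law:
    g = law(thf_scale * fol_tot * steady_state_thf_fraction(...)).  TYMS
    kinetics default to the ones registered in ``params.tyms_kinetics``
    but may be overridden (e.g. when scanning TYMS activity).
    """
    ctx = params.context(tyms_name)
    if tyms is None:
        if tyms_name not in params.tyms_kinetics:
            raise KeyError(f"no TYMS kinetics for background {tyms_name!r}")
        tyms = params.tyms_kinetics[tyms_name]
    frac = steady_state_thf_fraction(GKInputs.from_kinetics(dhfr, tyms, ctx))
    return float(
        growth_from_thf(params.thf_scale * ctx.fol_tot * frac, params.growth_law)
    )


def growth_and_epistasis_grid(
    kcat_range: Sequence[float],
    km_range: Sequence[float],
    backgrounds: Sequence[str],
    params: ModelParams,
    wt_background: str = "WT",
) -> dict[str, dict[str, np.ndarray]]:
    """Simulated growth and epistasis landscapes over DHFR kinetic space.

    For each TYMS background, evaluates growth on the (kcat, Km) grid and
    the epistasis matrix relative to the reference background
    (``epsilon = g_bg - g_wt`` elementwise).  Rows index ``kcat_range``,
    columns ``km_range``.
    """
    kcat = np.asarray(kcat_range, dtype=float)
    km = np.asarray(km_range, dtype=float)
    if kcat.size == 0 or km.size == 0:
        raise ValueError("kcat_range and km_range must be non-empty")
    if np.any(kcat <= 0) or np.any(km <= 0):
        raise ValueError("grid values must be positive")
    kk, mm = np.meshgrid(kcat, km, indexing="ij")
    g_wt = _predict_growth_arrays(kk, mm, wt_background, params)
    out: dict[str, dict[str, np.ndarray]] = {}
    for bg in backgrounds:
        g = (
            g_wt
            if bg == wt_background
            else _predict_growth_arrays(kk, mm, bg, params)
        )
        out[bg] = {"growth": g, "epistasis": g - g_wt}
    return out


def neutral_fraction_grid(
    mutant_kinetics: Iterable[EnzymeKinetics],
    tyms_kcat_grid: Sequence[float],
    tyms_km_grid: Sequence[float],
    params: ModelParams,
    threshold: float = 0.9,
    tyms_conc: float | None = None,
) -> np.ndarray:
    """Fraction of DHFR mutants neutral (growth >= threshold) vs TYMS activity.

    Scans TYMS kcat (rows) and Km (columns); each cell holds the fraction
    of the supplied DHFR mutant set whose predicted growth meets the
    threshold.  The TYMS concentration defaults to the WT background's.
    """
    mutants = list(mutant_kinetics)
    if not mutants:
        raise ValueError("mutant set must be non-empty")
    t_kcat = np.asarray(tyms_kcat_grid, dtype=float)
    t_km = np.asarray(tyms_km_grid, dtype=float)
    conc = params.tyms_concs["WT"] if tyms_conc is None else tyms_conc
    d_kcat = np.array([m.kcat for m in mutants])
    d_km = np.array([m.km for m in mutants])
    frac = np.empty((t_kcat.size, t_km.size))
    for i, tk in enumerate(t_kcat):
        for j, tm in enumerate(t_km):
            x = _gk_fraction(
                params.dhfr_conc * d_kcat,
                conc * tk,
                d_km / params.fol_tot,
                tm / params.fol_tot,
            )
            g = growth_from_thf(
                params.thf_scale * params.fol_tot * x, params.growth_law
            )
            frac[i, j] = np.mean(g >= threshold)
    return frac


def log_spaced_multiplier_grid(n: int = 50, lo: float = -2.0, hi: float = 2.0):
    """Natural-log-spaced multiplier grid exp(linspace(lo, hi, n)).

    Used to scan TYMS kcat/Km around their WT values on Fig-style
    tolerance maps.
    """
    return np.exp(np.linspace(lo, hi, n))
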