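"""Carbohydrate-solubilization accounting and recalcitrant-fraction kinetics.

This module implements the quantitative core of steady-state digester
analysis for a particulate lignocellulosic feedstock:

* the fractional carbohydrate solubilization statistic
  ``FCS = (mass_in - mass_out) / mass_in`` on a monomer-equivalent basis;
* the first-order-in-accessible-substrate rate law

  .. math:: r = k\\,(C - C_0 f_r)

  where ``C`` is the unutilized carbohydrate concentration (g monomer
  equivalent/L), ``C0`` the carbohydrate concentration entering the
  reactor, ``k`` a first-order rate constant (1/day) and ``f_r`` the
  fraction of entering carbohydrate that is recalcitrant at infinite
  residence time;
* the glucan–xylan co-solubilization regression; and
* mass / electron (COD) balance closure for the reactor streams.

The fit is exposed both as plain functions mirroring a lab notebook
(:func:`fit_recalcitrant_first_order`) and as a statsmodels-style model
object (:class:`SolubilizationKinetics`) whose :meth:`~SolubilizationKinetics.fit`
returns a results object with parameter covariances, diagnostics and a
``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import (
    DomainError,
    FitError,
    MeasurementInconsistencyError,
    NonPhysicalFitError,
)

__all__ = [
    "FeedstockComposition",
    "SteadyStateObservation",
    "KineticPoint",
    "KineticFit",
    "BalanceStreams",
    "SWITCHGRASS_MIDSEASON",
    "COD_PER_G_CH4",
    "feed_carbohydrate_concentration",
    "compute_fcs",
    "steady_state_point",
    "points_from_observations",
    "fit_recalcitrant_first_order",
    "predict_steady_state_fcs",
    "glucan_xylan_regression",
    "cod_recovery",
    "mass_recovery",
    "dissolved_co2_concentration",
    "SolubilizationKinetics",
    "SolubilizationKineticsResults",
]

#: g COD carried per g CH4 (full-oxidation stoichiometry CH4 + 2 O2).
COD_PER_G_CH4 = 4.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeedstockComposition:
    """Monomer-equivalent carbohydrate fractions and COD of the feed.

    Fractions are g per g of as-is (wet) solids; carbohydrate is expressed
    as glucose / xylose / arabinose monomer equivalents.
    """

    glucan_frac: float
    xylan_frac: float
    arabinan_frac: float
    moisture_frac: float = 0.0
    ash_frac: float = 0.0
    cod_per_gram: float = 1.0

    def __post_init__(self) -> None:
        for name in ("glucan_frac", "xylan_frac", "arabinan_frac",
                     "moisture_frac", "ash_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DomainError(f"{name}={v!r} outside [0, 1]")
        total = (self.glucan_frac + self.xylan_frac + self.arabinan_frac
                 + self.ash_frac + self.moisture_frac)
        if total > 1.0 + 1e-9:
            raise DomainError(
                f"carbohydrate + ash + moisture fractions sum to {total:.4f} > 1")
        if self.cod_per_gram <= 0:
            raise DomainError(f"cod_per_gram={self.cod_per_gram!r} must be > 0")

    @property
    def carbohydrate_frac(self) -> float:
        """Total carbohydrate fraction (g monomer equivalent / g as-is)."""
        return self.glucan_frac + self.xylan_frac + self.arabinan_frac


#: Mid-season switchgrass, 0.5 mm milled, on an as-is basis (6.05 % moisture).
SWITCHGRASS_MIDSEASON = FeedstockComposition(
    glucan_frac=0.306,
    xylan_frac=0.229,
    arabinan_frac=0.0407,
    moisture_frac=0.0605,
    ash_frac=0.0592,
    cod_per_gram=1.22,
)


@dataclass(frozen=True)
class SteadyStateObservation:
    """One steady-state operating point of a semi-continuously fed reactor."""

    rt_days: float
    fcs_total: float
    fcs_glucan: float = float("nan")
    fcs_xylan: float = float("nan")
    ch4_frac: float = float("nan")
    co2_frac: float = float("nan")
    vfa_g_per_l: float = float("nan")
    ph: float = float("nan")
    reactor_id: str = ""

    def __post_init__(self) -> None:
        if not self.rt_days > 0:
            raise DomainError(f"rt_days={self.rt_days!r} must be > 0")
        for name in ("fcs_total", "fcs_glucan", "fcs_xylan"):
            v = getattr(self, name)
            if not math.isnan(v) and not 0.0 <= v <= 1.0:
                raise DomainError(f"{name}={v!r} outside [0, 1]")
        if (not math.isnan(self.ch4_frac) and not math.isnan(self.co2_frac)
                and self.ch4_frac + self.co2_frac > 1.0 + 1e-9):
            raise DomainError("ch4_frac + co2_frac > 1")


@dataclass(frozen=True)
class KineticPoint:
    """A (C, r) pair: unutilized carbohydrate vs. solubilization rate."""

    c_unutilized: float
    rate: float
    rt_days: float

    def __post_init__(self) -> None:
        if self.c_unutilized < 0:
            raise DomainError(f"c_unutilized={self.c_unutilized!r} must be >= 0")
        if self.rate < 0:
            raise DomainError(f"rate={self.rate!r} must be >= 0")


@dataclass(frozen=True)
class KineticFit:
    """Fitted rate constant and recalcitrant fraction with uncertainties."""

    k: float
    f_r: float
    k_se: float
    f_r_se: float
    c0: float
    r_squared: float

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise NonPhysicalFitError(f"k={self.k!r} must be > 0")
        if not 0.0 <= self.f_r < 1.0:
            raise NonPhysicalFitError(f"f_r={self.f_r!r} outside [0, 1)")
        if not 0.0 <= self.r_squared <= 1.0:
            raise NonPhysicalFitError(
                f"r_squared={self.r_squared!r} outside [0, 1]")


@dataclass(frozen=True)
class BalanceStreams:
    """Daily mass flows in and out of the reactor used for balance closure."""

    feed_solids: float
    feed_cod: float
    ch4_mass: float
    co2_gas_mass: float
    co2_dissolved_mass: float
    slurry_dry_mass: float
    slurry_cod: float

    def __post_init__(self) -> None:
        for name in ("feed_solids", "feed_cod", "ch4_mass", "co2_gas_mass",
                     "co2_dissolved_mass", "slurry_dry_mass", "slurry_cod"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")


# ---------------------------------------------------------------------------
# solubilization accounting
# ---------------------------------------------------------------------------

def feed_carbohydrate_concentration(comp: FeedstockComposition,
                                    solids_loading: float) -> float:
    """Carbohydrate concentration C0 entering the reactor (g monomer eq./L).

    Parameters
    ----------
    comp
        Feedstock composition on an as-is basis.
    solids_loading
        As-is solids loading of the feed, g/L.
    """
    if solids_loading <= 0:
        raise DomainError(f"solids_loading={solids_loading!r} must be > 0")
    return comp.carbohydrate_frac * solids_loading


def compute_fcs(mass_initial: float, mass_final: float) -> float:
    """Fractional carbohydrate solubilization, (initial − final) / initial.

    Both masses are on a soluble monomer-equivalent basis.  A residual
    exceeding the input is a measurement inconsistency and raises rather
    than silently clipping to 0 — a negative FCS hides an assay problem.
    """
    if mass_initial <= 0:
        raise DomainError(f"mass_initial={mass_initial!r} must be > 0")
    if mass_final < 0:
        raise DomainError(f"mass_final={mass_final!r} must be >= 0")
    if mass_final > mass_initial:
        raise MeasurementInconsistencyError(mass_initial, mass_final)
    return (mass_initial - mass_final) / mass_initial


def steady_state_point(obs: SteadyStateObservation, c0: float) -> KineticPoint:
    """Convert a steady-state observation into a (C, r) kinetic point.

    At steady state the unutilized concentration is ``C = C0 (1 − FCS)``
    and the volumetric solubilization rate is ``r = C0 · FCS / RT``.
    """
    if c0 <= 0:
        raise DomainError(f"c0={c0!r} must be > 0")
    if obs.rt_days <= 0:  # unreachable through the dataclass, kept for raw use
        raise DomainError("rt_days must be > 0")
    c = c0 * (1.0 - obs.fcs_total)
    r = c0 * obs.fcs_total / obs.rt_days
    return KineticPoint(c_unutilized=c, rate=r, rt_days=obs.rt_days)


def points_from_observations(observations: Iterable[SteadyStateObservation],
                             c0: float,
                             by_rt_mean: bool = False) -> list[KineticPoint]:
    """Build kinetic points from observations, optionally averaging per RT.

    ``by_rt_mean=True`` averages FCS across reactors at each residence time
    before converting, the entry mode used when per-reactor replication is
    summarized into residence-time means.
    """
    obs = list(observations)
    if not by_rt_mean:
        return [steady_state_point(o, c0) for o in obs]
    by_rt: dict[float, list[float]] = {}
    for o in obs:
        by_rt.setdefault(o.rt_days, []).append(o.fcs_total)
    points = []
    for rt in sorted(by_rt, reverse=True):
        mean_fcs = float(np.mean(by_rt[rt]))
        points.append(steady_state_point(
            SteadyStateObservation(rt_days=rt, fcs_total=mean_fcs), c0))
    return points


def predict_steady_state_fcs(fit: "KineticFit | tuple[float, float]",
                             rt_days) -> "float | np.ndarray":
    """Closed-form steady-state FCS of a continuously washed-out reactor.

    Solving ``k (C − C0 f_r) = (C0 − C) / RT`` for C and converting gives

    .. math:: FCS = (1 - f_r)\\,\\frac{k\\,RT}{1 + k\\,RT}

    strictly increasing in RT and k, approaching ``1 − f_r`` as RT → ∞.
    Accepts a :class:`KineticFit` or a bare ``(k, f_r)`` pair; ``rt_days``
    may be a scalar or array.
    """
    if isinstance(fit, KineticFit):
        k, f_r = fit.k, fit.f_r
    else:
        k, f_r = fit
    rt = np.asarray(rt_days, dtype=float)
    if np.any(rt <= 0):
        raise DomainError("rt_days must be > 0")
    out = (1.0 - f_r) * k * rt / (1.0 + k * rt)
    return float(out) if np.isscalar(rt_days) else out


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class SolubilizationKinetics:
    """First-order accessible-substrate solubilization model, r = k (C − C0 f_r).

    A linear model in disguise: ordinary least squares of the rate r on the
    unutilized concentration C gives slope ``k`` and intercept
    ``−k C0 f_r``, from which ``f_r = −intercept / (k C0)``.

    Parameters
    ----------
    points
        Steady-state kinetic points, at least three with distinct C.
    c0
        Feed carbohydrate concentration, g monomer equivalent/L.

    Examples
    --------
    >>> model = SolubilizationKinetics.from_fcs(
    ...     rt_days=[20, 10, 5, 3.3], fcs=[0.711, 0.654, 0.581, 0.538],
    ...     c0=17.3)
    >>> res = model.fit()
    >>> round(res.k, 3), round(res.f_r, 3)
    (0.725, 0.248)
    """

    def __init__(self, points: Sequence[KineticPoint], c0: float):
        if c0 <= 0:
            raise DomainError(f"c0={c0!r} must be > 0")
        self.points = list(points)
        self.c0 = float(c0)
        if len(self.points) < 3:
            raise FitError(
                f"need >= 3 kinetic points, got {len(self.points)}")
        c = np.array([p.c_unutilized for p in self.points])
        if np.ptp(c) < 1e-12:
            raise FitError("all points share one C value; slope is undefined")
        self.endog = np.array([p.rate for p in self.points])
        self.exog = sm.add_constant(c)

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_fcs(cls, rt_days: Sequence[float], fcs: Sequence[float],
                 c0: float) -> "SolubilizationKinetics":
        """Build the model directly from (RT, FCS) pairs."""
        obs = [SteadyStateObservation(rt_days=rt, fcs_total=f)
               for rt, f in zip(rt_days, fcs, strict=True)]
        return cls(points_from_observations(obs, c0), c0)

    @classmethod
    def from_observations(cls, observations: Iterable[SteadyStateObservation],
                          c0: float,
                          by_rt_mean: bool = False) -> "SolubilizationKinetics":
        return cls(points_from_observations(observations, c0, by_rt_mean), c0)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, c0: float,
                       by_rt_mean: bool = False) -> "SolubilizationKinetics":
        """Build from a steady-state table with rt_days / fcs_total columns."""
        obs = [SteadyStateObservation(
                   rt_days=float(row["rt_days"]),
                   fcs_total=float(row["fcs_total"]),
                   reactor_id=str(row.get("reactor_id", "")))
               for _, row in df.iterrows()]
        return cls.from_observations(obs, c0, by_rt_mean=by_rt_mean)

    # -- estimation ---------------------------------------------------------

    def fit(self) -> "SolubilizationKineticsResults":
        """Unweighted OLS of r on C; delta-method standard error for f_r."""
        ols = sm.OLS(self.endog, self.exog).fit()
        intercept, slope = ols.params  # exog columns: const, C
        if slope <= 0:
            raise NonPhysicalFitError(
                f"fitted slope {slope:.4g} <= 0: rate must increase with C")
        k = float(slope)
        f_r = float(-intercept / (k * self.c0))
        cov = np.asarray(ols.cov_params())  # order (const, C)
        k_se = float(np.sqrt(cov[1, 1]))
        # f_r = -b/(a c0) with a=slope, b=intercept:
        # df/db = -1/(a c0), df/da = b/(a^2 c0)
        grad = np.array([-1.0 / (k * self.c0),
                         intercept / (k ** 2 * self.c0)])
        f_r_var = float(grad @ cov @ grad)
        f_r_se = math.sqrt(max(f_r_var, 0.0))
        return SolubilizationKineticsResults(
            model=self, ols_results=ols, k=k, f_r=f_r,
            k_se=k_se, f_r_se=f_r_se, r_squared=float(ols.rsquared))


@dataclass
class SolubilizationKineticsResults:
    """Results of fitting :class:`SolubilizationKinetics`."""

    model: SolubilizationKinetics
    ols_results: object = field(repr=False)
    k: float = 0.0
    f_r: float = 0.0
    k_se: float = 0.0
    f_r_se: float = 0.0
    r_squared: float = 0.0

    @property
    def params(self) -> dict[str, float]:
        return {"k": self.k, "f_r": self.f_r}

    @property
    def bse(self) -> dict[str, float]:
        return {"k": self.k_se, "f_r": self.f_r_se}

    @property
    def c0(self) -> float:
        return self.model.c0

    @property
    def nobs(self) -> int:
        return len(self.model.points)

    @property
    def fittedvalues(self) -> np.ndarray:
        return np.asarray(self.ols_results.fittedvalues)

    @property
    def resid(self) -> np.ndarray:
        return np.asarray(self.ols_results.resid)

    @property
    def kinetic_fit(self) -> KineticFit:
        return KineticFit(k=self.k, f_r=self.f_r, k_se=self.k_se,
                          f_r_se=self.f_r_se, c0=self.c0,
                          r_squared=self.r_squared)

    def predict(self, rt_days) -> "float | np.ndarray":
        """Steady-state FCS at the given residence time(s), closed form."""
        return predict_steady_state_fcs((self.k, self.f_r), rt_days)

    def summary(self) -> str:
        lines = [
            "Recalcitrant-fraction first-order solubilization fit",
            "====================================================",
            f"  n points          : {self.nobs}",
            f"  C0 (g/L)          : {self.c0:.3f}",
            f"  k (1/day)         : {self.k:.4f} +/- {self.k_se:.4f}",
            f"  f_r (fraction)    : {self.f_r:.4f} +/- {self.f_r_se:.4f}",
            f"  f_r (%)           : {100 * self.f_r:.1f} +/- {100 * self.f_r_se:.1f}",
            f"  R-squared         : {self.r_squared:.4f}",
            f"  FCS limit (RT→∞)  : {1 - self.f_r:.4f}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-ready report: parameters, uncertainties, per-point residuals."""
        return {
            "k": self.k, "k_se": self.k_se,
            "f_r": self.f_r, "f_r_se": self.f_r_se,
            "c0": self.c0, "r_squared": self.r_squared,
            "n_points": self.nobs,
            "points": [
                {"rt_days": p.rt_days, "c_unutilized": p.c_unutilized,
                 "rate": p.rate, "fitted_rate": float(f), "residual": float(r)}
                for p, f, r in zip(self.model.points, self.fittedvalues,
                                   self.resid)
            ],
        }

    def plot(self, ax=None):
        """Scatter of (C, r) with the fitted line (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = np.array([p.c_unutilized for p in self.model.points])
        r = np.array([p.rate for p in self.model.points])
        ax.plot(c, r, "ko", label="steady states")
        grid = np.linspace(0, c.max() * 1.05, 50)
        ax.plot(grid, self.k * (grid - self.c0 * self.f_r), "k-",
                label=f"r = {self.k:.3f} (C − {self.c0:.1f}·{self.f_r:.3f})")
        ax.set_xlabel("unutilized carbohydrate C (g/L)")
        ax.set_ylabel("solubilization rate r (g/L/day)")
        ax.legend()
        return ax


def fit_recalcitrant_first_order(points: Sequence[KineticPoint],
                                 c0: float) -> KineticFit:
    """OLS fit of the rate law r = k (C − C0 f_r); see :class:`SolubilizationKinetics`."""
    return SolubilizationKinetics(points, c0).fit().kinetic_fit


# ---------------------------------------------------------------------------
# glucan–xylan co-solubilization
# ---------------------------------------------------------------------------

def glucan_xylan_regression(pairs: Sequence[tuple[float, float]]
                            ) -> tuple[float, float, float]:
    """OLS of xylan solubilization on glucan solubilization.

    Returns ``(slope, intercept, r_squared)`` for ``FCS_x = slope·FCS_g +
    intercept`` across samples.
    """
    if len(pairs) < 3:
        raise FitError(f"need >= 3 (FCS_g, FCS_x) pairs, got {len(pairs)}")
    g = np.array([p[0] for p in pairs], dtype=float)
    x = np.array([p[1] for p in pairs], dtype=float)
    if np.ptp(g) < 1e-12:
        raise FitError("degenerate FCS_g values; slope is undefined")
    ols = sm.OLS(x, sm.add_constant(g)).fit()
    intercept, slope = ols.params
    return float(slope), float(intercept), float(ols.rsquared)


# ---------------------------------------------------------------------------
# mass and electron balances
# ---------------------------------------------------------------------------

def cod_recovery(streams: BalanceStreams) -> float:
    """Electron balance closure, percent.

    COD leaving as methane (4 g COD/g CH4) plus slurry COD, relative to the
    COD fed.  CO2 carries no COD.
    """
    if streams.feed_cod <= 0:
        raise DomainError("feed_cod must be > 0")
    out = COD_PER_G_CH4 * streams.ch4_mass + streams.slurry_cod
    return 100.0 * out / streams.feed_cod


def mass_recovery(streams: BalanceStreams) -> float:
    """Dry-mass balance closure, percent.

    Methane, gaseous CO2, dissolved CO2 and freeze-dried slurry leaving,
    relative to the dry feed solids added per day.
    """
    if streams.feed_solids <= 0:
        raise DomainError("feed_solids must be > 0")
    out = (streams.ch4_mass + streams.co2_gas_mass
           + streams.co2_dissolved_mass + streams.slurry_dry_mass)
    return 100.0 * out / streams.feed_solids


#: Henry constant for CO2 in water at 55 degC, mol/(L atm).
HENRY_CO2_55C = 0.0164
#: First carbonate dissociation constant near 55 degC (pKa1 ~ 6.30).
KA1_CO2_55C = 10 ** -6.30
_MW_CO2 = 44.01


def dissolved_co2_concentration(co2_frac: float, ph: float,
                                henry_const: float = HENRY_CO2_55C,
                                ka1: float = KA1_CO2_55C,
                                total_pressure_atm: float = 1.0) -> float:
    """Dissolved inorganic carbon as g CO2-equivalent per liter of broth.

    A simplified Henry's-law estimate: CO2(aq) in equilibrium with the
    headspace partial pressure, augmented by bicarbonate through the first
    dissociation at the measured pH.  The second dissociation is negligible
    below pH ~8 and is ignored.
    """
    if not 0.0 <= co2_frac <= 1.0:
        raise DomainError(f"co2_frac={co2_frac!r} outside [0, 1]")
    if ph <= 0:
        raise DomainError(f"ph={ph!r} must be > 0")
    p_co2 = co2_frac * total_pressure_atm
    co2_aq = henry_const * p_co2                     # mol/L
    total = co2_aq * (1.0 + ka1 / (10 ** -ph))       # + bicarbonate
    return total * _MW_CO2
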