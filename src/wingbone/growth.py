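"""Growth-curve metrics and field metabolic rate standardization.

Sigmoidal growth models (logistic, Gompertz, von Bertalanffy in its
mass form) are summarized at the age of growth inflection by two
quantities: maximum growth rate (g/day) and body mass at inflection (g).
Their ratio is the relative growth rate (RGR, 1/day), a size-standardized
measure of how fast a species grows.  Field metabolic rate (FMR, kJ/day)
is standardized by body mass; both RGR and mass-specific FMR are
log10-transformed downstream for scaling regressions.

Closed forms at the inflection point (mass m(t), asymptote A, growth
constant K per day, location t0):

* logistic    m = A / (1 + e^(-K(t-t0)))    -> m* = A/2,   max dm/dt = KA/4
* Gompertz    m = A exp(-e^(-K(t-t0)))      -> m* = A/e,   max dm/dt = KA/e
* von Bertalanffy  m = A (1 - e^(-K(t-t0)))^3
                                            -> m* = 8A/27, max dm/dt = 4KA/9
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

GROWTH_MODELS = ("logistic", "gompertz", "von_bertalanffy")


@dataclass
class GrowthCurveFit:
    model: str
    A: float          # asymptotic mass, g
    K: float          # growth constant, 1/day
    t0: float         # location parameter, day
    residual_sd: float | None = None

    def __post_init__(self) -> None:
        if self.model not in GROWTH_MODELS:
            raise ValueError(f"unsupported growth model {self.model!r}")
        if self.A <= 0 or self.K <= 0:
            raise ValueError("A and K must be positive")


@dataclass
class GrowthMetrics:
    max_rate: float          # g/day
    inflection_mass: float   # g
    rgr: float               # 1/day
    asymptotic_mass: float   # g
    log10_rgr: float = field(init=False)
    log10_asymptotic_mass: float = field(init=False)

    def __post_init__(self) -> None:
        if self.rgr <= 0:
            raise ValueError("RGR must be positive")
        self.log10_rgr = math.log10(self.rgr)
        self.log10_asymptotic_mass = math.log10(self.asymptotic_mass)


@dataclass
class FMRRecord:
    species: str
    mass_g: float
    fmr_kj_day: float
    mass_specific_fmr: float = field(init=False)
    log10_mass: float = field(init=False)
    log10_mass_specific_fmr: float = field(init=False)

    def __post_init__(self) -> None:
        if self.mass_g <= 0 or self.fmr_kj_day <= 0:
            raise ValueError("mass and FMR must be positive")
        self.mass_specific_fmr = self.fmr_kj_day / self.mass_g
        self.log10_mass = math.log10(self.mass_g)
        self.log10_mass_specific_fmr = math.log10(self.mass_specific_fmr)


def growth_curve(model: str, t: np.ndarray, A: float, K: float, t0: float) -> np.ndarray:
    """Evaluate a growth model at ages ``t`` (days)."""
    t = np.asarray(t, float)
    if model == "logistic":
        return A / (1.0 + np.exp(-K * (t - t0)))
    if model == "gompertz":
        return A * np.exp(-np.exp(-K * (t - t0)))
    if model == "von_bertalanffy":
        return A * (1.0 - np.exp(-K * (t - t0))) ** 3
    raise ValueError(f"unsupported growth model {model!r}")


def inflection_age(fit: GrowthCurveFit) -> float:
    """Age (days) at which the growth rate is maximal."""
    if fit.model == "logistic":
        return fit.t0
    if fit.model == "gompertz":
        return fit.t0
    # von Bertalanffy: maximum where e^(-K(t-t0)) = 1/3
    return fit.t0 + math.log(3.0) / fit.K


def inflection_metrics(fit: GrowthCurveFit) -> GrowthMetrics:
    """Maximum growth rate, mass at inflection, and RGR from a fitted curve."""
    if fit.model == "logistic":
        mass, rate = fit.A / 2.0, fit.K * fit.A / 4.0
    elif fit.model == "gompertz":
        mass, rate = fit.A / math.e, fit.K * fit.A / math.e
    elif fit.model == "von_bertalanffy":
        mass, rate = 8.0 * fit.A / 27.0, 4.0 * fit.K * fit.A / 9.0
    else:  # pragma: no cover - guarded by GrowthCurveFit
        raise ValueError(f"unsupported growth model {fit.model!r}")
    return GrowthMetrics(max_rate=rate, inflection_mass=mass, rgr=rate / mass,
                         asymptotic_mass=fit.A)


def relative_growth_rate(metrics: GrowthMetrics) -> float:
    """RGR = maximum growth rate / mass at inflection (1/day)."""
    if metrics.inflection_mass <= 0:
        raise ValueError("inflection mass must be positive")
    return metrics.max_rate / metrics.inflection_mass


def fit_growth_curve(ages: np.ndarray, masses: np.ndarray, model: str) -> GrowthCurveFit:
    """Nonlinear least-squares fit of a growth model to an (age, mass) series."""
    ages = np.asarray(ages, float)
    masses = np.asarray(masses, float)
    if ages.size < 5:
        raise ValueError("need at least 5 time points spanning the inflection")
    if model not in GROWTH_MODELS:
        raise ValueError(f"unsupported growth model {model!r}")
    a0 = 1.05 * float(masses.max())
    span = float(ages.max() - ages.min()) or 1.0
    k0 = 4.0 / span
    t00 = float(ages[int(np.argmin(np.abs(masses - a0 / 2.0)))])
    p0 = (a0, k0, t00)
    try:
        popt, _ = curve_fit(
            lambda t, A, K, t0: growth_curve(model, t, A, K, t0),
            ages, masses, p0=p0,
            bounds=([1e-9, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as err:
        raise RuntimeError(
            f"growth-curve fit did not converge (model={model}, start={p0})"
        ) from err
    resid = masses - growth_curve(model, ages, *popt)
    sd = float(np.sqrt(np.mean(resid**2)))
    return GrowthCurveFit(model=model, A=float(popt[0]), K=float(popt[1]),
                          t0=float(popt[2]), residual_sd=sd)


def mass_specific_fmr(species: str, mass_g: float, fmr_kj_day: float) -> FMRRecord:
    """Standardize a field metabolic rate by body mass."""
    return FMRRecord(species=species, mass_g=mass_g, fmr_kj_day=fmr_kj_day)
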