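"""Parametric cause-specific hazard models and scenario calibration.

The simulated disease has two competing causes of death:

* **Cancer-specific mortality** — a Weibull-type baseline hazard with a
  log-linear effect of standardised age at diagnosis whose strength decays
  with time since diagnosis (an ``age x log(t)`` interaction), and a
  proportional-hazards effect of the binary prognostic Factor X:

      lambda_c(t | age, x) = (k/s) (t/s)^(k-1)
                             * exp{(b0 + b1 log t) z(age) + g x},

  with z(age) = (age - 70)/15.  Collecting powers of t this is a power-law
  hazard C * t^(p-1) with p = k + b1 z(age), so the cumulative hazard and
  its inverse are closed-form; adaptive quadrature is available as a
  cross-check.

* **Other-cause mortality** — a Gompertz hazard in *attained* age
  (age + t), optionally multiplied by a Factor-X hazard ratio:

      lambda_o(t | age, x) = a exp{b (age + t - 70)} exp(g_o x).

Nine scenarios (A-I) combine three cancer-survival levels (5-year net
survival of roughly 21%, 36% and 70%) with Factor-X hazard ratios of 1.5
or 3 on cancer mortality and 1 or 3 on other-cause mortality.  The
baseline Weibull scale of each scenario is calibrated by root-finding so
that the *marginal* 5-year net survival — averaged over the truncated
normal age distribution and the Factor-X mixture — hits the scenario
target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import yaml
from scipy import integrate, optimize
from scipy.stats import truncnorm

from .netsurv import Lifetable

AGE_CENTER = 70.0
AGE_SCALE = 15.0
AGE_MIN = 18.0
AGE_MAX = 100.0


class CalibrationError(RuntimeError):
    pass


class QuadratureError(RuntimeError):
    pass


def standardise_age(age):
    """Age in standard-deviation units around the population mean."""
    return (np.asarray(age, dtype=float) - AGE_CENTER) / AGE_SCALE


def age_distribution(age_mean: float = AGE_CENTER, age_sd: float = AGE_SCALE,
                     age_min: float = AGE_MIN, age_max: float = AGE_MAX):
    """The truncated-normal age-at-diagnosis distribution."""
    a, b = (age_min - age_mean) / age_sd, (age_max - age_mean) / age_sd
    return truncnorm(a, b, loc=age_mean, scale=age_sd)


@dataclass(frozen=True)
class CancerHazardSpec:
    """Cancer-specific hazard: Weibull baseline, decaying age effect, X PH effect."""

    baseline_shape: float = 0.9
    baseline_scale: float = 1.0
    beta_age0: float = 0.3
    beta_age1: float = -0.1
    log_hr_x: float = math.log(1.5)

    def __post_init__(self) -> None:
        if self.baseline_shape <= 0 or self.baseline_scale <= 0:
            raise ValueError("Weibull shape and scale must be positive")
        # the effective power-law exponent p = k + b1*z must stay positive
        # over the supported age range, otherwise the cumulative hazard
        # diverges at t = 0
        for age in (AGE_MIN, AGE_MAX):
            p = self.baseline_shape + self.beta_age1 * standardise_age(age)
            if p <= 0:
                raise ValueError(
                    f"time exponent {p:.3f} non-positive at age {age}; "
                    "reduce |beta_age1| or increase baseline_shape"
                )

    def _power(self, age):
        return self.baseline_shape + self.beta_age1 * standardise_age(age)

    def _loglin(self, age, x):
        return self.beta_age0 * standardise_age(age) + self.log_hr_x * np.asarray(x)

    def hazard(self, t, age, x):
        """lambda_c(t | age, x) per year; requires t > 0."""
        t = np.asarray(t, dtype=float)
        if np.any(t <= 0):
            raise ValueError("cancer hazard defined for t > 0 only")
        k, s = self.baseline_shape, self.baseline_scale
        base = (k / s) * (t / s) ** (k - 1)
        tdep = np.exp(self.beta_age1 * np.log(t) * standardise_age(age))
        return base * tdep * np.exp(self._loglin(age, x))

    def cumulative_hazard(self, t, age, x, method: str = "closed_form"):
        """Lambda_c(t) = C t^p / p with p = k + b1 z(age); Lambda_c(0) = 0."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("cumulative hazard requires t >= 0")
        if method == "closed_form":
            k, s = self.baseline_shape, self.baseline_scale
            p = self._power(age)
            coef = (k / s**k) * np.exp(self._loglin(age, x))
            with np.errstate(divide="ignore"):
                out = np.where(t > 0, coef * t**p / p, 0.0)
            return out if out.ndim else float(out)
        if method == "quadrature":
            return _quad_cumhaz(lambda u: self.hazard(u, age, x), t)
        raise ValueError(f"unknown method {method!r}")

    def inverse_cumulative_hazard(self, target, age, x):
        """Solve Lambda_c(t) = target for t (closed form, vectorised)."""
        target = np.asarray(target, dtype=float)
        k, s = self.baseline_shape, self.baseline_scale
        p = self._power(age)
        coef = (k / s**k) * np.exp(self._loglin(age, x))
        return (target * p / coef) ** (1.0 / p)


@dataclass(frozen=True)
class OtherCauseHazardSpec:
    """Other-cause mortality: Gompertz in attained age, optional X effect.

    Defaults put the rate at attained age 70 near general-population
    all-cause mortality (~0.02/year) doubling roughly every 8 years
    (shape ~ log(2)/8 ~ 0.085).
    """

    gompertz_rate: float = 0.02
    gompertz_shape: float = 0.085
    log_hr_x: float = 0.0

    def __post_init__(self) -> None:
        if self.gompertz_rate <= 0:
            raise ValueError("gompertz_rate must be positive")

    def hazard(self, t, age, x):
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("other-cause hazard requires t >= 0")
        attained = np.asarray(age, dtype=float) + t
        return (self.gompertz_rate
                * np.exp(self.gompertz_shape * (attained - AGE_CENTER))
                * np.exp(self.log_hr_x * np.asarray(x)))

    def cumulative_hazard(self, t, age, x, method: str = "closed_form"):
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("cumulative hazard requires t >= 0")
        if method == "quadrature":
            return _quad_cumhaz(lambda u: self.hazard(u, age, x), t)
        if method != "closed_form":
            raise ValueError(f"unknown method {method!r}")
        b = self.gompertz_shape
        level = (self.gompertz_rate
                 * np.exp(self.gompertz_shape * (np.asarray(age, float) - AGE_CENTER))
                 * np.exp(self.log_hr_x * np.asarray(x)))
        if abs(b) < 1e-12:
            out = level * t
        else:
            out = level * np.expm1(b * t) / b
        return out if np.ndim(out) else float(out)

    def inverse_cumulative_hazard(self, target, age, x):
        """Solve Lambda_o(t) = target for t (closed form, vectorised)."""
        target = np.asarray(target, dtype=float)
        b = self.gompertz_shape
        level = (self.gompertz_rate
                 * np.exp(self.gompertz_shape * (np.asarray(age, float) - AGE_CENTER))
                 * np.exp(self.log_hr_x * np.asarray(x)))
        if abs(b) < 1e-12:
            return target / level
        arg = target * b / level
        # arg > -1 always for b > 0; log1p handles small arguments accurately
        return np.log1p(arg) / b


def _quad_cumhaz(hazard, t):
    t = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.empty_like(t)
    for i, ti in enumerate(t):
        if ti == 0:
            out[i] = 0.0
            continue
        val, err = integrate.quad(hazard, 0.0, ti, limit=200, epsrel=1e-10,
                                  epsabs=1e-12)
        if not np.isfinite(val) or (val > 0 and err / val > 1e-6):
            raise QuadratureError(
                f"cumulative-hazard quadrature failed at t={ti}: "
                f"value={val}, abs err={err}"
            )
        out[i] = val
    return out if out.size > 1 else float(out[0])


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioConfig:
    """One scenario: a survival level plus Factor-X hazard ratios.

    The nine admissible combinations (A-I) pair three 5-year net-survival
    targets (0.21 low, 0.36 intermediate, 0.70 high) with hazard ratios of
    Factor X on cancer mortality (1.5 or 3) and on other-cause mortality
    (1 for A-F, 3 for G-I).
    """

    scenario_id: str
    survival_level: str
    target_5yr_net_survival: float
    hr_x_cancer: float
    hr_x_other: float
    n_cases: int = 5000
    n_replicates: int = 100
    age_mean: float = AGE_CENTER
    age_sd: float = AGE_SCALE
    p_x: float = 0.25

    def __post_init__(self) -> None:
        if not (0 < self.target_5yr_net_survival < 1):
            raise ValueError("target 5-year net survival must be in (0, 1)")
        if not (0 < self.p_x < 1):
            raise ValueError("p_x must be in (0, 1)")
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")

    def cancer_spec(self, **overrides) -> CancerHazardSpec:
        """Uncalibrated cancer hazard spec with this scenario's X effect."""
        kw = dict(log_hr_x=math.log(self.hr_x_cancer))
        kw.update(overrides)
        return CancerHazardSpec(**kw)

    def other_spec(self, **overrides) -> OtherCauseHazardSpec:
        kw = dict(log_hr_x=math.log(self.hr_x_other))
        kw.update(overrides)
        return OtherCauseHazardSpec(**kw)


def _load_scenario_table() -> dict:
    with resources.files("registrysim.data").joinpath("scenarios.yaml").open() as fh:
        return yaml.safe_load(fh)


_SCENARIO_CACHE: dict | None = None


def scenario_table() -> dict:
    global _SCENARIO_CACHE
    if _SCENARIO_CACHE is None:
        _SCENARIO_CACHE = _load_scenario_table()
    return _SCENARIO_CACHE


def scenario(scenario_id: str, **overrides) -> ScenarioConfig:
    """Look up one of the nine bundled scenarios by its letter A-I."""
    table = scenario_table()
    try:
        row = table["scenarios"][scenario_id]
    except KeyError:
        raise KeyError(f"unknown scenario {scenario_id!r}; use A-I") from None
    kw = dict(table["defaults"])
    kw.update(row)
    kw["scenario_id"] = scenario_id
    kw.update(overrides)
    return ScenarioConfig(**kw)


def all_scenarios(**overrides) -> list[ScenarioConfig]:
    return [scenario(sid, **overrides) for sid in scenario_table()["scenarios"]]


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def marginal_net_survival(spec: CancerHazardSpec, t: float, p_x: float,
                          age_mean: float = AGE_CENTER, age_sd: float = AGE_SCALE,
                          age_min: float = AGE_MIN, age_max: float = AGE_MAX,
                          n_nodes: int = 200) -> float:
    """E over (age, X) of exp(-Lambda_c(t | age, x)).

    Gauss-Legendre integration of the net-survival function against the
    truncated-normal age density, mixed over the Factor-X distribution.
    This is the quantity the scenario survival levels refer to.
    """
    nodes, wts = np.polynomial.legendre.leggauss(n_nodes)
    ages = 0.5 * (age_max - age_min) * nodes + 0.5 * (age_max + age_min)
    scale = 0.5 * (age_max - age_min)
    dens = age_distribution(age_mean, age_sd, age_min, age_max).pdf(ages)
    total = 0.0
    for x, px in ((0, 1 - p_x), (1, p_x)):
        s = np.exp(-spec.cumulative_hazard(t, ages, x))
        total += px * float(np.sum(wts * dens * s)) * scale
    return total


def calibrate_baseline(scen: ScenarioConfig, base_spec: CancerHazardSpec | None = None,
                       tol: float = 0.002, horizon: float = 5.0,
                       bracket: tuple[float, float] = (1e-3, 1e4),
                       ) -> CancerHazardSpec:
    """Root-find the Weibull baseline scale hitting the scenario's target.

    All other parameters (shape, age effects, Factor-X log-HR) are held at
    their scenario values; only ``baseline_scale`` moves.  The implied
    marginal ``horizon``-year net survival of the returned spec is within
    ``tol`` of ``scen.target_5yr_net_survival``.
    """
    spec0 = base_spec if base_spec is not None else scen.cancer_spec()
    spec0 = replace(spec0, log_hr_x=math.log(scen.hr_x_cancer))
    target = scen.target_5yr_net_survival

    def f(scale):
        s = replace(spec0, baseline_scale=scale)
        return marginal_net_survival(
            s, horizon, scen.p_x, scen.age_mean, scen.age_sd) - target

    lo, hi = bracket
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise CalibrationError(
            f"target {target} unreachable in scale bracket [{lo}, {hi}]: "
            f"f({lo})={flo:.4f}, f({hi})={fhi:.4f}"
        )
    scale = optimize.brentq(f, lo, hi, xtol=1e-10, rtol=1e-12)
    spec = replace(spec0, baseline_scale=scale)
    achieved = marginal_net_survival(spec, horizon, scen.p_x, scen.age_mean,
                                     scen.age_sd)
    if abs(achieved - target) > tol:
        raise CalibrationError(
            f"calibration landed at {achieved:.4f}, target {target:.4f}"
        )
    return spec


# ---------------------------------------------------------------------------
# Expected-mortality lifetable export
# ---------------------------------------------------------------------------

def make_lifetable(other: OtherCauseHazardSpec, p_x: float = 0.25,
                   age_min: float = AGE_MIN, age_max: float = 111.0,
                   stratify_x: bool = False):
    """Expected-mortality rates in 1-year attained-age bands.

    By default the table is marginal over Factor X at prevalence ``p_x``
    (rates mixed at each attained age) — mimicking a real registry's
    X-blind population lifetable, so that scenarios where X drives
    other-cause mortality exhibit lifetable-unexplained variation.  With
    ``stratify_x=True`` a DataFrame with an ``x`` column is returned
    instead (one stratum per X level).
    """
    import pandas as pd

    lo = np.arange(age_min, age_max)
    hi = lo + 1.0
    mid = lo + 0.5
    rate_by_x = {x: np.asarray(other.hazard(0.0, mid, x)) for x in (0, 1)}
    if stratify_x:
        frames = [
            pd.DataFrame({"age_low": lo, "age_high": hi,
                          "rate_per_year": rate_by_x[x], "x": x})
            for x in (0, 1)
        ]
        return pd.concat(frames, ignore_index=True)
    marginal = (1 - p_x) * rate_by_x[0] + p_x * rate_by_x[1]
    return Lifetable(lo, hi, marginal)


# thin functional wrappers over the spec objects ----------------------------

def cancer_hazard(spec: CancerHazardSpec, t, age, x):
    return spec.hazard(t, age, x)


def cumulative_cancer_hazard(spec: CancerHazardSpec, t, age, x,
                             method: str = "closed_form"):
    return spec.cumulative_hazard(t, age, x, method=method)


def other_cause_hazard(spec: OtherCauseHazardSpec, t, age, x):
    return spec.hazard(t, age, x)


def cumulative_other_cause_hazard(spec: OtherCauseHazardSpec, t, age, x,
                                  method: str = "closed_form"):
    return spec.cumulative_hazard(t, age, x, method=method)
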