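"""Generation of complete ("perfect-registry") cancer cohorts.

Each case gets an age at diagnosis from a truncated normal, a Factor-X
indicator, and two latent event times — death from cancer and death from
other causes — drawn by inverse-transform sampling of the cause-specific
cumulative hazards (solve Lambda(t) = -log U).  The observed outcome is
the minimum of the two latent times and an administrative censoring time;
cause of death is whichever latent time attains the minimum (exact ties,
a probability-zero event, resolve to cancer).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from . import hazards
from .hazards import CancerHazardSpec, OtherCauseHazardSpec, ScenarioConfig
from .netsurv import Lifetable, NetSurvivalEstimate, pohar_perme

#: Default administrative censoring (years since diagnosis).
ADMIN_CENSOR = 10.0
#: Working horizon for latent event times; draws beyond it count as
#: "no event before censoring".
HORIZON = 100.0

CAUSES = ("cancer", "other", "censored")

COHORT_COLUMNS = ["case_id", "age", "x", "t_cancer", "t_other",
                  "t_observed", "cause"]


@dataclass
class Cohort:
    """A complete simulated cohort plus its provenance."""

    data: pd.DataFrame
    scenario: ScenarioConfig | None = None
    seed: int | None = None
    replicate_id: int = 0
    admin_censor: float = ADMIN_CENSOR

    def __len__(self) -> int:
        return len(self.data)

    def estimation_frame(self) -> pd.DataFrame:
        """age/time/dead view consumed by the net-survival estimator."""
        return pd.DataFrame(
            {
                "age": self.data["age"].to_numpy(),
                "time": self.data["t_observed"].to_numpy(),
                "dead": (self.data["cause"] != "censored").to_numpy(),
                "x": self.data["x"].to_numpy(),
            }
        )

    def to_csv(self, path, include_latent: bool = False) -> None:
        cols = COHORT_COLUMNS if include_latent else [
            c for c in COHORT_COLUMNS if not c.startswith("t_") or c == "t_observed"
        ]
        out = self.data[cols].copy()
        out["replicate_id"] = self.replicate_id
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, scenario: ScenarioConfig | None = None) -> "Cohort":
        df = pd.read_csv(path)
        rep = int(df["replicate_id"].iloc[0]) if "replicate_id" in df else 0
        df = df.drop(columns=["replicate_id"], errors="ignore")
        for col in ("t_cancer", "t_other"):
            if col not in df:
                df[col] = np.nan
        return cls(df[COHORT_COLUMNS], scenario=scenario, replicate_id=rep)


def sample_event_time(cumhaz, u: float, t_max: float = HORIZON,
                      tol: float = 1e-8) -> tuple[float, bool]:
    """Invert a cumulative hazard at a uniform draw: solve Lambda(t) = -log u.

    Generic bracketing solver for arbitrary strictly increasing cumulative
    hazards with Lambda(0) = 0.  Returns ``(t, beyond_horizon)``; when the
    target exceeds ``Lambda(t_max)`` the event lies beyond the working
    horizon and ``(t_max, True)`` is returned.  ``u`` must be in (0, 1):
    u = 1 would demand t = 0, which is not a valid event time — reject and
    redraw upstream.
    """
    if not (0.0 < u < 1.0):
        raise ValueError("u must be strictly inside (0, 1); redraw boundary values")
    target = -np.log(u)
    lam0 = float(cumhaz(0.0))
    if abs(lam0) > 1e-12:
        raise ValueError("cumulative hazard must satisfy Lambda(0) = 0")
    lam_max = float(cumhaz(t_max))
    if lam_max < lam0:
        raise ValueError("cumulative hazard is not non-decreasing")
    if lam_max < target:
        return t_max, True
    t = optimize.brentq(lambda s: float(cumhaz(s)) - target, 0.0, t_max,
                        xtol=tol)
    return float(t), False


def _positive_uniform(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform draws on the open interval (0, 1); boundary draws are redrawn."""
    u = rng.random(n)
    bad = u <= 0.0
    while np.any(bad):
        u[bad] = rng.random(int(bad.sum()))
        bad = u <= 0.0
    return u


def simulate_cohort(scen: ScenarioConfig, cancer: CancerHazardSpec,
                    other: OtherCauseHazardSpec, seed=None, replicate_id: int = 0,
                    admin_censor: float = ADMIN_CENSOR,
                    horizon: float = HORIZON) -> Cohort:
    """Draw one complete cohort under a scenario's calibrated hazards.

    ``seed`` may be an int or a ``numpy.random.SeedSequence``; the same
    (seed, replicate_id) always reproduces the cohort bit for bit.  Latent
    times use the closed-form inverses of the two cumulative hazards
    (equivalent to :func:`sample_event_time` at its tolerance, vectorised).
    """
    if scen.n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else \
        np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    n = scen.n_cases

    age_dist = hazards.age_distribution(scen.age_mean, scen.age_sd)
    age = age_dist.ppf(_positive_uniform(rng, n))
    x = (rng.random(n) < scen.p_x).astype(np.int8)

    e_cancer = -np.log(_positive_uniform(rng, n))
    e_other = -np.log(_positive_uniform(rng, n))
    t_cancer = cancer.inverse_cumulative_hazard(e_cancer, age, x)
    t_other = other.inverse_cumulative_hazard(e_other, age, x)
    # beyond-horizon events never happen before censoring
    t_cancer = np.minimum(t_cancer, horizon)
    t_other = np.minimum(t_other, horizon)

    t_observed = np.minimum(np.minimum(t_cancer, t_other), admin_censor)
    cause = np.where(
        t_observed >= admin_censor, "censored",
        np.where(t_cancer <= t_other, "cancer", "other"),
    )
    # guard against degenerate zero times from extreme draws
    t_observed = np.maximum(t_observed, 1e-12)

    df = pd.DataFrame(
        {
            "case_id": np.arange(n, dtype=np.int64),
            "age": age,
            "x": x,
            "t_cancer": t_cancer,
            "t_other": t_other,
            "t_observed": t_observed,
            "cause": pd.Categorical(cause, categories=list(CAUSES)),
        }
    )
    seed_repr = None if isinstance(seed, np.random.SeedSequence) else seed
    return Cohort(df, scenario=scen, seed=seed_repr, replicate_id=replicate_id,
                  admin_censor=admin_censor)


def true_net_survival_curve(cohort: Cohort, lifetable: Lifetable,
                            timepoints=(1.0, 5.0), **kwargs) -> NetSurvivalEstimate:
    """Net survival of the complete cohort — the truth arm of a bias pair."""
    return pohar_perme(cohort.estimation_frame(), lifetable, timepoints, **kwargs)


def cause_specific_survival(cohort: Cohort, t: float) -> float:
    """Kaplan-Meier survival treating other-cause deaths as censoring.

    In simulated data the true cause of death is known, so cause-specific
    survival is an alternative route to net survival; used to validate the
    scenario calibration and the lifetable-based estimator.
    """
    from lifelines import KaplanMeierFitter

    df = cohort.data
    km = KaplanMeierFitter()
    km.fit(df["t_observed"], event_observed=(df["cause"] == "cancer"))
    return float(km.survival_function_at_times(t).iloc[0])
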