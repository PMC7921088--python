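"""The registration-error process: missed cases, DCI trace-back, wrong dates.

A population-based registry misses a fraction of incident cases at
diagnosis, preferentially those with the adverse prognostic Factor X.  Of
the missed cases, only those who later die of cancer surface through a
death certificate (death-certificate-notified); after the clearance
interval these become death-certificate-initiated (DCI) cases.  Trace-back
recovers an incidence date with some probability — failures become
death-certificate-only (DCO) cases, which are excluded from survival
estimation by convention.  A recovered date may be wrong (later than the
true one), shortening the recorded survival time.

Missed cases who are still alive at the end of follow-up, or who die of
other causes, are never captured.  Cause of death is assumed perfectly
recorded.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort

STATUSES = ("notified", "dci_traced", "dco", "not_captured")

#: Grid levels of the four error parameters (3 x 2 x 2 x 2 = 24 combinations).
P_MISS_LEVELS = (0.05, 0.1, 0.2)
RR_MISS_LEVELS = (1.5, 5.0)
P_TRACE_LEVELS = (0.7, 0.9)
P_WRONG_DATE_LEVELS = (0.0, 0.3)


@dataclass(frozen=True)
class ErrorConfig:
    """The four registration-error parameters.

    ``p_miss`` is by default the *marginal* probability of a case being
    missed; the per-stratum probabilities are derived from the relative
    risk ``rr_miss_x`` of being missed given Factor X by solving
    ``(1 - p_x) p0 + p_x rr p0 = p_miss``.  Set
    ``miss_is_marginal=False`` to read ``p_miss`` as the X=0 baseline
    probability instead.
    """

    p_miss: float
    rr_miss_x: float
    p_trace: float
    p_wrong_date: float
    miss_is_marginal: bool = True

    def __post_init__(self) -> None:
        for name in ("p_miss", "p_trace", "p_wrong_date"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.rr_miss_x <= 0:
            raise ValueError("rr_miss_x must be positive")

    def stratum_miss_probs(self, p_x: float) -> tuple[float, float]:
        """(P(miss | X=0), P(miss | X=1)); errors if either exceeds 1."""
        if self.miss_is_marginal:
            p0 = self.p_miss / ((1.0 - p_x) + p_x * self.rr_miss_x)
        else:
            p0 = self.p_miss
        p1 = self.rr_miss_x * p0
        if p0 > 1.0 or p1 > 1.0:
            raise ValueError(
                f"infeasible miss probabilities for (p_miss={self.p_miss}, "
                f"rr_miss_x={self.rr_miss_x}, p_x={p_x}): "
                f"P(miss|X=0)={p0:.3f}, P(miss|X=1)={p1:.3f}"
            )
        return p0, p1

    def label(self) -> str:
        return (f"miss{self.p_miss:g}_rr{self.rr_miss_x:g}"
                f"_trace{self.p_trace:g}_wrong{self.p_wrong_date:g}")


def error_grid(p_miss=P_MISS_LEVELS, rr_miss_x=RR_MISS_LEVELS,
               p_trace=P_TRACE_LEVELS,
               p_wrong_date=P_WRONG_DATE_LEVELS) -> list[ErrorConfig]:
    """The factorial grid of error combinations (24 at default levels)."""
    return [
        ErrorConfig(pm, rr, pt, pw)
        for pm, rr, pt, pw in itertools.product(p_miss, rr_miss_x, p_trace,
                                                p_wrong_date)
    ]


@dataclass
class RegistryDataset:
    """A cohort as seen through the registration-error process.

    ``data`` carries the cohort columns plus per-case ``status`` (one of
    notified / dci_traced / dco / not_captured), ``recorded_time`` (NaN for
    dco and not_captured) and ``wrong_date_flag``.
    """

    data: pd.DataFrame
    error: ErrorConfig
    cohort: Cohort

    def estimation_view(self) -> pd.DataFrame:
        """The rows entering survival estimation: notified + traced DCI.

        DCO cases have no incidence date and are excluded by registry
        convention; never-captured cases are unknown to the registry.
        Times are the *recorded* survival times.
        """
        keep = self.data["status"].isin(["notified", "dci_traced"])
        sub = self.data[keep]
        return pd.DataFrame(
            {
                "age": sub["age"].to_numpy(),
                "time": sub["recorded_time"].to_numpy(),
                "dead": (sub["cause"] != "censored").to_numpy(),
                "x": sub["x"].to_numpy(),
            }
        )

    def status_counts(self) -> pd.Series:
        return self.data["status"].value_counts().reindex(STATUSES, fill_value=0)

    def to_csv(self, path, estimation_view: bool = False) -> None:
        if estimation_view:
            self.estimation_view().to_csv(path, index=False)
        else:
            self.data.to_csv(path, index=False)


def shorten_time(true_time, rng: np.random.Generator):
    """A wrong (later) incidence date rescales survival by U ~ Uniform(0, 1).

    The recorded time is strictly shorter than the truth almost surely and
    halves it on average; the model is deliberately isolated here so an
    alternative shortening law can be substituted.
    """
    true_time = np.asarray(true_time, dtype=float)
    if np.any(true_time <= 0):
        raise ValueError("true_time must be positive")
    u = rng.random(true_time.shape if true_time.ndim else None)
    out = u * true_time
    return out if np.ndim(out) else float(out)


def apply_registration_errors(cohort: Cohort, err: ErrorConfig,
                              seed=None) -> RegistryDataset:
    """Run the death-certificate clearance process over a complete cohort.

    1. Each case is missed with probability P(miss | X) derived from the
       marginal ``p_miss`` and ``rr_miss_x``.
    2. Missed cases dying of cancer before censoring surface as DCI
       candidates; the rest (alive, or dead of other causes) are never
       captured.
    3. Each candidate is traced successfully with probability ``p_trace``
       (status ``dci_traced``), otherwise it is a DCO.
    4. Each traced case independently receives a shortened recorded time
       with probability ``p_wrong_date``.
    5. Non-missed cases are notified with their true times.
    """
    p_x = cohort.scenario.p_x if cohort.scenario is not None else \
        float(cohort.data["x"].mean())
    p0, p1 = err.stratum_miss_probs(p_x)

    ss = seed if isinstance(seed, np.random.SeedSequence) else \
        np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)

    df = cohort.data.copy()
    n = len(df)
    x = df["x"].to_numpy()
    cause = df["cause"].to_numpy()
    t_obs = df["t_observed"].to_numpy(dtype=float)

    p_miss_i = np.where(x == 1, p1, p0)
    missed = rng.random(n) < p_miss_i
    cancer_death = cause == "cancer"

    candidate = missed & cancer_death
    traced = candidate & (rng.random(n) < err.p_trace)
    wrong = traced & (rng.random(n) < err.p_wrong_date)

    status = np.full(n, "notified", dtype=object)
    status[missed & ~cancer_death] = "not_captured"
    status[candidate & ~traced] = "dco"
    status[traced] = "dci_traced"

    recorded = t_obs.copy()
    # draw the shortening factors in one deterministic vectorised pass
    if np.any(wrong):
        recorded[wrong] = shorten_time(t_obs[wrong], rng)
    recorded[np.isin(status, ["dco", "not_captured"])] = np.nan

    df["status"] = pd.Categorical(status, categories=list(STATUSES))
    df["recorded_time"] = recorded
    df["wrong_date_flag"] = wrong.astype(np.int8)
    return RegistryDataset(df, error=err, cohort=cohort)


def dci_dco_proportions(registry: RegistryDataset) -> dict:
    """DCI and DCO shares among registered cases (DCOs included in the base).

    Registered cases are notified + traced DCI + DCO.  The DCI proportion
    counts every death-certificate-initiated case (traced or not); the DCO
    proportion counts trace-back failures only.  Both are also reported per
    100 registrations.
    """
    counts = registry.status_counts()
    registered = int(counts[["notified", "dci_traced", "dco"]].sum())
    if registered == 0:
        raise ValueError("empty registry: no registered cases")
    dci = int(counts["dci_traced"] + counts["dco"])
    dco = int(counts["dco"])
    return {
        "n_registered": registered,
        "dci_proportion": dci / registered,
        "dco_proportion": dco / registered,
        "dci_per_100": 100.0 * dci / registered,
        "dco_per_100": 100.0 * dco / registered,
        "denominator": "all registered cases including DCOs",
    }
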