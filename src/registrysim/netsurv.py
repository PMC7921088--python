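"""Net survival estimation with expected-mortality lifetables.

Net survival is the survival probability that would be observed if the
cancer under study were the only possible cause of death.  It is estimated
here non-parametrically from all-cause follow-up plus an age-indexed table
of expected (population) mortality rates, using the Pohar-Perme estimator:
each subject's counting-process contributions are weighted by the inverse
of its expected survival, which corrects for the informative removal of
older subjects by other-cause mortality.

The estimator is evaluated on the exact grid of observed death times.
Between consecutive death times the expected-hazard exposure of every
at-risk subject is integrated exactly against the piecewise-constant
lifetable; weights are evaluated at the event time.  Survival is formed as
the product-limit over the excess-hazard increments,

    S_E(t) = prod_{t_j <= t} (1 - dLambda_E(t_j)),

which reduces *exactly* to the all-cause Kaplan-Meier when all expected
rates are zero (weights identically 1, zero expected exposure).  The
cumulative excess hazard is therefore a step function jumping only at
observed deaths; net survival may locally exceed 1 and is clamped to [0, 1]
only at reporting time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default age grouping for standardisation: 18-54, 55-64, 65-74, 75+.
DEFAULT_AGE_GROUPS: tuple[tuple[float, float], ...] = (
    (18.0, 55.0),
    (55.0, 65.0),
    (65.0, 75.0),
    (75.0, 111.0),
)

#: International Cancer Survival Standard (ICSS-1 style) weights for the
#: same four bands, obtained by pooling the two youngest ICSS groups.
ICSS_WEIGHTS: tuple[float, ...] = (0.19, 0.23, 0.29, 0.29)


class LifetableCoverageError(KeyError):
    """An attained age falls outside the lifetable's bands."""


@dataclass(frozen=True)
class Lifetable:
    """Piecewise-constant expected mortality rates on contiguous age bands.

    Bands are half-open ``[age_low, age_high)`` in years and must partition
    an interval without gaps.  ``rate`` is the expected all-cause hazard per
    person-year within each band.
    """

    age_low: np.ndarray
    age_high: np.ndarray
    rate: np.ndarray
    _cum: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        lo = np.asarray(self.age_low, dtype=float)
        hi = np.asarray(self.age_high, dtype=float)
        r = np.asarray(self.rate, dtype=float)
        if lo.ndim != 1 or lo.shape != hi.shape or lo.shape != r.shape:
            raise ValueError("age_low, age_high and rate must be 1-d and congruent")
        if lo.size == 0:
            raise ValueError("empty lifetable")
        if not np.all(hi > lo):
            raise ValueError("bands must have age_high > age_low")
        if not np.allclose(lo[1:], hi[:-1]):
            raise ValueError("bands must be contiguous (no gaps or overlaps)")
        if np.any(r < 0):
            raise ValueError("expected rates must be non-negative")
        object.__setattr__(self, "age_low", lo)
        object.__setattr__(self, "age_high", hi)
        object.__setattr__(self, "rate", r)
        # cumulative integral of the rate function from the first band edge
        widths = hi - lo
        cum = np.concatenate([[0.0], np.cumsum(r * widths)])
        object.__setattr__(self, "_cum", cum)
        # uniform unit-width bands admit index arithmetic instead of search
        object.__setattr__(self, "_unit_bands", bool(np.allclose(widths, 1.0)))

    @property
    def support(self) -> tuple[float, float]:
        return float(self.age_low[0]), float(self.age_high[-1])

    def cumulative_at(self, age: np.ndarray | float) -> np.ndarray:
        """Integral of the expected rate from the first band edge to ``age``.

        Ages above the last band edge raise; ages below the first edge
        contribute zero (rates are only defined from the first edge on).
        """
        a = np.asarray(age, dtype=float)
        lo0, hi_last = self.support
        if np.any(a > hi_last + 1e-9):
            raise LifetableCoverageError(
                f"attained age {float(np.max(a)):.2f} beyond lifetable support "
                f"[{lo0}, {hi_last})"
            )
        a = np.clip(a, lo0, hi_last)
        if self._unit_bands:
            idx = np.minimum((a - lo0).astype(np.intp), self.age_low.size - 1)
            return self._cum[idx] + self.rate[idx] * (a - lo0 - idx)
        idx = np.minimum(
            np.searchsorted(self.age_low, a, side="right") - 1,
            self.age_low.size - 1,
        )
        idx = np.maximum(idx, 0)
        return self._cum[idx] + self.rate[idx] * (a - self.age_low[idx])

    def expected_cumhaz(self, age_at_entry, t) -> np.ndarray:
        """Expected cumulative hazard between entry and entry + t (broadcast)."""
        age_at_entry = np.asarray(age_at_entry, dtype=float)
        t = np.asarray(t, dtype=float)
        return self.cumulative_at(age_at_entry + t) - self.cumulative_at(age_at_entry)

    # ---- I/O ------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age_low": self.age_low, "age_high": self.age_high,
             "rate_per_year": self.rate}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Lifetable":
        df = df.sort_values("age_low")
        return cls(df["age_low"].to_numpy(), df["age_high"].to_numpy(),
                   df["rate_per_year"].to_numpy())

    @classmethod
    def from_csv(cls, path) -> "Lifetable":
        return cls.from_frame(pd.read_csv(path))

    @classmethod
    def zero(cls, age_min: float = 18.0, age_max: float = 111.0) -> "Lifetable":
        """A null lifetable (all expected rates zero) on one wide band."""
        return cls(np.array([age_min]), np.array([age_max]), np.array([0.0]))


@dataclass
class NetSurvivalEstimate:
    """Age-standardised net survival at fixed time points.

    ``group_survival`` holds the per-age-group estimates (groups x
    timepoints, clamped to [0, 1]); ``survival`` is the weighted combination
    sum_g w_g S_g with weights summing to 1.  ``identifiable`` flags
    timepoints at which every contributing group still had follow-up.
    """

    timepoints: np.ndarray
    survival: np.ndarray
    group_survival: np.ndarray
    age_groups: tuple[tuple[float, float], ...]
    weights: np.ndarray
    stratum: str = "overall"
    n_per_group: np.ndarray | None = None
    identifiable: np.ndarray | None = None

    def at(self, t: float) -> float:
        j = int(np.argmin(np.abs(self.timepoints - t)))
        if abs(self.timepoints[j] - t) > 1e-9:
            raise KeyError(f"timepoint {t} not estimated")
        return float(self.survival[j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stratum": self.stratum,
                "timepoint": self.timepoints,
                "net_survival": self.survival,
                "identifiable": (
                    self.identifiable
                    if self.identifiable is not None
                    else np.ones_like(self.timepoints, dtype=bool)
                ),
            }
        )


def _excess_hazard_curve(time, dead, age, lifetable: Lifetable, max_time: float,
                         weighted: bool = True):
    """Event grid and product-limit net survival for one (sub)sample.

    Returns ``(event_times, survival_steps, identifiable_to)`` where
    ``survival_steps[j]`` is the estimate just after ``event_times[j]`` and
    ``identifiable_to`` is the last follow-up time in the sample.

    ``weighted=False`` drops the inverse-expected-survival weights, giving
    an (unweighted) Ederer-II-type estimator used for sensitivity checks.
    """
    time = np.asarray(time, dtype=float)
    dead = np.asarray(dead, dtype=bool)
    age = np.asarray(age, dtype=float)
    if np.any(time <= 0):
        raise ValueError("all follow-up times must be positive")

    grid = np.unique(time[dead & (time <= max_time + 1e-12)])
    if grid.size == 0:
        return grid, np.ones(0), float(time.max(initial=0.0))

    r_entry = lifetable.cumulative_at(age)                       # (n,)
    attained = age[:, None] + grid[None, :]                      # (n, m)
    r_at = lifetable.cumulative_at(attained)                     # (n, m)
    if weighted:
        w = np.exp(r_at - r_entry[:, None])                      # 1 / S*_i(t_j)
    else:
        w = np.ones_like(r_at)
    at_risk = time[:, None] >= grid[None, :] - 1e-12             # (n, m)

    # expected-hazard exposure of at-risk subjects over (t_{j-1}, t_j]
    r_prev = np.concatenate([r_entry[:, None], r_at[:, :-1]], axis=1)
    expo = r_at - r_prev

    den = np.einsum("nm,nm->m", w, at_risk)
    num_expected = np.einsum("nm,nm,nm->m", w, expo, at_risk)

    is_death = dead & (time <= max_time + 1e-12)
    j_of_death = np.searchsorted(grid, time[is_death])
    if weighted:
        w_own = np.exp(lifetable.cumulative_at(age[is_death] + time[is_death])
                       - r_entry[is_death])
    else:
        w_own = np.ones(int(is_death.sum()))
    num_deaths = np.bincount(j_of_death, weights=w_own, minlength=grid.size)

    d_lambda = (num_deaths - num_expected) / den
    surv = np.cumprod(1.0 - d_lambda)
    return grid, surv, float(time.max())


def _step_lookup(grid, surv, timepoints):
    """Right-continuous step lookup: last grid value <= t (1 before any event)."""
    tp = np.asarray(timepoints, dtype=float)
    idx = np.searchsorted(grid, tp + 1e-12) - 1
    out = np.where(idx >= 0, np.concatenate([[1.0], surv])[idx + 1], 1.0)
    return out


from functools import lru_cache


@lru_cache(maxsize=64)
def _internal_age_weights_cached(age_groups, age_mean, age_sd, age_min,
                                 age_max) -> tuple:
    from scipy.stats import truncnorm

    a, b = (age_min - age_mean) / age_sd, (age_max - age_mean) / age_sd
    dist = truncnorm(a, b, loc=age_mean, scale=age_sd)
    w = np.array([
        dist.cdf(min(hi, age_max)) - dist.cdf(max(lo, age_min))
        for lo, hi in age_groups
    ])
    return tuple(w / w.sum())


def internal_age_weights(age_groups=DEFAULT_AGE_GROUPS, age_mean: float = 70.0,
                         age_sd: float = 15.0, age_min: float = 18.0,
                         age_max: float = 100.0) -> np.ndarray:
    """Theoretical age-group masses of the truncated-normal age model.

    Using the generating distribution (rather than the realised sample)
    guarantees the complete-cohort and corrupted-registry arms are
    standardised with identical weights.
    """
    key = tuple((float(lo), float(hi)) for lo, hi in age_groups)
    return np.array(_internal_age_weights_cached(
        key, float(age_mean), float(age_sd), float(age_min), float(age_max)))


def age_standardise(group_estimates, weights) -> np.ndarray:
    """Weighted combination sum_g w_g S_g of per-age-group estimates.

    ``group_estimates`` is (groups,) or (groups, timepoints); NaN rows
    (empty groups) must have zero weight.
    """
    est = np.asarray(group_estimates, dtype=float)
    one_d = est.ndim == 1
    est = est[:, None] if one_d else est
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or w.size != est.shape[0]:
        raise ValueError("weights must align with the group axis")
    if not np.isclose(w.sum(), 1.0):
        raise ValueError(f"weights must sum to 1 (got {w.sum():.6f})")
    bad = np.isnan(est).any(axis=1) & (w > 0)
    if np.any(bad):
        raise ValueError("positive weight on a group without an estimate")
    est = np.where(np.isnan(est), 0.0, est)
    out = w @ est
    return out[0] if one_d else out


def _resolve_weights(weights, age_groups):
    if weights is None or (isinstance(weights, str) and weights == "internal"):
        return internal_age_weights(age_groups)
    if isinstance(weights, str) and weights == "icss":
        if len(age_groups) != len(ICSS_WEIGHTS):
            raise ValueError("icss weights defined for the default 4 age groups")
        return np.asarray(ICSS_WEIGHTS, dtype=float)
    w = np.asarray(weights, dtype=float)
    if w.size != len(age_groups):
        raise ValueError("weights must match number of age groups")
    return w / w.sum()


def pohar_perme(data: pd.DataFrame, lifetable: Lifetable, timepoints=(1.0, 5.0),
                age_groups=DEFAULT_AGE_GROUPS, weights="internal",
                stratum: str = "overall", method: str = "pohar-perme",
                ) -> NetSurvivalEstimate:
    """Age-standardised net survival from all-cause follow-up data.

    Parameters
    ----------
    data
        One row per subject with columns ``age`` (years at diagnosis),
        ``time`` (all-cause follow-up, years) and ``dead`` (any-cause death
        indicator).  Entry is at time 0 for everyone.
    lifetable
        Expected-mortality rates by attained age.  Must cover every
        attained age in the data.
    timepoints
        Times at which to report the standardised estimate.
    age_groups, weights
        Standardisation bands and their weights; ``"internal"`` uses the
        truncated-normal age model's theoretical masses, ``"icss"`` the
        external standard, or pass explicit weights.  Groups that are empty
        in the data are merged into their nearest non-empty neighbour (the
        neighbour inherits the combined weight) and the merge is logged.
    method
        ``"pohar-perme"`` (inverse-expected-survival weighted, default) or
        ``"ederer2"`` (unweighted sensitivity variant).

    Returns
    -------
    NetSurvivalEstimate
        Standardised and per-group estimates clamped to [0, 1].
    """
    if method not in ("pohar-perme", "ederer2"):
        raise ValueError(f"unknown method {method!r}")
    if len(data) == 0:
        raise ValueError("no subjects to estimate from")
    tp = np.asarray(timepoints, dtype=float)
    max_t = float(tp.max())
    age = data["age"].to_numpy(dtype=float)
    time = data["time"].to_numpy(dtype=float)
    dead = data["dead"].to_numpy(dtype=bool)

    w_groups = _resolve_weights(weights, age_groups)
    membership = [
        (age >= lo) & (age < hi) for lo, hi in age_groups
    ]
    counts = np.array([int(m.sum()) for m in membership])

    # merge empty groups into the nearest populated neighbour
    eff_weights = w_groups.astype(float).copy()
    target = np.arange(len(age_groups))
    if np.any(counts == 0) and counts.sum() > 0:
        populated = np.flatnonzero(counts > 0)
        for g in np.flatnonzero(counts == 0):
            tgt = populated[np.argmin(np.abs(populated - g))]
            logger.warning(
                "age group %s empty; merging its weight into group %s",
                age_groups[g], age_groups[tgt],
            )
            eff_weights[tgt] += eff_weights[g]
            eff_weights[g] = 0.0
            target[g] = tgt
    if counts.sum() == 0:
        raise ValueError("all age groups empty")

    n_groups = len(age_groups)
    group_surv = np.full((n_groups, tp.size), np.nan)
    ident = np.ones(tp.size, dtype=bool)
    for g in range(n_groups):
        if eff_weights[g] == 0.0:
            continue
        m = membership[g]
        if target[g] != g:  # should not happen: weight was moved
            continue
        sel = m.copy()
        for g2 in np.flatnonzero(target == g):
            sel |= membership[g2]
        grid, surv, follow = _excess_hazard_curve(
            time[sel], dead[sel], age[sel], lifetable, max_t,
            weighted=(method == "pohar-perme"),
        )
        group_surv[g] = _step_lookup(grid, surv, tp)
        ident &= tp <= follow + 1e-12

    group_surv_rep = np.clip(group_surv, 0.0, 1.0)
    std = age_standardise(np.where(np.isnan(group_surv), np.nan, group_surv_rep),
                          eff_weights)
    return NetSurvivalEstimate(
        timepoints=tp,
        survival=np.clip(np.atleast_1d(std), 0.0, 1.0),
        group_survival=group_surv_rep,
        age_groups=tuple(age_groups),
        weights=eff_weights,
        stratum=stratum,
        n_per_group=counts,
        identifiable=ident,
    )


def ederer2(data: pd.DataFrame, lifetable: Lifetable, timepoints=(1.0, 5.0),
            **kwargs) -> NetSurvivalEstimate:
    """Unweighted excess-hazard (Ederer-II-type) net survival, for sensitivity."""
    return pohar_perme(data, lifetable, timepoints, method="ederer2", **kwargs)
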