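"""Independent brute-force oracles used to validate the estimators.

Everything here is deliberately written with explicit per-subject loops
and its own lifetable integration, sharing no code with the package's
vectorised implementation.
"""

import math


def expected_cumhaz_between(age_entry, t0, t1, band_low, band_high, rates):
    """Integral of the piecewise-constant rate over attained age
    [age_entry + t0, age_entry + t1], by walking the bands one by one."""
    a0, a1 = age_entry + t0, age_entry + t1
    total = 0.0
    for lo, hi, r in zip(band_low, band_high, rates):
        left = max(a0, lo)
        right = min(a1, hi)
        if right > left:
            total += r * (right - left)
    # exposure beyond the last band edge accrues at the last band's rate
    # only if explicitly clamped; here we mirror the implementation's clamp
    last_hi = band_high[-1]
    if a1 > last_hi:
        raise ValueError("attained age beyond lifetable support")
    return total


def pohar_perme_oracle(times, dead, ages, band_low, band_high, rates,
                       max_time):
    """Term-by-term weighted counting-process computation of net survival.

    Product-limit over excess-hazard increments on the grid of distinct
    death times <= max_time; weights 1/S*_i evaluated at event times;
    expected-hazard exposure integrated exactly over each inter-event
    interval for subjects still at risk at its end.

    Returns a list of (event_time, survival_after) pairs.
    """
    n = len(times)
    grid = sorted({times[i] for i in range(n)
                   if dead[i] and times[i] <= max_time + 1e-12})
    out = []
    surv = 1.0
    prev = 0.0
    for tj in grid:
        num_deaths = 0.0
        num_expected = 0.0
        den = 0.0
        for i in range(n):
            if times[i] >= tj - 1e-12:  # at risk at tj
                h_entry_tj = expected_cumhaz_between(
                    ages[i], 0.0, tj, band_low, band_high, rates)
                w = math.exp(h_entry_tj)
                den += w
                num_expected += w * expected_cumhaz_between(
                    ages[i], prev, tj, band_low, band_high, rates)
                if dead[i] and abs(times[i] - tj) <= 1e-12:
                    num_deaths += w
        surv *= 1.0 - (num_deaths - num_expected) / den
        out.append((tj, surv))
        prev = tj
    return out


def oracle_survival_at(times, dead, ages, band_low, band_high, rates,
                       timepoint):
    """Step lookup of the oracle curve at one timepoint."""
    curve = pohar_perme_oracle(times, dead, ages, band_low, band_high, rates,
                               timepoint)
    s = 1.0
    for tj, sj in curve:
        if tj <= timepoint + 1e-12:
            s = sj
    return s
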