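"""Orchestration of the bias experiment.

For every (scenario, registration-error combination, replicate) the
pipeline simulates a complete cohort, estimates age-standardised net
survival at 1 and 5 years (the truth arm), pushes the same cohort through
the registration-error process, re-estimates on the registry's estimation
view (notified + traced DCI cases, recorded times), and records the paired
difference

    bias = 100 * (S_full - S_corrupted)   [percentage points],

so a positive bias is an underestimate of survival.  The full experiment
is 9 scenarios x 24 error combinations = 216 configurations, 100
replicates of 5000 cases each; a reduced profile (scenarios A-C, 20
replicates) covers the headline results at desk scale.

Randomness is organised as one stream per (scenario, replicate) for
cohort generation and one per (scenario, replicate, error) for the error
process, all spawned from a master seed via ``numpy.random.SeedSequence``
spawn keys — results are bit-reproducible regardless of execution order
or worker count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import hazards
from .cohort import Cohort, simulate_cohort, true_net_survival_curve
from .hazards import ScenarioConfig, calibrate_baseline, make_lifetable
from .netsurv import DEFAULT_AGE_GROUPS, Lifetable, pohar_perme
from .registration import (ErrorConfig, RegistryDataset,
                           apply_registration_errors, dci_dco_proportions,
                           error_grid)

logger = logging.getLogger(__name__)

ERROR_KEYS = ["p_miss", "rr_miss_x", "p_trace", "p_wrong_date"]
CONFIG_KEYS = ["scenario_id"] + ERROR_KEYS


@dataclass
class GridResult:
    """Replicate-level bias records plus per-configuration summaries."""

    records: pd.DataFrame
    dci_dco: pd.DataFrame
    exclusions: pd.DataFrame
    master_seed: int | None = None

    def summary(self, grouping=None) -> pd.DataFrame:
        return summarise_bias(self.records, grouping)

    def dci_dco_summary(self) -> pd.DataFrame:
        return (self.dci_dco
                .groupby(CONFIG_KEYS, as_index=False)
                .agg(dci_proportion=("dci_proportion", "mean"),
                     dco_proportion=("dco_proportion", "mean"),
                     n_replicates=("replicate_id", "size")))

    def to_dir(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(out / "bias_records.csv", index=False)
        self.summary().to_csv(out / "grid_summary.csv", index=False)
        self.dci_dco_summary().to_csv(out / "dci_dco_table.csv", index=False)
        if len(self.exclusions):
            self.exclusions.to_csv(out / "exclusions.csv", index=False)


def _cohort_seed(master_seed, scen_idx: int, rep: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(master_seed, spawn_key=(scen_idx, rep))


def _error_seed(master_seed, scen_idx: int, rep: int,
                err_idx: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(master_seed,
                                  spawn_key=(scen_idx, rep, 1000 + err_idx))


def _estimates_by_stratum(frame: pd.DataFrame, lifetable: Lifetable,
                          timepoints, age_groups, weights, by_x: bool) -> dict:
    out = {"overall": pohar_perme(frame, lifetable, timepoints,
                                  age_groups=age_groups, weights=weights)}
    if by_x:
        for xv in (0, 1):
            sub = frame[frame["x"] == xv]
            out[f"x={xv}"] = pohar_perme(sub, lifetable, timepoints,
                                         age_groups=age_groups, weights=weights,
                                         stratum=f"x={xv}")
    return out


def _replicate_records(scen: ScenarioConfig, scen_idx: int, rep: int,
                       cancer_spec, other_spec, lifetable, errors,
                       master_seed, timepoints, age_groups, weights, by_x):
    """All bias records for one (scenario, replicate): shared cohort, one
    truth arm, one corrupted arm per error combination."""
    rows, dci_rows, excl = [], [], []
    cohort = simulate_cohort(scen, cancer_spec, other_spec,
                             seed=_cohort_seed(master_seed, scen_idx, rep),
                             replicate_id=rep)
    truth = _estimates_by_stratum(cohort.estimation_frame(), lifetable,
                                  timepoints, age_groups, weights, by_x)
    for err_idx, err in enumerate(errors):
        registry = apply_registration_errors(
            cohort, err, seed=_error_seed(master_seed, scen_idx, rep, err_idx))
        base = {
            "scenario_id": scen.scenario_id,
            "p_miss": err.p_miss, "rr_miss_x": err.rr_miss_x,
            "p_trace": err.p_trace, "p_wrong_date": err.p_wrong_date,
            "replicate_id": rep,
        }
        try:
            corrupted = _estimates_by_stratum(
                registry.estimation_view(), lifetable, timepoints, age_groups,
                weights, by_x)
        except Exception as exc:  # noqa: BLE001 - recorded, never silent
            logger.warning("estimation failed for %s rep %s (%s): %s",
                           scen.scenario_id, rep, err.label(), exc)
            excl.append({**base, "reason": str(exc)})
            continue
        dci_rows.append({**base, **{k: v for k, v in
                                    dci_dco_proportions(registry).items()
                                    if k != "denominator"}})
        for stratum, est_t in truth.items():
            est_c = corrupted[stratum]
            for j, tp in enumerate(np.asarray(timepoints, dtype=float)):
                s_full = float(est_t.survival[j])
                s_corr = float(est_c.survival[j])
                rows.append({
                    **base,
                    "timepoint": tp,
                    "stratum": stratum,
                    "survival_full": s_full,
                    "survival_corrupted": s_corr,
                    "bias": 100.0 * (s_full - s_corr),
                })
    return rows, dci_rows, excl


def run_grid(scenarios=("A", "B", "C"), errors=None, n_reps: int = 20,
             n_cases: int = 5000, master_seed: int = 0,
             timepoints=(1.0, 5.0), age_groups=DEFAULT_AGE_GROUPS,
             weights="internal", by_x: bool = True, n_jobs: int = 1,
             ) -> GridResult:
    """Run the bias experiment over a scenario x error grid.

    Parameters
    ----------
    scenarios
        Scenario letters, or :class:`ScenarioConfig` objects.  ``n_cases``
        overrides the per-scenario cohort size.
    errors
        List of :class:`ErrorConfig`; defaults to the full 24-combination
        grid.
    n_reps
        Replicates per configuration.  Each replicate's cohort is shared
        across all error combinations (the truth arm is estimated once).
    master_seed
        Seeds the whole experiment; identical seeds reproduce every record
        bit for bit independent of ``n_jobs``.
    n_jobs
        Parallel workers over (scenario, replicate) tasks via joblib when
        > 1; determinism is unaffected.
    """
    if errors is None:
        errors = error_grid()
    scens = [
        s if isinstance(s, ScenarioConfig) else hazards.scenario(s,
                                                                 n_cases=n_cases)
        for s in scenarios
    ]
    tasks = []
    for scen_idx, scen in enumerate(scens):
        cancer_spec = calibrate_baseline(scen)
        other_spec = scen.other_spec()
        lifetable = make_lifetable(other_spec, p_x=scen.p_x)
        for rep in range(n_reps):
            tasks.append((scen, scen_idx, rep, cancer_spec, other_spec,
                          lifetable))

    def _run(task):
        scen, scen_idx, rep, cancer_spec, other_spec, lifetable = task
        return _replicate_records(scen, scen_idx, rep, cancer_spec, other_spec,
                                  lifetable, errors, master_seed, timepoints,
                                  age_groups, weights, by_x)

    if n_jobs and n_jobs != 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=n_jobs)(delayed(_run)(t) for t in tasks)
    else:
        results = [_run(t) for t in tasks]

    rows = [r for res in results for r in res[0]]
    dci_rows = [r for res in results for r in res[1]]
    excl = [r for res in results for r in res[2]]
    if excl:
        logger.warning("%d replicate estimations excluded", len(excl))
    return GridResult(
        records=pd.DataFrame(rows),
        dci_dco=pd.DataFrame(dci_rows),
        exclusions=pd.DataFrame(excl,
                                columns=CONFIG_KEYS + ["replicate_id", "reason"]),
        master_seed=master_seed,
    )


def summarise_bias(records: pd.DataFrame,
                   grouping: list[str] | None = None) -> pd.DataFrame:
    """Mean, Monte-Carlo SE, min, max of bias per configuration cell.

    Default grouping is the full grid key (scenario, the four error
    parameters, timepoint, stratum); pass any subset of record columns to
    aggregate further.  MC-SE is the standard error of the replicate mean.
    """
    if records.empty:
        raise ValueError("no bias records to summarise")
    if grouping is None:
        grouping = CONFIG_KEYS + ["timepoint", "stratum"]
    unknown = [g for g in grouping if g not in records.columns]
    if unknown:
        raise KeyError(f"unknown grouping columns: {unknown}")
    g = records.groupby(grouping, as_index=False)["bias"]
    out = g.agg(
        mean_bias="mean",
        sd_bias="std",
        min_bias="min",
        max_bias="max",
        n_replicates="size",
    )
    out["mc_se"] = out["sd_bias"] / np.sqrt(out["n_replicates"])
    return out


def full_grid_size(scenarios=None, errors=None) -> int:
    """Number of configuration cells in the experiment grid."""
    n_s = len(scenarios) if scenarios is not None else \
        len(hazards.all_scenarios())
    n_e = len(errors) if errors is not None else len(error_grid())
    return n_s * n_e
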