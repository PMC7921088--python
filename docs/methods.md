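# Methods

## Disease model

Two competing causes of death act on each case from diagnosis (t = 0).

**Cancer-specific mortality.** The hazard is a Weibull baseline with a
log-linear covariate term,

    λ_c(t | age, x) = (k/s)(t/s)^{k−1} · exp{(β₀ + β₁ log t)·z(age) + γ·x},

where `z(age) = (age − 70)/15` is age standardised by the population mean
and SD and `x` indicates the prognostic Factor X.  The `β₁ log t`
interaction makes the age effect decay with time since diagnosis, the
qualitative behaviour typical of cancer excess mortality.  Collecting
powers of `t` the hazard is `C·t^{p−1}` with `p = k + β₁ z(age)`, so the
cumulative hazard `Λ_c(t) = C·t^p/p` and its inverse are closed-form; an
adaptive-quadrature path exists and is held to 1e−8 relative agreement in
the tests.  Validity requires `p > 0` across the supported age range
[18, 100]; the spec constructor enforces this.

Defaults: `k = 0.9` (sub-exponential decline), `β₀ = 0.3` per SD of age,
`β₁ = −0.1`, `γ = log 1.5` or `log 3` by scenario.  These magnitudes are
plausible for registry cancers; all are exposed in configuration.  `s` is
never a free choice — it is calibrated (below).

**Other-cause mortality.** Gompertz in attained age,

    λ_o(t | age, x) = a·exp{b(age + t − 70)}·exp(γ_o·x),

with `a = 0.02`/year at attained age 70 and `b = 0.085` (rates double
roughly every 8 years), approximating general-population all-cause
mortality; `γ_o = 0` in scenarios A–F and `log 3` in G–I.  Cumulative
hazard and inverse are closed-form.

**Scenarios.** Nine scenarios cross three 5-year net-survival levels
(0.21, 0.36, 0.70) with Factor-X hazard ratios on cancer (1.5 or 3) and
other-cause (1 or 3) mortality; `data/scenarios.yaml` is the single source
of truth.  Cohort defaults: 5000 cases, 100 replicates,
age ~ N(70, 15²) truncated to [18, 100], P(X) = 0.25.

**Calibration.** The Weibull scale is found by Brent root-finding so that
the *marginal* 5-year net survival — `E[exp(−Λ_c(5 | age, X))]` integrated
over the truncated-normal age density (200-node Gauss–Legendre) and the
X mixture — equals the scenario target within 0.002.  Calibration targets
the marginal rather than a covariate-reference survival because the
scenario levels describe the cancer as a whole.

## Cohort generation

Ages are drawn by inverse-CDF of the truncated normal (equivalent in law
to resampling a plain normal into [18, 100], but a single-stream, fully
reproducible transformation).  Latent event times solve `Λ(t) = −log U`
through the closed-form inverses; a generic bracketing solver
(`sample_event_time`, tolerance 1e−8) is provided for arbitrary cumulative
hazards and anchors the closed-form paths in tests.  Uniform draws of
exactly 0/1 are redrawn.  Latent times beyond a 100-year working horizon
are treated as "no event".  Administrative censoring is applied at 10
years — the source design is silent on follow-up; a horizon comfortably
beyond the 5-year estimate is needed so that alive-at-end cases exist —
and exact latent-time ties resolve to cancer (probability-zero event,
conservative for death-certificate capture).

## Registration-error process

Four parameters: `p_miss ∈ {0.05, 0.1, 0.2}`, `rr_miss_x ∈ {1.5, 5}`,
`p_trace ∈ {0.7, 0.9}`, `p_wrong_date ∈ {0, 0.3}` (24 combinations).
`p_miss` is read as the *marginal* miss probability; the per-stratum
probabilities solve `(1−p_x)p₀ + p_x·rr·p₀ = p_miss`, keeping missingness
levels comparable across RR settings (a switch reinterprets `p_miss` as
the X=0 baseline).  Infeasible combinations (stratum probability > 1) are
rejected with the offending values named.

Missed cases dying of cancer before the censoring horizon surface as DCI
candidates (cause of death is assumed perfectly recorded); trace-back
succeeds with `p_trace` → status `dci_traced`, else `dco`.  Missed
survivors and missed other-cause deaths are `not_captured`.  A traced case
receives, with probability `p_wrong_date`, a *recorded* time `U·t` with
`U ~ Uniform(0,1)` — the least-informative shortening law, isolated in one
function for substitution.  The estimation view of a registry contains
notified + traced DCI rows only, with recorded times.  Wrong-date cases
keep their true age at diagnosis; a real registry would also mis-derive
age from the wrong date, a refinement not modelled here.

## Net-survival estimation

The Pohar-Perme estimator is implemented from scratch.  Expected mortality
comes from a 1-year attained-age-band lifetable built from the other-cause
model *marginalised over X* at P(X) = 0.25 (band rate evaluated at the
midpoint) — deliberately X-blind, like a real population lifetable, which
is what lets scenarios G–I carry lifetable-unexplained other-cause
variation.

Numerical conventions:

- The estimator is evaluated on the exact grid of distinct observed death
  times up to the last requested timepoint.  Weights `1/S*_i(t_j)` are
  evaluated at event times; each at-risk subject's expected-hazard
  exposure over `(t_{j−1}, t_j]` is integrated exactly against the step
  lifetable.  Subjects censored strictly inside an interval drop out of
  that interval's sums.
- Survival is the product-limit over excess-hazard increments,
  `S_E(t) = Π (1 − ΔΛ_E(t_j))`.  With zero expected rates this *equals*
  the all-cause Kaplan-Meier exactly, which the exponentiated-cumulative
  form would not; this exact reduction is an asserted invariant.
- The cumulative excess hazard is a step function jumping only at deaths;
  net survival may locally exceed 1 and is clamped to [0, 1] only at
  reporting.  Estimates at t = 1, 5 use the last event-grid value ≤ t.
- Non-identifiable timepoints (follow-up exhausted) carry the last value
  and are flagged.  Empty age groups donate their weight to the nearest
  populated band and the merge is logged.

Age standardisation uses four bands (18–54, 55–64, 65–74, 75+) with
weights equal to the *theoretical* truncated-normal band masses, so the
complete-cohort and corrupted-registry arms are standardised identically;
ICSS-style external weights are available.  An unweighted (Ederer-II-type)
variant is provided for sensitivity only.  No variance estimation is
implemented — the study design needs point-estimate biases only.

## Experiment orchestration

Per (scenario, replicate): one cohort is simulated and its truth-arm
estimate computed once; every error combination corrupts *the same*
cohort, so bias differences across error settings are replicate-paired.
Seeds are `numpy SeedSequence` children of the master seed keyed by
(scenario index, replicate) and (scenario index, replicate, error index):
results are bit-reproducible regardless of execution order or joblib
worker count.  Replicate-level estimation failures are recorded in an
exclusions table, never silently dropped.  The headline summary is the
mean bias over replicates with its Monte-Carlo SE (min/max retained);
mean-over-replicates is the transparent aggregation for a per-configuration
figure value.

Problem sizes: the package's default experiment profile is scenarios A–C
× 24 combinations × 20 replicates of 5000 cases (the full 216-cell × 100
replicate profile is behind `--full`); calibration verification simulates
200,000 cases per survival level and compares the cause-specific
Kaplan-Meier at 5 years (an independent route to net survival available
because true causes are known in simulation).

## What the generator does and does not emulate

The simulation reproduces the structural features the study reasons about:
prognosis-dependent missingness, death-certificate capture limited to
cancer deaths, trace-back failure, shortened survival times, and
other-cause mortality optionally unexplained by the lifetable.  It does
not emulate cause-of-death misclassification, late notifications, linkage
failure ("immortals"), calendar-time effects, or registry-specific age
structures — so passing tests show the error process behaves as designed,
not that any particular real registry has biases of these magnitudes.

## Known limitations

- The exact coefficients of the time-dependent age effect and the
  other-cause model are design choices (the qualitative structure and the
  three survival targets are the binding constraints); bias magnitudes
  shift somewhat under other plausible parametrizations.
- Under these defaults, one corner of the grid (low-survival scenario,
  missingness concentrated on Factor-X cases at RR 5, trace-back 0.7, no
  wrong dates) shows a *tiny negative* mean bias at 1 year (~−0.02 to
  −0.07 pp): DCO exclusion of cancer deaths slightly outweighs the loss of
  missed survivors.  Every other configuration underestimates survival, as
  expected.  Relatedly, at 5 years the largest bias occurs in the
  high-survival scenario rather than the intermediate one.
- Cause-specific Kaplan-Meier and lifetable-based Pohar-Perme estimands
  differ slightly in the presence of age-driven dependence between causes;
  the 200,000-case calibration checks absorb this within their ±0.5 pp
  tolerance.
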