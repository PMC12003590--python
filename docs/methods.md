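# Methods

`xenoscale` predicts tumor-size dynamics and time to progression (TTP) in
treated cancer patients starting from tumor-growth-inhibition (TGI)
studies in patient-derived-xenograft (PDX) mice. The chain has four
stages: population fitting of the Simeoni TGI model in mice, allometric
scaling of growth rate and drug potency to humans, Monte Carlo virtual
trials, and Kaplan–Meier TTP analysis. This note documents the models,
the estimation choices, the synthetic study conditions, and the numerical
decisions.

## Tumor models

**Mouse (Simeoni TGI).** The proliferating tumor mass x1 grows
exponentially at rate λ0 [1/day] while small and linearly at rate λ1
[cm³/day] once the total burden w passes the switch point λ1/λ0; the two
regimes are blended by the divisor `[1 + (λ0/λ1·w)^ψ]^(1/ψ)`. Drug kill
moves cells out of x1 at rate `k2·c(t)·x1` (k2 [L/(mg·day)], c plasma
concentration [mg/L]) into a three-stage damage chain x2→x3→x4 with
transit rate k1 [1/day]; w = x1+x2+x3+x4. The sharpness ψ defaults to 20,
the value in common use — large enough that the switch is effectively
sharp, small enough that the ODE stays well conditioned; it is a
parameter, not a constant. With k2 = 0 the chain stays empty and the
solution is provably independent of k1 (asserted in tests).

**Human.** Tumor volume grows exponentially at λ0,human [1/month] with a
first-order kill proportional to concentration through k2,human
[L/(mg·month)]:

    dTV/dt = (λ0,human − k2,human·c(t))·TV,  TV(0) = TV0.

This integrates in closed form, `ln TV(t) = ln TV0 + λ0,human·t −
k2,human·CAUC(t)` with CAUC the running integral of c, which is why a
1000-replicate × 200-patient Monte Carlo costs seconds. The ODE route is
retained purely as a test oracle. There is no linear phase and no damage
chain in the human model, so λ1 and k1 never cross species — a structural
consequence, not an option.

**Geometry and units.** Tumor weight [g] and volume [cm³] are treated as
numerically identical (unit-density convention of xenograft data; not
configurable). The clinical size measure is the diameter of a single
sphere, `TD = 2·(3·TV/4π)^(1/3)`; a 20% diameter increase is exactly a
1.728-fold volume increase. Concentrations are mg/L and potencies L/mg
throughout, on both sides of the translation; one month is exactly
30 days wherever days and months are converted.

## Pharmacokinetics

All exposure models are linear: mammillary one- or two-compartment
disposition, optionally preceded by a first-order depot (i.p. or simple
oral dosing) or a transit chain (oral drugs with absorption delay).
Because the system is linear, profiles are computed exactly by piecewise
matrix-exponential propagation between dose events — no ODE stepping
error — and the running exposure integral is a trapezoid sum on a grid
refined around each dose: geometric points through the fast phases, the
slow phase sampled at ~3% of its time constant, and a sparse geometric
deep tail so the hand-off to the coarse base grid happens only once the
concentration is negligible. This keeps the cumulative-AUC error around
0.01% for all shipped configurations (verified against closed-form
AUC = dose/clearance).

Named protocols expand cyclic rules into explicit events:
`gemcitabine_standard` is weekly 30-min infusions of 1000 mg/m² for 7
weeks, one rest week, then 3-weeks-on/1-week-off (body surface area must
be supplied; examples use 1.8 m² for the 70-kg reference adult);
`sorafenib_standard` is 400 mg orally every 12 h. Human profiles are
simulated once from typical PK parameters and shared by all virtual
patients — no PK inter-individual variability. The shipped PK parameter
values are package defaults with plausible magnitudes for the stated
model structures (e.g. a rapidly cleared nucleoside analog for the
gemcitabine-like human model), editable YAML, and are not transcriptions
of any published population fit. Enterohepatic recirculation is not
modeled mechanistically; externally supplied concentration CSVs can be
plugged in wherever a profile is consumed.

## Population estimation (two-stage with bootstrap)

Full nonlinear mixed-effects estimation (e.g. SAEM) is replaced by a
documented two-stage procedure. This is well posed here because each PDX
study contributes a single arm-averaged curve per arm, and the output
interface — typical values θ, log-scale covariance Ω, residual-error
model — is exactly what the translation consumes, so an NLME backend
could drop in without touching anything downstream.

**Stage one** fits each study by maximum likelihood jointly over both
arms under a proportional (`SD = b·ŷ`) or combined
(`SD = √(a² + (b·ŷ)²)`) residual model, with the error magnitudes
estimated alongside the five structural parameters (λ0, λ1, w0 from the
control arm; k1, k2 added by the treated arm) on the log scale with
physiological box constraints. Optimization is bounded L-BFGS-B from a
data-driven start (early log-slope of the control arm for λ0, late slope
for λ1, end-of-study arm ratio over cumulative exposure for k2), followed
by a ±one-decade lattice of (k1, k2) restarts — explored unconditionally,
because a misfit start can hide behind an inflated error SD — with the
best optimum polished. Standard errors come from the observed information
(finite-difference Hessian). w0 is estimated per study and never enters
the translated random-effect structure. Studies with regrowing treated
arms are fit as-is; there is no resistance term, matching the human
model's assumptions.

The likelihood is evaluated with a fixed-step RK4 integrator (compiled
with numba) on a dose-refined step grid, holding the concentration at its
exact per-step average taken from the trapezoid CAUC. The grid depends
only on the study design and is precomputed once per fit; the objective
is then smooth and deterministic, which quasi-Newton methods need. The
integrator agrees with the adaptive reference path to ~10⁻⁴ relative,
well inside the 1% recovery tolerances asserted in tests.

**Nuisance shrinkage.** With 8 points per arm, some studies leave
directions of the model flat: λ1 when the control never reaches the
linear phase, λ0 when growth is linear from day one (implant already past
the switch), k1 when the drug effect is small. Plain ML wanders to a box
edge in those directions and a geometric mean is badly damaged by a
single such fit. `fit_panel` therefore refits any study whose estimate of
a parameter lands more than three robust SDs (MAD-based, floored) from
the panel median — or on a bound — with a mild lognormal penalty on that
parameter centered at the panel median. This mirrors the shrinkage an
NLME estimator applies implicitly; parameters within the normal range are
never penalized.

**Stage two** takes geometric means of the per-study estimates as θ and
the sample covariance of the logs as Ω, zeroing every off-diagonal except
(λ0, k2) — the only random-effect correlation the model structure admits.
The retained 2×2 block is a principal submatrix of a sample covariance,
hence positive semidefinite by construction; the correlation is clamped
to [−1, 1] against rounding. Uncertainty is a nonparametric bootstrap
over studies (resampling with replacement at the panel size, re-running
stage two on cached stage-one fits; replicates with fewer than three
distinct studies are redrawn).

## Interspecies translation

Typical values scale as

    λ0,human = 30 · λ0,mouse · (BW_h/BW_m)^(−α)
    k2,human = 30 · k2,mouse · (BW_h/BW_m)^(−α) · f_u,h/f_u,m

with defaults BW_h = 70 kg, BW_m = 0.025 kg, α = 1/3, and unbound-fraction
ratio 1 (appropriate for both drugs the protocols emulate); 30 converts
1/day to 1/month. At the defaults the factor is 30/2800^(1/3) ≈ 2.1285.
The (λ0, k2) log-scale covariance is copied verbatim from the mouse Ω —
multiplicative scaling of a lognormal leaves geometric CVs and
correlations invariant, so variability is propagated, not rescaled. No
alternative interspecies rules (brain weight, lifespan) are offered; α is
a config knob.

## Virtual trials and TTP

A virtual patient is a draw (λ0,i, k2,i) from the scaled bivariate
lognormal plus a baseline volume TV0 — fixed at 1 cm³ by default, or
lognormal (e.g. 115.3·e^η with η ~ N(0, 0.16), the clinical baseline
distribution used for trajectory comparisons). Because the log-volume
gain g(t) = λ0·t − k2·CAUC(t) never sees TV0, progression times are
provably independent of baseline size; the fixed 1 cm³ is a convenience,
and the invariance is asserted exactly in tests.

**Progression** (simplified RECIST) is the first time the diameter
exceeds its reference by 20%: diameter ratio `exp((g − g_ref)/3)` with
g_ref = 0 for the baseline reference or the running minimum of g for the
nadir reference. Nadir is the default (closest to RECIST's
smallest-sum-on-study); both references are implemented and the
acceptance pipeline reports both, since they differ whenever tumors
shrink before regrowing. The optional absolute-increase floor (RECIST's
5-mm rule) is off by default. g is piecewise linear under the trapezoid
exposure interpolant, so the threshold crossing is located by exact
linear inversion inside the bracketing interval — equivalent to bisection
but exact for the interpolant, and exactly `3·ln(1.2)/λ0` in the
drug-free case. The trial time grid is midpoint-refined until the
piecewise-linear CAUC is accurate to 2×10⁻⁴ mg·month/L, keeping located
crossings within ~10⁻³ month of a dense scan. Patients without a crossing
by the horizon (default 14 months) are censored there; adherence to the
protocol is strict, with no dropout or dose modification.

**Kaplan–Meier** is the hand-written product-limit estimator (censored
subjects remain at risk until their censoring time); it matches the
`lifelines` implementation to 10⁻¹² on randomized censored data. The
median is the first time S(t) ≤ 0.5, flagged undefined when never
reached.

**Monte Carlo aggregation.** Replicate r draws its population parameters
from the bootstrap replicates (cycled), samples a fresh cohort with an
RNG substream derived by a counter-based seed split — so enlarging the
replicate count never reshuffles earlier replicates — and produces a KM
curve and its median. Across replicates the pointwise 5th/50th/95th
percentiles (empirical, type-7) form the median and 90% prediction band
for both the TTP curve and the cohort-median diameter trajectory.
Replicate medians that never reach 0.5 are recorded at the horizon, and
the summary carries a flag when the reported median or band touches the
horizon. Defaults are 200 patients × 1000 replicates.

**TTP from PFS/OS.** When clinical TTP is unavailable it is reconstructed
from progression-free and overall survival under independence of
progression and death: S_TTP = S_PFS/S_OS on the union of step grids,
clipped to [0, 1] and made non-increasing by a running minimum. S_PFS >
S_OS violations up to 2% (digitization noise) are clipped; larger ones
raise. Once S_OS reaches zero the ratio is uninformative and the last
defined value is carried forward.

## Synthetic study conditions

Real PDX panels of this shape are proprietary, so the generator emulates
their structure and is itself first-class, tested code. Defaults, chosen
once as a realistic mid-sized chemotherapy panel:

| quantity | default | rationale |
|---|---|---|
| panel size | 27 studies | typical single-indication PDX panel |
| θ: λ0, λ1, k1, k2 | 0.08/d, 0.15 cm³/d, 0.4/d, 0.4 L/(mg·d) | 8.7-day doubling time; ~1-log kill over the course for the typical animal |
| ω²: λ0, λ1, k1, k2 | 0.25, 0.10, 0.10, 0.25 | ~50% geometric CV on the translated parameters |
| corr(λ0, k2) | 0.5 | faster-growing models respond more |
| residual error | proportional, 10% CV | arm-averaged data |
| design | 8 obs/arm, days 0–42 (q6d), w0 typical 0.25 cm³ | long enough that control arms traverse the growth switch, making λ1 identifiable |
| regimen | i.p. q3d×4, 100 mg/kg | the standard xenograft chemotherapy template |
| mouse PK | 2-comp, CL 3.6 L/day, ka 10/day | rapidly cleared agent; per-course exposure 2.78 mg·day/L |

Noise that would push an observation non-positive is resampled, not
clipped, to avoid upward bias of small tumors; a truncation rate above 5%
warns that noise overwhelms signal. What the generator does **not**
emulate: per-animal variability within arms (the pipeline, like the data
it mimics, sees arm means), dropout and tumor-size-dependent sacrifice,
measurement error structure beyond the stated residual models, informative
observation schedules, non-exponential human growth, and acquired
resistance. Passing tests on this generator therefore demonstrate the
estimator and translation machinery under the stated model, not
robustness to model misspecification in real panels.

## Recovery metrics: generating truth vs realized panel

At 27 studies with ω ≈ 0.5, the geometric mean of the drawn per-study
parameters itself wanders ~10% (1 SD) around the generating typical
value. Recovery analyses therefore report two comparisons: against the
generating θ (what a user of one panel experiences — dominated by draw
luck) and against the panel's *realized* geometric means
(`realized_population`), which isolates estimator error. The estimator is
unbiased within ~1% on the translated parameters (λ0, k2) in the latter
sense; recovery checks in the test suite average over three independent
panels to keep the draw-luck contribution below the asserted bounds. The
same logic applies to the end-to-end trial check, which compares the
fitted pipeline's median TTP both to a trial driven by the generating
parameters and to one driven by the panel-realized parameters.

## Numerical choices

- Reference ODE path (`simulate_simeoni`): adaptive LSODA, rtol 1e-8 /
  atol 1e-10, integration restarted at every dose discontinuity. The
  generator tightens atol to 1e-16 because strong-kill draws legitimately
  regress through many decades; a non-positive state raises an explicit
  integration error naming the time point (the model excludes it
  analytically, so it flags a tolerance problem).
- The growth divisor is computed with over/underflow guards so ψ = 20
  powers never overflow.
- Fit-path RK4 step grid: 0.25-day coarse steps, 0.01-day steps for
  0.75 day after each dose (where the kill rate is fastest), observation
  times always included.
- Problem sizes in the test suite and acceptance script — 3 × 27-study
  panels, 200 bootstrap replicates, 1000 × 200 virtual trials — are the
  package's default study conditions; the closed-form human model makes
  the trial stage near-free, and the panel fits dominate the runtime
  (~30 s per panel).
- Degenerate inputs: fewer than 3 complete fits refuse population
  summary; an all-identical panel yields Ω = 0 with a warning; empty
  event sets, non-positive volumes, unsorted grids, and non-PSD
  covariances raise immediately.

## Known limitations

- The two case-study protocols are emulated with package-default PK
  values, so absolute TTP predictions from the shipped configs are
  illustrative; reproducing a published case study requires transcribing
  its population PK and TGI estimates into the config/JSON inputs.
- Two-stage estimation loses efficiency relative to NLME when per-study
  information is very low, and the nuisance shrinkage, while
  outlier-triggered and mild, is a heuristic stand-in for joint
  estimation.
- Ω estimates for λ1 and k1 absorb fit noise and are reported but not
  translated; only the (λ0, k2) block crosses species.
- The KM prediction bands reflect parameter uncertainty via bootstrap
  replicates and cohort sampling only; no dropout, censoring processes,
  or per-lesion bookkeeping.
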