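# xenoscale

Predict tumor-size dynamics and time to progression (TTP) in treated
cancer patients starting only from tumor-growth-inhibition (TGI) studies
in patient-derived-xenograft (PDX) mice.

PDX panels — a control and a treated arm of arm-averaged tumor weights
per model — are a rich, early source of treatment-efficacy information,
but they live on the wrong species and the wrong timescale. `xenoscale`
implements the translational chain that bridges them to clinical
endpoints, for modelers in oncology drug development who want
preclinical-informed predictions of clinical tumor dynamics, virtual
control arms, or priors for clinical TGI models.

## The model chain

1. **Population TGI fit (mouse).** Each PDX study is described by the
   Simeoni TGI model: exponential-then-linear growth of the proliferating
   mass (rates λ0 [1/day], λ1 [cm³/day]) with drug kill `k2·c(t)·x1`
   driving cells through a three-stage damage chain (rate k1 [1/day]).
   Per-study maximum-likelihood fits (proportional or combined residual
   error) are summarized into a multivariate lognormal population —
   typical values θ and log-scale covariance Ω with the single admissible
   correlation, between λ0 and k2 — with nonparametric bootstrap
   uncertainty.

2. **Allometric translation.** Growth rate and potency cross species by

       λ0,human = 30 · λ0,mouse · (BW_h/BW_m)^(−α)
       k2,human = 30 · k2,mouse · (BW_h/BW_m)^(−α) · f_u,h/f_u,m

   (defaults 70 kg / 0.025 kg, α = 1/3, unbound-fraction ratio 1; the
   factor is ≈ 2.1285). The (λ0, k2) covariance block passes through
   unchanged — geometric CVs and correlation are invariant under scaling.

3. **Virtual clinical trials (human).** Tumor volume follows
   `dTV/dt = (λ0,human − k2,human·c(t))·TV`, solved in closed form via
   cumulative drug exposure; diameter is the sphere equivalent
   `TD = 2·(3TV/4π)^(1/3)`. Cohorts of virtual patients are drawn from
   the scaled distribution, progression is a 20% diameter increase over
   the nadir (or baseline), and Kaplan–Meier TTP curves across Monte
   Carlo replicates yield medians with 90% prediction intervals. TTP can
   also be reconstructed from published PFS/OS curves
   (`S_TTP = S_PFS / S_OS` under independence).

A synthetic-data module generates PDX panels with the same structure as
the proprietary panels this kind of analysis runs on, so the whole chain
is testable end to end; packaged PK configs and dosing protocols emulate
weekly gemcitabine infusions and twice-daily oral sorafenib.

## Worked example

The full chain on synthetic data (`examples/06_full_pipeline.py`):

```bash
$ python examples/06_full_pipeline.py
1. generated 27 PDX studies (control + treated arms)
2. two-stage fit: theta = {'lambda0': 0.084, 'lambda1': 0.151, 'k1': 0.414, 'k2': 0.43} corr(lambda0,k2) = 0.17
3. scaled to humans: lambda0 = 0.178/month (typical across bootstrap draws)
4. virtual trials: predicted median TTP 4.45 months (90%PI 3.64-5.54)
   trial driven by the panel's true parameters: 4.31 months
   pipeline-vs-truth deviation: 3.3% — estimation plus Monte Carlo error accumulated across the whole chain.
```

Reading the numbers: the generating typical values were λ0 = 0.08/day and
k2 = 0.4 L/(mg·day); the fit recovers them within a few percent, the
scaled growth rate 0.178/month corresponds to a ~4-month doubling time,
and a 200-patient virtual trial under the standard weekly-infusion
protocol progresses half its cohort by ~4.5 months. The last line is the
end-to-end self-consistency check: fitting noisy data and pushing the
estimate through scaling and simulation reproduces the trial one would
run with the panel's true parameters to within a few percent.

Each capability has its own narrative script under `examples/`:
tumor-dynamics simulation, panel fitting, allometric scaling, virtual
trials, and PFS/OS → TTP reconstruction.

A thin CLI wraps the same calls:

```bash
xenoscale synth --n-studies 27 --seed 1 --out panel.csv
xenoscale fit --panel panel.csv --error proportional --bootstrap 200 --seed 1 --out popest.json
xenoscale scale --popest popest.json --out humanpop.json
xenoscale vtrial --humanpop humanpop.json --patients 200 --replicates 1000 --seed 7 --out trial/
xenoscale reconstruct-ttp --pfs pfs.csv --os os.csv --out ttp.csv
```

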