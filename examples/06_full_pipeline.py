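"""The whole translational chain on synthetic data, end to end.

Panel generation -> per-study fits -> population summary + bootstrap ->
allometric scaling -> virtual trials with parameter-uncertainty
propagation.  Compares the pipeline's predicted median TTP against a
trial driven directly by the generating parameters.  Takes ~1 minute.
"""

import xenoscale as xs
from xenoscale.io import default_pk_spec

truth = xs.PanelTruth(n_studies=27)
panel, true_params = xs.generate_pdx_panel(truth, seed=2027)
print(f"1. generated {len(panel)} PDX studies (control + treated arms)")

fits = xs.fit_panel(panel, error="proportional", compute_se=False)
est = xs.fit_population(fits)
est.bootstrap = xs.bootstrap_population(fits, B=200, seed=1)
print(
    "2. two-stage fit: theta =",
    {k: round(v, 3) for k, v in est.theta.items()},
    f"corr(lambda0,k2) = {est.corr_lambda0_k2:.2f}",
)

pops = [xs.build_human_distribution(b) for b in est.bootstrap]
print(
    f"3. scaled to humans: lambda0 = {pops[0].lambda0_pop:.3f}/month "
    f"(typical across bootstrap draws)"
)

conc = xs.simulate_pk(
    default_pk_spec("human_gemcitabine"),
    xs.build_regimen("gemcitabine_standard", 14 * 30.0, bsa_m2=1.8),
).to_unit("month")
rule = xs.ProgressionRule(reference="nadir", horizon=14.0)
predicted = xs.run_virtual_trials(
    pops, conc, rule=rule, n_patients=200, n_replicates=400, seed=5
)
reference = xs.run_virtual_trials(
    xs.build_human_distribution(xs.realized_population(true_params)),
    conc, rule=rule, n_patients=200, n_replicates=400, seed=5,
)
lo, hi = predicted.median_ttp_pi90
print(
    f"4. virtual trials: predicted median TTP {predicted.median_ttp:.2f} "
    f"months (90%PI {lo:.2f}-{hi:.2f})"
)
print(
    f"   trial driven by the panel's true parameters: "
    f"{reference.median_ttp:.2f} months"
)
print(
    f"   pipeline-vs-truth deviation: "
    f"{100 * abs(predicted.median_ttp / reference.median_ttp - 1):.1f}% — "
    "estimation plus Monte Carlo error accumulated across the whole chain."
)
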