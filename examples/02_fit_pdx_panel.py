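"""Generate a synthetic PDX panel and fit the population TGI model.

Creates a 12-study panel (control + treated arm each) at the default
study conditions, runs the two-stage population fit, and compares the
estimated typical values and variability against the generating truth.
"""

import xenoscale as xs

truth = xs.PanelTruth(n_studies=12)
panel, true_params = xs.generate_pdx_panel(truth, seed=42)
print(f"generated {len(panel)} studies; first study control arm:")
print("  days:", panel[0].control_times.astype(int).tolist())
print("  tumor [cm^3]:", [round(float(v), 3) for v in panel[0].control_obs])

fits = xs.fit_panel(panel, error="proportional", compute_se=False)
est = xs.fit_population(fits)
est.bootstrap = xs.bootstrap_population(fits, B=200, seed=7)

report = xs.recovery_report(truth, est)
realized = xs.realized_population(true_params)
report["theta_realized"] = [
    realized.theta.get(p, float("nan")) for p in report["parameter"].head(4)
] + [realized.corr_lambda0_k2]
cols = ["parameter", "theta_true", "theta_realized", "theta_est", "rel_bias"]
print("\nrecovery report (typical values):")
print(report[cols].round(3).to_string(index=False))
print(
    "\nrel_bias is (estimate / generating truth - 1). At n = 12 the "
    "panel's realized geometric means (theta_realized) wander well away "
    "from the generating values by draw luck alone; the estimates track "
    "the realized column much more closely, which is what recovery of a "
    "finite panel can deliver. lambda0 [1/day] and k2 [L/(mg*day)] are "
    "the two parameters that cross species; estimated corr(lambda0, k2) "
    f"= {est.corr_lambda0_k2:.2f} (generating value "
    f"{truth.corr_lambda0_k2}, realized {realized.corr_lambda0_k2:.2f})."
)
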