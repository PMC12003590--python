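"""Allometric scaling of a mouse population estimate to humans.

Takes a population estimate (here the generator's typical values with
their inter-PDX variability) and applies the body-weight power law with
the day-to-month unit conversion; the log-scale covariance of the
(lambda0, k2) random effects crosses species unchanged.
"""

import numpy as np

import xenoscale as xs
from xenoscale.translate import ScalingConfig

truth = xs.PanelTruth()
est = truth.population_estimate()
cfg = ScalingConfig()  # 70 kg human, 25 g mouse, alpha = 1/3, fu ratio 1

pop = xs.build_human_distribution(est, cfg)
print(f"allometric factor 30*(BW_h/BW_m)^(-1/3) = {cfg.factor:.4f}")
print(f"lambda0: {est.theta['lambda0']:.3f}/day  ->  {pop.lambda0_pop:.4f}/month")
print(f"k2:      {est.theta['k2']:.3f} L/(mg*day)  ->  {pop.k2_pop:.4f} L/(mg*month)")
print("human log-scale covariance (copied from the mouse lambda0/k2 block):")
print(np.array2string(pop.omega, precision=3))
print(
    f"\nGeometric CVs and the correlation ({pop.corr:.2f}) are invariant: "
    "scaling multiplies typical values only, so the spread of the "
    "lognormal population crosses species untouched."
)
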