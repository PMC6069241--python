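"""Threshold-switched pesticide wash-off and coefficient fitting.

Shows the regime rule (10 mg sediment threshold), the particle-bound
transfer function, equilibrium partitioning, and recovery of the transfer
coefficients by ordinary least squares from noisy synthetic storms.
"""

import numpy as np

from pyrewash import (
    WashoffParams, dissolved_fraction, fit_transfer_coefficients,
    predict_washoff,
)

params = WashoffParams(transfer_intercept=0.1, transfer_slope=0.3,
                       tss_threshold=10.0, regression_space="log10", kd=1e5)

m_avail = 5.0  # g available at the start of the storm
for tss in (4.0, 10.0, 40.0, 400.0):
    regime, load = predict_washoff(m_avail, tss, params)
    print(f"sediment load {tss:6.1f} mg -> {regime:14s}  washed {load:.3f} g")
# at or below 10 mg the whole available mass is washed (dissolved control);
# above, the washed fraction grows with log10 of the sediment load.

print(f"\nf_diss at 50 mg/L TSS: {dissolved_fraction(1e5, 50e-6):.3f} "
      "(strong particle association)")

rng = np.random.default_rng(0)
tss = 10.0 ** rng.uniform(1.05, 2.8, size=40)
frac = 0.1 + 0.3 * np.log10(tss) + rng.normal(0, 0.01, size=40)
fit = fit_transfer_coefficients(list(zip(tss, frac)), space="log10")
print(f"\nrefit from 40 noisy storms: a={fit.intercept:.3f}+-{fit.stderr_intercept:.3f} "
      f"b={fit.slope:.3f}+-{fit.stderr_slope:.3f}  R^2={fit.r_squared:.3f}")
# the fitted (a, b) match the generating coefficients within the quoted
# standard errors.
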