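"""Closed-form inner optima for scaling, offset and noise parameters.

For a group of datapoints sharing statics, the conditionally optimal values
are weighted least-squares expressions: s and b form a line fit of the data
against the simulated observable, and sigma^2 is the mean squared residual.
"""

import numpy as np

import hieropt as hp

rng = np.random.default_rng(0)
h = rng.uniform(0.5, 3.0, 12)            # simulated unscaled observable
y = 2.5 * h + 0.8 + rng.normal(0, 0.1, 12)  # relative data: s=2.5, b=0.8

s, b = hp.optimal_scaling_offset(h, y, sigma=1.0)
sigma, clipped = hp.optimal_sigma(y - (s * h + b), sigma_floor=1e-10)
print(f"optimal scaling s = {s:.4f}   (generated with 2.5)")
print(f"optimal offset  b = {b:.4f}   (generated with 0.8)")
print(f"optimal noise sigma = {sigma:.4f} (generated with 0.1), clipped={clipped}")

# With the offset fixed at zero the coupled formula reduces exactly to the
# single-scaling expression:
s_only, _ = hp.optimal_scaling_offset(h, y, sigma=1.0, b_fixed=0.0)
print(f"scaling with b fixed to 0: s = {s_only:.4f} "
      "(biased upward because the offset is absorbed)")
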