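"""Diagnosing fat tails: QQ-plot data and exact density curves.

Exports the plot-ready tables a database provider should publish: normal
QQ quantile pairs for a standardized sample (curvature away from the
identity line reveals the tail) and the exact density of the standardized
lognormal next to the Gaussian.
"""

import numpy as np

from fatnorms import (
    DistributionSpec, density_comparison, qq_data, sample, standardize,
)

spec = DistributionSpec.lognormal(0.5)
z = standardize(sample(spec, 10_000, seed=23), spec=spec, seed=23)
qq = qq_data(z)
print("QQ pairs (theoretical, sample) at the upper tail:")
for t, s in zip(qq.theoretical_quantiles[-3:], qq.sample_quantiles[-3:]):
    print(f"  {t:6.2f} {s:8.2f}")
print("sample quantiles far above theoretical: right-tail curvature.\n")

table = density_comparison(sigmas=(0.1, 0.5), grid=np.array([0.0, 2.0, 3.0, 4.0]))
print(table.round(5).to_string(index=False))
print(
    "\nAt x = 3 the sigma = 0.5 density is an order of magnitude above the "
    "Gaussian: that excess mass is exactly the surplus of 'abnormal' scores."
)
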