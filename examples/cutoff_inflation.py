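"""How fat tails inflate "abnormal" classifications at sigma cut-offs.

Simulates the 2-sigma cut-off over the lognormal compression grid: in each
replicate a lognormal and a Gaussian sample (n = 1000) are z-standardized
and values above +2 are counted; pooled counts give the inflation of
positives relative to the Gaussian.  The closed-form population ratio is
shown alongside.  Already at sigma_log = 0.1 — where skewness is 0.3 and
kurtosis only 4% above Gaussian — about a third more observations are
flagged "abnormal" than the nominal 2.3% rate implies.
"""

from fatnorms import Sim1Config, analytic_inflation_ratio, run_grid

config = Sim1Config(cutoffs=(2.0,), n=1000, reps=2000, seed=11)
print(f"{'sigma_log':>9} {'inflation %':>12} {'analytic %':>11}")
for cell in run_grid(config):
    oracle = 100 * (analytic_inflation_ratio(cell.sigma_log, 2.0) - 1)
    print(f"{cell.sigma_log:9.3f} {cell.inflation_pct:12.1f} {oracle:11.1f}")
print(
    "\ninflation % = percent excess of >2-sigma observations vs the Gaussian "
    "arm (pooled over 2000 replicates); analytic % = population-level ratio."
)
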