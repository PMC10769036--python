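"""Spurious "normalization" of extreme scores under fat tails.

For pre/post score pairs at a given test-retest reliability, the critical
difference z_{0.975} * sqrt(2 (1 - rho)) bounds the change explainable by
measurement error — under a homoscedastic Gaussian.  This example runs the
retest simulation at poor (0.5) and excellent (0.95) reliability and shows
the three per-cell statistics: mean log10 Breusch-Pagan p (0.43 below zero
under the null, strongly negative under heteroscedasticity), the error-slope
statistic log10(1 + slope), and the inflation of "normalization" events
(pre > 2 and pre - post above the critical difference) relative to a
Gaussian arm.  Note the paradox: the inflation is LARGEST at excellent
reliability, because a small critical difference is easiest for tail noise
to cross.
"""

from fatnorms import critical_difference, run_retest_grid

for rho in (0.5, 0.95):
    print(f"rho_jj = {rho}: critical difference = "
          f"{critical_difference(rho).value:.3f}")

cells = run_retest_grid(rhos=(0.5, 0.95), sigmas=(0.001, 0.271, 0.5),
                        n=1000, reps=500, seed=13)
print(f"\n{'rho':>5} {'sigma':>6} {'mean log10 BP p':>16} "
      f"{'slope_log':>10} {'normalization inflation':>24}")
for c in cells:
    print(f"{c.rho_jj:5.2f} {c.sigma_log:6.3f} {c.mean_log10_bp_p:16.2f} "
          f"{c.slope_log:10.3f} {c.exceed_inflation:24.2f}")
print(
    "\nsigma 0.001 is the Gaussian reference column: BP p ~ -0.43, slope ~ 0, "
    "inflation ~ 0.  Inflation > 0 means more apparent pre-to-post recoveries "
    "than test-retest reliability can explain."
)
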