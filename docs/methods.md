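# Methods

## The generating model

All synthetic scores derive from a standard normal latent variable Z. The
fat-tailed family of interest is the lognormal X = exp(σZ) with the log-mean
fixed at 0: every simulation z-standardizes each sample, which removes both
location and scale of the raw variable, so the log-mean is unidentifiable
and fixing it keeps the closed forms one-line (E X = e^{σ²/2},
Var X = (e^{σ²}−1)e^{σ²}, skewness (e^{σ²}+2)√(e^{σ²}−1), excess kurtosis
e^{4σ²}+2e^{3σ²}+3e^{2σ²}−6). The grid σ ∈ {0.001, 0.100, 0.157, 0.214,
0.271, 0.329, 0.386, 0.443, 0.500} spans kurtosis ratios 1.00–2.97
(population) or ≈ 1.00–2.8 (mean sample value at n = 1000), covering the
mild fat-tailedness reported for normative EEG databases. σ = 0.001 doubles
as the Gaussian reference column. Alternate families for the supplementary
comparisons: Student t (df 3–40), chi-squared (df 1–20), Pareto I with
minimum 1 (tail exponents 0.5–8; moments beyond the (a−1)-th do not exist,
and `theoretical_kurtosis_ratio` returns `inf` rather than raising when the
fourth moment is undefined — non-existence is a value on the fat-tailedness
axis, not an input error).

## Moment conventions

Sample skewness g₁ = m₃/m₂^{3/2} and kurtosis b₂ = m₄/m₂², central moments
with the 1/n denominator and no small-sample correction, so a Gaussian has
kurtosis 3 and the reported "kurtosis ratio" is b₂/3. This is the convention
of the R `moments` package in which normative-database moments are usually
reported. Standardization uses the n−1 sample SD; at n = 1000 the n vs n−1
choice is orders of magnitude below every tolerance here but is fixed for
bit-reproducibility. Under fat tails the *mean* per-replicate sample moment
at n = 1000 sits well below the population value (e.g. mean b₂/3 ≈ 2.8
against a population 2.97 at σ = 0.5) and the per-replicate distribution of
b₂ is itself heavily right-skewed, so its median (≈ 2.5) sits well below its
mean; published moment tables that do not state their aggregation are
ambiguous in exactly this range. This package reports means over replicates
throughout, with the exact population values printed alongside.

## Simulation 1: cut-off inflation

Design: cut-offs {1.5, 2.0, 2.5, 3.0} × the σ grid, k = 10000 replicates of
n = 1000 per cell. Each replicate standardizes one lognormal and one
Gaussian sample by their own moments — per-replicate standardization is the
operative feature, it is what a finite norm sample does. Counting is
one-sided (> +c) by default: the lognormal's excess mass is in the right
tail, and its short left tail would otherwise *deflate* the two-sided count
at small σ (ratio ≈ 0.98 at σ = 0.1, c = 2, against 1.33 one-sided); a
two-sided mode is provided. Counts are pooled across replicates before the
ratio is formed because the expected Gaussian count per replicate at c = 3
is ≈ 1.35, making per-replicate ratios frequently undefined. The Gaussian
denominator is simulated by default (two noisy arms, as a real comparison
would have); an `analytic_expected` mode replaces it with k·n·(1−Φ(c)) for
variance reduction and oracle tests. If a pooled simulated denominator is 0
the analytic expectation is substituted with a logged warning. Cells whose
expected Gaussian count is below 10 log a precision warning.

Oracle: a standardized lognormal exceeds +c iff the raw value exceeds
μ + c·s, so the population ratio is [1 − Φ(ln(μ + c·s)/σ)]/[1 − Φ(c)].
Per-replicate standardization at n = 1000 inflates the simulated ratio a few
percent above this (the sample SD underestimates the true SD under fat
tails, pushing the cut-off inward); the effect scales away by n = 10⁵, where
simulated and analytic ratios agree within 2%.

## Simulation 2: retest changes

Pre/post pairs are built from a bivariate standard normal with correlation
ρ on the latent (log) scale, each margin transformed by exp(σ·) and
standardized. The reliability grid is {0.5, 0.7, 0.8, 0.95}. The latent
scale carries ρ by default — the pair is "the same measurement with the same
logarithmic compression twice" — and a `corr_scale="raw"` switch instead
solves ρ_latent = log1p(ρ_raw(e^{σ²}−1))/σ² so the raw-scale correlation
hits the target; the raw-scale correlation under the latent scheme is the
closed form (e^{ρσ²}−1)/(e^{σ²}−1).

Per cell (k = 10000 replicates of n = 1000 pairs), three statistics:

* **Breusch–Pagan.** OLS of D = pre − post on pre; auxiliary regression of
  squared residuals on pre; studentized (Koenker) statistic LM = n·R²_aux
  against χ²(1) by default (the default of standard R/statsmodels
  implementations), classical variant selectable. Reported as the mean over
  replicates of log₁₀ p — mean of logs, because under the null p is uniform
  and E[log₁₀ U] = −log₁₀ e = −0.4343, giving an exact null calibration
  check; the log of the mean would not.
* **Error slope.** Default: the auxiliary slope of squared residuals on
  pre, reported as log₁₀(1 + mean slope). The literal slope of D on pre is
  *not* used as the default because its expectation under the bivariate
  Gaussian is 1 − ρ (regression to the mean), not the 0 a null column must
  show; the squared-residual slope is 0 under homoscedasticity and measures
  precisely the error growth that invalidates a uniform critical
  difference. `abs_diff_on_pre` and Bland–Altman-style `diff_on_avg`
  definitions are selectable.
* **Normalization inflation.** Critical difference
  crit = z_{1−α/2}√(2(1−ρ)) at α = 0.05 two-sided (α is a convention, fixed
  at the conventional value). Events are counted one-sidedly — pre > 2 and
  D > crit, the "elevated score that then recovers" pattern — pooled over
  replicates, in the fat-tailed arm and a Gaussian arm at the same ρ;
  reported as count_fat/count_gauss − 1. At ρ = 1 the difference degenerates
  to exactly 0, strict inequalities give no events in either arm, and the
  statistic is 0 by convention. A zero Gaussian count otherwise falls back
  to the analytic expected count from the bivariate normal orthant
  probability (corr(pre, D) = √((1−ρ)/2)), with a logged warning.

The magnitudes of the interior grid cells depend materially on the pairing
scheme (latent vs raw ρ) and slope definition; the *null column*
(−0.4343, 0, 0), the emergence of systematic heteroscedasticity by
σ ≈ 0.27, and the orderings — more heteroscedasticity with more
compression, and more spurious normalization at ρ = 0.95 than at ρ = 0.5
under strong compression — are scheme-robust, and those are what the test
suite gates on.

## Reporting utilities

QQ data use plotting positions (i − 0.5)/n against Φ⁻¹. The standardized
lognormal density is exact via change of variables: f(x) = s·f_L(μ + s·x)
for μ + s·x > 0, zero otherwise. Percentile cut-offs use the
linear-interpolation quantile convention (numpy default) — tail percentiles
are convention-sensitive, so the convention is part of the contract — with a
seeded bootstrap percentile CI; a requested level with fewer than 5 expected
observations in the relevant tail raises a precision error rather than
returning a pseudo-estimate.

## Randomness and reproducibility

Every entry point takes an integer seed. Per-cell generators are derived
via `SeedSequence(seed, spawn_key=(namespace, cell parameters))`, so a cell
result is invariant to which grid it is computed in, different modules
sharing one seed draw independent streams, and every CSV is bit-reproducible
from its JSON sidecar (`fatnorms rerun`). Replicate blocks are processed in
chunks of ≈ 5 × 10⁶ values so memory stays near 100 MB whatever the design.

## Problem sizes

The shipped defaults are the full study design (n = 1000, k = 10000;
≈ 3.6 × 10⁸ draws for the full Simulation-1 grid, about a minute
vectorized). The test suite exercises the same machinery at k = 500–2000
for grid-shaped checks — the pooled Monte Carlo error there is still an
order of magnitude below the asserted tolerances — and at the full
k = 10000 where a tolerance genuinely needs it (the ±0.02 null-calibration
band of the Breusch–Pagan panel). Oracle-equivalence tests run at n = 10⁵
with the analytic denominator and replicate counts chosen so every cell's
pooled count exceeds ≈ 4.5 × 10⁴ (3 relative SEs below the 2% band).

## Limitations

* The generator emulates the *distributional* properties claimed for
  normative EEG parameters, not EEG itself: no autocorrelation within a
  recording, no age/sex stratification, no measurement artefacts. Passing
  tests show the consequences of fat tails for the classification rules,
  not that any particular database is lognormal.
* Pairing schemes more exotic than latent/raw-scale correlation (e.g.
  additive true-score models on the raw scale) are not implemented; the
  interior retest-cell magnitudes would change under them.
* Box–Cox or other transformation *fitting* is out of scope; the package
  quantifies the cost of not transforming, not how to transform.
* The bootstrap CI for percentile cut-offs is the simple percentile method;
  at extreme levels and small n it is known to undercover.
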