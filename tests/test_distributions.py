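"""Samplers, standardization and moment formulas."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from fatnorms import (
    DegenerateSampleError,
    DistributionSpec,
    ParameterError,
    correlated_pairs,
    lognormal_theoretical_moments,
    sample,
    sample_moments,
    standardize,
    theoretical_kurtosis_ratio,
)
from fatnorms.distributions import paired_matrices, row_moments, standardize_rows


class TestDistributionSpec:
    @pytest.mark.parametrize(
        "build",
        [
            lambda: DistributionSpec.lognormal(0.0),
            lambda: DistributionSpec.lognormal(-0.1),
            lambda: DistributionSpec.pareto(0.0),
            lambda: DistributionSpec.pareto(2.0, location=-1.0),
            lambda: DistributionSpec("lognormal"),
            lambda: DistributionSpec("gaussian", sigma_log=0.5),
            lambda: DistributionSpec("student_t", df=5, shape=2.0),
            lambda: DistributionSpec("weibull"),
        ],
    )
    def test_invalid_parameters_rejected(self, build):
        with pytest.raises(ParameterError):
            build()

    def test_param_exposes_the_fat_tailedness_scalar(self):
        assert DistributionSpec.lognormal(0.5).param == 0.5
        assert DistributionSpec.student_t(5).param == 5
        assert DistributionSpec.pareto(2).param == 2
        assert DistributionSpec.gaussian().param is None


class TestSample:
    def test_seed_determinism_bit_identical(self):
        spec = DistributionSpec.lognormal(0.3)
        assert np.array_equal(sample(spec, 1000, 7), sample(spec, 1000, 7))
        assert not np.array_equal(sample(spec, 1000, 7), sample(spec, 1000, 8))

    def test_n_too_small(self):
        with pytest.raises(ParameterError):
            sample(DistributionSpec.gaussian(), 1, 0)

    def test_lognormal_raw_mean_matches_closed_form(self):
        # E X = e^{sigma^2 / 2} = 1.13315 at sigma = 0.5
        x = sample(DistributionSpec.lognormal(0.5), 1_000_000, 3)
        assert x.mean() == pytest.approx(math.exp(0.125), abs=0.005)

    def test_tiny_sigma_is_gaussian_shaped(self):
        x = sample(DistributionSpec.lognormal(0.001), 1_000_000, 4)
        assert sample_moments(x).skewness_g1 == pytest.approx(0.0, abs=0.01)

    def test_pareto_minimum_at_location(self):
        x = sample(DistributionSpec.pareto(2.0, location=1.0), 10_000, 5)
        assert x.min() >= 1.0

    @pytest.mark.parametrize(
        "spec",
        [
            DistributionSpec.gaussian(),
            DistributionSpec.student_t(5),
            DistributionSpec.chi_squared(3),
        ],
    )
    def test_family_dispatch_draws_from_the_right_law(self, spec):
        x = sample(spec, 50_000, 11)
        ref = {
            "gaussian": stats.norm,
            "student_t": stats.t(5),
            "chi_squared": stats.chi2(3),
        }[spec.family]
        assert stats.kstest(x, ref.cdf).pvalue > 0.01


class TestStandardize:
    def test_symmetric_three_point_case(self):
        assert np.allclose(standardize([1, 2, 3]).values, [-1, 0, 1])

    def test_hand_computed_four_point_case(self):
        # [0,0,0,4]: mean 1, SD 2 (n-1 denominator) -> max element 1.5
        z = standardize([0, 0, 0, 4]).values
        assert abs(z.mean()) < 1e-10
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-10)
        assert z.max() == pytest.approx(1.5)

    def test_idempotent(self, rng):
        x = rng.normal(3.0, 7.0, size=500)
        once = standardize(x)
        twice = standardize(once)
        assert np.allclose(once.values, twice.values, atol=1e-10)

    def test_affine_equivariant(self, rng):
        x = rng.normal(size=200)
        assert np.allclose(
            standardize(x).values, standardize(5.0 * x - 3.0).values, atol=1e-9
        )

    def test_constant_input_raises(self):
        with pytest.raises(DegenerateSampleError):
            standardize([2.0, 2.0, 2.0])

    def test_rowwise_matches_scalar(self, rng):
        m = rng.lognormal(sigma=0.4, size=(5, 100))
        rows = standardize_rows(m)
        for i in range(5):
            assert np.allclose(rows[i], standardize(m[i]).values, atol=1e-10)


class TestSampleMoments:
    def test_two_point_symmetric_minimum_kurtosis(self):
        ms = sample_moments([-1, 1, -1, 1])
        assert ms.skewness_g1 == pytest.approx(0.0, abs=1e-12)
        assert ms.kurtosis_b2 == pytest.approx(1.0)
        assert ms.kurtosis_ratio == pytest.approx(1.0 / 3.0)

    def test_hand_computed_skewness(self):
        # [0,0,0,4]: m2 = 3, m3 = 6 -> g1 = 6 / 3^1.5
        ms = sample_moments([0, 0, 0, 4])
        assert ms.skewness_g1 == pytest.approx(6 / 3**1.5)

    def test_matches_scipy_conventions(self, rng):
        x = rng.lognormal(sigma=0.5, size=1000)
        ms = sample_moments(x)
        assert ms.skewness_g1 == pytest.approx(stats.skew(x, bias=True))
        assert ms.kurtosis_b2 == pytest.approx(
            stats.kurtosis(x, fisher=False, bias=True)
        )

    def test_constant_input_raises(self):
        with pytest.raises(DegenerateSampleError):
            sample_moments([1.0] * 10)

    def test_row_moments_match_scalar(self, rng):
        m = rng.lognormal(sigma=0.3, size=(4, 200))
        g1, b2 = row_moments(m)
        for i in range(4):
            ms = sample_moments(m[i])
            assert g1[i] == pytest.approx(ms.skewness_g1)
            assert b2[i] == pytest.approx(ms.kurtosis_b2)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.floats(-100, 100, allow_nan=False, allow_subnormal=False),
            min_size=4,
            max_size=50,
            unique=True,
        ).filter(lambda v: max(v) - min(v) > 1e-3)
    )
    def test_pearson_inequality(self, values):
        # b2 >= 1 + g1^2 for every sample
        ms = sample_moments(np.array(values))
        assert ms.kurtosis_b2 >= (1.0 + ms.skewness_g1**2) * (1 - 1e-9)


class TestTheoreticalMoments:
    def test_degenerate_limit(self):
        m = lognormal_theoretical_moments(1e-8)
        assert m.mean == pytest.approx(1.0)
        assert m.sd == pytest.approx(0.0, abs=1e-6)
        assert m.skewness == pytest.approx(0.0, abs=1e-6)
        assert m.excess_kurtosis == pytest.approx(0.0, abs=1e-6)

    def test_closed_forms_at_half(self):
        m = lognormal_theoretical_moments(0.5)
        assert m.skewness == pytest.approx(1.7502, abs=1e-4)
        assert m.excess_kurtosis == pytest.approx(5.8985, abs=1e-4)

    def test_matches_scipy_lognorm(self):
        for s in (0.1, 0.3, 0.5):
            mean, var, skew, exkurt = stats.lognorm.stats(s, moments="mvsk")
            m = lognormal_theoretical_moments(s)
            assert m.mean == pytest.approx(float(mean))
            assert m.sd == pytest.approx(float(np.sqrt(var)))
            assert m.skewness == pytest.approx(float(skew))
            assert m.excess_kurtosis == pytest.approx(float(exkurt))

    def test_invalid_sigma(self):
        with pytest.raises(ParameterError):
            lognormal_theoretical_moments(-1.0)


class TestKurtosisRatio:
    @pytest.mark.parametrize(
        "spec, expected",
        [
            (DistributionSpec.gaussian(), 1.0),
            (DistributionSpec.student_t(1e9), pytest.approx(1.0, abs=1e-8)),
            (DistributionSpec.student_t(5), 3.0),  # excess 6/(df-4) = 6
            (DistributionSpec.chi_squared(12), pytest.approx(4.0 / 3.0)),
            (DistributionSpec.student_t(4), math.inf),
            (DistributionSpec.pareto(3), math.inf),
        ],
    )
    def test_known_values(self, spec, expected):
        assert theoretical_kurtosis_ratio(spec) == expected

    def test_pareto_matches_scipy(self):
        spec = DistributionSpec.pareto(8)
        assert theoretical_kurtosis_ratio(spec) == pytest.approx(
            (3.0 + float(stats.pareto(8).stats(moments="k"))) / 3.0
        )


class TestCorrelatedPairs:
    def test_gaussian_pair_hits_target_correlation(self):
        pair = correlated_pairs(DistributionSpec.gaussian(), 0.95, 300_000, 1)
        assert np.corrcoef(pair.pre, pair.post)[0, 1] == pytest.approx(0.95, abs=0.002)

    def test_margins_standardized_and_diff_consistent(self):
        pair = correlated_pairs(DistributionSpec.lognormal(0.3), 0.7, 5000, 2)
        for v in (pair.pre, pair.post):
            assert abs(v.mean()) < 1e-10
            assert v.std(ddof=1) == pytest.approx(1.0, abs=1e-10)
        assert np.allclose(pair.diff, pair.pre - pair.post)

    def test_latent_scheme_matches_bivariate_lognormal_closed_form(self):
        # raw-scale corr = (e^{rho s^2} - 1) / (e^{s^2} - 1) = 0.4688 at
        # s = 0.5, latent rho = 0.5; standardization is affine so the
        # correlation of the standardized margins equals the raw one.
        pair = correlated_pairs(DistributionSpec.lognormal(0.5), 0.5, 1_000_000, 3)
        expected = (math.exp(0.125) - 1.0) / (math.exp(0.25) - 1.0)
        assert np.corrcoef(pair.pre, pair.post)[0, 1] == pytest.approx(
            expected, abs=0.005
        )

    def test_raw_scheme_hits_target_on_the_raw_scale(self):
        pair = correlated_pairs(
            DistributionSpec.lognormal(0.5), 0.5, 1_000_000, 4, corr_scale="raw"
        )
        assert np.corrcoef(pair.pre, pair.post)[0, 1] == pytest.approx(0.5, abs=0.005)

    def test_zero_correlation(self):
        pair = correlated_pairs(DistributionSpec.lognormal(0.4), 0.0, 200_000, 5)
        assert np.corrcoef(pair.pre, pair.post)[0, 1] == pytest.approx(0.0, abs=0.01)

    def test_invalid_rho(self):
        with pytest.raises(ParameterError):
            correlated_pairs(DistributionSpec.gaussian(), 1.5, 100, 0)

    def test_unsupported_family(self):
        with pytest.raises(ParameterError):
            correlated_pairs(DistributionSpec.student_t(5), 0.5, 100, 0)

    def test_paired_matrices_deterministic(self):
        r1 = np.random.default_rng(9)
        r2 = np.random.default_rng(9)
        a = paired_matrices(DistributionSpec.lognormal(0.2), 0.8, 3, 50, r1)
        b = paired_matrices(DistributionSpec.lognormal(0.2), 0.8, 3, 50, r2)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
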