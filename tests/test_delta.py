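import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import corrdelta as cd
from corrdelta.delta import DegenerateOutputError, GivenDataDelta


class TestEstimateDensity:
    def test_standard_normal_density_at_zero(self, rng):
        d = cd.estimate_density(rng.standard_normal(100_000))
        at0 = np.interp(0.0, d.grid, d.density)
        assert 0.37 < at0 < 0.43  # phi(0) = 0.3989

    def test_integral_is_one(self, rng):
        for sample in (rng.standard_normal(500), rng.exponential(2.0, 5000)):
            d = cd.estimate_density(sample)
            assert 0.98 < d.integral() < 1.02

    def test_constant_input_raises_degenerate(self):
        with pytest.raises(DegenerateOutputError):
            cd.estimate_density(np.ones(100))

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="at least 8"):
            cd.estimate_density(np.arange(5.0))


class TestSeparationMeasure:
    def test_identical_densities_give_zero(self, rng):
        d = cd.estimate_density(rng.standard_normal(1000))
        assert cd.separation_measure(d, d) == 0.0

    def test_disjoint_densities_approach_two(self):
        grid = np.linspace(0.0, 10.0, 2001)
        f = np.where(np.abs(grid - 2) < 1, 0.5 * (1 - np.abs(grid - 2)) * 2, 0)
        g = np.where(np.abs(grid - 8) < 1, 0.5 * (1 - np.abs(grid - 8)) * 2, 0)
        da = cd.DensityOnGrid(grid=grid, density=f)
        db = cd.DensityOnGrid(grid=grid, density=g)
        assert 1.96 <= cd.separation_measure(da, db) <= 2.0

    def test_shifted_normals_match_closed_form(self):
        # L1(N(0,1), N(1,1)) = 2*(2*Phi(0.5) - 1) = 0.7658...
        from scipy.stats import norm

        grid = np.linspace(-8, 9, 4001)
        da = cd.DensityOnGrid(grid=grid, density=norm.pdf(grid))
        db = cd.DensityOnGrid(grid=grid, density=norm.pdf(grid, loc=1.0))
        assert cd.separation_measure(da, db) == pytest.approx(
            0.7658499, abs=1e-4
        )

    def test_grid_mismatch_rejected(self, rng):
        d1 = cd.estimate_density(rng.standard_normal(100))
        d2 = cd.estimate_density(rng.standard_normal(100) + 5)
        with pytest.raises(ValueError, match="grid"):
            cd.separation_measure(d1, d2)


class TestEstimateDelta:
    def test_deterministic_bijection_has_delta_near_one(self, rng):
        x = rng.standard_normal(20_000)
        df = pd.DataFrame({"X1": x})
        est = cd.estimate_delta(df, x, partitions=30)
        assert est["X1"] >= 0.8

    def test_linear_example_ordering(self, linear_indep):
        X, Y = linear_indep
        est = cd.estimate_delta(X, Y, partitions=30)
        assert abs(est["X1"] - est["X2"]) < 0.02
        assert est["X1"] > est["X3"] > est["X4"]

    def test_rank_preserving_input_transform_leaves_delta_unchanged(
        self, linear_indep
    ):
        X, Y = linear_indep
        base = cd.estimate_delta(X, Y, partitions=30)
        warped = X.data.copy()
        warped["X1"] = np.exp(warped["X1"])          # strictly increasing
        warped["X2"] = -np.exp(-warped["X2"])        # strictly increasing
        warped["X3"] = warped["X3"] ** 3             # strictly increasing
        est = cd.estimate_delta(warped, Y, partitions=30)
        for name in base:
            assert abs(est[name] - base[name]) < 1e-12

    def test_constant_column_excluded_with_warning(self, rng):
        df = pd.DataFrame(
            {"a": rng.standard_normal(2000), "c": np.ones(2000)}
        )
        y = df["a"].to_numpy() * 2
        with pytest.warns(UserWarning, match="constant columns"):
            est = cd.estimate_delta(df, y, partitions=10)
        assert "c" not in est

    def test_nonfinite_outputs_dropped_in_tandem(self, rng):
        df = pd.DataFrame({"a": rng.standard_normal(2000)})
        y = df["a"].to_numpy().copy()
        y[:100] = np.nan
        with pytest.warns(UserWarning, match="dropped 100 rows"):
            engine = GivenDataDelta(df, y, partitions=10)
        assert engine.dropped_rows == 100
        assert engine.n == 1900

    def test_too_few_samples_per_class_rejected(self, rng):
        df = pd.DataFrame({"a": rng.standard_normal(100)})
        with pytest.raises(ValueError, match="50"):
            cd.estimate_delta(df, df["a"].to_numpy(), partitions=30)

    def test_all_deltas_within_unit_interval(self, linear_corr):
        X, Y = linear_corr
        est = cd.estimate_delta(X, Y, partitions=30)
        assert all(0.0 <= v <= 1.0 for v in est.values())


class TestBootstrap:
    def test_ci_brackets_median_and_seed_determinism(self, rng):
        x = rng.standard_normal(3000)
        df = pd.DataFrame({"a": x, "b": rng.standard_normal(3000)})
        y = 3 * x + rng.standard_normal(3000)
        ests1 = cd.bootstrap_deltas(df, y, partitions=10, B=50, seed=42)
        ests2 = cd.bootstrap_deltas(df, y, partitions=10, B=50, seed=42)
        for e1, e2 in zip(ests1, ests2):
            assert e1 == e2
            assert e1.ci_low <= e1.bootstrap_median <= e1.ci_high

    def test_smaller_sample_widens_intervals(self):
        # bootstrap CI width for the weak input X3 shrinks with n
        widths = {}
        for n in (5000, 20_000):
            X, Y = cd.linear_benchmark(n, seed=7, independent=True)
            ests = cd.bootstrap_deltas(X, Y, partitions=10, B=60, seed=1)
            e = {x.name: x for x in ests}["X3"]
            widths[n] = e.ci_high - e.ci_low
        assert widths[5000] > widths[20_000]

    def test_b_below_two_rejected(self, rng):
        df = pd.DataFrame({"a": rng.standard_normal(1000)})
        with pytest.raises(ValueError):
            cd.bootstrap_deltas(df, df["a"].to_numpy(), partitions=10, B=1)


class TestSignificance:
    def test_noise_threshold_is_constant_for_constant_vector(self):
        assert cd.noise_threshold(np.full(100, 0.03)) == pytest.approx(0.03)

    def test_noise_threshold_linear_interpolation(self):
        # independent hand computation of the linear-interp quantile on
        # the explicit sequence {0.01 k, k = 1..1000}
        v = 0.01 * np.arange(1, 1001)
        pos = (v.size - 1) * 0.975
        k = int(np.floor(pos))
        expected = v[k] + (pos - k) * (v[k + 1] - v[k])
        assert cd.noise_threshold(v) == pytest.approx(expected)
        assert expected == pytest.approx(9.75025)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0, max_value=1, allow_nan=False),
            min_size=1,
            max_size=200,
        )
    )
    def test_noise_threshold_bracketed_by_extremes(self, values):
        t = cd.noise_threshold(values)
        assert min(values) <= t <= max(values)

    def test_apply_significance_zeroing(self):
        e_hi = cd.DeltaEstimate("a", 0.05, 0.05, 0.04, 0.06)
        e_lo = cd.DeltaEstimate("b", 0.01, 0.01, 0.005, 0.015)
        hi, lo = cd.apply_significance([e_hi, e_lo], threshold=0.02)
        assert hi.significant and hi.zeroed_value == 0.05
        assert not lo.significant and lo.zeroed_value == 0.0

    def test_empty_noise_vector_rejected(self):
        with pytest.raises(ValueError):
            cd.noise_threshold([])


class TestOracle:
    def test_limits(self):
        # delta = 1 for a deterministic bijection, 0 for an irrelevant input
        orc = cd.gaussian_delta_oracle([1.0, 0.0])
        assert orc["X1"] == pytest.approx(1.0, abs=1e-4)
        assert orc["X2"] == pytest.approx(0.0, abs=1e-4)

    def test_rescaling_invariance(self):
        # delta is invariant under jointly rescaling all coefficients
        a = cd.gaussian_delta_oracle([100.0, 100.0, 10.0, 0.0])
        b = cd.gaussian_delta_oracle([1.0, 1.0, 0.1, 0.0])
        for k in a:
            assert a[k] == pytest.approx(b[k], abs=1e-9)

    def test_linear_example_orderings(self):
        spec = cd.LinearBenchmarkSpec()
        ind = cd.gaussian_delta_oracle(spec.coefficients)
        cor = cd.gaussian_delta_oracle(spec.coefficients, spec.correlation())
        assert ind["X1"] == pytest.approx(ind["X2"], abs=1e-6)
        assert ind["X1"] > ind["X3"] > ind["X4"] == 0.0
        assert cor["X4"] > cor["X3"]
        assert cor["X1"] == pytest.approx(ind["X1"], abs=1e-6)
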