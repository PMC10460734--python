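import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import corrdelta as cd
from corrdelta.distributions import CorrelationTemplate


class TestParameterSpec:
    def test_lognormal_requires_positive_typical_value(self):
        with pytest.raises(ValueError):
            cd.ParameterSpec("a", typical_value=-1.0, cv=0.1)

    def test_negative_cv_rejected(self):
        with pytest.raises(ValueError):
            cd.ParameterSpec("a", typical_value=1.0, cv=-0.1)


class TestBuildJoint:
    def test_zero_cv_gives_point_mass(self):
        joint = cd.build_joint([cd.ParameterSpec("a", 1.0, 0.0)])
        assert joint.log_location[0] == 0.0
        assert joint.log_scale[0] == 0.0

    def test_lognormal_transform_matches_cv_convention(self):
        # drug potency k2 under the low-accuracy scenario: 40% CV
        joint = cd.build_joint([cd.ParameterSpec("k2", 0.129, 0.40)])
        assert joint.log_location[0] == pytest.approx(np.log(0.129))
        assert joint.log_scale[0] == pytest.approx(np.sqrt(np.log(1.16)))

    def test_non_pd_correlation_rejected(self):
        specs = [cd.ParameterSpec(n, 1.0, 0.2) for n in "abc"]
        bad = np.array([[1, 0.9, -0.9], [0.9, 1, 0.9], [-0.9, 0.9, 1.0]])
        with pytest.raises(ValueError, match="positive definite"):
            cd.build_joint(specs, bad)

    def test_dimension_mismatch_rejected(self):
        specs = [cd.ParameterSpec("a", 1.0, 0.2)]
        with pytest.raises(ValueError):
            cd.build_joint(specs, np.eye(2))

    def test_duplicate_names_rejected(self):
        specs = [cd.ParameterSpec("a", 1.0, 0.2)] * 2
        with pytest.raises(ValueError, match="unique"):
            cd.build_joint(specs)


class TestDrawSamples:
    def test_zero_cv_draws_constant_columns(self):
        joint = cd.build_joint(
            [cd.ParameterSpec("a", 2.5, 0.0), cd.ParameterSpec("b", 1.0, 0.0)]
        )
        s = cd.draw_samples(joint, 50, seed=1)
        assert np.allclose(s.data["a"], 2.5)
        assert np.allclose(s.data["b"], 1.0)

    def test_seed_determinism(self, cv1_joint):
        a = cd.draw_samples(cv1_joint, 500, seed=7)
        b = cd.draw_samples(cv1_joint, 500, seed=7)
        assert a.data.equals(b.data)

    def test_empirical_median_matches_typical_value(self):
        joint = cd.build_joint([cd.ParameterSpec("a", 1.0, 0.5)])
        s = cd.draw_samples(joint, 100_000, seed=3)
        assert 0.99 < s.data["a"].median() < 1.01

    def test_empirical_cv_roundtrip(self, cv1_joint):
        # natural-scale CV of the draws converges to the requested CV
        s = cd.draw_samples(cv1_joint, 100_000, seed=4)
        specs = {p.name: p for p in cd.deb_parameter_scenario("CV1")}
        for name in cv1_joint.names:
            col = s.data[name]
            emp_cv = col.std() / col.mean()
            assert emp_cv == pytest.approx(specs[name].cv, rel=0.02)

    def test_log_scale_correlation_matches_target(self):
        corr = np.array([[1.0, 0.8], [0.8, 1.0]])
        joint = cd.build_joint(
            [cd.ParameterSpec("a", 1.0, 0.3), cd.ParameterSpec("b", 2.0, 0.6)],
            corr,
        )
        s = cd.draw_samples(joint, 100_000, seed=5)
        logx = np.log(s.data.to_numpy())
        emp = np.corrcoef(logx.T)
        assert abs(emp[0, 1] - 0.8) < 0.01

    def test_independent_flag_breaks_correlation_keeps_marginals(self):
        corr = np.array([[1.0, 0.9], [0.9, 1.0]])
        joint = cd.build_joint(
            [cd.ParameterSpec("a", 1.0, 0.3), cd.ParameterSpec("b", 1.0, 0.3)],
            corr,
        )
        s_ind = cd.draw_samples(joint, 100_000, seed=6, independent=True)
        s_cor = cd.draw_samples(joint, 100_000, seed=7, independent=False)
        logx = np.log(s_ind.data.to_numpy())
        assert abs(np.corrcoef(logx.T)[0, 1]) < 0.01
        from scipy.stats import ks_2samp

        for name in ("a", "b"):
            ks = ks_2samp(s_ind.data[name], s_cor.data[name]).statistic
            assert ks < 0.01

    def test_n_below_two_rejected(self, cv1_joint):
        with pytest.raises(ValueError):
            cd.draw_samples(cv1_joint, 1, seed=0)


class TestNoiseColumn:
    def test_appends_standard_normal_column(self, cv1_joint):
        s = cd.draw_samples(cv1_joint, 100_000, seed=8)
        s2 = cd.append_noise_column(s, seed=9)
        assert s2.data.columns[-1] == "Noise"
        assert s2.data.shape[1] == s.data.shape[1] + 1
        noise = s2.data["Noise"]
        assert abs(noise.mean()) < 0.02
        assert 0.99 < noise.std() < 1.01
        for name in cv1_joint.names:
            r = np.corrcoef(noise, np.log(s2.data[name]))[0, 1]
            assert abs(r) < 0.01

    def test_duplicate_noise_rejected(self, cv1_joint):
        s = cd.append_noise_column(cd.draw_samples(cv1_joint, 100, seed=1), 2)
        with pytest.raises(ValueError, match="Noise"):
            cd.append_noise_column(s, seed=3)


def _template(values, names=None):
    values = np.asarray(values, float)
    names = names or tuple(f"p{i}" for i in range(len(values)))
    return CorrelationTemplate(names=names, values=values)


class TestCompleteCorrelation:
    def test_fully_known_pd_matrix_unchanged(self):
        m = np.array([[1.0, 0.5], [0.5, 1.0]])
        out = cd.complete_correlation(_template(m))
        assert np.array_equal(out, m)

    def test_all_unknown_gives_identity(self):
        nan = np.nan
        m = [[1.0, nan, nan], [nan, 1.0, nan], [nan, nan, 1.0]]
        assert np.array_equal(cd.complete_correlation(_template(m)), np.eye(3))

    def test_partial_completion_stays_feasible(self):
        # with r12 = r13 = 0.95 fixed, PD forces r23 > 2*0.95^2 - 1 = 0.805
        nan = np.nan
        m = [[1.0, 0.95, 0.95], [0.95, 1.0, nan], [0.95, nan, 1.0]]
        out = cd.complete_correlation(_template(m))
        assert out[0, 1] == pytest.approx(0.95)
        assert out[0, 2] == pytest.approx(0.95)
        assert 0.805 < out[1, 2] < 1.0
        assert np.linalg.eigvalsh(out).min() > 0

    def test_infeasible_known_entries_warn_and_perturb(self):
        # r12 = 0.95, r13 = 0.95, r23 = -0.9 admits no PD completion
        m = [[1.0, 0.95, 0.95], [0.95, 1.0, -0.9], [0.95, -0.9, 1.0]]
        with pytest.warns(UserWarning, match="perturbed"):
            out = cd.complete_correlation(_template(m))
        assert np.linalg.eigvalsh(out).min() > 0

    def test_asymmetric_template_rejected(self):
        with pytest.raises(ValueError):
            _template([[1.0, 0.5], [0.4, 1.0]])

    def test_out_of_range_entry_rejected(self):
        with pytest.raises(ValueError):
            _template([[1.0, 1.5], [1.5, 1.0]])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_completion_always_symmetric_pd(self, seed):
        # random known/unknown pattern with strong entries
        r = np.random.default_rng(seed)
        p = int(r.integers(2, 7))
        m = np.full((p, p), np.nan)
        np.fill_diagonal(m, 1.0)
        for i in range(p):
            for j in range(i):
                if r.random() < 0.6:
                    m[i, j] = m[j, i] = r.uniform(-0.98, 0.98)
        with np.errstate(all="ignore"):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out = cd.complete_correlation(_template(m))
        assert np.allclose(out, out.T)
        assert np.allclose(np.diag(out), 1.0)
        assert np.linalg.eigvalsh(out).min() > 0
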