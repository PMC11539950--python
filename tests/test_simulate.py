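import numpy as np
import pytest

from mliv import (
    SimulationConfig,
    gen_errors,
    gen_non_instrument,
    gen_robustness,
    gen_valid,
    generate,
    preset_specs,
)
from mliv.simulate import mediator


class TestErrors:
    def test_target_correlation_at_large_n(self):
        e1, e2 = gen_errors(100_000, 0.8, seed=1)
        assert np.corrcoef(e1, e2)[0, 1] == pytest.approx(0.8, abs=0.01)
        assert e1.std() == pytest.approx(1.0, abs=0.02)
        assert e2.std() == pytest.approx(1.0, abs=0.02)

    def test_zero_correlation(self):
        e1, e2 = gen_errors(10_000, 0.0, seed=2)
        assert abs(np.corrcoef(e1, e2)[0, 1]) < 3 / np.sqrt(10_000)

    def test_same_seed_identical_draws(self):
        a = gen_errors(100, 0.8, seed=3)
        b = gen_errors(100, 0.8, seed=3)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError):
            gen_errors(10, 1.0, seed=0)


class TestValidDGP:
    def test_treatment_variance(self):
        # Var(t) = Var(x) + Var(z) + Var(z^2) + Var(e1) = 1+1+2+1 = 5
        d = gen_valid(SimulationConfig(n=100_000, seed=4))
        assert d.t.var() == pytest.approx(5.0, abs=0.15)

    def test_treatment_mean(self):
        # E[t] = E[z^2] = 1
        d = gen_valid(SimulationConfig(n=100_000, seed=5))
        assert d.t.mean() == pytest.approx(1.0, abs=0.02)

    def test_structural_identity(self):
        # y - x - t = e2: unit variance, correlation 0.8 with e1 = t-x-z-z^2
        d = gen_valid(SimulationConfig(n=100_000, seed=6))
        x, z = d.X[:, 0], d.Z[:, 0]
        e2 = d.y - x - d.t
        e1 = d.t - x - z - z**2
        assert e2.var() == pytest.approx(1.0, abs=0.02)
        assert np.corrcoef(e1, e2)[0, 1] == pytest.approx(0.8, abs=0.01)


class TestNonInstrumentDGP:
    def test_phi_zero_identical_to_valid_dgp(self):
        cfg = dict(n=500, seed=7)
        a = gen_valid(SimulationConfig(dgp="valid", **cfg))
        b = gen_non_instrument(SimulationConfig(dgp="non_instrument", phi=0.0, **cfg))
        np.testing.assert_array_equal(a.y, b.y)
        np.testing.assert_array_equal(a.t, b.t)

    def test_mediator_leak_raw_scale(self):
        # cov(y - x - t, z^3) = phi * E[z^6] = 15 phi for the raw mediator
        cfg = SimulationConfig(dgp="non_instrument", n=100_000, phi=1.0,
                               seed=8, mediator_scale="raw")
        d = gen_non_instrument(cfg)
        leak = d.y - d.X[:, 0] - d.t
        cov = np.cov(leak, d.Z[:, 0] ** 3)[0, 1]
        assert cov == pytest.approx(15.0, abs=1.0)

    def test_mediator_leak_unit_scale(self):
        # default mediator has unit variance: cov(y-x-t, z^3) = phi*sqrt(15)
        d = gen_non_instrument(SimulationConfig(
            dgp="non_instrument", n=100_000, phi=1.0, seed=8))
        leak = d.y - d.X[:, 0] - d.t
        cov = np.cov(leak, d.Z[:, 0] ** 3)[0, 1]
        assert cov == pytest.approx(np.sqrt(15.0), abs=0.3)
        m = mediator(d.Z[:, 0])
        assert m.var() == pytest.approx(1.0, abs=0.05)

    def test_schema_has_exactly_four_columns(self):
        d = gen_non_instrument(SimulationConfig(dgp="non_instrument", n=50,
                                                phi=1.0, seed=9))
        # the mediator itself is never exposed
        assert list(d.to_frame().columns) == ["x1", "z1", "t", "y"]


class TestRobustnessDGP:
    def test_quadratic_variance(self):
        # t = x + z^2 + e1: Var = 1 + 2 + 1 = 4
        d = gen_robustness(SimulationConfig(dgp="robustness", n=100_000,
                                            pi=1.0, f_name="quadratic", seed=10))
        assert d.t.var() == pytest.approx(4.0, abs=0.15)

    def test_unit_effect_identity(self):
        # y - x - t = e2 (beta_true = 1), unit variance
        d = gen_robustness(SimulationConfig(dgp="robustness", n=50_000,
                                            pi=0.5, f_name="exp", seed=11))
        assert (d.y - d.X[:, 0] - d.t).var() == pytest.approx(1.0, abs=0.03)

    @pytest.mark.parametrize("f_name", ["quadratic", "cubic", "exp", "log",
                                        "sqrt", "logistic"])
    def test_all_six_forms_generate(self, f_name):
        d = gen_robustness(SimulationConfig(dgp="robustness", n=100, pi=1.0,
                                            f_name=f_name, seed=12))
        assert np.all(np.isfinite(d.t))

    def test_zero_strength_instrument_is_irrelevant(self):
        from mliv import relevance_check, FeatureSpec
        hits = 0
        for seed in range(20):
            d = gen_robustness(SimulationConfig(dgp="robustness", n=400,
                                                pi=0.0, f_name="logistic",
                                                seed=seed))
            res = relevance_check(
                d, FeatureSpec(["x1", "z1", "z1^2"], include_intercept=True),
                FeatureSpec(["x1"], include_intercept=True))
            hits += res.passed
        assert hits <= 1

    def test_missing_f_name_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(dgp="robustness", n=100, seed=0)


class TestDeterminismAndStreams:
    def test_generators_are_pure_functions_of_config(self):
        cfg = SimulationConfig(dgp="valid", n=200, seed=13)
        a, b = gen_valid(cfg), gen_valid(cfg)
        np.testing.assert_array_equal(a.y, b.y)

    def test_signal_parameters_do_not_touch_noise_streams(self):
        """Changing phi alters only the mediator contribution: x, z, t
        are identical draws, enabling paired comparisons."""
        a = gen_non_instrument(SimulationConfig(dgp="non_instrument", n=300,
                                                phi=0.1, seed=14))
        b = gen_non_instrument(SimulationConfig(dgp="non_instrument", n=300,
                                                phi=1.0, seed=14))
        np.testing.assert_array_equal(a.X, b.X)
        np.testing.assert_array_equal(a.Z, b.Z)
        np.testing.assert_array_equal(a.t, b.t)
        assert not np.array_equal(a.y, b.y)

    def test_dispatch(self):
        d = generate(SimulationConfig(dgp="valid", n=50, seed=15))
        assert d.n == 50


def test_presets_match_printed_predictor_matrices():
    s = preset_specs("identification")
    assert s["stage_one"].terms == ("x1", "z1", "z1^2")
    assert s["stage_two"].terms == ("x1", "t_hat")
    assert s["remainder"].terms == ("x1", "z1", "z1^2")
    assert s["stage_one"].include_intercept
    assert not s["stage_two"].include_intercept
    with pytest.raises(KeyError):
        preset_specs("nope")
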