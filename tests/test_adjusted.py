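import numpy as np
import pytest
from scipy import stats

from selbias import (
    AllocationSequence,
    DesignParams,
    OutcomeModel,
    PolicySpec,
    bias_vector,
    f_test_adjusted,
    f_test_unadjusted,
    generate_outcomes,
    generate_pbd,
    power_simulation,
    rejection_probability,
)
from selbias.adjusted import ModelError
from selbias.policies import bias_vectors
from selbias.designs import sample_pbd


@pytest.fixture
def seq24():
    return generate_pbd(DesignParams(3, 1, 8), 17)


class TestGenerateOutcomes:
    def test_reproducible(self, worked_seq):
        model = OutcomeModel(mu=[0.0, 1.0, 2.0])
        a = generate_outcomes(worked_seq, model, 5)
        b = generate_outcomes(worked_seq, model, 5)
        assert np.array_equal(a, b)

    def test_small_sigma_limit(self, worked_seq):
        model = OutcomeModel(mu=[1.0, 2.0, 3.0], sigma=1e-9)
        y = generate_outcomes(worked_seq, model, 0)
        assert np.allclose(y, [1, 2, 1, 3, 3, 2], atol=1e-6)

    def test_mean_matches_model(self, worked_seq, policy_i, rng):
        # law of large numbers componentwise over many replicates
        b = bias_vector(worked_seq, policy_i)
        model = OutcomeModel(mu=np.array([0.5, -0.5, 0.0]), eta=1.2, b=b)
        reps = 100_000
        draws = np.stack([generate_outcomes(worked_seq, model, rng) for _ in range(200)])
        # vectorized equivalent for the bulk
        mu_vec = model.mu[worked_seq.treatments - 1] + 1.2 * b.values
        y = mu_vec + rng.standard_normal((reps, 6))
        err = y.mean(axis=0) - mu_vec
        assert np.all(np.abs(err) < 4 / np.sqrt(reps))
        assert np.all(np.abs(draws.mean(axis=0) - mu_vec) < 4 / np.sqrt(200))

    def test_eta_requires_bias_vector(self, worked_seq):
        with pytest.raises(ModelError, match="bias vector"):
            generate_outcomes(worked_seq, OutcomeModel(mu=np.zeros(3), eta=1.0), 0)

    def test_sigma_positive(self):
        with pytest.raises(ModelError):
            OutcomeModel(mu=np.zeros(3), sigma=0.0)


class TestUnadjusted:
    def test_matches_scipy_f_oneway(self, seq24, rng):
        y = rng.standard_normal(24)
        res = f_test_unadjusted(y, seq24)
        groups = [y[seq24.treatments == k] for k in (1, 2, 3)]
        ref = stats.f_oneway(*groups)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)
        assert (res.df1, res.df2) == (2, 21)

    def test_constant_response(self, seq24):
        res = f_test_unadjusted(np.full(24, 3.3), seq24)
        assert res.statistic == 0.0
        assert res.p_value == 1.0
        assert not res.reject

    def test_hand_computed_example(self, worked_seq):
        # arm 1 gets y = (2,4), arm 2 gets (4,6), arm 3 gets (8,6)
        y = np.array([2.0, 4.0, 4.0, 8.0, 6.0, 6.0])
        # arm means (3,5,7), grand 5: SSB = 2*(4+0+4) = 16, SSW = 2+2+2 = 6
        res = f_test_unadjusted(y, worked_seq)
        assert res.statistic == pytest.approx((16 / 2) / (6 / 3))

    def test_size_under_null(self, rng):
        t = np.tile([1, 2, 3], (40_000, 4))
        from selbias.adjusted import _f_unadjusted_batch

        y = rng.standard_normal(t.shape)
        f = _f_unadjusted_batch(y, t, 3)
        rate = np.mean(f > stats.f.isf(0.05, 2, 9))
        assert rate == pytest.approx(0.05, abs=3 * np.sqrt(0.05 * 0.95 / 40_000))

    def test_bridges_to_exact_rejection_probability(self, worked_seq, policy_i, rng):
        b = bias_vector(worked_seq, policy_i)
        exact = rejection_probability(worked_seq, b, eta=1.07, alpha=0.05)
        reps = 200_000
        y = 1.07 * b.values + rng.standard_normal((reps, 6))
        from selbias.adjusted import _f_unadjusted_batch

        f = _f_unadjusted_batch(y, np.tile(worked_seq.treatments, (reps, 1)), 3)
        emp = float(np.mean(f > stats.f.isf(0.05, 2, 3)))
        se = np.sqrt(emp * (1 - emp) / reps)
        assert abs(emp - exact) < 3 * se

    def test_degenerate_input(self, seq24):
        with pytest.raises(ModelError):
            f_test_unadjusted(np.zeros(5), seq24)


class TestAdjusted:
    def test_zero_b_falls_back(self, seq24, rng):
        y = rng.standard_normal(24)
        adj = f_test_adjusted(y, seq24, np.zeros(24))
        base = f_test_unadjusted(y, seq24)
        assert adj.degenerate
        assert adj.statistic == pytest.approx(base.statistic)
        assert adj.reject == base.reject
        assert adj.eta_hat is None

    def test_constant_b_falls_back(self, seq24, rng):
        adj = f_test_adjusted(rng.standard_normal(24), seq24, np.ones(24))
        assert adj.degenerate

    def test_b_in_group_span_falls_back(self, seq24, rng):
        b = (seq24.treatments == 1).astype(float)  # indicator of arm 1
        adj = f_test_adjusted(rng.standard_normal(24), seq24, b)
        assert adj.degenerate

    def test_matches_statsmodels_type3(self, seq24, rng):
        import pandas as pd
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        b = bias_vector(seq24, PolicySpec("I", {1}))
        y = rng.standard_normal(24) + 0.8 * b.values
        res = f_test_adjusted(y, seq24, b)
        df = pd.DataFrame({"y": y, "g": seq24.treatments.astype(str), "b": b.values})
        fit = smf.ols("y ~ C(g) + b", data=df).fit()
        tab = anova_lm(fit, typ=3)
        assert res.statistic == pytest.approx(tab.loc["C(g)", "F"], rel=1e-8)
        assert res.p_value == pytest.approx(tab.loc["C(g)", "PR(>F)"], rel=1e-8)
        assert res.eta_hat == pytest.approx(fit.params["b"], rel=1e-8)
        assert (res.df1, res.df2) == (2, 20)

    def test_invariant_to_constant_shift_of_b(self, seq24, rng):
        b = bias_vector(seq24, PolicySpec("I", {1})).values.astype(float)
        y = rng.standard_normal(24)
        a = f_test_adjusted(y, seq24, b)
        c = f_test_adjusted(y, seq24, b + 7.0)
        assert a.statistic == pytest.approx(c.statistic, rel=1e-10)

    def test_eta_recovery(self, rng):
        # parameter recovery: eta_hat is unbiased for the generating eta
        seq = generate_pbd(DesignParams(3, 1, 32), 3)  # N = 96
        b = bias_vector(seq, PolicySpec("I", {1}))
        reps, eta = 10_000, 2.0
        from selbias.adjusted import _f_adjusted_batch

        t = np.tile(seq.treatments, (reps, 1))
        bmat = np.tile(b.values, (reps, 1))
        y = eta * bmat + rng.standard_normal((reps, 96))
        _, eta_hat, degenerate = _f_adjusted_batch(y, t, bmat, 3)
        assert not degenerate.any()
        se = eta_hat.std() / np.sqrt(reps)
        assert abs(eta_hat.mean() - eta) < 2 * se + 1e-3

    def test_size_restored_under_bias(self, rng):
        # under H0 with eta > 0 the adjusted test keeps its nominal level
        reps, alpha = 20_000, 0.05
        params = DesignParams(3, 1, 8)
        t = sample_pbd(params, reps, rng)
        b = bias_vectors(t, 3, PolicySpec("I", frozenset({1})))
        y = 1.0 * b + rng.standard_normal(t.shape)
        from selbias.adjusted import _f_adjusted_batch, _f_unadjusted_batch

        f_adj, _, degenerate = _f_adjusted_batch(y, t, b, 3)
        f_un = _f_unadjusted_batch(y, t, 3)
        rej = np.where(
            degenerate,
            f_un > stats.f.isf(alpha, 2, 21),
            f_adj > stats.f.isf(alpha, 2, 20),
        )
        rate = float(np.mean(rej))
        assert abs(rate - alpha) < 3 * np.sqrt(alpha * (1 - alpha) / reps)

    def test_needs_enough_df(self, worked_seq):
        # N = 6, K = 3 leaves no room for the extra covariate... N > K+1 fails at 4
        tiny = generate_pbd(DesignParams(3, 1, 1), 0)
        with pytest.raises(ModelError):
            f_test_adjusted(np.zeros(3), tiny, np.zeros(3))


class TestPowerSimulation:
    def test_output_shape_and_anchor(self):
        from selbias import PowerSpec, cohens_f, delta_for_power, mean_vector

        spec = PowerSpec(3, 16)
        f = cohens_f(spec)
        mu = mean_vector(delta_for_power(spec), 3)
        df = power_simulation(
            3, 16, PolicySpec("I", {1}), mu, f,
            rhos=(0.0,), schemes=("PBD_N",), replicates=4000, seed=8,
        )
        assert set(df["test"]) == {"adjusted", "unadjusted"}
        # with no bias the unadjusted test attains the design power
        unadj = df[df["test"] == "unadjusted"]["power"].iloc[0]
        assert unadj == pytest.approx(0.8, abs=0.025)

    def test_replicates_validated(self):
        with pytest.raises(ModelError):
            power_simulation(3, 16, PolicySpec("I", {1}), np.zeros(3), 1.0, replicates=0)

    def test_mu_length_validated(self):
        with pytest.raises(ModelError):
            power_simulation(3, 16, PolicySpec("I", {1}), np.zeros(4), 1.0)
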