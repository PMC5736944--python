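import math

import numpy as np
import pytest

from mph import (
    ExpressionMatrix,
    PosteriorState,
    Proportions,
    Profiles,
    SyntheticSpec,
    log_likelihood,
    match_components,
    run_mcmc,
    simulate,
    simulate_null,
    uniform_prior,
)
from mph.dsection import match_components_bruteforce


def _state(x, p, w, lam):
    comps = [f"comp{t + 1}" for t in range(p.shape[0])]
    profiles = {
        c: Profiles(x.gene_ids, comps, w[c], condition=c) for c in w
    }
    return PosteriorState(
        p=Proportions(x.sample_ids, comps, p),
        x=profiles,
        lam=np.asarray(lam, dtype=float),
    )


class TestLogLikelihood:
    def test_standard_normal_at_its_mean(self):
        x = ExpressionMatrix(["g1"], ["s1"], [[2.0]], {"s1": "A"})
        st = _state(x, np.array([[1.0]]), {"A": np.array([[2.0]])}, [1.0])
        assert log_likelihood(x, st) == pytest.approx(-0.5 * math.log(2 * math.pi),
                                                      abs=1e-12)

    def test_unit_deviation(self):
        x = ExpressionMatrix(["g1"], ["s1"], [[3.0]], {"s1": "A"})
        st = _state(x, np.array([[1.0]]), {"A": np.array([[2.0]])}, [1.0])
        expected = -0.5 * math.log(2 * math.pi) - 0.5
        assert log_likelihood(x, st) == pytest.approx(expected, abs=1e-12)

    def test_matches_per_cell_brute_force(self, rng):
        I, J, T = 20, 4, 2
        vals = rng.uniform(0, 10, size=(I, J))
        cond = {f"s{j}": ("A" if j < 2 else "B") for j in range(J)}
        x = ExpressionMatrix([f"g{i}" for i in range(I)],
                             list(cond), vals, cond)
        p = rng.dirichlet(np.ones(T), size=J).T
        w = {c: rng.uniform(0, 10, size=(I, T)) for c in ("A", "B")}
        lam = rng.gamma(2, 0.5, size=I)
        st = _state(x, p, w, lam)

        # independent per-cell Gaussian density summation
        expected = 0.0
        for i in range(I):
            for j, s in enumerate(x.sample_ids):
                mu = float(w[cond[s]][i] @ p[:, j])
                var = 1.0 / lam[i]
                expected += -0.5 * math.log(2 * math.pi * var) \
                    - (vals[i, j] - mu) ** 2 / (2 * var)
        assert log_likelihood(x, st) == pytest.approx(expected, abs=1e-10)

    def test_nonpositive_precision_rejected(self):
        x = ExpressionMatrix(["g1"], ["s1"], [[2.0]], {"s1": "A"})
        st = _state(x, np.array([[1.0]]), {"A": np.array([[2.0]])}, [0.0])
        with pytest.raises(ValueError, match="positive"):
            log_likelihood(x, st)


class TestRunMcmc:
    def test_single_component_degenerates_to_condition_means(self):
        ds = simulate(SyntheticSpec(I=80, T=1, markers_per_component=5, seed=2))
        x = ds.expression
        mc = run_mcmc(x, 1, uniform_prior(x, 1), n_iter=600, burn_in=200,
                      thin=2, seed=1, keep_chain=False)
        np.testing.assert_array_equal(mc.p_mean.values, 1.0)
        means = x.values.mean(axis=1)
        assert np.abs(mc.x_mean["cond1"].values[:, 0] - means).mean() < 0.5

    def test_fixed_seed_reproduces_chain(self, default_dataset):
        x = default_dataset.expression
        kw = dict(n_iter=150, burn_in=50, thin=2, seed=123)
        a = run_mcmc(x, 2, uniform_prior(x, 2), **kw)
        b = run_mcmc(x, 2, uniform_prior(x, 2), **kw)
        np.testing.assert_array_equal(a.p_mean.values, b.p_mean.values)
        np.testing.assert_array_equal(a.lam_mean, b.lam_mean)
        assert a.log_likelihood_trace == b.log_likelihood_trace

    def test_kept_draws_satisfy_invariants(self, default_dataset):
        x = default_dataset.expression
        mc = run_mcmc(x, 2, uniform_prior(x, 2), n_iter=120, burn_in=40,
                      thin=2, seed=3)
        assert len(mc.chain) == (120 - 40 + 1) // 2
        for st in mc.chain:
            np.testing.assert_allclose(st.p.values.sum(axis=0), 1.0, atol=1e-12)
            assert (st.p.values >= 0).all()
            assert (st.lam > 0).all()
            for prof in st.x.values():
                assert (prof.values >= 0).all()
        np.testing.assert_allclose(mc.p_mean.values.sum(axis=0), 1.0, atol=1e-9)

    def test_recovers_mixture_proportions(self, default_dataset):
        ds = default_dataset
        mc = run_mcmc(ds.expression, 2, uniform_prior(ds.expression, 2),
                      n_iter=1200, burn_in=400, thin=3, seed=7,
                      keep_chain=False)
        perm = match_components(mc.p_mean, ds.truth_proportions)
        err = np.abs(mc.p_mean.values[perm] - ds.truth_proportions.values)
        assert err.max() < 0.06
        assert 0.05 < mc.acceptance_rate < 0.95

    def test_null_data_gives_no_spurious_separation(self, null_dataset):
        x = null_dataset.expression
        mc = run_mcmc(x, 2, uniform_prior(x, 2), n_iter=1500, burn_in=500,
                      thin=3, seed=7, keep_chain=False)
        w = mc.x_mean["cond1"].values
        assert np.corrcoef(w[:, 0], w[:, 1])[0, 1] > 0.9

    def test_lambda_concentrates_with_more_samples(self):
        ds = simulate(SyntheticSpec(I=200, J=30, seed=8))
        mc = run_mcmc(ds.expression, 2, uniform_prior(ds.expression, 2),
                      n_iter=800, burn_in=300, thin=2, seed=5,
                      keep_chain=False)
        rel = np.abs(mc.lam_mean - ds.truth_lambda) / ds.truth_lambda
        assert np.median(rel) < 0.3

    def test_excess_components_warn_not_error(self):
        ds = simulate(SyntheticSpec(I=40, J=3, markers_per_component=4,
                                    seed=1))
        x = ds.expression
        mc = run_mcmc(x, 4, uniform_prior(x, 4), n_iter=30, burn_in=10,
                      thin=1, seed=1, keep_chain=False)
        assert any("identifiability" in w for w in mc.warnings)


class TestMatchComponents:
    def test_swap_detected(self, rng):
        vals = rng.dirichlet(np.ones(2), size=8).T
        truth = Proportions([f"s{j}" for j in range(8)], ["a", "b"], vals)
        est = Proportions([f"s{j}" for j in range(8)], ["a", "b"], vals[::-1])
        np.testing.assert_array_equal(match_components(est, truth), [1, 0])

    def test_identity_for_identical(self, rng):
        vals = rng.uniform(0, 5, size=(10, 3))
        w = Profiles([f"g{i}" for i in range(10)], ["a", "b", "c"], vals)
        np.testing.assert_array_equal(match_components(w, w), [0, 1, 2])

    def test_agrees_with_exhaustive_search(self, rng):
        for _ in range(5):
            a = rng.uniform(0, 5, size=(10, 3))
            b = rng.uniform(0, 5, size=(10, 3))
            genes = [f"g{i}" for i in range(10)]
            wa = Profiles(genes, ["a", "b", "c"], a)
            wb = Profiles(genes, ["a", "b", "c"], b)
            np.testing.assert_array_equal(
                match_components(wb, wa),
                match_components_bruteforce(wb, wa),
            )
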