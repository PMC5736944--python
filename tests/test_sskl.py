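import math

import numpy as np
import pytest

from mph import (
    FactorizationState,
    MarkerSet,
    SyntheticSpec,
    apply_marker_constraints,
    kl_divergence,
    multiplicative_step,
    run_sskl,
    simulate,
)
from mph.sskl import multiplicative_step_reference


class TestKlDivergence:
    def test_perfect_reconstruction_is_zero(self, rng):
        W = rng.uniform(0.5, 2, size=(6, 2))
        H = rng.uniform(0.5, 2, size=(2, 4))
        assert kl_divergence(W @ H, W, H) == pytest.approx(0.0, abs=1e-10)

    def test_single_cell_formula(self):
        X = np.array([[2.0]])
        W = np.array([[1.0]])
        H = np.array([[1.0]])
        expected = 2 * math.log(2) - 2 + 1
        assert kl_divergence(X, W, H) == pytest.approx(expected, abs=1e-12)

    def test_zero_data_cell_contributes_reconstruction(self):
        assert kl_divergence(np.array([[0.0]]), np.array([[1.0]]),
                             np.array([[1.0]])) == pytest.approx(1.0)

    def test_positive_data_zero_reconstruction_is_inf(self):
        d = kl_divergence(np.array([[2.0]]), np.array([[0.0]]),
                          np.array([[0.0]]))
        assert d == math.inf and not math.isnan(d)


class TestMultiplicativeStep:
    def test_exact_factorization_is_fixed_point(self, rng):
        W = rng.uniform(0.5, 2, size=(8, 2))
        H = rng.uniform(0.5, 2, size=(2, 5))
        X = W @ H
        st = FactorizationState(W=W, H=H, k=2, divergence=0.0)
        out = multiplicative_step(X, st)
        np.testing.assert_allclose(out.W, W, rtol=1e-12)
        np.testing.assert_allclose(out.H, H, rtol=1e-12)

    def test_divergence_never_increases(self, rng):
        X = rng.uniform(0, 10, size=(10, 4))
        st = FactorizationState(W=rng.random((10, 2)) + 0.1,
                                H=rng.random((2, 4)) + 0.1,
                                k=2, divergence=math.inf)
        st.divergence = kl_divergence(X, st.W, st.H)
        for _ in range(100):
            new = multiplicative_step(X, st)
            assert new.divergence <= st.divergence + 1e-9
            st = new

    def test_matches_straight_loop_reference(self, rng):
        X = rng.uniform(0, 10, size=(10, 4))
        W = rng.random((10, 2)) + 0.1
        H = rng.random((2, 4)) + 0.1
        for _ in range(10):
            st = multiplicative_step(
                X, FactorizationState(W=W, H=H, k=2, divergence=0.0))
            W_ref, H_ref = multiplicative_step_reference(X, W, H)
            np.testing.assert_allclose(st.W, W_ref, atol=1e-10)
            np.testing.assert_allclose(st.H, H_ref, atol=1e-10)
            W, H = st.W, st.H

    def test_rank_one_matrix_factorizes_exactly(self, rng):
        u = rng.uniform(1, 5, size=12)
        v = rng.uniform(1, 5, size=5)
        X = np.outer(u, v)
        W = rng.random((12, 1)) + 0.1
        H = rng.random((1, 5)) + 0.1
        div = kl_divergence(X, W, H)
        for _ in range(200):
            st = multiplicative_step(
                X, FactorizationState(W=W, H=H, k=1, divergence=div))
            W, H, div = st.W, st.H, st.divergence
            if div < 1e-8:
                break
        assert div < 1e-8


class TestMarkerConstraints:
    def test_off_component_entries_zeroed(self):
        m = MarkerSet(["a", "b"], {"a": ["g0"], "b": ["g2"]})
        st = FactorizationState(W=np.ones((3, 2)), H=np.ones((2, 2)),
                                k=2, divergence=0.0)
        out = apply_marker_constraints(st, m, {"g0": 0, "g1": 1, "g2": 2})
        assert out.W[0, 1] == 0.0 and out.W[0, 0] == 1.0
        assert out.W[2, 0] == 0.0 and out.W[2, 1] == 1.0
        assert (out.W[1] == 1.0).all()  # non-marker gene untouched

    def test_missing_marker_gene_listed(self):
        m = MarkerSet(["a", "b"], {"a": ["gX"], "b": ["g1"]})
        st = FactorizationState(W=np.ones((2, 2)), H=np.ones((2, 2)),
                                k=2, divergence=0.0)
        with pytest.raises(KeyError, match="gX"):
            apply_marker_constraints(st, m, {"g0": 0, "g1": 1})

    def test_markers_anchor_component_labels(self, default_dataset):
        """With planted markers the fit needs no post-hoc matching: each
        marker's weight lands in its own component."""
        ds = default_dataset
        fit = run_sskl(ds.expression, ds.truth_markers, k=2, n_restarts=5,
                       max_iter=500, tol=1e-6, seed=0)
        gi = {g: i for i, g in enumerate(fit.W.gene_ids)}
        for t, comp in enumerate(ds.truth_markers.components):
            for g in ds.truth_markers.genes_of[comp]:
                row = fit.W.values[gi[g]]
                assert row.argmax() == t
                assert np.delete(row, t).max() == 0.0


class TestRunSskl:
    def test_rank_one_no_markers(self, default_dataset):
        x = default_dataset.expression
        fit = run_sskl(x, None, k=1, n_restarts=3, max_iter=300, tol=1e-8,
                       seed=0)
        np.testing.assert_allclose(fit.H_normalized.values, 1.0, atol=1e-12)
        w = fit.W.values[:, 0]
        rm = x.values.mean(axis=1)
        corr = np.corrcoef(w, rm)[0, 1]
        assert corr > 0.9999  # W column proportional to row means

    def test_near_noiseless_marker_recovery(self, quiet_dataset):
        ds = quiet_dataset
        xm = ds.expression.subset_genes(ds.truth_markers.all_genes())
        fit = run_sskl(xm, ds.truth_markers, k=2, n_restarts=10,
                       max_iter=1000, tol=1e-7, seed=0)
        err = np.abs(fit.H_normalized.values - ds.truth_proportions.values)
        assert err.max() < 0.02

    def test_seed_to_seed_stability(self, default_dataset):
        ds = default_dataset
        kw = dict(k=2, n_restarts=10, max_iter=1000, tol=1e-6)
        a = run_sskl(ds.expression, ds.truth_markers, seed=1, **kw)
        b = run_sskl(ds.expression, ds.truth_markers, seed=2, **kw)
        assert np.abs(a.H_normalized.values - b.H_normalized.values).max() < 0.02

    def test_wh_invariant_under_scale_identification(self, default_dataset):
        ds = default_dataset
        fit = run_sskl(ds.expression, ds.truth_markers, k=2, n_restarts=3,
                       max_iter=300, tol=1e-5, seed=0)
        # reassemble W H from the reported, rescaled factors
        W_unit = fit.W.values / np.median(fit.h_colsums)
        H_raw = fit.H_normalized.values * fit.h_colsums[None, :]
        np.testing.assert_allclose(W_unit @ H_raw, fit.fitted, atol=1e-10)
        np.testing.assert_allclose(fit.H_normalized.values.sum(axis=0), 1.0,
                                   atol=1e-12)

    def test_gene_permutation_invariance(self, default_dataset, rng):
        ds = default_dataset
        x = ds.expression
        perm = rng.permutation(x.n_genes)
        xp = x.subset_genes([x.gene_ids[i] for i in perm])
        kw = dict(k=2, n_restarts=3, max_iter=300, tol=1e-5, seed=4)
        a = run_sskl(x, ds.truth_markers, **kw)
        b = run_sskl(xp, ds.truth_markers, **kw)
        # same initialization per gene; differences only from float
        # summation order in the matrix products
        np.testing.assert_allclose(a.H_normalized.values,
                                   b.H_normalized.values, atol=1e-8)
        np.testing.assert_allclose(a.W.values[perm], b.W.values, atol=1e-6)

    def test_unconstrained_trace_monotone(self, rng):
        from mph import ExpressionMatrix
        vals = rng.uniform(0, 10, size=(30, 5))
        x = ExpressionMatrix([f"g{i}" for i in range(30)],
                             [f"s{j}" for j in range(5)], vals,
                             {f"s{j}": "A" for j in range(5)})
        fit = run_sskl(x, None, k=2, n_restarts=2, max_iter=200, tol=1e-9,
                       seed=0)
        t = np.array(fit.divergence_trace)
        assert (np.diff(t) <= 1e-9).all()

    def test_k_must_match_marker_components(self, default_dataset):
        ds = default_dataset
        with pytest.raises(ValueError, match="k must equal"):
            run_sskl(ds.expression, ds.truth_markers, k=3)
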