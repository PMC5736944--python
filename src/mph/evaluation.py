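"""Validation harness: recovery, calibration and correctness metrics
computed on synthetic ground truth.

These routines re-run the package's estimators on data from
:mod:`mph.simulate` under the default study conditions (500 genes, 6
samples, 2 subpopulations mixed (0.7, 0.3)/(0.3, 0.7), 12 planted markers
per subpopulation) and report scalar summaries: proportion-recovery
errors, run-to-run spread, test calibration and power, marker-count
stability, and agreement of the numerical kernels with independent
straight-loop oracles.
"""

from __future__ import annotations

import math

import numpy as np

from .containers import ExpressionMatrix
from .dsection import (
    PosteriorState,
    log_likelihood,
    match_components,
    run_mcmc,
    uniform_prior,
)
from .hettest import lrt
from .sensitivity import sensitivity_scan
from .simulate import SyntheticSpec, simulate, simulate_null
from .sskl import (
    FactorizationState,
    kl_divergence,
    multiplicative_step,
    multiplicative_step_reference,
    run_sskl,
)
from .containers import Proportions, Profiles

LEAN_FIT = dict(n_restarts=3, max_iter=200, tol=1e-5)


def _spawn(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31))
            for s in np.random.SeedSequence(seed).spawn(n)]


def kl_update_check(n_matrices: int = 50, shape: tuple[int, int] = (200, 12),
                    k: int = 2, n_steps: int = 200, n_ref_steps: int = 25,
                    seed: int = 0) -> dict[str, float]:
    """Monotonicity of the KL divergence under the coupled multiplicative
    updates, and agreement of the vectorized step with the straight-loop
    reference over the first ``n_ref_steps`` steps of each run."""
    rng = np.random.default_rng(seed)
    I, J = shape
    max_increase = -math.inf
    max_mismatch = 0.0
    for _ in range(n_matrices):
        X = rng.uniform(0, 10, size=(I, J))
        W = rng.random((I, k)) + 0.05
        H = rng.random((k, J)) + 0.05
        div = kl_divergence(X, W, H)
        for step in range(n_steps):
            st = multiplicative_step(
                X, FactorizationState(W=W, H=H, k=k, divergence=div))
            if step < n_ref_steps:
                W_ref, H_ref = multiplicative_step_reference(X, W, H)
                max_mismatch = max(
                    max_mismatch,
                    float(np.abs(st.W - W_ref).max()),
                    float(np.abs(st.H - H_ref).max()),
                )
            max_increase = max(max_increase, st.divergence - div)
            W, H, div = st.W, st.H, st.divergence
    return {"max_step_increase": max_increase, "max_ref_mismatch": max_mismatch}


def likelihood_oracle_check(n_instances: int = 100, seed: int = 0) -> float:
    """Max absolute difference between the model log-likelihood and an
    independent per-cell Gaussian density summation on random instances."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        I = int(rng.integers(3, 21))
        J = int(rng.integers(2, 7))
        T = int(rng.integers(1, 4))
        n_cond = int(rng.integers(1, 3))
        conds = [f"c{rng.integers(n_cond)}" for _ in range(J)]
        cond_of = {f"s{j}": conds[j] for j in range(J)}
        vals = rng.uniform(0, 10, size=(I, J))
        x = ExpressionMatrix([f"g{i}" for i in range(I)],
                             list(cond_of), vals, cond_of)
        comps = [f"t{t}" for t in range(T)]
        p = rng.dirichlet(np.ones(T), size=J).T
        w = {c: rng.uniform(0, 10, size=(I, T)) for c in set(conds)}
        lam = rng.gamma(2.0, 2.0, size=I)
        state = PosteriorState(
            p=Proportions(list(cond_of), comps, p),
            x={c: Profiles(x.gene_ids, comps, w[c], condition=c) for c in w},
            lam=lam,
        )
        got = log_likelihood(x, state)
        ref = 0.0
        for i in range(I):
            for j in range(J):
                mu = float(w[conds[j]][i] @ p[:, j])
                var = 1.0 / lam[i]
                ref += -0.5 * math.log(2 * math.pi * var) \
                    - (vals[i, j] - mu) ** 2 / (2 * var)
        worst = max(worst, abs(got - ref))
    return worst


def sskl_recovery(n_replicates: int = 20, seed: int = 0,
                  n_restarts: int = 10, max_iter: int = 1000,
                  tol: float = 1e-6) -> dict[str, float]:
    """Proportion recovery of the marker-guided factorization under the
    default study conditions, plus per-entry run-to-run spread."""
    ds = simulate(SyntheticSpec(seed=seed))
    fit_seeds = _spawn(seed + 1, n_replicates)
    estimates = []
    for s in fit_seeds:
        fit = run_sskl(ds.expression, ds.truth_markers, k=2,
                       n_restarts=n_restarts, max_iter=max_iter, tol=tol,
                       seed=s)
        estimates.append(fit.H_normalized.values)
    est = np.stack(estimates)
    mae = float(np.abs(est - ds.truth_proportions.values[None]).mean())
    spread = float((est.max(axis=0) - est.min(axis=0)).max())
    return {"proportion_mae": mae, "run_to_run_spread": spread,
            "n_replicates": n_replicates}


def dsection_recovery(seed: int = 0, n_iter: int = 2000, burn_in: int = 500,
                      thin: int = 3) -> dict[str, float]:
    """Posterior-mean proportion recovery of the Bayesian deconvolution
    with a uniform prior, and bit-identical reproducibility at fixed seed."""
    ds = simulate(SyntheticSpec(seed=seed))
    x = ds.expression
    chain_seed = _spawn(seed + 1, 1)[0]
    kw = dict(n_iter=n_iter, burn_in=burn_in, thin=thin, seed=chain_seed,
              keep_chain=False)
    a = run_mcmc(x, 2, uniform_prior(x, 2), **kw)
    b = run_mcmc(x, 2, uniform_prior(x, 2), **kw)
    perm = match_components(a.p_mean, ds.truth_proportions)
    err = float(np.abs(a.p_mean.values[perm] - ds.truth_proportions.values).max())
    identical = bool(
        np.array_equal(a.p_mean.values, b.p_mean.values)
        and np.array_equal(a.lam_mean, b.lam_mean)
        and a.log_likelihood_trace == b.log_likelihood_trace
    )
    return {"max_proportion_error": err, "reproducible": identical,
            "acceptance_rate": a.acceptance_rate}


def lrt_calibration(n_datasets: int = 100, n_boot: int = 200,
                    alpha: float = 0.05, seed: int = 0) -> dict[str, float]:
    """Empirical type-I error of the bootstrap LRT on homogeneous data."""
    gen_seeds = _spawn(seed, n_datasets)
    test_seeds = _spawn(seed + 1, n_datasets)
    rejected = 0
    for gs, ts in zip(gen_seeds, test_seeds):
        ds = simulate_null(SyntheticSpec(seed=gs))
        x = ds.expression.subset_genes(ds.truth_markers.all_genes())
        res = lrt(x, ds.truth_markers, alpha=alpha, n_boot=n_boot, seed=ts,
                  **LEAN_FIT)
        rejected += res.reject
    return {"rejection_rate": rejected / n_datasets, "n_datasets": n_datasets}


def lrt_power(n_datasets: int = 20, n_boot: int = 200, alpha: float = 0.05,
              seed: int = 0) -> dict[str, float]:
    """Empirical power of the bootstrap LRT on strong two-component data."""
    gen_seeds = _spawn(seed, n_datasets)
    test_seeds = _spawn(seed + 1, n_datasets)
    rejected = 0
    for gs, ts in zip(gen_seeds, test_seeds):
        ds = simulate(SyntheticSpec(seed=gs))
        x = ds.expression.subset_genes(ds.truth_markers.all_genes())
        res = lrt(x, ds.truth_markers, alpha=alpha, n_boot=n_boot, seed=ts,
                  **LEAN_FIT)
        rejected += res.reject
    return {"rejection_rate": rejected / n_datasets, "n_datasets": n_datasets}


def marker_count_robustness(counts: tuple[int, ...] = (3, 6, 9, 12),
                            reps: int = 10, seed: int = 0) -> dict:
    """Dispersion of estimated proportions across marker subsamples at a
    grid of marker counts, on the default study conditions."""
    ds = simulate(SyntheticSpec(seed=seed))
    rep = sensitivity_scan(ds.expression, ds.truth_markers,
                           counts=list(counts), reps=reps, seed=seed + 1,
                           n_restarts=5, max_iter=500, tol=1e-6)
    return {
        "dispersion_by_count": rep.dispersion_by_count,
        "nonincreasing": rep.dispersion_is_nonincreasing(),
    }
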