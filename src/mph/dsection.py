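"""Bayesian deconvolution by a mixed Gibbs / Metropolis-Hastings sampler.

Model: the expression of gene i in sample j is a convex mixture of T
per-condition subpopulation profiles observed with Gaussian noise,

    y_ij | p_j, x, lam ~ N( sum_t p_tj * x_{t,i,c(j)}, 1 / lam_i ),

with per-gene precision lam_i shared across subpopulations and conditions.
Priors: profile entries Normal(x_mean, x_var) truncated at 0; precisions
Gamma(lambda_shape0, lambda_rate0); per-sample proportions
Dirichlet(concentration * p0_j) around user-supplied centers p0 (uniform
when no knowledge is available).

Profile and precision conditionals are conjugate and sampled by Gibbs;
proportion vectors move by Metropolis-Hastings with a Dirichlet proposal
centered at the current value (asymmetric, corrected in the acceptance
ratio).  Mixture components are exchangeable, so label switching is
resolved after the fact by :func:`match_components`, never inside the
sampler.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import gammaln, ndtr, ndtri

from .containers import ExpressionMatrix, Proportions, Profiles

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass
class PriorSpec:
    """Hyperparameters of the Bayesian model.

    ``x_mean`` / ``x_var`` default to the empirical matrix mean and 2.5x
    the empirical variance when left as None (resolved against the data at
    sampler start).  The profile-prior width matters more than usual here:
    the mixture is only partially identified (mixing the components leaves
    the likelihood surface flat along a simplex ridge), and an overly
    diffuse profile prior lets the marginal volume factor shrink the
    proportions toward the prior center, while an overly tight one pushes
    them outward to compensate for profiles shrunk toward the global mean.
    A moderately tight prior balances the two opposing pulls.
    """

    p0: Proportions
    concentration: float = 10.0
    x_mean: float | None = None
    x_var: float | None = None
    lambda_shape0: float = 1.0
    lambda_rate0: float = 1.0

    def __post_init__(self) -> None:
        for name in ("concentration", "lambda_shape0", "lambda_rate0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.x_var is not None and self.x_var <= 0:
            raise ValueError("x_var must be positive")


def uniform_prior(x: ExpressionMatrix, T: int, *, concentration: float = 10.0,
                  components: list[str] | None = None, **kw) -> PriorSpec:
    """Prior with uniform proportion centers 1/T for every sample."""
    comps = components or [f"comp{t + 1}" for t in range(T)]
    p0 = Proportions(
        sample_ids=x.sample_ids,
        components=comps,
        values=np.full((T, x.n_samples), 1.0 / T),
    )
    return PriorSpec(p0=p0, concentration=concentration, **kw)


@dataclass
class PosteriorState:
    """One draw of theta = (p, x, lam)."""

    p: Proportions
    x: dict[str, Profiles]  # condition -> profiles
    lam: np.ndarray


@dataclass
class McmcResult:
    chain: list[PosteriorState]
    p_mean: Proportions
    x_mean: dict[str, Profiles]
    lam_mean: np.ndarray
    acceptance_rate: float
    log_likelihood_trace: list[float]
    seed: int
    n_iter: int
    burn_in: int
    thin: int
    warnings: list[str] = field(default_factory=list)


def _mixture_mean(x: ExpressionMatrix, state: PosteriorState) -> np.ndarray:
    m = np.empty_like(x.values)
    for j, s in enumerate(x.sample_ids):
        w = state.x[x.condition_of[s]].values
        m[:, j] = w @ state.p.values[:, j]
    return m


def log_likelihood(x: ExpressionMatrix, state: PosteriorState) -> float:
    """Gaussian log-likelihood of the data under one parameter draw."""
    lam = np.asarray(state.lam, dtype=float)
    if (lam <= 0).any():
        raise ValueError("precisions lam must be positive")
    m = _mixture_mean(x, state)
    return gaussian_loglik(x.values, m, lam)


def gaussian_loglik(y: np.ndarray, mean: np.ndarray, lam: np.ndarray) -> float:
    """Sum over cells of log N(y_ij; mean_ij, 1/lam_i)."""
    resid2 = (y - mean) ** 2
    per_gene = 0.5 * y.shape[1] * (np.log(lam) - _LOG_2PI) \
        - 0.5 * lam * resid2.sum(axis=1)
    return float(per_gene.sum())


def _truncnorm_positive(mean: np.ndarray, sd: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    """Exact draws from N(mean, sd^2) truncated to [0, inf), inverse-CDF."""
    lo = ndtr(-mean / sd)  # P(Z < -mean/sd), mass below zero
    u = lo + (1.0 - lo) * rng.random(mean.shape)
    u = np.clip(u, 1e-16, 1.0 - 1e-16)
    return mean + sd * ndtri(u)


def _dirichlet_logpdf(x: np.ndarray, alpha: np.ndarray) -> float:
    x = np.clip(x, 1e-300, None)
    return float(
        gammaln(alpha.sum()) - gammaln(alpha).sum()
        + ((alpha - 1.0) * np.log(x)).sum()
    )


def run_mcmc(
    x: ExpressionMatrix,
    T: int,
    prior: PriorSpec,
    n_iter: int = 4000,
    burn_in: int = 1000,
    thin: int = 3,
    seed: int = 0,
    proposal_precision: float = 100.0,
    keep_chain: bool = True,
) -> McmcResult:
    """Sample the posterior of (p, x, lam) and return averaged summaries.

    Fixed seed reproduces the chain bit-identically.  T exceeding the
    sample count within a condition is an identifiability risk and is
    warned about, not rejected.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if not n_iter > burn_in >= 0:
        raise ValueError("need n_iter > burn_in >= 0")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    if prior.p0.values.shape != (T, x.n_samples):
        raise ValueError("prior p0 shape does not match T x J")

    rng = np.random.default_rng(seed)
    I, J = x.n_genes, x.n_samples
    y = x.values
    conditions = x.conditions
    cols_of = {c: np.asarray(x.samples_in(c), dtype=int) for c in conditions}
    comps = list(prior.p0.components)

    warn: list[str] = []
    for c in conditions:
        if T > len(cols_of[c]):
            warn.append(
                f"T={T} exceeds the {len(cols_of[c])} samples of condition "
                f"{c!r}: identifiability risk"
            )

    x_mean0 = float(np.mean(y)) if prior.x_mean is None else prior.x_mean
    x_var0 = (2.5 * float(np.var(y)) if prior.x_var is None else prior.x_var)
    x_var0 = max(x_var0, 1e-12)

    # initial state: per-condition gene means per component with a small
    # seeded jitter to break component symmetry
    W = {}
    for c in conditions:
        base = y[:, cols_of[c]].mean(axis=1)
        W[c] = np.maximum(
            base[:, None] * (1.0 + 0.05 * rng.standard_normal((I, T))), 1e-6
        )
    gene_var = y.var(axis=1) + 1e-6
    lam = 1.0 / gene_var
    P = prior.p0.values.copy()

    alpha0 = prior.concentration * np.clip(prior.p0.values, 1e-6, None)

    def mixture_mean_cols(c: str) -> np.ndarray:
        return W[c] @ P[:, cols_of[c]]

    accepted = 0
    proposed = 0
    chain: list[PosteriorState] = []
    ll_trace: list[float] = []
    p_acc = np.zeros((T, J))
    x_acc = {c: np.zeros((I, T)) for c in conditions}
    lam_acc = np.zeros(I)
    n_kept = 0

    for it in range(n_iter):
        # --- Gibbs: profile entries x_{t,i,c}, truncated-normal conditional
        for c in conditions:
            cols = cols_of[c]
            yc = y[:, cols]
            pc = P[:, cols]
            for t in range(T):
                pt = pc[t, :]
                resid = yc - W[c] @ pc + np.outer(W[c][:, t], pt)
                prec = lam * float(pt @ pt) + 1.0 / x_var0
                mean = (lam * (resid @ pt) + x_mean0 / x_var0) / prec
                W[c][:, t] = _truncnorm_positive(mean, 1.0 / np.sqrt(prec), rng)

        # --- Gibbs: per-gene precision, conjugate Gamma
        ssr = np.zeros(I)
        for c in conditions:
            ssr += ((y[:, cols_of[c]] - mixture_mean_cols(c)) ** 2).sum(axis=1)
        shape = prior.lambda_shape0 + 0.5 * J
        rate = prior.lambda_rate0 + 0.5 * ssr
        lam = rng.gamma(shape, 1.0 / rate)
        lam = np.maximum(lam, 1e-300)

        # --- MH: per-sample proportions with Dirichlet random-walk proposal
        if T > 1:
            for j, s in enumerate(x.sample_ids):
                proposed += 1
                cur = P[:, j]
                a_fwd = proposal_precision * np.clip(cur, 1e-6, None)
                prop = rng.dirichlet(a_fwd)
                prop = np.clip(prop, 1e-10, None)
                prop = prop / prop.sum()
                a_rev = proposal_precision * np.clip(prop, 1e-6, None)

                w = W[x.condition_of[s]]
                yj = y[:, j]
                ll_cur = -0.5 * float(lam @ (yj - w @ cur) ** 2)
                ll_prop = -0.5 * float(lam @ (yj - w @ prop) ** 2)
                log_alpha = (
                    ll_prop - ll_cur
                    + _dirichlet_logpdf(prop, alpha0[:, j])
                    - _dirichlet_logpdf(cur, alpha0[:, j])
                    + _dirichlet_logpdf(cur, a_rev)
                    - _dirichlet_logpdf(prop, a_fwd)
                )
                if math.log(rng.random()) < log_alpha:
                    P[:, j] = prop
                    accepted += 1
        else:
            accepted += J
            proposed += J

        if it >= burn_in and (it - burn_in) % thin == 0:
            state = PosteriorState(
                p=Proportions(sample_ids=x.sample_ids, components=comps,
                              values=P.copy()),
                x={c: Profiles(gene_ids=x.gene_ids, components=comps,
                               values=W[c].copy(), condition=c)
                   for c in conditions},
                lam=lam.copy(),
            )
            ll = log_likelihood(x, state)
            if not math.isfinite(ll):
                raise RuntimeError(
                    f"divergent log-likelihood ({ll}) at iteration {it}"
                )
            ll_trace.append(ll)
            p_acc += P
            for c in conditions:
                x_acc[c] += W[c]
            lam_acc += lam
            n_kept += 1
            if keep_chain:
                chain.append(state)

    p_mean = p_acc / n_kept
    p_mean = p_mean / p_mean.sum(axis=0, keepdims=True)
    x_mean = {c: x_acc[c] / n_kept for c in conditions}

    # Component labels are exchangeable independently within each condition
    # (profiles are condition-specific and nothing ties labels across
    # conditions under a symmetric prior).  Align every condition's
    # posterior-mean profiles to the first condition's by correlation so the
    # summaries use one consistent labeling; the per-sample proportion rows
    # of that condition are permuted jointly.
    if T > 1 and len(conditions) > 1:
        ref = x_mean[conditions[0]]
        for c in conditions[1:]:
            perm = _match_columns(ref, x_mean[c])
            if not np.array_equal(perm, np.arange(T)):
                x_mean[c] = x_mean[c][:, perm]
                cols = cols_of[c]
                p_mean[:, cols] = p_mean[perm][:, cols]

    return McmcResult(
        chain=chain,
        p_mean=Proportions(sample_ids=x.sample_ids, components=comps,
                           values=p_mean),
        x_mean={c: Profiles(gene_ids=x.gene_ids, components=comps,
                            values=x_mean[c], condition=c)
                for c in conditions},
        lam_mean=lam_acc / n_kept,
        acceptance_rate=accepted / proposed if proposed else 1.0,
        log_likelihood_trace=ll_trace,
        seed=seed,
        n_iter=n_iter,
        burn_in=burn_in,
        thin=thin,
        warnings=warn,
    )


def _match_columns(ref: np.ndarray, other: np.ndarray) -> np.ndarray:
    """Column permutation of ``other`` maximizing summed correlation with
    the corresponding columns of ``ref``."""
    T = ref.shape[1]
    corr = np.zeros((T, T))
    for k in range(T):
        for m in range(T):
            if ref[:, k].std() > 0 and other[:, m].std() > 0:
                corr[k, m] = float(np.corrcoef(ref[:, k], other[:, m])[0, 1])
    row, col = linear_sum_assignment(-corr)
    perm = np.empty(T, dtype=int)
    perm[row] = col
    return perm


def _component_vectors(obj: Proportions | Profiles) -> np.ndarray:
    """Per-component vectors as rows (T x n)."""
    if isinstance(obj, Proportions):
        return obj.values
    return obj.values.T


def match_components(est: Proportions | Profiles,
                     truth: Proportions | Profiles) -> np.ndarray:
    """Permutation resolving mixture label switching.

    Returns ``perm`` (0-based) such that est component ``perm[k]`` matches
    truth component ``k``, maximizing the summed Pearson correlation of the
    matched component vectors.  Constant vectors get correlation 0.
    """
    a = _component_vectors(truth)
    b = _component_vectors(est)
    if a.shape[0] != b.shape[0]:
        raise ValueError("component counts differ")
    T = a.shape[0]
    corr = np.zeros((T, T))
    for k in range(T):
        for m in range(T):
            sa, sb = a[k].std(), b[m].std()
            if sa == 0 or sb == 0:
                corr[k, m] = 0.0
            else:
                corr[k, m] = float(np.corrcoef(a[k], b[m])[0, 1])
    row, col = linear_sum_assignment(-corr)
    perm = np.empty(T, dtype=int)
    perm[row] = col
    return perm


def match_components_bruteforce(est: Proportions | Profiles,
                                truth: Proportions | Profiles) -> np.ndarray:
    """Exhaustive-search reference for :func:`match_components`."""
    a = _component_vectors(truth)
    b = _component_vectors(est)
    T = a.shape[0]

    def score(perm: tuple[int, ...]) -> float:
        tot = 0.0
        for k in range(T):
            sa, sb = a[k].std(), b[perm[k]].std()
            if sa > 0 and sb > 0:
                tot += float(np.corrcoef(a[k], b[perm[k]])[0, 1])
        return tot

    best = max(permutations(range(T)), key=score)
    return np.asarray(best, dtype=int)
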