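"""Marker-guided nonnegative factorization minimizing the generalized
Kullback-Leibler divergence.

The bulk matrix is approximated as X ~= W H with W, H >= 0, minimizing

    F(X, W, H) = sum_ij [ X_ij log(X_ij / (WH)_ij) - X_ij + (WH)_ij ],

by the classical multiplicative updates (H half-step, then W half-step,
each monotone in F).  Semi-supervision: for every marker gene of component
t, the W entries in all other components are clamped to zero after
initialization and after every step, anchoring component identity and
labels.  Hard zeroing can in principle break the per-step monotonicity
guarantee; violations are detected and logged, never hidden.

Scale ambiguity (W D, D^-1 H fit equally well for diagonal D > 0) is
resolved by rescaling W columns to unit sum — absorbed into H so the WH
product is unchanged — after which per-sample proportions are the simplex
normalization of the H columns.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .containers import ExpressionMatrix, MarkerSet, Proportions, Profiles

logger = logging.getLogger(__name__)

_FLOOR = 1e-12


@dataclass
class FactorizationState:
    W: np.ndarray  # I x k
    H: np.ndarray  # k x J
    k: int
    divergence: float
    iteration: int = 0


@dataclass
class SsklResult:
    W: Profiles
    H_normalized: Proportions
    divergence: float
    divergence_trace: list[float]
    converged: bool
    n_iter: int
    seed: int
    best_restart: int
    fitted: np.ndarray | None = None  # raw WH reconstruction (I x J)
    h_colsums: np.ndarray | None = None  # per-sample scale absorbed out of H
    marker_constraint_log: list[str] = field(default_factory=list)
    monotonicity_violations: int = 0


def kl_divergence(x: np.ndarray | ExpressionMatrix, W: np.ndarray,
                  H: np.ndarray) -> float:
    """Generalized KL divergence F(X, W, H); 0*log0 taken as 0.

    A cell with X > 0 but (WH) = 0 makes the divergence infinite (reported
    as inf, never NaN).
    """
    X = x.values if isinstance(x, ExpressionMatrix) else np.asarray(x, float)
    WH = W @ H
    if ((X > 0) & (WH == 0)).any():
        return math.inf
    pos = X > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(pos, X * np.log(np.where(pos, X, 1.0) / np.where(WH > 0, WH, 1.0)), 0.0)
    return float(term.sum() - X.sum() + WH.sum())


def multiplicative_step(x: np.ndarray | ExpressionMatrix,
                        state: FactorizationState) -> FactorizationState:
    """One coupled multiplicative update: H half-step, then W half-step.

    Factor entries are floored at machine-epsilon scale after each
    half-step to protect against zero denominators.
    """
    X = x.values if isinstance(x, ExpressionMatrix) else np.asarray(x, float)
    W = state.W.copy()
    H = state.H.copy()

    WH = np.maximum(W @ H, _FLOOR)
    H *= (W.T @ (X / WH)) / np.maximum(W.sum(axis=0)[:, None], _FLOOR)
    H = np.maximum(H, _FLOOR)

    WH = np.maximum(W @ H, _FLOOR)
    W *= ((X / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], _FLOOR)
    W = np.maximum(W, _FLOOR)

    return FactorizationState(
        W=W, H=H, k=state.k,
        divergence=kl_divergence(X, W, H),
        iteration=state.iteration + 1,
    )


def multiplicative_step_reference(X: np.ndarray, W: np.ndarray,
                                  H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Straight-loop (non-vectorized) form of the coupled updates.

    Independent reference used to cross-check the vectorized step; kept
    deliberately naive.
    """
    I, J = X.shape
    k = W.shape[1]
    WH = [[max(sum(W[i][a] * H[a][j] for a in range(k)), _FLOOR)
           for j in range(J)] for i in range(I)]
    Hn = [[0.0] * J for _ in range(k)]
    for a in range(k):
        wsum = max(sum(W[i][a] for i in range(I)), _FLOOR)
        for j in range(J):
            num = sum(W[i][a] * X[i][j] / WH[i][j] for i in range(I))
            Hn[a][j] = max(H[a][j] * num / wsum, _FLOOR)
    WH2 = [[max(sum(W[i][a] * Hn[a][j] for a in range(k)), _FLOOR)
            for j in range(J)] for i in range(I)]
    Wn = [[0.0] * k for _ in range(I)]
    for a in range(k):
        hsum = max(sum(Hn[a][j] for j in range(J)), _FLOOR)
        for i in range(I):
            num = sum(Hn[a][j] * X[i][j] / WH2[i][j] for j in range(J))
            Wn[i][a] = max(W[i][a] * num / hsum, _FLOOR)
    return np.asarray(Wn), np.asarray(Hn)


def marker_mask(markers: MarkerSet, gene_index: dict[str, int],
                I: int) -> np.ndarray:
    """Boolean I x T mask; True where a W entry must be zeroed.

    For a marker gene of component t, every column other than t is masked.
    Raises if any marker gene is missing from ``gene_index``.
    """
    T = markers.n_components
    missing = [g for g in markers.all_genes() if g not in gene_index]
    if missing:
        raise KeyError(f"marker genes absent from matrix: {missing}")
    mask = np.zeros((I, T), dtype=bool)
    for t, comp in enumerate(markers.components):
        for g in markers.genes_of[comp]:
            i = gene_index[g]
            mask[i, :] = True
            mask[i, t] = False
    return mask


def apply_marker_constraints(state: FactorizationState, markers: MarkerSet,
                             gene_index: dict[str, int],
                             x: np.ndarray | ExpressionMatrix | None = None,
                             log: list[str] | None = None) -> FactorizationState:
    """Zero W entries of marker genes outside their own component.

    When ``x`` is supplied the divergence is recomputed for the constrained
    factors; otherwise the stale value is carried over.
    """
    if markers.n_components != state.k:
        raise ValueError(
            f"rank k={state.k} does not match {markers.n_components} marker components"
        )
    mask = marker_mask(markers, gene_index, state.W.shape[0])
    W = state.W.copy()
    n_zeroed = int((W[mask] != 0).sum())
    W[mask] = 0.0
    if log is not None and n_zeroed:
        log.append(f"iteration {state.iteration}: zeroed {n_zeroed} off-component entries")
    div = kl_divergence(x, W, state.H) if x is not None else state.divergence
    return FactorizationState(
        W=W, H=state.H, k=state.k, divergence=div, iteration=state.iteration,
    )


def run_sskl(
    x: ExpressionMatrix,
    markers: MarkerSet | None,
    k: int,
    n_restarts: int = 30,
    max_iter: int = 2000,
    tol: float = 1e-6,
    seed: int = 0,
) -> SsklResult:
    """Best-of-restarts marker-constrained KL-NMF.

    Each restart initializes W, H ~ Uniform(0,1) * mean(X) (seeded),
    applies the marker constraints, and iterates the coupled updates until
    the relative divergence change drops below ``tol`` or ``max_iter`` is
    reached.  The restart with the lowest final divergence wins.  Returned
    proportions are the simplex-normalized H columns; W is reported on the
    intensity scale (unit-sum columns rescaled by the median per-sample H
    column sum).
    """
    if markers is not None and markers.n_components != k:
        raise ValueError("k must equal the number of marker components")
    if max_iter < 1 or tol <= 0:
        raise ValueError("need max_iter >= 1 and tol > 0")
    X = x.values
    I, J = X.shape
    gene_index = x.gene_index()
    mask = marker_mask(markers, gene_index, I) if markers is not None else None
    scale = max(float(X.mean()), _FLOOR)

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(max(n_restarts, 1))

    best: tuple[float, np.ndarray, np.ndarray, list[float], bool, int, int] | None = None
    constraint_log: list[str] = []
    violations = 0

    # draw the initial W rows keyed to sorted gene ids so the fit is
    # invariant to row permutation of the input (up to the same W
    # permutation and float summation order)
    order = np.argsort(np.asarray(x.gene_ids, dtype=object))

    for r in range(max(n_restarts, 1)):
        rng = np.random.default_rng(child_seeds[r])
        W = np.empty((I, k))
        W[order] = rng.random((I, k)) * scale
        H = rng.random((k, J)) * scale
        if mask is not None:
            W[mask] = 0.0
        div = kl_divergence(X, W, H)
        trace = [div]
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            state = multiplicative_step(
                X, FactorizationState(W=W, H=H, k=k, divergence=div, iteration=it)
            )
            W, H = state.W, state.H
            if mask is not None:
                n_zeroed = int((W[mask] > _FLOOR).sum())
                W[mask] = 0.0
                new_div = kl_divergence(X, W, H)
                if n_zeroed and new_div > trace[-1] + 1e-9:
                    violations += 1
                    constraint_log.append(
                        f"restart {r} iteration {it}: divergence rose "
                        f"{new_div - trace[-1]:.3e} after marker zeroing"
                    )
            else:
                new_div = state.divergence
            trace.append(new_div)
            if math.isfinite(new_div) and math.isfinite(trace[-2]):
                denom = max(abs(trace[-2]), _FLOOR)
                if abs(trace[-2] - new_div) / denom < tol:
                    converged = True
                    break
            div = new_div
        final = trace[-1]
        if best is None or final < best[0]:
            best = (final, W, H, trace, converged, it, r)

    if best is None or not math.isfinite(best[0]):
        raise RuntimeError(
            "all restarts reached infinite divergence; consider adding a "
            "pseudocount to the expression matrix"
        )
    final_div, W, H, trace, converged, n_iter, best_r = best

    # scale identification: unit-sum W columns, absorbed into H (WH preserved)
    d = np.maximum(W.sum(axis=0), _FLOOR)
    Wn = W / d[None, :]
    Hn = H * d[:, None]
    colsum = np.maximum(Hn.sum(axis=0), _FLOOR)
    H_prop = Hn / colsum[None, :]
    W_out = Wn * float(np.median(colsum))

    comps = (list(markers.components) if markers is not None
             else [f"comp{t + 1}" for t in range(k)])
    return SsklResult(
        W=Profiles(gene_ids=x.gene_ids, components=comps, values=W_out),
        H_normalized=Proportions(sample_ids=x.sample_ids, components=comps,
                                 values=H_prop),
        divergence=final_div,
        divergence_trace=trace,
        converged=converged,
        n_iter=n_iter,
        seed=seed,
        best_restart=best_r,
        fitted=W @ H,
        h_colsums=colsum,
        marker_constraint_log=constraint_log,
        monotonicity_violations=violations,
    )


def marker_direction_warnings(x: ExpressionMatrix, markers: MarkerSet,
                              result: SsklResult) -> list[str]:
    """Warn when a marker's fitted fold-change direction contradicts its
    component assignment (the method assumes markers that agree in
    direction; it does not auto-correct them)."""
    out: list[str] = []
    gi = {g: i for i, g in enumerate(result.W.gene_ids)}
    for t, comp in enumerate(markers.components):
        for g in markers.genes_of[comp]:
            if g not in gi:
                continue
            row = result.W.values[gi[g]]
            if row.argmax() != t:
                out.append(
                    f"marker {g!r} of {comp!r} peaks in "
                    f"{markers.components[int(row.argmax())]!r}"
                )
    return out
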