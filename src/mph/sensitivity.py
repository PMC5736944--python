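"""Marker-count robustness analysis.

How many marker genes per subpopulation does the factorization need before
the estimated proportions stop moving?  The scan subsamples the marker
lists at a grid of sizes, refits on each subsample, and summarizes the
across-replicate spread of the estimates:

* ``dispersion_by_count[n]`` — max over samples of the standard deviation
  of the first component's estimated proportion across replicates at
  marker count n (a single interpretable stability scalar per count);
* ``fc_vs_shift`` — per setting, the mean fold change of the subsampled
  markers (from the full-marker reference profiles) against the mean
  absolute deviation of the estimate from the full-marker reference,
  probing whether stronger markers pin the proportions down harder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import ExpressionMatrix, MarkerSet, Proportions
from .sskl import run_sskl


@dataclass
class SensitivityReport:
    counts: list[int]
    reps: int
    seed: int
    reference: Proportions
    proportions_by_setting: dict[tuple[int, int], Proportions]
    dispersion_by_count: dict[int, float]
    fc_vs_shift: list[dict] = field(default_factory=list)

    def dispersion_is_nonincreasing(self) -> bool:
        vals = [self.dispersion_by_count[c] for c in sorted(self.counts)]
        return all(b <= a + 1e-12 for a, b in zip(vals, vals[1:]))


def subsample_markers(markers: MarkerSet, n_per_component: int,
                      seed: int) -> MarkerSet:
    """Uniform random subset of n markers per component, seeded.

    Original within-component gene order is preserved, so the full-size
    subsample equals the input marker set.
    """
    rng = np.random.default_rng(seed)
    genes_of: dict[str, list[str]] = {}
    for comp in markers.components:
        pool = markers.genes_of[comp]
        if n_per_component > len(pool):
            raise ValueError(
                f"cannot draw {n_per_component} markers from the "
                f"{len(pool)} of component {comp!r}"
            )
        idx = sorted(rng.choice(len(pool), size=n_per_component, replace=False))
        genes_of[comp] = [pool[i] for i in idx]
    return MarkerSet(components=list(markers.components), genes_of=genes_of)


def sensitivity_scan(
    x: ExpressionMatrix,
    markers: MarkerSet,
    counts: list[int],
    reps: int = 10,
    seed: int = 0,
    n_restarts: int = 5,
    max_iter: int = 500,
    tol: float = 1e-6,
    vary_seeds: bool = True,
) -> SensitivityReport:
    """Refit the factorization on marker subsamples across a count grid.

    Every replicate draws its own marker subsample and its own
    factorization seed, so at the full marker count the dispersion
    reflects pure run-to-run variability of the fit.  With
    ``vary_seeds=False`` all replicates of a count share one subsample and
    fit seed (dispersion degenerates to 0 — a determinism check).
    """
    if not counts:
        raise ValueError("counts must be nonempty")
    if reps < 2:
        raise ValueError("reps must be >= 2")
    fit_kw = dict(n_restarts=n_restarts, max_iter=max_iter, tol=tol)
    k = markers.n_components

    ref = run_sskl(x.subset_genes(markers.all_genes()), markers, k=k,
                   seed=seed, **fit_kw)
    ref_fc = _marker_fc(ref)

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(counts) * reps * 2)
    proportions: dict[tuple[int, int], Proportions] = {}
    dispersion: dict[int, float] = {}
    fc_vs_shift: list[dict] = []

    idx = 0
    for count in counts:
        first_comp = np.empty((reps, x.n_samples))
        for r in range(reps):
            sub_seed = int(children[idx].generate_state(1)[0] % (2**31))
            fit_seed = int(children[idx + 1].generate_state(1)[0] % (2**31))
            if vary_seeds:
                idx += 2
            sub = subsample_markers(markers, count, seed=sub_seed)
            fit = run_sskl(x.subset_genes(sub.all_genes()), sub, k=k,
                           seed=fit_seed, **fit_kw)
            proportions[(count, r)] = fit.H_normalized
            first_comp[r] = fit.H_normalized.values[0]
            shift = float(
                np.abs(fit.H_normalized.values - ref.H_normalized.values).mean()
            )
            fc_vs_shift.append({
                "count": count,
                "replicate": r,
                "mean_marker_fc": _mean_fc(ref_fc, sub),
                "mean_abs_shift": shift,
            })
        dispersion[count] = float(first_comp.std(axis=0, ddof=1).max())

    return SensitivityReport(
        counts=list(counts),
        reps=reps,
        seed=seed,
        reference=ref.H_normalized,
        proportions_by_setting=proportions,
        dispersion_by_count=dispersion,
        fc_vs_shift=fc_vs_shift,
    )


def _marker_fc(ref) -> dict[str, float]:
    """Fold change of each marker gene between reference profile columns."""
    W = ref.W.values + 1e-6
    out: dict[str, float] = {}
    for i, g in enumerate(ref.W.gene_ids):
        row = W[i]
        out[g] = float(row.max() / row.min())
    return out


def _mean_fc(fc_of: dict[str, float], sub: MarkerSet) -> float:
    vals = [fc_of[g] for g in sub.all_genes() if g in fc_of]
    return float(np.mean(vals)) if vals else float("nan")
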