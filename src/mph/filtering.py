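"""Differential-expression filtering and fold-change ranking.

Genes that separate two experimental conditions are selected with a
two-sample t-test (Welch by default, pooled-variance optional) at a raw
p-value threshold; no multiple-testing correction is applied by default,
with an optional Benjamini-Hochberg FDR flag.  Candidate markers are then
ranked by fold change between two inferred subpopulation profiles, defined
symmetrically as max/min on pseudocount-shifted linear values so that both
up- and down-regulated genes rank high.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import ExpressionMatrix, Profiles

FC_PSEUDOCOUNT = 1e-6


@dataclass
class FilterResult:
    selected_gene_ids: list[str]
    pvalue_of: dict[str, float]
    statistic_of: dict[str, float]
    alpha: float


@dataclass
class FoldChangeRanking:
    ranked_gene_ids: list[str]
    fc_of: dict[str, float]
    direction_of: dict[str, str]  # which component is higher per gene


def ttest_filter(
    x: ExpressionMatrix,
    cond_a: str,
    cond_b: str,
    alpha: float = 0.05,
    equal_var: bool = False,
    fdr: bool = False,
) -> FilterResult:
    """Select genes with a two-sided two-sample t-test p-value below alpha.

    Genes with zero variance in both groups and equal means are assigned
    p = 1 (never NaN) and excluded.  Input gene order is preserved in the
    selection.  With ``fdr=True`` the threshold applies to BH-adjusted
    p-values instead of raw ones.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    ja = x.samples_in(cond_a)
    jb = x.samples_in(cond_b)
    if len(ja) < 2 or len(jb) < 2:
        raise ValueError(
            f"both conditions need >= 2 samples (got {len(ja)} for {cond_a!r}, "
            f"{len(jb)} for {cond_b!r})"
        )
    a = x.values[:, ja]
    b = x.values[:, jb]
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat, pval = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    # identical groups with zero spread: scipy yields NaN; define p = 1
    degenerate = ~np.isfinite(pval)
    pval = np.where(degenerate, 1.0, pval)
    tstat = np.where(degenerate, 0.0, tstat)

    crit = pval
    if fdr:
        crit = _bh_adjust(pval)
    selected = [g for g, p in zip(x.gene_ids, crit) if p < alpha]
    return FilterResult(
        selected_gene_ids=selected,
        pvalue_of=dict(zip(x.gene_ids, pval.tolist())),
        statistic_of=dict(zip(x.gene_ids, tstat.tolist())),
        alpha=alpha,
    )


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    n = len(pvals)
    order = np.argsort(pvals, kind="stable")
    ranked = pvals[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def fold_change_rank(
    profiles: Profiles,
    comp_a: str,
    comp_b: str,
    top_n: int = 500,
) -> FoldChangeRanking:
    """Rank genes by symmetric fold change max(a,b)/min(a,b) between two
    profile columns, descending; ties broken lexicographically by gene id.

    Both values are shifted by a small pseudocount so the ratio is defined
    at zeros.  ``top_n`` larger than the gene count returns all genes with
    a warning.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    for comp in (comp_a, comp_b):
        if comp not in profiles.components:
            raise ValueError(f"component {comp!r} not in profiles")
    ia = profiles.components.index(comp_a)
    ib = profiles.components.index(comp_b)
    a = profiles.values[:, ia] + FC_PSEUDOCOUNT
    b = profiles.values[:, ib] + FC_PSEUDOCOUNT
    fc = np.maximum(a, b) / np.minimum(a, b)
    direction = np.where(a >= b, comp_a, comp_b)

    order = sorted(range(len(fc)), key=lambda i: (-fc[i], profiles.gene_ids[i]))
    if top_n > len(order):
        warnings.warn(
            f"top_n={top_n} exceeds {len(order)} genes; returning all",
            stacklevel=2,
        )
        top_n = len(order)
    kept = order[:top_n]
    return FoldChangeRanking(
        ranked_gene_ids=[profiles.gene_ids[i] for i in kept],
        fc_of={profiles.gene_ids[i]: float(fc[i]) for i in kept},
        direction_of={profiles.gene_ids[i]: str(direction[i]) for i in kept},
    )
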