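"""Core in-memory containers for the deconvolution pipeline.

The model decomposes a nonnegative gene x sample expression matrix ``X``
into subpopulation profiles ``W`` (genes x components) and per-sample
mixing proportions ``H`` (components x samples, columns on the simplex):

    X ~= W H

All containers validate their invariants on construction and raise
:class:`ValidationError` with the offending identifier or coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SIMPLEX_TOL = 1e-9


class ValidationError(ValueError):
    """An input violated a container invariant."""


def _check_unique(ids, what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """Nonnegative expression matrix with per-sample condition labels.

    Rows are genes, columns are samples; values are linear-scale
    intensities.  Every sample carries a condition label (the experimental
    group it was measured under).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    condition_of: dict[str, str]

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if len(self.gene_ids) < 1 or len(self.sample_ids) < 1:
            raise ValidationError("expression matrix must be at least 1 x 1")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        bad = ~np.isfinite(self.values)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-finite value at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        neg = self.values < 0
        if neg.any():
            i, j = np.argwhere(neg)[0]
            raise ValidationError(
                f"negative value {self.values[i, j]} at gene "
                f"{self.gene_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )
        missing = [s for s in self.sample_ids if s not in self.condition_of]
        if missing:
            raise ValidationError(f"samples missing a condition label: {missing}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def conditions(self) -> list[str]:
        """Distinct condition labels, in first-appearance order."""
        out: list[str] = []
        for s in self.sample_ids:
            c = self.condition_of[s]
            if c not in out:
                out.append(c)
        return out

    def samples_in(self, condition: str) -> list[int]:
        """Column indices of samples carrying ``condition``."""
        return [
            j for j, s in enumerate(self.sample_ids)
            if self.condition_of[s] == condition
        ]

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        idx = self.gene_index()
        missing = [g for g in gene_ids if g not in idx]
        if missing:
            raise ValidationError(f"genes absent from matrix: {missing}")
        rows = [idx[g] for g in gene_ids]
        return ExpressionMatrix(
            gene_ids=list(gene_ids),
            sample_ids=self.sample_ids,
            values=self.values[rows, :].copy(),
            condition_of=dict(self.condition_of),
        )

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise ValidationError(f"samples absent from matrix: {missing}")
        cols = [pos[s] for s in sample_ids]
        return ExpressionMatrix(
            gene_ids=self.gene_ids,
            sample_ids=list(sample_ids),
            values=self.values[:, cols].copy(),
            condition_of={s: self.condition_of[s] for s in sample_ids},
        )


@dataclass
class MarkerSet:
    """Named subpopulations with disjoint marker-gene lists.

    A marker gene is assumed expressed predominantly in its own
    subpopulation; marker lists anchor and label the factorization
    components.
    """

    components: list[str]
    genes_of: dict[str, list[str]]

    def __post_init__(self) -> None:
        self.components = list(self.components)
        _check_unique(self.components, "component")
        if set(self.components) != set(self.genes_of):
            raise ValidationError("components and genes_of keys disagree")
        seen: dict[str, str] = {}
        for comp in self.components:
            for g in self.genes_of[comp]:
                if g in seen:
                    raise ValidationError(
                        f"marker gene {g!r} appears in both "
                        f"{seen[g]!r} and {comp!r}"
                    )
                seen[g] = comp

    @property
    def n_components(self) -> int:
        return len(self.components)

    def all_genes(self) -> list[str]:
        out: list[str] = []
        for comp in self.components:
            out.extend(self.genes_of[comp])
        return out

    def component_of(self) -> dict[str, str]:
        return {
            g: comp for comp in self.components for g in self.genes_of[comp]
        }

    def resolve_against(self, x: ExpressionMatrix) -> None:
        """Raise if any marker gene is absent from the matrix."""
        idx = set(x.gene_ids)
        missing = [g for g in self.all_genes() if g not in idx]
        if missing:
            raise ValidationError(f"marker genes absent from matrix: {missing}")


@dataclass
class Proportions:
    """Per-sample subpopulation fractions; each column on the T-simplex."""

    sample_ids: list[str]
    components: list[str]
    values: np.ndarray  # T x J

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.components = list(self.components)
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.components, "component")
        if self.values.shape != (len(self.components), len(self.sample_ids)):
            raise ValidationError(
                f"proportions shape {self.values.shape} does not match "
                f"{len(self.components)} components x {len(self.sample_ids)} samples"
            )
        if (self.values < -SIMPLEX_TOL).any() or (self.values > 1 + SIMPLEX_TOL).any():
            raise ValidationError("proportion entries must lie in [0, 1]")
        colsum = self.values.sum(axis=0)
        off = np.abs(colsum - 1.0)
        if (off > SIMPLEX_TOL).any():
            j = int(np.argmax(off))
            raise ValidationError(
                f"column for sample {self.sample_ids[j]!r} sums to "
                f"{colsum[j]!r}, not 1"
            )


@dataclass
class Profiles:
    """Subpopulation-specific expression profiles (genes x components)."""

    gene_ids: list[str]
    components: list[str]
    values: np.ndarray  # I x T
    condition: str | None = field(default=None)

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.components = list(self.components)
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.components, "component")
        if self.values.shape != (len(self.gene_ids), len(self.components)):
            raise ValidationError(
                f"profiles shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.components)} components"
            )
        if not np.isfinite(self.values).all():
            raise ValidationError("profile entries must be finite")
        if (self.values < 0).any():
            i, t = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative profile entry at gene {self.gene_ids[i]!r}, "
                f"component {self.components[t]!r}"
            )
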