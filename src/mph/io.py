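"""Plain-text readers/writers: expression TSV, condition map, GMT markers,
proportions and profiles TSVs.

All tables are UTF-8 tab-separated with a header row.  Round-trips preserve
values to 12 significant digits and preserve row/column order.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .containers import (
    ExpressionMatrix,
    MarkerSet,
    Proportions,
    Profiles,
    ValidationError,
)

_FLOAT_FMT = "%.17g"  # lossless float round-trip


def read_condition_map(path: str | os.PathLike) -> dict[str, str]:
    """Read a two-column TSV (sample_id, condition) into a dict."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValidationError(f"condition map {path} needs two columns")
    sample_col, cond_col = df.columns[:2]
    if df[sample_col].duplicated().any():
        dup = df[sample_col][df[sample_col].duplicated()].iloc[0]
        raise ValidationError(f"duplicate sample identifier in condition map: {dup!r}")
    return dict(zip(df[sample_col], df[cond_col]))


def read_expression(
    path: str | os.PathLike, condition_map: str | os.PathLike | dict[str, str]
) -> ExpressionMatrix:
    """Read an expression TSV (first column gene ids, header sample ids).

    ``condition_map`` is a path to a two-column TSV or an already-loaded
    sample -> condition dict.  Validation failures name the offending
    identifier or cell.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    gene_ids = [str(g) for g in df.index]
    sample_ids = [str(s) for s in df.columns]
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric expression value in {path}: {exc}") from exc
    cond = (
        condition_map
        if isinstance(condition_map, dict)
        else read_condition_map(condition_map)
    )
    missing = [s for s in sample_ids if s not in cond]
    if missing:
        raise ValidationError(f"samples missing from condition map: {missing}")
    return ExpressionMatrix(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        values=values,
        condition_of={s: cond[s] for s in sample_ids},
    )


def write_expression(x: ExpressionMatrix, path: str | os.PathLike) -> None:
    df = pd.DataFrame(x.values, index=x.gene_ids, columns=x.sample_ids)
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def write_condition_map(x: ExpressionMatrix, path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        {"sample_id": x.sample_ids,
         "condition": [x.condition_of[s] for s in x.sample_ids]}
    )
    df.to_csv(path, sep="\t", index=False)


def read_markers(path: str | os.PathLike, min_components: int = 2) -> MarkerSet:
    """Read a GMT file (name, description, tab-separated gene ids)."""
    components: list[str] = []
    genes_of: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"GMT line needs name, description and at least one gene: {line!r}"
                )
            name = fields[0]
            genes = [g for g in fields[2:] if g]
            components.append(name)
            genes_of[name] = genes
    if len(components) < min_components:
        raise ValidationError(
            f"marker file {path} has {len(components)} component(s); "
            f"at least {min_components} required"
        )
    return MarkerSet(components=components, genes_of=genes_of)


def write_markers(markers: MarkerSet, path: str | os.PathLike,
                  description: str = "mph") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for comp in markers.components:
            fh.write("\t".join([comp, description, *markers.genes_of[comp]]) + "\n")


def write_proportions(p: Proportions, path: str | os.PathLike) -> None:
    """Write proportions as a TSV: components as rows, samples as columns."""
    df = pd.DataFrame(p.values, index=p.components, columns=p.sample_ids)
    df.index.name = "component"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_proportions(path: str | os.PathLike) -> Proportions:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return Proportions(
        sample_ids=[str(s) for s in df.columns],
        components=[str(c) for c in df.index],
        values=df.to_numpy(dtype=float),
    )


def write_profiles(w: Profiles, path: str | os.PathLike) -> None:
    df = pd.DataFrame(w.values, index=w.gene_ids, columns=w.components)
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_profiles(path: str | os.PathLike,
                  condition: str | None = None) -> Profiles:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return Profiles(
        gene_ids=[str(g) for g in df.index],
        components=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
        condition=condition,
    )


def unlog(x: ExpressionMatrix, base: float = 2.0) -> ExpressionMatrix:
    """Explicit unlog transform (base**value) for log-scale input.

    Applied only on user request: the factorization stage requires
    linear-scale nonnegative intensities and log-scale input is never
    auto-detected.
    """
    return ExpressionMatrix(
        gene_ids=x.gene_ids,
        sample_ids=x.sample_ids,
        values=np.power(base, x.values),
        condition_of=dict(x.condition_of),
    )
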