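"""Synthetic expression mixtures with known ground truth.

The generative model mirrors the deconvolution model itself: each sample j
is a convex mixture of T subpopulation profiles (per experimental
condition), observed with additive Gaussian replication noise whose
variance 1/lambda_i differs by gene but is shared across subpopulations
and conditions,

    y_ij = sum_t p_tj * x_{t,i,c(j)} + eps_ij,   eps_ij ~ N(0, 1/lambda_i).

Marker genes are planted with a high expression value in their own
component's profile and a low value in every other component, so every
downstream stage (fold-change ranking, marker-guided factorization,
heterogeneity testing) has an oracle.

Defaults: background profile entries Uniform(1, 10); lambda_i drawn
Gamma(shape=2, rate=0.5), giving per-gene noise sd roughly 0.7-2.5 against
intensities 1-10; markers at 10 (own component) vs 0.5 (others).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import ExpressionMatrix, MarkerSet, Proportions, Profiles


@dataclass
class SyntheticSpec:
    """Parameters of the generative model.

    ``true_profiles`` / ``true_proportions`` override the random defaults;
    when absent, background profiles are drawn Uniform(1, 10) per gene per
    component and proportions default to alternating (0.7, 0.3)/(0.3, 0.7)
    for T=2 (a seeded Dirichlet(5) draw for other T).
    """

    I: int = 500
    J: int = 6
    T: int = 2
    conditions: dict[str, str] | None = None  # sample -> condition
    true_profiles: dict[str, Profiles] | None = None  # per condition
    true_proportions: Proportions | None = None
    lambda_shape: float = 2.0
    lambda_rate: float = 0.5
    markers_per_component: int = 12
    marker_high: float = 10.0
    marker_low: float = 0.5
    background_low: float = 1.0
    background_high: float = 10.0
    fixed_lambda: float | None = None  # bypass the Gamma draw (e.g. 1e12 for near-noiseless)
    share_profiles: bool = False  # one profile set reused across conditions
    seed: int = 0

    def __post_init__(self) -> None:
        if self.I < 1 or self.J < 1 or self.T < 1:
            raise ValueError("I, J and T must all be >= 1")
        if not self.marker_high > self.marker_low >= 0:
            raise ValueError("need marker_high > marker_low >= 0")
        if self.markers_per_component * self.T > self.I:
            raise ValueError(
                f"{self.markers_per_component} markers x {self.T} components "
                f"exceed {self.I} genes"
            )

    @property
    def sample_ids(self) -> list[str]:
        if self.conditions is not None:
            return list(self.conditions)
        return [f"s{j + 1}" for j in range(self.J)]

    def condition_of(self) -> dict[str, str]:
        if self.conditions is not None:
            return dict(self.conditions)
        return {s: "cond1" for s in self.sample_ids}


@dataclass
class SyntheticDataset:
    """A simulated mixture together with every ground-truth quantity."""

    expression: ExpressionMatrix
    truth_proportions: Proportions
    truth_profiles: dict[str, Profiles]
    truth_markers: MarkerSet
    truth_lambda: np.ndarray
    n_clipped: int = field(default=0)

    @property
    def clipped_fraction(self) -> float:
        return self.n_clipped / self.expression.values.size


def _component_names(T: int) -> list[str]:
    return [f"comp{t + 1}" for t in range(T)]


def _default_proportions(spec: SyntheticSpec, rng: np.random.Generator,
                         sample_ids: list[str]) -> np.ndarray:
    T, J = spec.T, len(sample_ids)
    if T == 1:
        return np.ones((1, J))
    if T == 2:
        base = np.array([0.7, 0.3])
        return np.column_stack([base if j % 2 == 0 else base[::-1]
                                for j in range(J)])
    return rng.dirichlet(np.full(T, 5.0), size=J).T


def _draw_profiles(spec: SyntheticSpec, rng: np.random.Generator,
                   gene_ids: list[str], conditions: list[str],
                   marker_rows: dict[str, np.ndarray]) -> dict[str, Profiles]:
    comps = _component_names(spec.T)
    out: dict[str, Profiles] = {}
    shared: np.ndarray | None = None
    for cond in conditions:
        if spec.share_profiles and shared is not None:
            w = shared.copy()
        else:
            w = rng.uniform(spec.background_low, spec.background_high,
                            size=(spec.I, spec.T))
            for t, comp in enumerate(comps):
                rows = marker_rows[comp]
                w[rows, :] = spec.marker_low
                w[rows, t] = spec.marker_high
            shared = w
        out[cond] = Profiles(gene_ids=gene_ids, components=comps,
                             values=w, condition=cond)
    return out


def _draw_lambda(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.fixed_lambda is not None:
        return np.full(spec.I, float(spec.fixed_lambda))
    return rng.gamma(shape=spec.lambda_shape, scale=1.0 / spec.lambda_rate,
                     size=spec.I)


def simulate(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw one dataset under the mixture-plus-Gaussian-noise model.

    Identical spec (including seed) yields a bit-identical dataset.
    Negative simulated intensities are clipped to 0 and the count recorded.
    """
    rng = np.random.default_rng(spec.seed)
    gene_ids = [f"g{i + 1}" for i in range(spec.I)]
    sample_ids = spec.sample_ids
    cond_of = spec.condition_of()
    conditions: list[str] = []
    for s in sample_ids:
        if cond_of[s] not in conditions:
            conditions.append(cond_of[s])
    comps = _component_names(spec.T)

    # plant markers in the first markers_per_component * T rows
    marker_rows = {
        comp: np.arange(t * spec.markers_per_component,
                        (t + 1) * spec.markers_per_component)
        for t, comp in enumerate(comps)
    }
    markers = MarkerSet(
        components=comps,
        genes_of={comp: [gene_ids[i] for i in rows]
                  for comp, rows in marker_rows.items()},
    )

    if spec.true_profiles is not None:
        profiles = spec.true_profiles
    else:
        profiles = _draw_profiles(spec, rng, gene_ids, conditions, marker_rows)

    if spec.true_proportions is not None:
        props = spec.true_proportions
    else:
        props = Proportions(sample_ids=sample_ids, components=comps,
                            values=_default_proportions(spec, rng, sample_ids))

    lam = _draw_lambda(spec, rng)
    noise_sd = 1.0 / np.sqrt(lam)

    y = np.empty((spec.I, spec.J))
    for j, s in enumerate(sample_ids):
        w = profiles[cond_of[s]].values
        y[:, j] = w @ props.values[:, j]
    y += rng.standard_normal(size=y.shape) * noise_sd[:, None]
    n_clipped = int((y < 0).sum())
    np.clip(y, 0.0, None, out=y)

    expression = ExpressionMatrix(gene_ids=gene_ids, sample_ids=sample_ids,
                                  values=y, condition_of=cond_of)
    return SyntheticDataset(
        expression=expression,
        truth_proportions=props,
        truth_profiles=profiles,
        truth_markers=markers,
        truth_lambda=lam,
        n_clipped=n_clipped,
    )


def simulate_null(spec: SyntheticSpec) -> SyntheticDataset:
    """Simulate under the homogeneous null: one profile per condition.

    The designated marker gene ids are kept in ``truth_markers`` (so
    marker-guided fits can still be run for test calibration) but their
    expression is drawn from the background distribution — under the null
    there is no planted contrast and no mixing.
    """
    rng = np.random.default_rng(spec.seed)
    gene_ids = [f"g{i + 1}" for i in range(spec.I)]
    sample_ids = spec.sample_ids
    cond_of = spec.condition_of()
    conditions: list[str] = []
    for s in sample_ids:
        if cond_of[s] not in conditions:
            conditions.append(cond_of[s])
    comps = _component_names(spec.T)
    marker_rows = {
        comp: np.arange(t * spec.markers_per_component,
                        (t + 1) * spec.markers_per_component)
        for t, comp in enumerate(comps)
    }
    markers = MarkerSet(
        components=comps,
        genes_of={comp: [gene_ids[i] for i in rows]
                  for comp, rows in marker_rows.items()},
    )

    profiles = {
        cond: Profiles(
            gene_ids=gene_ids,
            components=["comp1"],
            values=rng.uniform(spec.background_low, spec.background_high,
                               size=(spec.I, 1)),
            condition=cond,
        )
        for cond in conditions
    }
    props = Proportions(sample_ids=sample_ids, components=["comp1"],
                        values=np.ones((1, spec.J)))

    lam = _draw_lambda(spec, rng)
    noise_sd = 1.0 / np.sqrt(lam)
    y = np.empty((spec.I, spec.J))
    for j, s in enumerate(sample_ids):
        y[:, j] = profiles[cond_of[s]].values[:, 0]
    y += rng.standard_normal(size=y.shape) * noise_sd[:, None]
    n_clipped = int((y < 0).sum())
    np.clip(y, 0.0, None, out=y)

    expression = ExpressionMatrix(gene_ids=gene_ids, sample_ids=sample_ids,
                                  values=y, condition_of=cond_of)
    return SyntheticDataset(
        expression=expression,
        truth_proportions=props,
        truth_profiles=profiles,
        truth_markers=markers,
        truth_lambda=lam,
        n_clipped=n_clipped,
    )
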