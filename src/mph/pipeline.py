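"""End-to-end workflow orchestration.

Stage order: differential-expression filter -> Bayesian deconvolution
(uniform prior) -> fold-change candidate ranking -> [curated marker file
required] -> marker-guided KL factorization -> heterogeneity LRT ->
new-marker ranking.  Every stage writes plain TSV artifacts plus a JSON
manifest (config echo, seeds, stage status), and completed stages are
skipped on resume.  The marker-curation step is a deliberate human-in-the-
loop break point: the pipeline emits ranked candidates and halts until a
curated GMT is supplied, unless ``auto_markers`` injects the top candidates
per direction for testing.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .containers import MarkerSet, Profiles
from .dsection import run_mcmc, uniform_prior
from .filtering import fold_change_rank, ttest_filter
from .hettest import lrt
from .sskl import marker_direction_warnings, run_sskl

logger = logging.getLogger(__name__)

STAGES = ["filter", "dsection", "rank", "markers", "sskl", "lrt", "newmarkers"]


@dataclass
class PipelineConfig:
    expression: str
    conditions: str
    out_dir: str
    cond_a: str
    cond_b: str
    markers: str | None = None
    auto_markers: int = 0  # top-n candidates per direction; 0 = curated GMT required
    alpha: float = 0.05
    top_n: int = 500
    T: int = 2
    dsection_iters: int = 4000
    dsection_burn_in: int = 1000
    dsection_thin: int = 3
    dsection_concentration: float = 10.0
    sskl_restarts: int = 30
    sskl_max_iter: int = 2000
    sskl_tol: float = 1e-6
    gene_scope: str = "markers+filtered"  # markers | filtered | all | markers+filtered
    lrt_alpha: float = 0.05
    lrt_boot: int = 200
    seed: int = 0

    def validate(self) -> None:
        for p in (self.expression, self.conditions):
            if not Path(p).exists():
                raise FileNotFoundError(p)
        if self.markers is not None and not Path(self.markers).exists():
            raise FileNotFoundError(self.markers)
        if not 0 < self.alpha < 1 or not 0 < self.lrt_alpha < 1:
            raise ValueError("alpha values must lie in (0, 1)")
        if self.gene_scope not in {"markers", "filtered", "all", "markers+filtered"}:
            raise ValueError(f"unknown gene_scope {self.gene_scope!r}")

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineResult:
    status: str  # completed | awaiting_markers | stopped
    out_dir: str
    stages_run: list[str] = field(default_factory=list)
    stages_skipped: list[str] = field(default_factory=list)


def _write_manifest(cfg: PipelineConfig, out: Path, status: dict) -> None:
    from . import __version__
    manifest = {
        "version": __version__,
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stages": status,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def run_pipeline(config: PipelineConfig, stop_after: str | None = None,
                 resume: bool = True) -> PipelineResult:
    """Execute the workflow, writing artifacts under ``config.out_dir``.

    Returns with status ``awaiting_markers`` (not an error) when no curated
    marker file is available after the candidate-ranking stage.
    """
    config.validate()
    if stop_after is not None and stop_after not in STAGES:
        raise ValueError(f"unknown stage {stop_after!r}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    status: dict[str, str] = {}
    run, skipped = [], []

    x = mio.read_expression(config.expression, config.conditions)
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    seed_of = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(["dsection", "sskl", "lrt", "extra"], seeds)
    }

    def done(stage: str, artifact: Path) -> bool:
        if resume and artifact.exists():
            status[stage] = "skipped (artifact present)"
            skipped.append(stage)
            return True
        return False

    def finish(stage: str, t0: float) -> PipelineResult | None:
        status[stage] = f"completed in {time.time() - t0:.2f}s"
        run.append(stage)
        _write_manifest(config, out, status)
        if stop_after == stage:
            return PipelineResult("stopped", str(out), run, skipped)
        return None

    # --- filter
    filt_path = out / "filtered_genes.tsv"
    if not done("filter", filt_path):
        t0 = time.time()
        res = ttest_filter(x, config.cond_a, config.cond_b, alpha=config.alpha)
        pd.DataFrame({
            "gene_id": x.gene_ids,
            "statistic": [res.statistic_of[g] for g in x.gene_ids],
            "p_value": [res.pvalue_of[g] for g in x.gene_ids],
            "selected": [int(g in set(res.selected_gene_ids)) for g in x.gene_ids],
        }).to_csv(filt_path, sep="\t", index=False, float_format="%.12g")
        if (r := finish("filter", t0)) is not None:
            return r
    filt = pd.read_csv(filt_path, sep="\t")
    selected = [str(g) for g, s in zip(filt.gene_id, filt.selected) if s]
    if not selected:
        raise RuntimeError("no genes passed the differential-expression filter")
    x_filt = x.subset_genes(selected)

    # --- dsection
    ds_prop_path = out / "dsection_proportions.tsv"
    if not done("dsection", ds_prop_path):
        t0 = time.time()
        prior = uniform_prior(x_filt, config.T,
                              concentration=config.dsection_concentration)
        mc = run_mcmc(x_filt, config.T, prior, n_iter=config.dsection_iters,
                      burn_in=config.dsection_burn_in, thin=config.dsection_thin,
                      seed=seed_of["dsection"], keep_chain=False)
        mio.write_proportions(mc.p_mean, ds_prop_path)
        for c, prof in mc.x_mean.items():
            mio.write_profiles(prof, out / f"dsection_profiles_{c}.tsv")
        if (r := finish("dsection", t0)) is not None:
            return r

    # --- rank candidates for marker curation
    rank_path = out / "marker_candidates.tsv"
    if not done("rank", rank_path):
        t0 = time.time()
        profs = [mio.read_profiles(out / f"dsection_profiles_{c}.tsv", condition=c)
                 for c in x.conditions]
        mean_w = Profiles(
            gene_ids=profs[0].gene_ids,
            components=profs[0].components,
            values=np.mean([p.values for p in profs], axis=0),
        )
        ranking = fold_change_rank(mean_w, mean_w.components[0],
                                   mean_w.components[1], top_n=config.top_n)
        pd.DataFrame({
            "gene_id": ranking.ranked_gene_ids,
            "fc": [ranking.fc_of[g] for g in ranking.ranked_gene_ids],
            "direction": [ranking.direction_of[g] for g in ranking.ranked_gene_ids],
        }).to_csv(rank_path, sep="\t", index=False, float_format="%.12g")
        if (r := finish("rank", t0)) is not None:
            return r

    # --- curated markers (human-in-the-loop break point)
    markers_path = out / "markers_used.gmt"
    if not done("markers", markers_path):
        t0 = time.time()
        if config.markers is not None:
            markers = mio.read_markers(config.markers)
        elif config.auto_markers > 0:
            ranking = pd.read_csv(rank_path, sep="\t")
            genes_of: dict[str, list[str]] = {}
            for comp in sorted(ranking.direction.unique()):
                top = ranking[ranking.direction == comp].gene_id.head(
                    config.auto_markers
                )
                genes_of[str(comp)] = [str(g) for g in top]
            markers = MarkerSet(components=sorted(genes_of), genes_of=genes_of)
        else:
            status["markers"] = "awaiting curated marker GMT"
            _write_manifest(config, out, status)
            logger.info(
                "candidate ranking written to %s; curate a marker GMT and "
                "rerun with markers=<path> (or set auto_markers)", rank_path,
            )
            return PipelineResult("awaiting_markers", str(out), run, skipped)
        mio.write_markers(markers, markers_path)
        if (r := finish("markers", t0)) is not None:
            return r
    markers = mio.read_markers(markers_path)
    markers.resolve_against(x)

    scope = {
        "markers": markers.all_genes(),
        "filtered": selected,
        "all": x.gene_ids,
        "markers+filtered": list(dict.fromkeys(markers.all_genes() + selected)),
    }[config.gene_scope]
    x_scope = x.subset_genes(scope)

    # --- sskl
    sskl_prop_path = out / "proportions.tsv"
    if not done("sskl", sskl_prop_path):
        t0 = time.time()
        fit = run_sskl(x_scope, markers, k=markers.n_components,
                       n_restarts=config.sskl_restarts,
                       max_iter=config.sskl_max_iter, tol=config.sskl_tol,
                       seed=seed_of["sskl"])
        for w in marker_direction_warnings(x_scope, markers, fit):
            logger.warning(w)
        mio.write_proportions(fit.H_normalized, sskl_prop_path)
        mio.write_profiles(fit.W, out / "profiles.tsv")
        pd.DataFrame({"divergence": fit.divergence_trace}).to_csv(
            out / "divergence_trace.tsv", sep="\t", index=False,
            float_format="%.12g",
        )
        if (r := finish("sskl", t0)) is not None:
            return r

    # --- heterogeneity LRT, per experimental condition
    lrt_path = out / "lrt.tsv"
    if not done("lrt", lrt_path):
        t0 = time.time()
        rows = []
        for i, c in enumerate(x.conditions):
            xc = x_scope.subset_samples(
                [s for s in x_scope.sample_ids if x_scope.condition_of[s] == c]
            )
            res = lrt(xc, markers, alpha=config.lrt_alpha,
                      n_boot=config.lrt_boot, seed=seed_of["lrt"] + i,
                      T=markers.n_components)
            rows.append({
                "condition": c, "ll_h0": res.ll_h0, "ll_h1": res.ll_h1,
                "statistic": res.statistic, "df": res.df,
                "p_chi2": res.p_chi2, "p_boot": res.p_boot,
                "reject": int(res.reject),
            })
        pd.DataFrame(rows).to_csv(lrt_path, sep="\t", index=False,
                                  float_format="%.12g")
        if (r := finish("lrt", t0)) is not None:
            return r

    # --- new-marker ranking on the fitted profiles, input markers excluded
    new_path = out / "new_marker_candidates.tsv"
    if not done("newmarkers", new_path):
        t0 = time.time()
        W = mio.read_profiles(out / "profiles.tsv")
        ranking = fold_change_rank(W, W.components[0], W.components[1],
                                   top_n=min(config.top_n, len(W.gene_ids)))
        known = set(markers.all_genes())
        rows = [
            {"gene_id": g, "fc": ranking.fc_of[g],
             "direction": ranking.direction_of[g]}
            for g in ranking.ranked_gene_ids if g not in known
        ]
        pd.DataFrame(rows).to_csv(new_path, sep="\t", index=False,
                                  float_format="%.12g")
        if (r := finish("newmarkers", t0)) is not None:
            return r

    _write_manifest(config, out, status)
    return PipelineResult("completed", str(out), run, skipped)
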