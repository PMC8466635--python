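"""End-to-end orchestration: filter -> families -> noise -> Z + FDR ->
PCA + GMM -> reports, deterministic under a single seed.

Every output table carries a header comment with the configuration hash and
seed, so a run is a pure function of (inputs, config, seed).  Clustering is
skipped, with a recorded reason, when fewer than two parameters are
significant.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .data import MorphDataset, filter_min_cells
from .differential import select_families, z_matrix, permutation_fdr
from .noise import to_noise
from .cluster import pca_reduce, gmm_select, posterior_report, COV_MODELS

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    min_cells: int = 200
    n_perm: int = 2000
    alpha: float = 0.05
    ccr_cluster: float = 0.80
    ccr_similarity: float = 0.99
    c_range: tuple = tuple(range(1, 10))
    models: tuple = COV_MODELS
    loess_on: str = "all"         # population for CV-mean LOESS
    family_on: str = "wt"         # population for family selection
    gmm_starts: int = 20
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0,1)")
        if not (0 < self.ccr_cluster <= 1 and 0 < self.ccr_similarity <= 1):
            raise ValueError("CCR targets must lie in (0,1]")
        if self.n_perm < 1 or self.min_cells < 0:
            raise ValueError("n_perm >= 1 and min_cells >= 0 required")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    config: PipelineConfig
    dataset: MorphDataset
    fits: dict
    zmatrix: object
    noise_models: dict
    flagged_params: list
    category_counts: dict
    pca: Optional[object] = None
    scores: Optional[pd.DataFrame] = None
    gmm: Optional[object] = None
    assignments: Optional[pd.DataFrame] = None
    skipped_clustering: Optional[str] = None
    stage_log: list = field(default_factory=list)


def _stage(result, name, t0, shape_info):
    msg = f"{name}: {shape_info} ({time.perf_counter() - t0:.2f}s)"
    result.stage_log.append(msg)
    log.info("pipeline %s", msg)


def run_pipeline(ds: MorphDataset, config: PipelineConfig = None,
                 outdir=None) -> PipelineResult:
    """Run the full analysis on a validated dataset.

    When ``outdir`` is given, all tabular outputs are written there as TSV
    (with config-hash/seed provenance headers) plus the data behind a
    PC1/PC2 score plot and a per-category stacked-bar summary.
    """
    cfg = config or PipelineConfig()
    result = PipelineResult(cfg, ds, {}, None, {}, [], {})

    t0 = time.perf_counter()
    ds = filter_min_cells(ds.validate(), cfg.min_cells)
    _stage(result, "filter_min_cells", t0,
           f"{ds.n_rows()} rows, {len(ds.strains)} strains")

    t0 = time.perf_counter()
    ds, noise_models = to_noise(ds, on=cfg.loess_on)
    result.noise_models = noise_models
    _stage(result, "noise", t0, f"{len(noise_models)} cv parameters decoupled")

    t0 = time.perf_counter()
    fits = select_families(ds, on=cfg.family_on)
    result.fits = fits
    _stage(result, "families", t0, f"{len(fits)} parameters modeled")

    t0 = time.perf_counter()
    zm = z_matrix(ds, fits)
    _stage(result, "z_matrix", t0, f"{zm.z.shape[0]}x{zm.z.shape[1]} grid")

    t0 = time.perf_counter()
    zm = permutation_fdr(zm, ds, fits, n_perm=cfg.n_perm, alpha=cfg.alpha,
                         seed=cfg.seed)
    result.zmatrix = zm
    result.dataset = ds
    flagged = zm.flagged_params()
    result.flagged_params = flagged
    result.category_counts = {
        cat: sum(1 for p in flagged if ds.meta[p].category == cat)
        for cat in ("actin", "cell", "nucleus")}
    _stage(result, "permutation_fdr", t0,
           f"t*={zm.threshold:.3g}, {len(flagged)} significant parameters "
           f"(actin/cell/nucleus = "
           f"{result.category_counts['actin']}/{result.category_counts['cell']}"
           f"/{result.category_counts['nucleus']})")

    if len(flagged) < 2:
        result.skipped_clustering = (
            f"only {len(flagged)} significant parameters (< 2); "
            "clustering skipped")
        log.warning("pipeline: %s", result.skipped_clustering)
    else:
        t0 = time.perf_counter()
        pca, scores = pca_reduce(zm.z[flagged], ccr_target=cfg.ccr_cluster)
        result.pca, result.scores = pca, scores
        _stage(result, "pca", t0,
               f"k={pca.k} PCs, CCR={pca.ccr[pca.k - 1] * 100:.2f}%")
        t0 = time.perf_counter()
        gmm = gmm_select(scores.to_numpy(), c_range=cfg.c_range,
                         models=cfg.models, seed=cfg.seed,
                         n_starts=cfg.gmm_starts)
        result.gmm = gmm
        result.assignments = posterior_report(gmm, ids=list(scores.index))
        _stage(result, "gmm", t0,
               f"c={gmm.n_components}, model={gmm.model}, BIC={gmm.bic:.1f}")

    if outdir is not None:
        _write_outputs(result, Path(outdir))
    return result


def _write_outputs(result: PipelineResult, outdir: Path):
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    header = f"# morphoprofile config={cfg.hash()} seed={cfg.seed}\n"

    def _write(df, name, index=True):
        path = outdir / name
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index=index, float_format="%.6g")

    zm = result.zmatrix
    long = zm.z.stack(future_stack=True).rename("z").reset_index()
    long["coef"] = zm.coef.stack(future_stack=True).to_numpy()
    long["se"] = zm.se.stack(future_stack=True).to_numpy()
    long["flagged"] = zm.flags.stack(future_stack=True).to_numpy()
    _write(long, "z_long.tsv", index=False)

    fam_rows = [{"param": pid, "family": f.spec.name, "aic": f.aic,
                 "loglik": f.loglik,
                 **{f"aic_{k}": v.get("aic", np.nan)
                    for k, v in f.candidates.items()}}
                for pid, f in result.fits.items()]
    _write(pd.DataFrame(fam_rows), "families.tsv", index=False)

    noise_rows = [{"cv_param": pid, "mean_param": m.mean_param_id,
                   "span": m.span, "edf": m.edf, "aic": m.aic}
                  for pid, m in result.noise_models.items()]
    _write(pd.DataFrame(noise_rows), "noise_spans.tsv", index=False)

    cat = pd.DataFrame([result.category_counts])
    _write(cat, "category_counts.tsv", index=False)

    summary = {
        "config": asdict(cfg), "config_hash": cfg.hash(),
        "threshold": zm.threshold, "n_significant": len(result.flagged_params),
        "category_counts": result.category_counts,
        "skipped_clustering": result.skipped_clustering,
        "stages": result.stage_log,
    }
    if result.gmm is not None:
        summary["gmm"] = {"c": result.gmm.n_components, "model": result.gmm.model,
                          "bic": result.gmm.bic}
        summary["pca"] = {"k": result.pca.k,
                          "ccr": float(result.pca.ccr[result.pca.k - 1])}
        _write(result.gmm.selection_table, "gmm_selection.tsv", index=False)
        _write(result.assignments, "clusters.tsv")
        plot = result.scores.iloc[:, :2].copy()
        plot["cluster"] = result.gmm.labels
        _write(plot, "score_plot.tsv")
    # stage timings vary run to run; keep them out of the deterministic summary
    summary["stages"] = [s.split(" (")[0] for s in summary["stages"]]
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
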