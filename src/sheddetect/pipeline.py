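"""End-to-end orchestration: DEG -> DEP -> integrate -> classify -> substrates
(-> enrich/overlap), with a reproducible run manifest.

Stages are pure functions of (inputs, config, seed); rerunning with the
same inputs and seed reproduces every output byte-for-byte, which the
manifest's per-file SHA-256 hashes make checkable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diffexpr import (
    call_differential,
    estimate_common_dispersion,
    moderated_t,
    nb_exact_test,
    normalize_intensities,
    tmm_factors,
)
from .enrichment import build_background, fisher_enrichment, overlap_stats
from .io import (
    ExpressionMatrix,
    read_annotation_table,
    read_design_table,
    read_expression_table,
    read_gmt,
    write_result_table,
)
from .o2pls import O2PLS, cross_validate
from .substrates import filter_candidates, topology_summary
from .targets import classify_targets, pair_features

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "log2_cpm", "pair_samples"]


@dataclass
class RunConfig:
    """Inputs, thresholds, and component settings for a full run."""

    counts_path: str
    intensities_path: str
    design_path: str
    annotation_path: str
    out_dir: str
    bait_id: str
    gmt_path: str | None = None
    deg_fc: float = 1.5
    dep_fc: float = 1.2
    alpha: float = 0.05
    n_joint: int = 3
    n_orth_x: int = 2
    n_orth_y: int = 2
    cv_grid: list | None = None        # list of (n, nx, ny); overrides fixed components
    genome_size: int = 20000
    background_min_total: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.deg_fc <= 1 or self.dep_fc <= 1:
            raise ValueError("fold-change thresholds must exceed 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    def config_hash(self) -> str:
        # out_dir is where results land, not part of what they are
        payload = {k: v for k, v in dataclasses.asdict(self).items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def log2_cpm(counts: ExpressionMatrix, factors=None, prior: float = 0.5) -> ExpressionMatrix:
    """log2 counts-per-million on effective library sizes, with a prior count."""
    if factors is None:
        factors = tmm_factors(counts)
    lib = counts.values.sum(axis=1) * factors.reindex(counts.sample_ids).to_numpy()
    vals = np.log2((counts.values + prior) / lib[:, None] * 1.0e6)
    return ExpressionMatrix(vals, list(counts.sample_ids), list(counts.feature_ids),
                            "log_intensities")


def pair_samples(x: ExpressionMatrix, y: ExpressionMatrix) -> list[str]:
    """Shared sample ids in x's order (drop-unpaired policy)."""
    common = [s for s in x.sample_ids if s in set(y.sample_ids)]
    if len(common) < 3:
        raise ValueError("fewer than 3 shared samples between the blocks")
    dropped = sorted(set(x.sample_ids) ^ set(y.sample_ids))
    if dropped:
        logger.info("dropping unpaired samples: %s", dropped)
    return common


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage, write outputs under ``config.out_dir``, return the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    manifest: dict = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "config_hash": chash,
        "seed": config.seed,
        "stages": {},
        "outputs": {},
    }

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            manifest["stages"][name] = {
                "seconds": round(time.perf_counter() - t0, 3),
                **(result or {}),
            }
            return result

        return deco

    # ---- load ---------------------------------------------------------------
    counts = read_expression_table(config.counts_path, kind="counts")
    intensities = read_expression_table(config.intensities_path, kind="intensities")
    design = read_design_table(config.design_path)
    annotation = read_annotation_table(config.annotation_path)
    design.validate_against(counts)
    design.validate_against(intensities)

    state: dict = {}

    @stage("deg")
    def _deg():
        factors = tmm_factors(counts)
        disp = estimate_common_dispersion(counts, design, factors)
        res = nb_exact_test(counts, design, factors, disp)
        res = call_differential(res, config.deg_fc, config.alpha)
        write_result_table(res, out / "deg.tsv", chash)
        state["deg"] = res
        state["factors"] = factors
        return {"rows": len(res), "significant": int(res["significant"].sum()),
                "common_dispersion": disp.common_dispersion}

    @stage("dep")
    def _dep():
        res = moderated_t(intensities, design)
        res = call_differential(res, config.dep_fc, config.alpha)
        write_result_table(res, out / "dep.tsv", chash)
        state["dep"] = res
        return {"rows": len(res), "significant": int(res["significant"].sum())}

    @stage("integrate")
    def _integrate():
        common = pair_samples(counts, intensities)
        x = log2_cpm(counts, state["factors"]).subset_samples(common)
        y = normalize_intensities(intensities).subset_samples(common)
        keep = [f for i, f in enumerate(y.feature_ids) if np.isfinite(y.values[:, i]).all()]
        if len(keep) < y.n_features:
            logger.info("dropping %d proteins with missing values before integration",
                        y.n_features - len(keep))
            y = y.subset_features(keep)
        if config.cv_grid is not None:
            sel = cross_validate(x.values, y.values, grid=config.cv_grid,
                                 k_folds=min(5, len(common)), seed=config.seed)
            n, nx, ny = sel.n_joint, sel.n_orth_x, sel.n_orth_y
            sel.cv_error.to_csv(out / "cv_error.tsv", sep="\t", index=False)
        else:
            n, nx, ny = config.n_joint, config.n_orth_x, config.n_orth_y
        model = O2PLS(n_joint=n, n_orth_x=nx, n_orth_y=ny).fit(x.values, y.values)
        model.save(out / "o2pls_model.npz")
        state.update(model=model, x_paired=x, y_paired=y)
        return {"samples": len(common), "n_joint": n, "n_orth_x": nx, "n_orth_y": ny,
                "joint_variance_x": model.variance_explained("X")["joint"],
                "joint_variance_y": model.variance_explained("Y")["joint"]}

    @stage("classify")
    def _classify():
        pairs = pair_features(state["x_paired"], state["y_paired"], annotation)
        table = classify_targets(
            state["model"], state["x_paired"], state["y_paired"], state["dep"],
            pairs, config.bait_id, alpha=config.alpha, fc_gate=config.dep_fc,
        )
        write_result_table(table, out / "targets.tsv", chash)
        state["targets"] = table
        return {"rows": len(table),
                "transcriptional": int((table["regulation_class"] == "transcriptional").sum())
                if len(table) else 0}

    @stage("substrates")
    def _substrates():
        cand = filter_candidates(state["targets"], annotation)
        write_result_table(cand, out / "substrates.tsv", chash)
        summary = topology_summary(cand)
        (out / "topology_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        state["candidates"] = cand
        return {"rows": len(cand)}

    if config.gmt_path:

        @stage("enrich")
        def _enrich():
            library = read_gmt(config.gmt_path)
            background = build_background(counts, design, config.background_min_total)
            deg_genes = set(state["deg"].loc[state["deg"]["significant"], "feature_id"])
            res = fisher_enrichment(deg_genes, library, background)
            write_result_table(res, out / "enrichment.tsv", chash)
            return {"rows": len(res),
                    "significant": int((res["qvalue"] < config.alpha).sum()) if len(res) else 0}

        @stage("overlap")
        def _overlap():
            deg_genes = set(state["deg"].loc[state["deg"]["significant"], "feature_id"])
            gene_of = annotation.gene_of()
            dep_genes = {
                gene_of.get(p) for p in
                state["dep"].loc[state["dep"]["significant"], "feature_id"]
            } - {None}
            ov = overlap_stats(deg_genes, dep_genes, config.genome_size)
            (out / "overlap.json").write_text(json.dumps(dataclasses.asdict(ov), indent=2))
            return {"overlap": ov.overlap, "representation_factor": ov.representation_factor,
                    "pvalue": ov.pvalue}

    for f in sorted(out.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest["outputs"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
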