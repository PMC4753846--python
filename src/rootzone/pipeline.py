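"""Orchestration of the full analysis: normalize -> activity -> patterns ->
differential expression -> enrichment -> diagnostics, with deterministic
artifacts and a run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from rootzone import activity, de, diagnostics, enrichment, normalization
from rootzone import io as rio
from rootzone import patterns as pat
from rootzone.simulate import CELL_LABELS

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and stage parameters of one pipeline run."""

    counts_path: str
    design_path: str
    covariates_path: str
    out_dir: str
    annotation_path: str | None = None
    trim_m: float = 0.30
    trim_a: float = 0.05
    smoother_span: float = 0.5
    target_rpm: float = 2.0
    min_count: int = 5
    fdr_cut: float = 0.01
    lfc_cut: float = 1.0
    enrich_fdr: float = 0.05
    top_k: int = 500
    seed: int = 0
    stages: tuple[str, ...] = field(
        default_factory=lambda: (
            "normalize", "activity", "patterns", "de", "enrich", "qc"
        )
    )

    def validate(self) -> None:
        for name, lo, hi in (
            ("trim_m", 0.0, 0.5), ("trim_a", 0.0, 0.5),
            ("smoother_span", 0.01, 1.0),
            ("fdr_cut", 0.0, 1.0), ("enrich_fdr", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.target_rpm <= 0:
            raise ValueError("target_rpm must be positive")
        if self.min_count < 0:
            raise ValueError("min_count must be >= 0")
        for path in (self.counts_path, self.design_path, self.covariates_path):
            if not Path(path).exists():
                raise FileNotFoundError(path)
        if self.annotation_path and not Path(self.annotation_path).exists():
            raise FileNotFoundError(self.annotation_path)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the enabled stages in order; returns the output directory.

    Re-running with an identical config reproduces byte-identical artifacts.
    Any stage failure aborts with the stage name and cause.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "stages": list(config.stages),
        "inputs": {
            "counts": _sha256(config.counts_path),
            "design": _sha256(config.design_path),
            "covariates": _sha256(config.covariates_path),
        },
        "parameters": {
            k: getattr(config, k)
            for k in (
                "trim_m", "trim_a", "smoother_span", "target_rpm",
                "min_count", "fdr_cut", "lfc_cut", "enrich_fdr", "top_k",
            )
        },
        "completed": [],
    }
    counts = rio.read_counts(config.counts_path)
    design = rio.read_design(config.design_path)
    covariates = rio.read_covariates(config.covariates_path)
    counts = counts[list(design["sample_id"])]

    offsets = calls = expr = results = None
    stage = "setup"
    try:
        if "normalize" in config.stages:
            stage = "normalize"
            offsets = normalization.normalize(
                counts, covariates,
                trim_m=config.trim_m, trim_a=config.trim_a,
                span=config.smoother_span,
            )
            rio.write_table(
                offsets.offsets.rename_axis("gene_id"),
                out / "offsets.tsv", "offsets",
            )
            rio.write_table(
                pd.DataFrame(
                    {"tmm_factor": offsets.tmm,
                     "library_size": offsets.library_sizes}
                ).rename_axis("sample_id"),
                out / "factors.tsv", "factors",
            )
        if "activity" in config.stages:
            stage = "activity"
            hyper = activity.estimate_hyperparameters(
                counts, design, offsets.offsets
            )
            threshold = activity.calibrate_threshold(
                hyper, target_rpm=config.target_rpm,
                library_size=float(offsets.library_sizes.mean()),
                n_replicates=int(design["replicate"].nunique()),
            )
            posteriors = activity.fit_posteriors(
                counts, design, offsets.offsets, hyper
            )
            posteriors["p_exceed"] = activity.p_exceed(posteriors, threshold)
            rio.write_table(
                posteriors.set_index("gene_id"),
                out / "posteriors.tsv", "posteriors",
            )
            calls = activity.call_activity(posteriors, threshold)
            rio.write_table(calls, out / "activity_calls.tsv", "activity_calls")
            manifest["threshold_T"] = threshold
        if "patterns" in config.stages:
            stage = "patterns"
            if calls is None:
                raise RuntimeError("patterns stage requires activity calls")
            pats = pat.patterns_from_calls(calls)
            rio.write_table(
                pat.patterns_frame(pats), out / "patterns.tsv", "patterns"
            )
            summary = pat.tabulate_patterns(pats)
            rows = []
            for name, series in summary.items():
                for key, value in series.items():
                    rows.append((name, str(key), value))
            rio.write_table(
                pd.DataFrame(rows, columns=["table", "key", "value"])
                .set_index("table"),
                out / "pattern_summary.tsv", "pattern_summary",
            )
        if "de" in config.stages:
            stage = "de"
            kept = de.filter_low_counts(counts, design, config.min_count)
            eff_lib = (
                offsets.library_sizes.to_numpy() * offsets.tmm.to_numpy()
                if offsets is not None else None
            )
            expr = de.transform_and_weight(
                counts.loc[kept], design, effective_library_sizes=eff_lib
            )
            rho = de.estimate_block_correlation(expr, design)
            fits = de.fit_contrasts(expr, design, rho)
            results = de.moderate_and_test(fits)
            selection = de.select_responsive(
                results, fdr_cut=config.fdr_cut, lfc_cut=config.lfc_cut
            )
            rio.write_table(
                selection["results"].set_index("gene_id"),
                out / "de_results.tsv", "de_results",
            )
            overlap_rows = [
                ("rho", "lane_correlation", rho),
                ("n_multi_tissue", "", selection["n_multi_tissue"]),
                ("n_direction_consistent", "",
                 selection["n_direction_consistent"]),
                ("n_all_tissues", "", selection["n_all_tissues"]),
                ("n_any", "", selection["n_any"]),
            ] + [
                ("per_tissue", t, len(s))
                for t, s in selection["per_tissue"].items()
            ] + [
                ("up", t, ud[0]) for t, ud in selection["up_down"].items()
            ] + [
                ("down", t, ud[1]) for t, ud in selection["up_down"].items()
            ]
            rio.write_table(
                pd.DataFrame(overlap_rows, columns=["table", "key", "value"])
                .set_index("table"),
                out / "de_summary.tsv", "de_summary",
            )
        if "enrich" in config.stages and config.annotation_path:
            stage = "enrich"
            if results is None:
                raise RuntimeError("enrich stage requires DE results")
            annotation = rio.read_annotation(config.annotation_path)
            selection = de.select_responsive(
                results, fdr_cut=config.fdr_cut, lfc_cut=config.lfc_cut
            )
            background = set(results["gene_id"])
            for system, table in annotation.groupby("system"):
                de_set = set().union(*selection["per_tissue"].values())
                if not de_set:
                    logger.info("no responsive genes; skipping enrichment "
                                "for system %s", system)
                    continue
                enr = enrichment.fisher_enrichment(
                    de_set, background, table, fdr_cut=config.enrich_fdr
                )
                rio.write_table(
                    enr.set_index("category"),
                    out / f"enrichment_{system}.tsv", "enrichment",
                )
        if "qc" in config.stages:
            stage = "qc"
            if expr is None:
                kept = de.filter_low_counts(counts, design, config.min_count)
                expr = de.transform_and_weight(counts.loc[kept], design)
            distances = diagnostics.sample_distances(
                expr.logged, top_k=config.top_k
            )
            rio.write_table(
                distances.rename_axis("sample_id"),
                out / "sample_distances.tsv", "distances",
            )
            (out / "sample_tree.nwk").write_text(
                diagnostics.cluster_tree(distances) + "\n"
            )
            rio.write_table(
                diagnostics.mds_embedding(distances).rename_axis("sample_id"),
                out / "mds.tsv", "mds",
            )
    except Exception as exc:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=float, sort_keys=True) + "\n"
        )
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    else:
        manifest["completed"] = [
            s for s in config.stages
            if s != "enrich" or config.annotation_path
        ]
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=float, sort_keys=True) + "\n"
        )
    return out
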