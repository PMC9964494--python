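"""End-to-end analysis orchestration.

The full pipeline, mirroring the study design it re-implements:

1. per-subject global and nodal metrics (small-world sigma against
   degree-preserving random references),
2. covariate-controlled permutation group comparison — the global family
   FDR-corrected over its 4 metrics, each nodal metric over the 116 nodes,
3. logistic/ROC classification of group from each global metric with
   label-permutation AUROC significance,
4. Pearson correlations of metrics with clinical scores (PDSS, HAMD,
   illness duration) within the patient group,

with every stage's table written as CSV and a JSON run-metadata file
recording the seed and configuration.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .io import Cohort, read_labels, read_manifest
from .metrics import GLOBAL_METRIC_NAMES, NODAL_METRIC_NAMES, cohort_metrics
from .nullmodels import NullModelConfig
from .roc import roc_analysis
from .stats import compare_groups, pearson_correlation

__all__ = [
    "AnalysisConfig",
    "ReportBundle",
    "run_analysis",
    "write_report",
    "global_group_comparison",
    "nodal_group_comparison",
    "roc_table",
    "clinical_correlations",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisConfig:
    """Pipeline settings; defaults follow the anchor study's analysis plan
    (10,000 group-comparison permutations, 1000 ROC permutations, FDR 0.05)."""

    n_perm_group: int = 10_000
    n_perm_roc: int = 1000
    n_random_networks: int = 100
    n_swaps_per_edge: int = 10
    fdr_alpha: float = 0.05
    seed: int = 0
    significant_only: bool = True  # nodal report: keep q < alpha rows only

    def __post_init__(self) -> None:
        if min(self.n_perm_group, self.n_perm_roc, self.n_random_networks) < 1:
            raise ValueError("all counts must be >= 1")
        if not 0 < self.fdr_alpha < 1:
            raise ValueError("fdr_alpha must be in (0, 1)")


@dataclass(frozen=True)
class ReportBundle:
    global_metrics: pd.DataFrame
    nodal_metrics: pd.DataFrame
    global_comparison: pd.DataFrame
    nodal_comparisons: dict[str, pd.DataFrame]
    roc_table: pd.DataFrame
    correlations: pd.DataFrame
    metadata: dict = field(repr=False)


def clinical_correlations(
    global_metrics: pd.DataFrame,
    metrics=GLOBAL_METRIC_NAMES,
    scores=("pdss", "hamd", "duration_months"),
) -> pd.DataFrame:
    """Pearson r of each metric against each clinical score in the PD group.

    Score columns that are missing, constant, or observed on fewer than 3
    patients are skipped.
    """
    pd_df = global_metrics[global_metrics["group"] == "PD"]
    rows = []
    for metric in metrics:
        for score in scores:
            if score not in pd_df.columns or metric not in pd_df.columns:
                continue
            vals = pd_df[[metric, score]].dropna()
            if len(vals) < 3 or vals[score].std() == 0 or vals[metric].std() == 0:
                continue
            r, p = pearson_correlation(vals[metric].to_numpy(), vals[score].to_numpy())
            rows.append({"metric": metric, "score": score, "r": r, "p": p})
    return pd.DataFrame(rows, columns=["metric", "score", "r", "p"])


def _results_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "metric": [r.metric_name for r in results],
            "pd_mean": [r.mean_pd for r in results],
            "pd_sd": [r.sd_pd for r in results],
            "hc_mean": [r.mean_hc for r in results],
            "hc_sd": [r.sd_hc for r in results],
            "t": [r.observed_t for r in results],
            "p_perm": [r.p_perm for r in results],
            "p_fdr": [r.p_fdr for r in results],
        }
    )


def global_group_comparison(
    glob_df: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int = 0,
    metrics=GLOBAL_METRIC_NAMES,
) -> pd.DataFrame:
    """Permutation comparison of the global metric family (FDR over the 4)."""
    metrics = [m for m in metrics if m in glob_df.columns and glob_df[m].notna().all()]
    results = compare_groups(glob_df, metrics, n_perm=n_perm, seed=seed)
    return _results_frame(results)


def nodal_group_comparison(
    nodal_df: pd.DataFrame,
    metric: str,
    n_perm: int = 10_000,
    seed: int = 0,
    fdr_alpha: float = 0.05,
    significant_only: bool = True,
) -> pd.DataFrame:
    """Permutation comparison of one nodal metric across all nodes (FDR over
    the 116-node family); rows in atlas order, optionally q < alpha only."""
    regions = list(dict.fromkeys(nodal_df["region"]))  # atlas order
    wide = nodal_df.pivot_table(
        index="subject_id", columns="region", values=metric, sort=False
    )
    meta = (
        nodal_df[["subject_id", "group", "age", "gender_code"]]
        .drop_duplicates()
        .set_index("subject_id")
    )
    table = meta.join(wide).reset_index()
    results = compare_groups(table, regions, n_perm=n_perm, seed=seed)
    frame = _results_frame(results).rename(columns={"metric": "region"})
    if significant_only:
        frame = frame[frame["p_fdr"] < fdr_alpha]
    return frame.reset_index(drop=True)


def roc_table(
    glob_df: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    metrics=GLOBAL_METRIC_NAMES,
) -> pd.DataFrame:
    """One logistic/ROC model per global metric (age and gender controlled)."""
    y = (glob_df["group"] == "PD").to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for metric in metrics:
        if metric not in glob_df.columns or glob_df[metric].isna().any():
            continue
        res = roc_analysis(
            metric,
            glob_df[metric].to_numpy(dtype=float),
            glob_df["age"].to_numpy(dtype=float),
            glob_df["gender_code"].to_numpy(dtype=float),
            y,
            n_perm=n_perm,
            seed=int(rng.integers(2**31)),
        )
        rows.append(
            {
                "metric": metric,
                "auroc": res.auroc,
                "p_perm": res.p_perm,
                "threshold": res.threshold,
                "sensitivity": res.sensitivity,
                "specificity": res.specificity,
            }
        )
    return pd.DataFrame(rows)


def run_analysis(
    manifest: str | os.PathLike | None = None,
    labels_path: str | os.PathLike | None = None,
    cfg: AnalysisConfig | None = None,
    cohort: Cohort | None = None,
    out_dir: str | os.PathLike | None = None,
) -> ReportBundle:
    """Run the full analysis on a cohort (from *manifest* + *labels_path*, or
    passed directly) and optionally write the report CSVs to *out_dir*.

    Deterministic given ``cfg.seed``: metric computation, every permutation
    stream and the null-network ensembles all derive from it.
    """
    cfg = cfg or AnalysisConfig()
    if cohort is None:
        if manifest is None or labels_path is None:
            raise ValueError("either a cohort or manifest + labels paths are required")
        cohort = read_manifest(manifest, read_labels(labels_path))
    for grp in ("PD", "HC"):
        if not cohort.group(grp):
            raise ValueError(f"cohort has no {grp} subjects")

    rng = np.random.default_rng(cfg.seed)
    null_cfg = NullModelConfig(
        n_random=cfg.n_random_networks,
        n_swaps_per_edge=cfg.n_swaps_per_edge,
        seed=int(rng.integers(2**31)),
    )
    logger.info("stage 1/4: per-subject metrics (%d subjects)", len(cohort))
    glob_df, nodal_df = cohort_metrics(cohort, null_cfg)

    logger.info("stage 2/4: group comparison (%d permutations)", cfg.n_perm_group)
    global_tbl = global_group_comparison(
        glob_df, n_perm=cfg.n_perm_group, seed=int(rng.integers(2**31))
    )
    nodal_tables = {
        metric: nodal_group_comparison(
            nodal_df,
            metric,
            n_perm=cfg.n_perm_group,
            seed=int(rng.integers(2**31)),
            fdr_alpha=cfg.fdr_alpha,
            significant_only=cfg.significant_only,
        )
        for metric in NODAL_METRIC_NAMES
    }

    logger.info("stage 3/4: ROC models (%d permutations)", cfg.n_perm_roc)
    roc_tbl = roc_table(glob_df, n_perm=cfg.n_perm_roc, seed=int(rng.integers(2**31)))

    logger.info("stage 4/4: clinical correlations")
    corr_tbl = clinical_correlations(glob_df)

    metadata = {
        "package_version": __version__,
        "config": asdict(cfg),
        "n_subjects": len(cohort),
        "n_pd": len(cohort.group("PD")),
        "n_hc": len(cohort.group("HC")),
        "n_nodes": len(cohort.labels),
    }
    bundle = ReportBundle(
        global_metrics=glob_df,
        nodal_metrics=nodal_df,
        global_comparison=global_tbl,
        nodal_comparisons=nodal_tables,
        roc_table=roc_tbl,
        correlations=corr_tbl,
        metadata=metadata,
    )
    if out_dir is not None:
        write_report(bundle, out_dir)
    return bundle


def write_report(bundle: ReportBundle, out_dir: str | os.PathLike) -> None:
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    bundle.global_metrics.to_csv(os.path.join(out_dir, "global_metrics.csv"), index=False)
    bundle.nodal_metrics.to_csv(os.path.join(out_dir, "nodal_metrics.csv"), index=False)
    bundle.global_comparison.to_csv(
        os.path.join(out_dir, "global_comparison.csv"), index=False
    )
    for metric, tbl in bundle.nodal_comparisons.items():
        tbl.to_csv(os.path.join(out_dir, f"nodal_comparison_{metric}.csv"), index=False)
    bundle.roc_table.to_csv(os.path.join(out_dir, "roc.csv"), index=False)
    bundle.correlations.to_csv(os.path.join(out_dir, "correlations.csv"), index=False)
    with open(os.path.join(out_dir, "run_metadata.json"), "w") as fh:
        json.dump(bundle.metadata, fh, indent=2)
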