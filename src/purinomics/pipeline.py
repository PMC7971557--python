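"""End-to-end metabolomics run: z-scoring through supercluster ranking.

``run_pipeline`` takes a MetaboliteMatrix and an AnalysisConfig and writes
a result bundle to disk: per-metabolite statistics, the pathway-impact
ranking, the supercluster report, a JSON summary, and a run log echoing
the configuration.  Every stage is deterministic given the config seeds;
failures abort with the stage name and cause.  No samples or metabolites
are silently dropped — counts are logged at each stage.
"""

from __future__ import annotations

import json
import logging
from contextlib import contextmanager
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .io import AnalysisConfig, MetaboliteMatrix
from .multivariate import ensemble_mda, pca_variance_explained, plsda_fit
from .pathways import (aggregate_pathway_vip, count_changed, knn_superclusters,
                       rank_clusters)
from .preprocess import control_zscore
from .univariate import significance_filter, univariate_table

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"  # 6 significant digits keeps regression outputs byte-stable


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@contextmanager
def _stage(name: str):
    logger.info("stage %s", name)
    try:
        yield
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - rewrap with stage context
        raise PipelineError(name, exc) from exc


@dataclass
class PipelineResult:
    """In-memory bundle mirroring the files written by run_pipeline."""

    stats: pd.DataFrame
    pathway_ranking: pd.DataFrame
    cluster_report: pd.DataFrame
    clusters: pd.Series
    summary: dict


def run_pipeline(
    matrix: MetaboliteMatrix,
    config: AnalysisConfig,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full metabolomics analysis and write the result bundle.

    Stages: control z-scoring; per-metabolite univariate statistics;
    PLSDA + VIP; bagged-tree MDA; significance filter; pathway VIP
    ranking; k-NN superclusters with impact ranking.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    with _stage("preprocess"):
        zmat = control_zscore(matrix, config.control_group)
        logger.info("z-scored %d samples x %d metabolites (%d excluded)",
                    *zmat.z.shape, len(zmat.excluded))
    with _stage("univariate"):
        stats = univariate_table(zmat)
    with _stage("plsda"):
        model = plsda_fit(zmat, zmat.groups, n_components=config.n_components)
        vip = model.vip
        pca_frac, _ = pca_variance_explained(zmat)
    with _stage("mda"):
        importance = ensemble_mda(zmat, zmat.groups, n_trees=config.n_trees,
                                  seed=config.seed)
    with _stage("significance_filter"):
        mask, n_sig, frac = significance_filter(
            stats, vip, fdr_max=config.fdr_max, vip_min=config.vip_min,
            p_max=config.p_max,
        )
        stats = stats.assign(vip=vip.reindex(stats.index),
                             mda=importance.mda.reindex(stats.index),
                             pathway=matrix.pathways.reindex(stats.index),
                             significant=mask)
        count, percent = count_changed(n_sig, len(stats))
        logger.info("%d (%d%%) of %d metabolites significant",
                    count, percent, len(stats))
    with _stage("pathway_ranking"):
        ranking = aggregate_pathway_vip(
            stats.index[mask], vip, matrix.pathways, mean_z=stats["mean_z"]
        )
    with _stage("superclusters"):
        clusters = knn_superclusters(
            zmat, k_neighbors=config.knn_k, n_clusters=config.n_clusters,
            seed=config.seed,
        )
        report = rank_clusters(clusters, vip, importance.mda,
                               vip_threshold=config.cluster_vip_threshold)
        mean_sd = {
            cid: _cluster_mean_sd(zmat, clusters, cid)
            for cid in report["cluster"]
        }
        report["mean_z"] = [mean_sd[c][0] for c in report["cluster"]]
        report["sd_z"] = [mean_sd[c][1] for c in report["cluster"]]
    summary = {
        "version": __version__,
        "config": config.to_dict(),
        "n_samples": int(matrix.auc.shape[0]),
        "n_metabolites": int(matrix.auc.shape[1]),
        "n_excluded_zero_sd": len(zmat.excluded),
        "n_significant": count,
        "percent_significant": percent,
        "pca_variance_pc1_pct": float(100 * pca_frac[0]),
        "plsda_explained_y": [float(v) for v in model.explained_y],
        "top_pathways": ranking["pathway"].head(5).tolist(),
        "top2_cluster_impact": float(
            report.sort_values("rank")["impact_fraction"].head(2).sum()
        ),
    }
    with _stage("write"):
        out.mkdir(parents=True, exist_ok=True)
        stats.to_csv(out / "metabolite_stats.tsv", sep="\t",
                     float_format=FLOAT_FORMAT)
        ranking.to_csv(out / "pathway_ranking.tsv", sep="\t", index=False,
                       float_format=FLOAT_FORMAT)
        report.to_csv(out / "cluster_report.tsv", sep="\t", index=False,
                      float_format=FLOAT_FORMAT)
        clusters.rename("supercluster").to_csv(out / "cluster_members.tsv",
                                               sep="\t")
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        (out / "run_log.txt").write_text(
            f"purinomics {__version__}\nconfig: {json.dumps(config.to_dict())}\n"
            f"samples: {summary['n_samples']} metabolites: "
            f"{summary['n_metabolites']}\n"
            f"significant: {count} ({percent}%)\n"
        )
    return PipelineResult(stats=stats, pathway_ranking=ranking,
                          cluster_report=report, clusters=clusters,
                          summary=summary)


def _cluster_mean_sd(zmat, clusters: pd.Series, cid) -> tuple[float, float]:
    from .pathways import cluster_summary

    return cluster_summary(clusters.index[clusters == cid], zmat)
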