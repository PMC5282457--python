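"""End-to-end orchestration: reads (or a count table) in, reports out.

The pipeline composes the stage functions with structured logging and a
run manifest, so a full analysis is one call.  Entry points:

* per-round read files (FASTA/FASTQ) -> filter/extract -> unique-count
  table -> clustering -> trajectories, or
* a pre-tabulated unique-sequence count table (one count column per
  round), skipping the read-level stages.

Re-running with the same inputs and seed reproduces outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Mapping, Optional

import pandas as pd

from . import __version__
from .clustering import (
    ClusterParams,
    ClusterResult,
    cluster_pool,
    cluster_table,
    read_count_table,
    tabulate_uniques,
    write_count_table,
)
from .enrichment import EnrichmentTrajectory, abundance_trajectory
from .read_processing import FilterReport, filter_and_extract
from .seqio import LibraryDesign, read_sequences

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger("aptapool")


@dataclass
class PipelineConfig:
    """Inputs and parameters for one pipeline run.

    Exactly one of ``reads_by_round`` (round label -> FASTA/FASTQ path) or
    ``count_table`` (path to a tabulated unique-sequence table) must be set.
    """

    reads_by_round: Optional[Mapping[str, str]] = None
    count_table: Optional[str] = None
    design: LibraryDesign = field(default_factory=LibraryDesign)
    cluster_params: ClusterParams = field(default_factory=ClusterParams)
    max_flank_mismatch: int = 0
    outdir: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.reads_by_round is None) == (self.count_table is None):
            raise ValueError("set exactly one of reads_by_round or count_table")


@dataclass
class PipelineResult:
    manifest: dict
    filter_reports: dict[str, FilterReport]
    cluster_result: ClusterResult
    trajectory: EnrichmentTrajectory


def _digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_trajectory_tables(traj: EnrichmentTrajectory, outdir: str, params_line: str) -> None:
    def dump(df: pd.DataFrame, name: str, index_label: str) -> None:
        path = os.path.join(outdir, name)
        with open(path, "w") as fh:
            fh.write(f"# {params_line}\n")
            df.round(1).to_csv(fh, sep="\t", index_label=index_label)

    dump(traj.cluster_percent, "trajectory_cluster_percent.tsv", "cluster_id")
    dump(traj.centroid_percent, "trajectory_centroid_percent.tsv", "cluster_id")
    summary = pd.DataFrame(
        {
            "total_reads": traj.round_totals.astype(int),
            "enrichment_percent": traj.enrichment_percent,
            "ambiguous_percent": traj.ambiguous_percent,
        }
    )
    dump(summary, "round_summary.tsv", "round")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and (optionally) write all tables under ``outdir``.

    Stage counts are logged and conservation is asserted at each hand-off:
    reads in = passed + rejected; uniques in = clustered + ambiguous.
    """
    manifest: dict = {
        "tool": "aptapool",
        "version": __version__,
        "seed": config.seed,
        "design": {
            "left_constant": config.design.left_constant,
            "right_constant": config.design.right_constant,
            "vr_min": config.design.vr_min,
            "vr_max": config.design.vr_max,
            "min_read_length": config.design.min_read_length,
        },
        "cluster_params": {
            "radius": config.cluster_params.radius,
            "max_assignment_distance": config.cluster_params.max_assignment_distance,
        },
        "inputs": {},
        "stages": {},
    }
    filter_reports: dict[str, FilterReport] = {}

    if config.reads_by_round is not None:
        vr_by_round: dict[str, list[str]] = {}
        for label, path in config.reads_by_round.items():
            manifest["inputs"][label] = {"path": path, "sha256": _digest(path)}
            accepted, report = filter_and_extract(
                read_sequences(path), config.design, config.max_flank_mismatch
            )
            assert report.balanced, "filter report does not balance"
            filter_reports[label] = report
            vr_by_round[label] = [r.vr for r in accepted]
            logger.info(
                "round %s: %d reads, %d passed, %d rejected",
                label, report.total, report.passed, report.total - report.passed,
            )
        uniques = tabulate_uniques(vr_by_round)
    else:
        manifest["inputs"]["count_table"] = {
            "path": config.count_table,
            "sha256": _digest(config.count_table),
        }
        uniques = read_count_table(config.count_table)
        logger.info("count table: %d unique sequences", len(uniques))

    manifest["stages"]["unique_sequences"] = len(uniques)

    result = cluster_pool(uniques, config.cluster_params)
    n_clustered = sum(1 + len(c.members) for c in result.clusters)
    assert n_clustered + len(result.ambiguous) == len(uniques), "clustering lost sequences"
    manifest["stages"]["clusters"] = len(result.clusters)
    manifest["stages"]["ambiguous"] = len(result.ambiguous)
    logger.info(
        "clustering: %d clusters, %d ambiguous of %d uniques",
        len(result.clusters), len(result.ambiguous), len(uniques),
    )

    traj = abundance_trajectory(result)
    manifest["stages"]["rounds"] = traj.round_labels
    manifest["filter_reports"] = {
        label: {"total": r.total, "passed": r.passed, **{f"rejected_{k}": v for k, v in r.rejected.items()}}
        for label, r in filter_reports.items()
    }

    if config.outdir is not None:
        os.makedirs(config.outdir, exist_ok=True)
        params_line = (
            f"aptapool {__version__} radius={config.cluster_params.radius} "
            f"max_flank_mismatch={config.max_flank_mismatch} seed={config.seed}"
        )
        write_count_table(
            os.path.join(config.outdir, "unique_counts.tsv"), uniques, params_line
        )
        with open(os.path.join(config.outdir, "clusters.tsv"), "w") as fh:
            fh.write(f"# {params_line}\n")
            cluster_table(result).to_csv(fh, sep="\t", index=False)
        for label, report in filter_reports.items():
            with open(os.path.join(config.outdir, f"filter_report_{label}.tsv"), "w") as fh:
                fh.write(report.to_tsv())
        _write_trajectory_tables(traj, config.outdir, params_line)
        with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")

    return PipelineResult(
        manifest=manifest,
        filter_reports=filter_reports,
        cluster_result=result,
        trajectory=traj,
    )
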