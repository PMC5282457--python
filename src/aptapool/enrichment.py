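"""Round-enrichment and per-cluster abundance statistics.

The pool enrichment of one selection round measures the collapse of
sequence diversity under selection::

    enrichment% = (1 - unique sequences / total reads) * 100

A fully diverse pool (every read distinct) scores 0; a pool taken over by
one sequence approaches 100.  Per-cluster abundance trajectories report the
percent of each round's reads that fall in each cluster, in two variants:
cluster-inclusive (centroid + members, the default headline) and
centroid-exact (the centroid sequence's own reads only).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .clustering import Cluster, ClusterResult

__all__ = [
    "RoundPool",
    "MotifSpan",
    "EnrichmentTrajectory",
    "round_enrichment",
    "abundance_trajectory",
    "mutation_profile",
    "motif_conservation",
]


@dataclass(frozen=True)
class RoundPool:
    """Summary of one sequenced round: read total and distinct-VR count."""

    round_label: str
    total_reads: int
    unique_count: int

    def __post_init__(self) -> None:
        if self.total_reads < 0 or self.unique_count < 0:
            raise ValueError("counts must be non-negative")
        if self.unique_count > self.total_reads:
            raise ValueError("unique_count cannot exceed total_reads")

    @staticmethod
    def from_vr_counts(round_label: str, counts: Sequence[int]) -> "RoundPool":
        present = [c for c in counts if c > 0]
        return RoundPool(round_label, total_reads=sum(present), unique_count=len(present))


@dataclass(frozen=True)
class MotifSpan:
    """Half-open interval marking the conserved motif within a centroid VR."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start <= self.end):
            raise ValueError("require 0 <= start <= end")

    def __contains__(self, position: int) -> bool:
        return self.start <= position < self.end


def round_enrichment(pool: RoundPool) -> float:
    """Percent enrichment of a round: (1 - unique/total) * 100, in [0, 100)."""
    if pool.total_reads == 0:
        raise ValueError(f"round {pool.round_label!r} has zero reads; enrichment undefined")
    return (1.0 - pool.unique_count / pool.total_reads) * 100.0


@dataclass
class EnrichmentTrajectory:
    """Per-round enrichment and per-cluster abundance percentages.

    ``cluster_percent`` and ``centroid_percent`` are DataFrames with one row
    per cluster and one column per round; ``ambiguous_percent`` is a Series
    over rounds.  Per round, cluster-inclusive percentages plus the
    ambiguous percentage sum to 100 (NaN for rounds with zero reads).
    """

    round_labels: list[str]
    round_totals: pd.Series
    enrichment_percent: pd.Series
    cluster_percent: pd.DataFrame
    centroid_percent: pd.DataFrame
    ambiguous_percent: pd.Series


def _round_labels_of(result: ClusterResult) -> list[str]:
    labels: list[str] = []
    for seq in result.all_sequences():
        for lab, _ in seq.counts:
            if lab not in labels:
                labels.append(lab)
    return labels


def abundance_trajectory(
    result: ClusterResult,
    round_labels: Optional[Sequence[str]] = None,
) -> EnrichmentTrajectory:
    """Compute enrichment and abundance percentages from a clustering.

    Round totals are the summed counts of every sequence in the result
    (clusters plus ambiguous), i.e. all reads that survived filtering.
    Rounds with zero total reads get NaN percentages.
    """
    labels = list(round_labels) if round_labels is not None else _round_labels_of(result)
    n_rounds = len(labels)

    def counts_vector(seqs) -> np.ndarray:
        v = np.zeros(n_rounds)
        for seq in seqs:
            cm = seq.count_map
            for j, lab in enumerate(labels):
                v[j] += cm.get(lab, 0)
        return v

    cluster_counts = np.array(
        [counts_vector(cl.sequences) for cl in result.clusters]
    ).reshape(len(result.clusters), n_rounds)
    centroid_counts = np.array(
        [counts_vector([cl.centroid]) for cl in result.clusters]
    ).reshape(len(result.clusters), n_rounds)
    ambiguous_counts = counts_vector([e.sequence for e in result.ambiguous])

    totals = cluster_counts.sum(axis=0) + ambiguous_counts
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.where(totals > 0, totals, np.nan)
        cluster_pct = 100.0 * cluster_counts / denom
        centroid_pct = 100.0 * centroid_counts / denom
        ambiguous_pct = 100.0 * ambiguous_counts / denom

    enrichment = pd.Series(
        [
            round_enrichment(
                RoundPool.from_vr_counts(
                    lab,
                    [seq.count_map.get(lab, 0) for seq in result.all_sequences()],
                )
            )
            if totals[j] > 0
            else math.nan
            for j, lab in enumerate(labels)
        ],
        index=labels,
        name="enrichment_percent",
    )
    cluster_ids = list(range(len(result.clusters)))
    return EnrichmentTrajectory(
        round_labels=labels,
        round_totals=pd.Series(totals, index=labels, name="total_reads"),
        enrichment_percent=enrichment,
        cluster_percent=pd.DataFrame(cluster_pct, index=cluster_ids, columns=labels),
        centroid_percent=pd.DataFrame(centroid_pct, index=cluster_ids, columns=labels),
        ambiguous_percent=pd.Series(ambiguous_pct, index=labels, name="ambiguous_percent"),
    )


def mutation_profile(cluster: Cluster) -> tuple[np.ndarray, int]:
    """Per-position mismatch tally of members against their centroid.

    Entry ``i`` counts members whose base at position ``i`` differs from the
    centroid's.  Members whose length differs from the centroid's are
    excluded (indel placement is alignment-dependent) and their number is
    returned alongside the profile.
    """
    centroid = cluster.centroid.vr
    profile = np.zeros(len(centroid), dtype=np.int64)
    excluded = 0
    for member, _ in cluster.members:
        if len(member.vr) != len(centroid):
            excluded += 1
            continue
        for i, (x, y) in enumerate(zip(centroid, member.vr)):
            if x != y:
                profile[i] += 1
    return profile, excluded


def motif_conservation(cluster: Cluster, motif: MotifSpan) -> tuple[int, int]:
    """Split the cluster's mutation mass by position relative to the motif.

    Returns (in_motif_mismatches, out_motif_mismatches); a conserved motif
    has zero in-motif mismatches.
    """
    centroid_len = len(cluster.centroid.vr)
    if motif.end > centroid_len:
        raise ValueError(
            f"motif span [{motif.start}, {motif.end}) exceeds centroid length {centroid_len}"
        )
    profile, _ = mutation_profile(cluster)
    inside = int(profile[motif.start : motif.end].sum())
    return inside, int(profile.sum()) - inside
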