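"""Greedy mismatch-radius clustering of unique aptamer variable regions.

The pooled, deduplicated variable regions from all selection rounds are
clustered by a greedy centroid rule: walking the unique sequences in
descending total read count (count ties broken lexicographically), a
sequence becomes a new centroid iff it is more than ``radius`` mismatches
away from every previously chosen centroid.  Remaining sequences join the
cluster of their unique nearest centroid; sequences equidistant from two or
more centroids are "ambiguous" and belong to no cluster.

Distance is Hamming (number of mismatches) for equal-length sequences and
Levenshtein edit distance otherwise — the filter admits 38-42 nt regions,
so unequal lengths do occur.  Internally equal-length comparisons are
vectorised with numpy for speed; the scalar ``sequence_distance`` defines
the semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import edlib
import numpy as np
import pandas as pd

__all__ = [
    "UniqueSequence",
    "ClusterParams",
    "Cluster",
    "AmbiguousEntry",
    "ClusterResult",
    "sequence_distance",
    "pick_centroids",
    "assign_members",
    "cluster_pool",
    "tabulate_uniques",
    "read_count_table",
    "write_count_table",
    "cluster_table",
]


@dataclass(frozen=True)
class UniqueSequence:
    """A deduplicated variable region with per-round read counts."""

    vr: str
    counts: tuple[tuple[str, int], ...]  # (round_label, count), insertion order

    @staticmethod
    def from_counts(vr: str, counts: Mapping[str, int]) -> "UniqueSequence":
        return UniqueSequence(vr=vr, counts=tuple(counts.items()))

    @property
    def count_map(self) -> dict[str, int]:
        return dict(self.counts)

    @property
    def total_count(self) -> int:
        return sum(c for _, c in self.counts)


@dataclass(frozen=True)
class ClusterParams:
    radius: int = 4
    max_assignment_distance: Optional[int] = None

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("radius must be >= 0")
        if self.max_assignment_distance is not None and self.max_assignment_distance < 0:
            raise ValueError("max_assignment_distance must be >= 0")


@dataclass
class Cluster:
    centroid: UniqueSequence
    members: list[tuple[UniqueSequence, int]] = field(default_factory=list)

    @property
    def sequences(self) -> list[UniqueSequence]:
        return [self.centroid] + [m for m, _ in self.members]

    def round_counts(self) -> dict[str, int]:
        totals: dict[str, int] = {}
        for seq in self.sequences:
            for label, c in seq.counts:
                totals[label] = totals.get(label, 0) + c
        return totals


@dataclass
class AmbiguousEntry:
    sequence: UniqueSequence
    tied_centroids: tuple[int, ...]  # indices into ClusterResult.clusters
    reason: str  # "tie" | "too_far"


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    ambiguous: list[AmbiguousEntry]
    params: ClusterParams

    @property
    def centroids(self) -> list[UniqueSequence]:
        return [c.centroid for c in self.clusters]

    def all_sequences(self) -> list[UniqueSequence]:
        out: list[UniqueSequence] = []
        for c in self.clusters:
            out.extend(c.sequences)
        out.extend(e.sequence for e in self.ambiguous)
        return out


def sequence_distance(a: str, b: str) -> int:
    """Mismatch count between two sequences.

    Hamming distance when lengths agree (the number of mismatching
    positions); Levenshtein edit distance otherwise.  Symmetric, and zero
    iff the sequences are equal.
    """
    if not a or not b:
        raise ValueError("sequence_distance requires non-empty sequences")
    if len(a) == len(b):
        return sum(x != y for x, y in zip(a, b))
    return edlib.align(a, b, task="distance")["editDistance"]


def _ranked(uniques: Sequence[UniqueSequence]) -> list[UniqueSequence]:
    return sorted(uniques, key=lambda u: (-u.total_count, u.vr))


def _encode(seqs: Sequence[str]) -> np.ndarray:
    return np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8).reshape(len(seqs), -1)


class _DistanceIndex:
    """Distances from query sequences to a growing/fixed set of targets.

    Equal-length blocks go through a numpy mismatch count; unequal lengths
    fall back to edlib edit distance one pair at a time.
    """

    def __init__(self, targets: Sequence[str]):
        self.targets = list(targets)
        self._by_len: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        lengths = np.array([len(t) for t in self.targets])
        for L in np.unique(lengths):
            idx = np.nonzero(lengths == L)[0]
            self._by_len[int(L)] = (idx, _encode([self.targets[i] for i in idx]))

    def distances(self, query: str) -> np.ndarray:
        out = np.empty(len(self.targets), dtype=np.int64)
        q = len(query)
        for L, (idx, mat) in self._by_len.items():
            if L == q:
                qv = np.frombuffer(query.encode("ascii"), dtype=np.uint8)
                out[idx] = (mat != qv).sum(axis=1)
            else:
                for i in idx:
                    out[i] = edlib.align(query, self.targets[i], task="distance")["editDistance"]
        return out


def pick_centroids(uniques: Sequence[UniqueSequence], params: ClusterParams) -> list[UniqueSequence]:
    """Greedy centroid selection in descending total-count order.

    A sequence is adopted as a centroid iff its distance to every previously
    adopted centroid exceeds ``params.radius`` ("within radius" blocks,
    inclusively).  Returns centroids in adoption order.
    """
    centroids: list[UniqueSequence] = []
    cent_seqs: list[str] = []
    for u in _ranked(uniques):
        if all(sequence_distance(u.vr, c) > params.radius for c in cent_seqs):
            centroids.append(u)
            cent_seqs.append(u.vr)
    return centroids


def assign_members(
    uniques: Sequence[UniqueSequence],
    centroids: Sequence[UniqueSequence],
    params: ClusterParams,
) -> ClusterResult:
    """Assign every non-centroid sequence to its unique nearest centroid.

    Ties for nearest centroid make a sequence ambiguous (all tied indices
    recorded).  When ``max_assignment_distance`` is set, sequences farther
    than it from every centroid are also set aside, flagged ``"too_far"``.
    Member order within a cluster follows the global count/lexicographic
    ranking, so results are independent of input order.
    """
    clusters = [Cluster(centroid=c) for c in centroids]
    ambiguous: list[AmbiguousEntry] = []
    centroid_vrs = {c.vr for c in centroids}
    index = _DistanceIndex([c.vr for c in centroids]) if centroids else None
    for u in _ranked(uniques):
        if u.vr in centroid_vrs:
            continue
        if index is None:
            ambiguous.append(AmbiguousEntry(u, (), "too_far"))
            continue
        d = index.distances(u.vr)
        dmin = int(d.min())
        if params.max_assignment_distance is not None and dmin > params.max_assignment_distance:
            ambiguous.append(AmbiguousEntry(u, (), "too_far"))
            continue
        nearest = tuple(int(i) for i in np.nonzero(d == dmin)[0])
        if len(nearest) == 1:
            clusters[nearest[0]].members.append((u, dmin))
        else:
            ambiguous.append(AmbiguousEntry(u, nearest, "tie"))
    return ClusterResult(clusters=clusters, ambiguous=ambiguous, params=params)


def cluster_pool(
    uniques: Sequence[UniqueSequence],
    params: ClusterParams = ClusterParams(),
) -> ClusterResult:
    """Full greedy clustering: pick centroids, then assign members."""
    seen = set()
    for u in uniques:
        if u.vr in seen:
            raise ValueError(f"duplicate sequence in input: {u.vr!r}")
        seen.add(u.vr)
    return assign_members(uniques, pick_centroids(uniques, params), params)


# ---------------------------------------------------------------------------
# count tables


def tabulate_uniques(reads_by_round: Mapping[str, Iterable[str]]) -> list[UniqueSequence]:
    """Deduplicate per-round VR strings into a pooled unique-sequence list.

    Round label order follows the mapping's order; every UniqueSequence
    carries a count (possibly 0) for every round.
    """
    labels = list(reads_by_round)
    counts: dict[str, dict[str, int]] = {}
    for label in labels:
        for vr in reads_by_round[label]:
            row = counts.setdefault(vr, {lab: 0 for lab in labels})
            row[label] += 1
    return [UniqueSequence.from_counts(vr, row) for vr, row in counts.items()]


def read_count_table(path: str) -> list[UniqueSequence]:
    """Read a tab-separated unique-sequence count table.

    Layout: a ``sequence`` column plus one integer count column per round.
    Percentage columns (header containing ``%`` or ``percent``), as found in
    published per-round supplementary tables, are ignored.  Lines starting
    with ``#`` are comments.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = list(df.columns)
    seq_col = cols[0]
    count_cols = [
        c for c in cols[1:] if "%" not in str(c) and "percent" not in str(c).lower()
    ]
    out = []
    for _, row in df.iterrows():
        vr = str(row[seq_col]).strip().upper()
        out.append(
            UniqueSequence.from_counts(vr, {str(c): int(row[c]) for c in count_cols})
        )
    return out


def write_count_table(path: str, uniques: Sequence[UniqueSequence], header_comment: str = "") -> None:
    labels: list[str] = []
    for u in uniques:
        for lab, _ in u.counts:
            if lab not in labels:
                labels.append(lab)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("sequence\t" + "\t".join(labels) + "\n")
        for u in uniques:
            cm = u.count_map
            fh.write(u.vr + "\t" + "\t".join(str(cm.get(lab, 0)) for lab in labels) + "\n")


def cluster_table(result: ClusterResult) -> pd.DataFrame:
    """Flatten a ClusterResult into a tidy per-sequence table."""
    rows = []
    for i, cl in enumerate(result.clusters):
        rows.append(
            {"cluster_id": i, "role": "centroid", "sequence": cl.centroid.vr, "distance": 0,
             "total_count": cl.centroid.total_count, **cl.centroid.count_map}
        )
        for member, dist in cl.members:
            rows.append(
                {"cluster_id": i, "role": "member", "sequence": member.vr, "distance": dist,
                 "total_count": member.total_count, **member.count_map}
            )
    for entry in result.ambiguous:
        rows.append(
            {"cluster_id": -1, "role": "ambiguous", "sequence": entry.sequence.vr,
             "distance": -1, "total_count": entry.sequence.total_count,
             **entry.sequence.count_map}
        )
    return pd.DataFrame(rows)
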