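"""Shared fixtures and independent oracles for the test suite.

The clustering oracle here is a deliberately literal, brute-force
transcription of the clustering rules (full distance matrix, explicit
greedy walk, explicit tie detection) and an independent naive edit-distance
dynamic program — it never calls the package's clustering internals, so it
can adjudicate them.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import pytest

from aptapool.clustering import UniqueSequence
from aptapool.seqio import LibraryDesign

LEFT = "TCGGGCGAGTCGTCTG"
RIGHT = "CCGCATCGTCCTCCCTA"


@pytest.fixture
def design() -> LibraryDesign:
    return LibraryDesign()


def random_dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


def naive_edit_distance(a: str, b: str) -> int:
    """Textbook Levenshtein DP, independent of edlib."""
    prev = list(range(len(b) + 1))
    for i, x in enumerate(a, 1):
        cur = [i]
        for j, y in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (x != y)))
        prev = cur
    return prev[-1]


def naive_distance(a: str, b: str) -> int:
    if len(a) == len(b):
        return sum(x != y for x, y in zip(a, b))
    return naive_edit_distance(a, b)


@dataclass
class OracleResult:
    centroids: list[str]
    members: dict[str, list[tuple[str, int]]]  # centroid vr -> [(member vr, dist)]
    ambiguous: list[tuple[str, tuple[int, ...]]]  # (vr, tied centroid indices)
    too_far: list[str] = field(default_factory=list)


def brute_force_cluster(
    uniques: list[UniqueSequence],
    radius: int,
    max_assignment_distance: int | None = None,
) -> OracleResult:
    """Literal greedy clustering over a precomputed full distance matrix."""
    ranked = sorted(uniques, key=lambda u: (-u.total_count, u.vr))
    vrs = [u.vr for u in ranked]
    dist = {
        (x, y): naive_distance(x, y) for x in vrs for y in vrs
    }
    centroids: list[str] = []
    for vr in vrs:
        if all(dist[(vr, c)] > radius for c in centroids):
            centroids.append(vr)
    members: dict[str, list[tuple[str, int]]] = {c: [] for c in centroids}
    ambiguous: list[tuple[str, tuple[int, ...]]] = []
    too_far: list[str] = []
    for vr in vrs:
        if vr in members:
            continue
        ds = [dist[(vr, c)] for c in centroids]
        dmin = min(ds)
        if max_assignment_distance is not None and dmin > max_assignment_distance:
            too_far.append(vr)
            continue
        tied = tuple(i for i, d in enumerate(ds) if d == dmin)
        if len(tied) == 1:
            members[centroids[tied[0]]].append((vr, dmin))
        else:
            ambiguous.append((vr, tied))
    return OracleResult(centroids, members, ambiguous, too_far)


def random_pool(rng: random.Random, n_max: int = 50) -> list[UniqueSequence]:
    """A random unique-sequence pool with planted family structure.

    Seeds a few base sequences and scatters mutated satellites around them,
    so pools exercise centroid adoption, membership, and ties rather than
    being uniformly far apart.
    """
    n = rng.randint(1, n_max)
    n_bases = rng.randint(1, max(1, n // 5))
    base_len = rng.randint(8, 12)
    bases = [random_dna(rng, base_len) for _ in range(n_bases)]
    seqs: dict[str, int] = {}
    while len(seqs) < n:
        if rng.random() < 0.2:
            s = random_dna(rng, rng.randint(base_len - 2, base_len + 2))
        else:
            s = list(rng.choice(bases))
            for _ in range(rng.randint(0, 4)):
                s[rng.randrange(len(s))] = rng.choice("ACGT")
            if rng.random() < 0.1:
                del s[rng.randrange(len(s))]
            s = "".join(s)
        if s not in seqs:
            seqs[s] = rng.randint(1, 100)
    rounds = ["R1", "R2"]
    out = []
    for vr, total in seqs.items():
        r1 = rng.randint(0, total)
        out.append(UniqueSequence.from_counts(vr, {"R1": r1, "R2": total - r1}))
    return out


def make_amplicon(vr: str, left: str = LEFT, right: str = RIGHT) -> str:
    return left + vr + right
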