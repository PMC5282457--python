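"""Pairwise global alignment and percent identity of variable regions.

A plain Needleman-Wunsch global aligner with simple unit scores, used to
compare variable regions selected in independent experiments.  Tie-breaking
in the traceback is fixed (diagonal, then up, then left) so alignments are
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AlignmentParams", "global_align", "percent_identity", "format_alignment"]

GAP = "-"


@dataclass(frozen=True)
class AlignmentParams:
    match: float = 1.0
    mismatch: float = 0.0
    gap: float = -1.0
    # identity denominator: "alignment" (aligned columns) or "shorter" sequence
    identity_denominator: str = "alignment"

    def __post_init__(self) -> None:
        if self.match <= self.mismatch:
            raise ValueError("match score must exceed mismatch score")
        if self.identity_denominator not in ("alignment", "shorter"):
            raise ValueError("identity_denominator must be 'alignment' or 'shorter'")


def global_align(
    a: str, b: str, params: AlignmentParams = AlignmentParams()
) -> tuple[str, str, float]:
    """Optimal global alignment of two sequences.

    Returns (aligned_a, aligned_b, score).  Ties in the traceback prefer the
    diagonal move, then the up move (gap in ``b``), then the left move.
    """
    if not a or not b:
        raise ValueError("global_align requires non-empty sequences")
    n, m = len(a), len(b)
    score = np.empty((n + 1, m + 1))
    score[0, :] = np.arange(m + 1) * params.gap
    score[:, 0] = np.arange(n + 1) * params.gap
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = params.match if a[i - 1] == b[j - 1] else params.mismatch
            score[i, j] = max(
                score[i - 1, j - 1] + sub,
                score[i - 1, j] + params.gap,
                score[i, j - 1] + params.gap,
            )
    # traceback with fixed move preference
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            sub = params.match if a[i - 1] == b[j - 1] else params.mismatch
            if score[i, j] == score[i - 1, j - 1] + sub:
                out_a.append(a[i - 1])
                out_b.append(b[j - 1])
                i -= 1
                j -= 1
                continue
        if i > 0 and score[i, j] == score[i - 1, j] + params.gap:
            out_a.append(a[i - 1])
            out_b.append(GAP)
            i -= 1
            continue
        out_a.append(GAP)
        out_b.append(b[j - 1])
        j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b)), float(score[n, m])


def percent_identity(a: str, b: str, params: AlignmentParams = AlignmentParams()) -> float:
    """Percent of identical aligned columns between two sequences.

    The denominator is the alignment length (default) or the shorter
    sequence's length, per ``params.identity_denominator``.

    Several distinct alignments can share the optimal score while differing
    in identical-column count, so the raw traceback is not symmetric in its
    arguments; the pair is aligned in canonical (lexicographic) order to
    make the reported identity symmetric and deterministic.
    """
    first, second = (a, b) if a <= b else (b, a)
    aligned_a, aligned_b, _ = global_align(first, second, params)
    identical = sum(x == y and x != GAP for x, y in zip(aligned_a, aligned_b))
    if params.identity_denominator == "alignment":
        denom = len(aligned_a)
    else:
        denom = min(len(a), len(b))
    return 100.0 * identical / denom


def format_alignment(aligned_a: str, aligned_b: str, width: int = 60) -> str:
    """Human-readable two-row alignment with a match line."""
    marks = "".join(
        "|" if x == y and x != GAP else " " for x, y in zip(aligned_a, aligned_b)
    )
    blocks = []
    for start in range(0, len(aligned_a), width):
        blocks.append(
            "\n".join(
                (
                    aligned_a[start : start + width],
                    marks[start : start + width],
                    aligned_b[start : start + width],
                )
            )
        )
    return "\n\n".join(blocks)
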