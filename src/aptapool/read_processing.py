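"""Read filtering, barcode demultiplexing and variable-region extraction.

Implements the amplicon filter used for selection-round sequencing data:
keep only reads that are at least ``min_read_length`` nt long and carry both
constant flanks with a variable region of ``vr_min``..``vr_max`` nt strictly
in between.  Rejections are values (counted per reason), never exceptions.
All coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

from .seqio import LibraryDesign, SequenceRecord, normalize_sequence, reverse_complement

__all__ = [
    "AptamerRead",
    "FilterReport",
    "RejectionReason",
    "demultiplex",
    "locate_flanks",
    "filter_and_extract",
]

# first-failing-rule-wins order; multiple_hits is folded in at the flank step
REJECTION_REASONS = (
    "too_short",
    "missing_left",
    "missing_right",
    "multiple_hits",
    "vr_length_out_of_range",
)

RejectionReason = str


@dataclass
class AptamerRead:
    """An accepted read with its extracted variable region.

    ``vr`` is the subsequence strictly between ``left_span.end`` and
    ``right_span.start`` of ``full_sequence`` (after re-orientation when the
    flanks were found on the reverse strand).
    """

    read_id: str
    full_sequence: str
    vr: str
    left_span: tuple[int, int]
    right_span: tuple[int, int]
    orientation: str  # "forward" | "reverse_complemented"


@dataclass
class FilterReport:
    """Per-reason rejection tallies; every input read counted exactly once."""

    total: int = 0
    passed: int = 0
    rejected: dict[str, int] = field(default_factory=lambda: {r: 0 for r in REJECTION_REASONS})

    def reject(self, reason: RejectionReason) -> None:
        self.rejected[reason] += 1
        self.total += 1

    def accept(self) -> None:
        self.passed += 1
        self.total += 1

    @property
    def balanced(self) -> bool:
        return self.passed + sum(self.rejected.values()) == self.total

    def to_tsv(self) -> str:
        lines = ["category\tcount", f"total\t{self.total}", f"passed\t{self.passed}"]
        lines += [f"rejected_{r}\t{n}" for r, n in self.rejected.items()]
        return "\n".join(lines) + "\n"


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _best_occurrence(pattern: str, text: str, max_mismatch: int, start: int = 0):
    """Best (fewest-mismatch) occurrence of pattern in text[start:].

    Returns (span, n_best_positions) where span is the leftmost best hit, or
    (None, 0) when no position is within max_mismatch.
    """
    m = len(pattern)
    if max_mismatch == 0:
        # exact matching: delegate to str.find, collecting every occurrence
        pos = text.find(pattern, start)
        if pos < 0:
            return None, 0
        n = 0
        first = pos
        while pos >= 0:
            n += 1
            pos = text.find(pattern, pos + 1)
        return (first, first + m), n
    best = max_mismatch + 1
    best_pos: list[int] = []
    for i in range(start, len(text) - m + 1):
        d = _hamming(pattern, text[i : i + m])
        if d < best:
            best = d
            best_pos = [i]
        elif d == best:
            best_pos.append(i)
    if not best_pos:
        return None, 0
    i = best_pos[0]
    return (i, i + m), len(best_pos)


def _locate_one_strand(seq: str, design: LibraryDesign, max_flank_mismatch: int):
    left, n_left = _best_occurrence(design.left_constant, seq, max_flank_mismatch)
    if left is None:
        return None, "missing_left"
    if n_left > 1:
        return None, "multiple_hits"
    right, n_right = _best_occurrence(design.right_constant, seq, max_flank_mismatch, start=left[1])
    if right is None:
        return None, "missing_right"
    if n_right > 1:
        return None, "multiple_hits"
    return (left, right), None


def locate_flanks(
    read: str,
    design: LibraryDesign,
    max_flank_mismatch: int = 0,
) -> Union[tuple[tuple[int, int], tuple[int, int], str], RejectionReason]:
    """Find both constant flanks in a read; a rejection reason on failure.

    The forward strand is searched first; if it fails and the design allows
    it, the reverse complement is searched and the returned spans refer to
    the re-oriented read.  A flank must have a unique best occurrence, else
    the read is rejected as ``multiple_hits``.
    """
    seq = normalize_sequence(read)
    spans, reason = _locate_one_strand(seq, design, max_flank_mismatch)
    if spans is not None:
        return spans[0], spans[1], "forward"
    if design.search_reverse_complement and "U" not in seq:
        rc = reverse_complement(seq)
        spans_rc, reason_rc = _locate_one_strand(rc, design, max_flank_mismatch)
        if spans_rc is not None:
            return spans_rc[0], spans_rc[1], "reverse_complemented"
    return reason


def filter_and_extract(
    records: Iterable[SequenceRecord],
    design: LibraryDesign,
    max_flank_mismatch: int = 0,
) -> tuple[list[AptamerRead], FilterReport]:
    """Apply length and flank filters; extract the VR of every passing read.

    Rules apply in fixed order (first failure wins): too_short before any
    flank search, then missing_left / missing_right / multiple_hits, then
    vr_length_out_of_range on the extracted region.
    """
    accepted: list[AptamerRead] = []
    report = FilterReport()
    for rec in records:
        seq = rec.sequence
        if len(seq) < design.min_read_length:
            report.reject("too_short")
            continue
        located = locate_flanks(seq, design, max_flank_mismatch)
        if isinstance(located, str):
            report.reject(located)
            continue
        left_span, right_span, orientation = located
        oriented = seq if orientation == "forward" else reverse_complement(seq)
        vr = oriented[left_span[1] : right_span[0]]
        if not (design.vr_min <= len(vr) <= design.vr_max):
            report.reject("vr_length_out_of_range")
            continue
        accepted.append(
            AptamerRead(
                read_id=rec.id,
                full_sequence=oriented,
                vr=vr,
                left_span=left_span,
                right_span=right_span,
                orientation=orientation,
            )
        )
        report.accept()
    assert report.balanced
    return accepted, report


def demultiplex(
    records: Iterable[SequenceRecord],
    barcode_map: dict[str, str],
    max_barcode_mismatch: int = 0,
) -> dict[str, list[SequenceRecord]]:
    """Split reads by the barcode at the read start; strip it when assigned.

    ``barcode_map`` maps barcode sequence -> round label.  Barcodes must be
    distinct, equal length, and pairwise more than ``2*max_barcode_mismatch``
    apart (otherwise assignment would be ambiguous by construction).  Reads
    matching no barcode within tolerance land under the ``"unassigned"`` key
    unmodified.
    """
    barcodes = [normalize_sequence(b) for b in barcode_map]
    labels = list(barcode_map.values())
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("duplicate barcodes")
    if len(set(len(b) for b in barcodes)) > 1:
        raise ValueError("barcodes must be equal length")
    for i in range(len(barcodes)):
        for j in range(i + 1, len(barcodes)):
            if _hamming(barcodes[i], barcodes[j]) <= 2 * max_barcode_mismatch:
                raise ValueError(
                    f"barcodes {barcodes[i]!r} and {barcodes[j]!r} are within "
                    f"2*max_barcode_mismatch of each other"
                )
    blen = len(barcodes[0]) if barcodes else 0
    out: dict[str, list[SequenceRecord]] = {label: [] for label in labels}
    out["unassigned"] = []
    for rec in records:
        prefix = rec.sequence[:blen]
        hits = [
            k
            for k, b in enumerate(barcodes)
            if len(prefix) == blen and _hamming(prefix, b) <= max_barcode_mismatch
        ]
        if len(hits) == 1:
            k = hits[0]
            out[labels[k]].append(
                SequenceRecord(
                    id=rec.id,
                    sequence=rec.sequence[blen:],
                    quality=rec.quality[blen:] if rec.quality is not None else None,
                )
            )
        else:
            out["unassigned"].append(rec)
    return out
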