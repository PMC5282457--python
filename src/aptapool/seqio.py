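"""Sequence I/O and elementary nucleotide transforms.

Reads and writes FASTA/FASTQ through Biopython, normalising everything to
upper case on the way in.  Sequences are plain Python strings over
``{A, C, G, T, U, N}``, oriented 5'->3'; DNA and RNA are distinguished only
by which of T/U appears (never both in one sequence).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterator, Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "DNA_ALPHABET",
    "LibraryDesign",
    "SequenceRecord",
    "normalize_sequence",
    "reverse_complement",
    "dna_to_rna",
    "read_sequences",
    "write_sequences",
]

DNA_ALPHABET = frozenset("ACGTN")
RNA_ALPHABET = frozenset("ACGUN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def normalize_sequence(bases: str, *, allow_empty: bool = False) -> str:
    """Upper-case ``bases`` and validate the nucleotide alphabet.

    Accepts DNA (``ACGTN``) or RNA (``ACGUN``); mixing T and U in one
    sequence is rejected, as is any character outside the two alphabets.
    """
    s = bases.upper()
    if not s and not allow_empty:
        raise ValueError("empty sequence not allowed here")
    letters = set(s)
    if not letters <= (DNA_ALPHABET | RNA_ALPHABET):
        bad = sorted(letters - (DNA_ALPHABET | RNA_ALPHABET))
        raise ValueError(f"invalid nucleotide characters: {bad!r}")
    if "T" in letters and "U" in letters:
        raise ValueError("sequence mixes T and U")
    return s


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of a DNA string (N maps to N).

    An involution: ``reverse_complement(reverse_complement(s)) == s``.
    RNA input (containing U) is rejected.
    """
    s = normalize_sequence(seq, allow_empty=True)
    if "U" in s:
        raise ValueError("reverse_complement is defined for DNA only (found U)")
    return s.translate(_COMPLEMENT)[::-1]


def dna_to_rna(seq: str) -> str:
    """Transcribed-strand conversion: replace T with U, leave the rest."""
    s = normalize_sequence(seq, allow_empty=True)
    if "U" in s:
        raise ValueError("input already contains U")
    return s.replace("T", "U")


@dataclass(frozen=True)
class LibraryDesign:
    """Constant flanks and length bounds of an aptamer library.

    Defaults describe a library whose members are
    ``left_constant + N40 + right_constant`` amplicons: a 40-nt random
    variable region (VR) between fixed primer-binding flanks.  Filtering
    accepts VRs of ``vr_min``..``vr_max`` nt and discards raw reads shorter
    than ``min_read_length``.
    """

    left_constant: str = "TCGGGCGAGTCGTCTG"
    right_constant: str = "CCGCATCGTCCTCCCTA"
    vr_min: int = 38
    vr_max: int = 42
    min_read_length: int = 70
    search_reverse_complement: bool = True

    def __post_init__(self) -> None:
        for name in ("left_constant", "right_constant"):
            s = normalize_sequence(getattr(self, name))
            if set(s) - set("ACGT"):
                raise ValueError(f"{name} must be unambiguous DNA (A/C/G/T only)")
            object.__setattr__(self, name, s)
        if not (0 < self.vr_min <= self.vr_max):
            raise ValueError("require 0 < vr_min <= vr_max")
        if self.min_read_length < 0:
            raise ValueError("min_read_length must be >= 0")


@dataclass
class SequenceRecord:
    id: str
    sequence: str
    quality: Optional[list[int]] = None  # Phred scores, FASTQ only


def _infer_format(path: str, fmt: Optional[str]) -> str:
    if fmt is not None:
        f = fmt.lower()
        if f not in ("fasta", "fastq"):
            raise ValueError(f"unknown sequence format: {fmt!r}")
        return f
    ext = os.path.splitext(path)[1].lower()
    if ext in (".fa", ".fasta", ".fna"):
        return "fasta"
    if ext in (".fq", ".fastq"):
        return "fastq"
    raise ValueError(f"cannot infer format from extension of {path!r}; pass format=")


def read_sequences(path: str, format: Optional[str] = None) -> Iterator[SequenceRecord]:
    """Stream records from a FASTA or FASTQ file in file order.

    Sequences are upper-cased and alphabet-checked; quality scores are
    present iff the file is FASTQ (Phred+33, not interpreted further).
    Malformed records raise ValueError naming the failing record index.
    """
    fmt = _infer_format(path, format)
    parser = SeqIO.parse(path, fmt)
    index = 0
    while True:
        try:
            rec = next(parser)
        except StopIteration:
            return
        except ValueError as exc:
            raise ValueError(f"malformed {fmt} record at index {index}: {exc}") from exc
        try:
            seq = normalize_sequence(str(rec.seq), allow_empty=True)
        except ValueError as exc:
            raise ValueError(f"record {index} ({rec.id!r}): {exc}") from exc
        qual = rec.letter_annotations.get("phred_quality") if fmt == "fastq" else None
        yield SequenceRecord(id=rec.id, sequence=seq, quality=list(qual) if qual else qual)
        index += 1


def write_sequences(path: str, records: Iterable[SequenceRecord], format: Optional[str] = None) -> int:
    """Write records as FASTA or FASTQ; returns the number written."""
    fmt = _infer_format(path, format)
    out = []
    for rec in records:
        sr = SeqRecord(Seq(rec.sequence), id=rec.id, description="")
        if fmt == "fastq":
            if rec.quality is None:
                raise ValueError(f"record {rec.id!r} has no quality; cannot write FASTQ")
            if len(rec.quality) != len(rec.sequence):
                raise ValueError(f"record {rec.id!r}: quality/sequence length mismatch")
            sr.letter_annotations["phred_quality"] = list(rec.quality)
        out.append(sr)
    return SeqIO.write(out, path, fmt)
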