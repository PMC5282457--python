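"""Forward simulator of selection rounds over a random aptamer library.

Models one in-vitro selection cycle as deterministic multiplicative
selection followed by finite-depth sequencing:

* every founder variable region ``i`` carries a selection coefficient
  ``s_i`` folding binding, internalization, nuclease survival and
  amplification into one multiplier; round-over-round the true pool
  fractions update as ``f'_i = s_i f_i / sum_j s_j f_j``;
* each sequenced round is a multinomial sample of ``depth_per_round`` reads
  from the true fractions, with optional per-base substitution error;
* reads are emitted as full amplicons (left constant + VR + right
  constant), so the filtering, clustering and enrichment stages see data
  with the structure they assume.

A handful of "sticky" founders with ``s > 1`` against a neutral background
reproduces the early-takeover dynamics seen in real cell selections, where
one sequence dominates the pool after a single round.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .clustering import sequence_distance
from .enrichment import MotifSpan
from .seqio import LibraryDesign, SequenceRecord, write_sequences

__all__ = [
    "StickyFounder",
    "SelexSimConfig",
    "SimulatedRound",
    "SelexRun",
    "generate_library",
    "advance_round",
    "sample_reads",
    "run_selection",
    "write_run",
    "takeover_config",
    "moderate_selection_config",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class StickyFounder:
    """A planted founder with its selection coefficient; vr=None means
    auto-generate a random VR at library construction."""

    coefficient: float
    vr: Optional[str] = None

    def __post_init__(self) -> None:
        if self.coefficient < 0:
            raise ValueError("selection coefficient must be >= 0")


@dataclass(frozen=True)
class SelexSimConfig:
    """Study conditions for one simulated selection.

    ``vr_length_weights`` gives the founder VR length distribution (default
    a point mass at 40 nt, matching an N40 library).  ``cluster_radius`` is
    only used to validate that planted sticky VRs are mutually more than
    twice the radius apart, so the planted truth stays recoverable by
    mismatch-radius clustering.
    """

    n_library: int = 1000
    vr_length_weights: tuple[tuple[int, float], ...] = ((40, 1.0),)
    design: LibraryDesign = field(default_factory=LibraryDesign)
    sticky: tuple[StickyFounder, ...] = ()
    default_coefficient: float = 1.0
    rounds: int = 7
    depth_per_round: int = 10_000
    per_base_error_rate: float = 0.001
    mutation_spares_motif: Optional[MotifSpan] = None
    cluster_radius: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_library < 1:
            raise ValueError("n_library must be >= 1")
        lengths = dict(self.vr_length_weights)
        if not lengths or any(w < 0 for w in lengths.values()) or sum(lengths.values()) <= 0:
            raise ValueError("vr_length_weights must be a non-empty distribution")
        if any(L < 1 for L in lengths):
            raise ValueError("VR lengths must be positive")
        if not (0 <= self.per_base_error_rate < 1):
            raise ValueError("per_base_error_rate must be in [0, 1)")
        if self.rounds < 1 or self.depth_per_round < 1:
            raise ValueError("rounds and depth_per_round must be >= 1")
        if self.default_coefficient < 0:
            raise ValueError("default_coefficient must be >= 0")


@dataclass
class SimulatedRound:
    round_label: str
    true_fractions: np.ndarray  # per founder, sums to 1
    founder_counts: np.ndarray  # multinomial sample, sums to depth
    reads: list[SequenceRecord]  # full amplicons


@dataclass
class SelexRun:
    config: SelexSimConfig
    founders: list[str]  # VR strings
    coefficients: np.ndarray
    rounds: list[SimulatedRound]

    @property
    def truth_table(self) -> pd.DataFrame:
        """True per-founder pool fractions, one column per sequenced round."""
        return pd.DataFrame(
            {r.round_label: r.true_fractions for r in self.rounds},
            index=self.founders,
        )

    @property
    def sticky_vrs(self) -> list[str]:
        n_sticky = len(self.config.sticky)
        return self.founders[:n_sticky]


def _random_vr(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def generate_library(
    config: SelexSimConfig, rng: Optional[np.random.Generator] = None
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Draw the founder set: sticky founders first, then random background.

    Returns (founder VRs, uniform initial fractions, coefficients).  All
    founders are distinct; sticky VRs must be pairwise more than
    ``2 * cluster_radius`` apart.  Errors out when ``n_library`` exceeds the
    sequence space of the shortest allowed VR length.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lengths = [L for L, w in config.vr_length_weights if w > 0]
    weights = np.array([w for _, w in config.vr_length_weights if w > 0], dtype=float)
    weights /= weights.sum()
    if config.n_library > sum(4**L for L in lengths):
        raise ValueError(
            f"n_library={config.n_library} exceeds the VR sequence space"
        )
    if len(config.sticky) > config.n_library:
        raise ValueError("more sticky founders than library members")

    founders: list[str] = []
    seen: set[str] = set()

    def draw_length() -> int:
        return int(rng.choice(lengths, p=weights))

    min_sep = 2 * config.cluster_radius
    for k, sticky in enumerate(config.sticky):
        if sticky.vr is not None:
            vr = sticky.vr.upper()
        else:
            for _ in range(1000):
                vr = _random_vr(rng, draw_length())
                if all(sequence_distance(vr, prev) > min_sep for prev in founders):
                    break
            else:  # pragma: no cover - astronomically unlikely for real lengths
                raise ValueError("could not place a sticky founder far enough from the others")
        if vr in seen:
            raise ValueError(f"duplicate sticky VR: {vr!r}")
        if founders and any(sequence_distance(vr, prev) <= min_sep for prev in founders):
            raise ValueError(
                f"sticky VRs must be pairwise > {min_sep} mismatches apart"
            )
        founders.append(vr)
        seen.add(vr)

    attempts = 0
    while len(founders) < config.n_library:
        vr = _random_vr(rng, draw_length())
        attempts += 1
        if vr in seen:
            if attempts > 100 * config.n_library + 1000:
                raise ValueError("sequence space too small to draw distinct founders")
            continue
        founders.append(vr)
        seen.add(vr)

    fractions = np.full(len(founders), 1.0 / len(founders))
    coefficients = np.full(len(founders), config.default_coefficient, dtype=float)
    for k, sticky in enumerate(config.sticky):
        coefficients[k] = sticky.coefficient
    return founders, fractions, coefficients


def advance_round(fractions: np.ndarray, coefficients: np.ndarray) -> np.ndarray:
    """One deterministic selection update: f'_i = s_i f_i / sum_j s_j f_j."""
    fractions = np.asarray(fractions, dtype=float)
    coefficients = np.asarray(coefficients, dtype=float)
    if np.any(fractions < 0) or np.any(coefficients < 0):
        raise ValueError("fractions and coefficients must be non-negative")
    if not np.isclose(fractions.sum(), 1.0):
        raise ValueError("fractions must sum to 1")
    weighted = coefficients * fractions
    total = weighted.sum()
    if total <= 0:
        raise ValueError("selection annihilated the pool (all weighted fractions zero)")
    return weighted / total


def _apply_errors(
    vr: str,
    n_reads: int,
    rate: float,
    rng: np.random.Generator,
    spare: Optional[MotifSpan],
) -> list[str]:
    """Emit n_reads copies of vr with iid per-base substitution errors.

    Positions inside ``spare`` never mutate (the conserved-motif toggle).
    """
    L = len(vr)
    base = np.frombuffer(vr.encode("ascii"), dtype=np.uint8)
    allowed = np.ones(L, dtype=bool)
    if spare is not None:
        allowed[spare.start : min(spare.end, L)] = False
    out: list[str] = []
    if rate == 0 or not allowed.any():
        return [vr] * n_reads
    for _ in range(n_reads):
        hits = np.nonzero((rng.random(L) < rate) & allowed)[0]
        if hits.size == 0:
            out.append(vr)
            continue
        mutated = base.copy()
        for pos in hits:
            # uniform over the three alternative bases
            alternatives = _BASES[_BASES != mutated[pos]]
            mutated[pos] = rng.choice(alternatives)
        out.append(mutated.tobytes().decode("ascii"))
    return out


def sample_reads(
    fractions: np.ndarray,
    founders: Sequence[str],
    config: SelexSimConfig,
    rng: np.random.Generator,
    round_label: str,
) -> SimulatedRound:
    """Multinomial sequencing sample of one round, as full amplicons."""
    counts = rng.multinomial(config.depth_per_round, fractions)
    design = config.design
    reads: list[SequenceRecord] = []
    i = 0
    for founder_idx in np.nonzero(counts)[0]:
        vrs = _apply_errors(
            founders[founder_idx],
            int(counts[founder_idx]),
            config.per_base_error_rate,
            rng,
            config.mutation_spares_motif,
        )
        for vr in vrs:
            full = design.left_constant + vr + design.right_constant
            reads.append(
                SequenceRecord(id=f"{round_label}_read{i:06d}", sequence=full)
            )
            i += 1
    return SimulatedRound(
        round_label=round_label,
        true_fractions=np.asarray(fractions, dtype=float).copy(),
        founder_counts=counts,
        reads=reads,
    )


def run_selection(config: SelexSimConfig) -> SelexRun:
    """Simulate the whole selection: R1..R<rounds> read sets plus truth.

    Round labels follow the convention that R1 is the pool *after* one
    selection update of the uniform founder library.  Fully reproducible
    from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    founders, fractions, coefficients = generate_library(config, rng)
    rounds: list[SimulatedRound] = []
    for r in range(1, config.rounds + 1):
        fractions = advance_round(fractions, coefficients)
        rounds.append(sample_reads(fractions, founders, config, rng, f"R{r}"))
    return SelexRun(config=config, founders=founders, coefficients=coefficients, rounds=rounds)


def write_run(run: SelexRun, outdir: str, format: str = "fasta") -> dict[str, str]:
    """Write one read file per round plus a truth-table TSV; returns paths."""
    import os

    os.makedirs(outdir, exist_ok=True)
    ext = "fasta" if format == "fasta" else "fastq"
    paths: dict[str, str] = {}
    for rnd in run.rounds:
        path = os.path.join(outdir, f"{rnd.round_label}.{ext}")
        records = rnd.reads
        if format == "fastq":
            records = [
                SequenceRecord(r.id, r.sequence, [30] * len(r.sequence)) for r in records
            ]
        write_sequences(path, records, format)
        paths[rnd.round_label] = path
    truth_path = os.path.join(outdir, "truth.tsv")
    run.truth_table.rename_axis("founder_vr").to_csv(truth_path, sep="\t")
    paths["truth"] = truth_path
    return paths


def takeover_config(seed: int = 0) -> SelexSimConfig:
    """Conditions reproducing a single-sequence takeover of the pool.

    One sticky founder (s=2500, starting at f0=0.001 in a uniform
    1000-member library) sequenced at depth 10,000 with no read error:
    after one selection round the sticky founder holds about 71% of the
    pool (closed form 2.5/(2.5+0.999)) and pool enrichment is near 90%,
    crossing 99% by round two — the early-takeover regime.
    """
    return SelexSimConfig(
        n_library=1000,
        sticky=(StickyFounder(coefficient=2500.0),),
        depth_per_round=10_000,
        per_base_error_rate=0.0,
        rounds=7,
        seed=seed,
    )


def moderate_selection_config(seed: int = 0) -> SelexSimConfig:
    """One sticky founder at s=10 starting from fraction 0.01.

    A 100-member uniform library puts the planted founder at exactly
    f0 = 0.01; its true trajectory follows the closed form
    f' = 10 f / (10 f + (1 - f)): about 0.092, 0.502, 0.910, ... over rounds.
    """
    return SelexSimConfig(
        n_library=100,
        sticky=(StickyFounder(coefficient=10.0),),
        depth_per_round=10_000,
        per_base_error_rate=0.0,
        rounds=7,
        seed=seed,
    )
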