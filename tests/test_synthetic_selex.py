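"""Selection-round simulator: determinism, selection dynamics, error model."""

import math

import numpy as np
import pytest

from aptapool.enrichment import MotifSpan
from aptapool.synthetic_selex import (
    SelexSimConfig,
    StickyFounder,
    advance_round,
    generate_library,
    moderate_selection_config,
    run_selection,
    sample_reads,
    write_run,
)


def closed_form_trajectory(s: float, f0: float, rounds: int) -> list[float]:
    f = f0
    out = []
    for _ in range(rounds):
        f = s * f / (s * f + (1 - f))
        out.append(f)
    return out


class TestGenerateLibrary:
    def test_seeded_determinism(self):
        config = SelexSimConfig(n_library=100, seed=42)
        a = generate_library(config)
        b = generate_library(config)
        assert a[0] == b[0]
        assert np.array_equal(a[1], b[1]) and np.array_equal(a[2], b[2])

    def test_uniform_fractions_and_distinct_founders(self):
        founders, fractions, _ = generate_library(SelexSimConfig(n_library=200, seed=1))
        assert len(set(founders)) == 200
        assert np.allclose(fractions, 1 / 200)

    def test_base_composition_near_equimolar(self):
        founders, _, _ = generate_library(SelexSimConfig(n_library=500, seed=3))
        joined = "".join(founders)
        n = len(joined)
        se = math.sqrt(n * 0.25 * 0.75)
        for base in "ACGT":
            assert abs(joined.count(base) - 0.25 * n) < 3 * se

    def test_space_exhaustion_errors(self):
        with pytest.raises(ValueError, match="sequence space"):
            generate_library(
                SelexSimConfig(n_library=300, vr_length_weights=((4, 1.0),), seed=0)
            )

    def test_sticky_coefficients_planted_first(self):
        config = SelexSimConfig(
            n_library=50, sticky=(StickyFounder(coefficient=9.0),), seed=5
        )
        founders, _, coefficients = generate_library(config)
        assert coefficients[0] == 9.0
        assert np.all(coefficients[1:] == 1.0)

    def test_close_sticky_pair_rejected(self):
        config = SelexSimConfig(
            n_library=50,
            sticky=(
                StickyFounder(coefficient=5.0, vr="A" * 40),
                StickyFounder(coefficient=5.0, vr="A" * 39 + "T"),
            ),
            seed=0,
        )
        with pytest.raises(ValueError, match="apart"):
            generate_library(config)


class TestAdvanceRound:
    def test_neutral_selection_leaves_fractions(self):
        f = np.array([0.2, 0.3, 0.5])
        assert np.allclose(advance_round(f, np.ones(3) * 7.0), f)

    def test_closed_form_single_round(self):
        f = np.array([0.01] + [0.99 / 99] * 99)
        s = np.array([10.0] + [1.0] * 99)
        out = advance_round(f, s)
        assert out[0] == pytest.approx(10 * 0.01 / (10 * 0.01 + 0.99))
        assert out.sum() == pytest.approx(1.0)

    def test_zero_coefficient_eliminates_founder(self):
        out = advance_round(np.array([0.5, 0.5]), np.array([0.0, 1.0]))
        assert out[0] == 0.0 and out[1] == 1.0

    def test_annihilated_pool_errors(self):
        with pytest.raises(ValueError):
            advance_round(np.array([0.5, 0.5]), np.zeros(2))


class TestSampleReads:
    def test_zero_error_reads_are_exact_founders(self):
        config = SelexSimConfig(n_library=20, per_base_error_rate=0.0, depth_per_round=500, seed=2)
        rng = np.random.default_rng(2)
        founders, fractions, _ = generate_library(config, rng)
        rnd = sample_reads(fractions, founders, config, rng, "R1")
        design = config.design
        founder_set = set(founders)
        assert len(rnd.reads) == 500
        for read in rnd.reads:
            assert read.sequence.startswith(design.left_constant)
            assert read.sequence.endswith(design.right_constant)
            vr = read.sequence[len(design.left_constant) : -len(design.right_constant)]
            assert vr in founder_set

    def test_multinomial_counts_near_expectation(self):
        config = SelexSimConfig(n_library=2, depth_per_round=10_000, per_base_error_rate=0.0, seed=9)
        rng = np.random.default_rng(9)
        founders, _, _ = generate_library(config, rng)
        rnd = sample_reads(np.array([0.5, 0.5]), founders, config, rng, "R1")
        se = math.sqrt(10_000 * 0.25)
        assert abs(rnd.founder_counts[0] - 5000) < 3 * se

    def test_error_rate_mutates_reads(self):
        config = SelexSimConfig(n_library=1, per_base_error_rate=0.05, depth_per_round=400, seed=4)
        rng = np.random.default_rng(4)
        founders, fractions, _ = generate_library(config, rng)
        rnd = sample_reads(fractions, founders, config, rng, "R1")
        vrs = {r.sequence[16:-17] for r in rnd.reads}
        assert len(vrs) > 1  # substitutions produced variant reads

    def test_motif_span_spared_from_errors(self):
        span = MotifSpan(10, 20)
        config = SelexSimConfig(
            n_library=1, per_base_error_rate=0.2, depth_per_round=300,
            mutation_spares_motif=span, seed=6,
        )
        rng = np.random.default_rng(6)
        founders, fractions, _ = generate_library(config, rng)
        rnd = sample_reads(fractions, founders, config, rng, "R1")
        motif = founders[0][span.start : span.end]
        for read in rnd.reads:
            vr = read.sequence[16:-17]
            assert vr[span.start : span.end] == motif


class TestRunSelection:
    def test_truth_follows_iterated_closed_form(self):
        run = run_selection(moderate_selection_config(seed=11))
        expected = closed_form_trajectory(10.0, 0.01, 7)
        sticky_row = run.truth_table.loc[run.sticky_vrs[0]]
        assert np.allclose(sticky_row.values, expected)
        assert expected[0] == pytest.approx(0.0917, abs=5e-5)
        assert expected[1] == pytest.approx(0.5025, abs=5e-5)
        assert expected[2] == pytest.approx(0.9099, abs=5e-5)

    def test_fractions_remain_distribution(self):
        run = run_selection(moderate_selection_config(seed=12))
        for rnd in run.rounds:
            assert rnd.true_fractions.min() >= 0
            assert rnd.true_fractions.sum() == pytest.approx(1.0)
            assert rnd.founder_counts.sum() == run.config.depth_per_round

    def test_sticky_fraction_strictly_increases(self):
        run = run_selection(moderate_selection_config(seed=13))
        traj = run.truth_table.loc[run.sticky_vrs[0]].values
        assert all(b > a for a, b in zip(traj, traj[1:]))

    def test_neutral_run_drifts_only_by_sampling(self):
        config = SelexSimConfig(n_library=50, depth_per_round=5000, per_base_error_rate=0.0, rounds=3, seed=14)
        run = run_selection(config)
        # true fractions stay exactly uniform under neutrality
        assert np.allclose(run.truth_table.values, 1 / 50)
        counts = run.rounds[0].founder_counts
        se = math.sqrt(5000 * (1 / 50) * (49 / 50))
        assert np.all(np.abs(counts - 100) < 5 * se)

    def test_same_seed_reproduces_reads(self):
        a = run_selection(moderate_selection_config(seed=15))
        b = run_selection(moderate_selection_config(seed=15))
        for ra, rb in zip(a.rounds, b.rounds):
            assert [r.sequence for r in ra.reads] == [r.sequence for r in rb.reads]

    def test_write_run_outputs_parse_back(self, tmp_path):
        config = SelexSimConfig(n_library=10, depth_per_round=50, rounds=2, seed=16)
        run = run_selection(config)
        paths = write_run(run, str(tmp_path), "fasta")
        from aptapool.seqio import read_sequences

        r1 = list(read_sequences(paths["R1"]))
        assert len(r1) == 50
        assert all(len(r.sequence) == 73 for r in r1)
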