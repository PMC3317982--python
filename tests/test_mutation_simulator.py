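import numpy as np
import pytest
from scipy import stats

from gcskewsim import (CircularSequence, CodingMask, DegenerateSignalError,
                       InputError, PointModel, SimulationStallError,
                       base_counts, gc_skew, gcsi, leading_strand_counts,
                       mutate_one_cycle, partition_strands, required_cycles,
                       run_simulation)
from gcskewsim.mutation_simulator import SimulationState

from conftest import random_sequence


class TestRequiredCycles:
    def test_ecoli_published_counts(self):
        # whole genome G/C and leading-strand G/C of E. coli K-12
        whole = {"G": 1_176_923, "C": 1_179_554}
        leading = {"G": 1_216_043, "C": 1_140_434}
        assert required_cycles(whole, leading) == 39_120

    def test_equal_composition_toy_genome(self):
        whole = {"G": 250_000, "C": 250_000}
        leading = {"G": 260_000, "C": 240_000}
        assert required_cycles(whole, leading) == 10_000

    def test_unbiased_genome_zero(self):
        counts = {"G": 100, "C": 120}
        assert required_cycles(counts, counts) == 0

    def test_inconsistent_counts_raise(self):
        with pytest.raises(InputError):
            required_cycles({"G": 100, "C": 100}, {"G": 110, "C": 95})


class TestPartitionStrands:
    def test_midpoint_partition(self):
        part = partition_strands(1, 51, 100)
        assert part.arm1 == (1, 50) and part.arm2 == (51, 100)
        assert part.arm1_length == 50

    def test_wrapped_equal_arms(self):
        part = partition_strands(80, 30, 100)
        assert part.arm1 == (80, 29) and part.arm2 == (30, 79)
        assert part.arm1_length == 50

    def test_every_position_in_exactly_one_arm(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            L = int(rng.integers(10, 1000))
            ori, ter = rng.choice(np.arange(1, L + 1), size=2,
                                  replace=False)
            part = partition_strands(int(ori), int(ter), L)
            in_arm1 = [part.in_arm1(p) for p in range(1, L + 1)]
            assert sum(in_arm1) == part.arm1_length
            assert part.in_arm1(int(ori)) and not part.in_arm1(int(ter))

    def test_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            partition_strands(5, 5, 100)


class TestMutateOneCycle:
    def test_conservation_per_cycle(self):
        seq = random_sequence(10_000, 1)
        state = SimulationState(seq, ori=1, model=PointModel(5_001),
                               max_cycles=50, seed=2)
        before = base_counts(seq)
        for _ in range(50):
            mutate_one_cycle(state)
        after = base_counts(state.sequence())
        assert after["A"] == before["A"] and after["T"] == before["T"]
        assert after["G"] + after["C"] == before["G"] + before["C"]
        changed = sum(a != b for a, b in zip(seq.seq,
                                             state.sequence().seq))
        assert changed <= 50  # one flip per cycle (a site may flip back)

    def test_arm_allocation_binomial(self):
        # under a fixed terminus the arm-1 share of mutations is binomial
        # with p = eligible-in-arm1 / eligible-total
        seq = random_sequence(40_000, 3)
        ter = 10_001  # asymmetric arms: arm1 a quarter of the circle
        counts1 = base_counts(seq, region=(1, ter - 1))
        counts2 = base_counts(seq, region=(ter, seq.length))
        p = counts1["C"] / (counts1["C"] + counts2["G"])
        n = 600
        state = SimulationState(seq, ori=1, model=PointModel(ter),
                                max_cycles=n, seed=4)
        for _ in range(n):
            mutate_one_cycle(state)
        gained = base_counts(state.sequence(),
                             region=(1, ter - 1))["G"] - counts1["G"]
        se = np.sqrt(n * p * (1 - p))
        assert abs(gained - n * p) <= 3 * se

    def test_stall_on_ineligible_genome(self):
        seq = CircularSequence("a", "A" * 500)
        state = SimulationState(seq, ori=1, model=PointModel(251),
                                max_cycles=1, seed=0)
        with pytest.raises(SimulationStallError):
            mutate_one_cycle(state)

    def test_mask_restricts_eligibility(self):
        seq = random_sequence(2_000, 5)
        include = np.zeros(2_000, dtype=bool)
        include[:500] = True
        state = SimulationState(seq, ori=1, model=PointModel(1_001),
                                max_cycles=40, seed=6,
                                mask=CodingMask(include))
        for _ in range(40):
            mutate_one_cycle(state)
        diff = [i for i, (a, b) in enumerate(zip(seq.seq,
                                                 state.sequence().seq))
                if a != b]
        assert diff and all(i < 500 for i in diff)


class TestRunSimulation:
    def test_zero_cycles_identity(self):
        seq = random_sequence(1_000, 7)
        state = run_simulation(seq, 1, PointModel(501), max_cycles=0,
                               seed=0)
        assert state.sequence().seq == seq.seq

    def test_fixed_point_leading_g_gain_is_exact(self):
        seq = random_sequence(20_000, 8)
        ter = 10_001
        n = 300
        before = leading_strand_counts(seq, 1, ter)
        state = run_simulation(seq, 1, PointModel(ter), max_cycles=n,
                               seed=9)
        after = leading_strand_counts(state.sequence(), 1, ter)
        assert after["G"] - before["G"] == n
        assert before["C"] - after["C"] == n

    def test_determinism_byte_identical(self):
        seq = random_sequence(5_000, 10)
        runs = [run_simulation(seq, 1, PointModel(2_501), max_cycles=100,
                               seed=11).sequence().seq for _ in range(2)]
        assert runs[0] == runs[1]
        other = run_simulation(seq, 1, PointModel(2_501), max_cycles=100,
                               seed=12).sequence().seq
        assert other != runs[0]

    def test_snapshots_recorded(self):
        seq = random_sequence(4_096, 13)
        state = run_simulation(seq, 1, PointModel(2_049), max_cycles=30,
                               snapshot_cycles=[0, 10, 30], seed=14,
                               window_count=16)
        assert [t for t, _ in state.snapshots] == [0, 10, 30]
        assert all(p.window_count == 16 for _, p in state.snapshots)
        with pytest.raises(InputError):
            run_simulation(seq, 1, PointModel(2_049), max_cycles=5,
                           snapshot_cycles=[9], seed=0)

    def test_gcsi_nondecreasing_over_snapshots(self, fixture_200k):
        # mutation load strengthens the skew signal monotonically
        seq, ann, truth = fixture_200k
        from gcskewsim import shuffle_sequence
        flat = shuffle_sequence(seq, 20)
        snaps = [0, 400, 800, 1200, 1680]
        values = []
        for t in snaps:
            # same seed: shorter runs are prefixes of longer ones
            st = run_simulation(flat, ann.ori, PointModel(truth["ter"]),
                                max_cycles=t, seed=21)
            cur = st.sequence()
            values.append(gcsi(gc_skew(cur, 64), cur, ori=ann.ori,
                               ter=truth["ter"]).gcsi)
        rho = stats.spearmanr(snaps, values).statistic
        assert rho > 0.9

    def test_round_trip_cycle_recovery(self, fixture_200k):
        seq, ann, truth = fixture_200k
        req = required_cycles(
            base_counts(seq),
            leading_strand_counts(seq, ann.ori, truth["ter"]))
        assert abs(req - truth["planted_cycles"]) <= 0.005 * seq.length

    def test_conservation_across_full_run(self, fixture_200k):
        seq, ann, truth = fixture_200k
        from gcskewsim import shuffle_sequence
        flat = shuffle_sequence(seq, 22)
        state = run_simulation(flat, ann.ori, PointModel(truth["ter"]),
                               max_cycles=500, seed=23)
        b, a = base_counts(flat), base_counts(state.sequence())
        assert (a["A"], a["T"], a["G"] + a["C"]) == \
            (b["A"], b["T"], b["G"] + b["C"])
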