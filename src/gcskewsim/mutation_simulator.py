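"""Iterative leading-strand C→G mutation engine.

Each simulation cycle: draw a terminus from the termination model,
partition the circle into two replichores at (ori, terminus), pick one
random eligible position — a published-strand C on the arm whose leading
strand is the published strand, or a published-strand G on the other arm
— and flip it (C→G, respectively G→C on the published strand, which is
the same C→G event viewed from that arm's leading strand). A and T
counts and the G+C total are invariant by construction.

Eligible positions are found by rejection sampling (draw a uniform
position, accept if eligible): roughly a quarter of all positions are
eligible in practice, so the expected cost per cycle is O(1) and no
index needs rebuilding when the terminus moves between cycles.

Randomness is split into two seeded streams. The *position* stream
consumes a fixed block of candidate draws per cycle regardless of where
acceptance happens, and the *terminus* stream feeds the termination
model. Two runs started from the same sequence and seed but different
models therefore see identical candidate positions cycle for cycle and
diverge only where their terminus draws disagree — common-random-number
coupling that makes model comparisons on one replicon nearly noise-free,
extending the design of reusing one shuffled sequence per organism.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np

from .errors import DegenerateSignalError, InputError, SimulationStallError
from .genome_io import CircularSequence, CodingMask
from .skew_metrics import gc_skew

_C, _G = ord("C"), ord("G")
#: candidate positions consumed per cycle (fixed, to keep coupled runs
#: aligned); all 64 ineligible at ~25% eligibility has probability ~1e-8
_POS_PER_CYCLE = 64
_CYCLES_PER_CHUNK = 128


# ---------------------------------------------------------------------------
# cycle-count rule
# ---------------------------------------------------------------------------

def required_cycles(whole_counts: Mapping[str, int],
                    leading_counts: Mapping[str, int]) -> int:
    """Number of C→G cycles needed to reproduce the observed strand bias.

    This is the absolute G (equivalently C) difference between the
    combined leading strands and the whole genome. The two computations
    must agree exactly — each simulated mutation adds one leading-strand
    G and removes one leading-strand C while leaving A/T untouched.
    """
    d_g = leading_counts["G"] - whole_counts["G"]
    d_c = whole_counts["C"] - leading_counts["C"]
    if d_g != d_c:
        raise InputError(
            f"inconsistent counts: G excess {d_g} != C deficit {d_c}")
    return abs(d_g)


# ---------------------------------------------------------------------------
# strand partition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StrandPartition:
    """The two replichores induced by an (ori, terminus) pair.

    ``arm1`` runs from ori forward (increasing coordinates, wrapping) up
    to but excluding the terminus and has its leading strand on the
    published strand; ``arm2`` is the complement, its leading strand
    being the complementary strand. Intervals are 1-based inclusive.
    """

    ori: int
    ter: int
    genome_length: int

    def __post_init__(self) -> None:
        if self.ori == self.ter:
            raise DegenerateSignalError("ori == ter: no strand partition")
        for pos in (self.ori, self.ter):
            if not (1 <= pos <= self.genome_length):
                raise InputError(f"position {pos} outside the genome")

    @property
    def arm1(self) -> Tuple[int, int]:
        return self.ori, (self.ter - 2) % self.genome_length + 1

    @property
    def arm2(self) -> Tuple[int, int]:
        return self.ter, (self.ori - 2) % self.genome_length + 1

    @property
    def arm1_length(self) -> int:
        return (self.ter - self.ori) % self.genome_length

    def in_arm1(self, position: int) -> bool:
        return ((position - self.ori) % self.genome_length) < \
            self.arm1_length


def partition_strands(ori: int, ter: int,
                      genome_length: int) -> StrandPartition:
    """Replichore partition for a given origin and terminus."""
    return StrandPartition(ori=ori, ter=ter, genome_length=genome_length)


# ---------------------------------------------------------------------------
# simulation state
# ---------------------------------------------------------------------------

class SimulationState:
    """Mutable state of one mutation-simulation run."""

    def __init__(self, seq: CircularSequence, ori: int, model,
                 max_cycles: int, seed: int,
                 mask: Optional[CodingMask] = None):
        if max_cycles < 0:
            raise InputError("max_cycles must be >= 0")
        if not (1 <= ori <= seq.length):
            raise InputError(f"ori {ori} outside [1, {seq.length}]")
        self.source_id = seq.id
        self.ori = ori
        self.model = model
        self.max_cycles = max_cycles
        self.seed = seed
        self.cycle = 0
        root = np.random.SeedSequence(seed)
        ter_seed, pos_seed = root.spawn(2)
        self.rng = np.random.default_rng(ter_seed)       # termini, fallback
        self._pos_rng = np.random.default_rng(pos_seed)  # candidate stream
        self.snapshots: list = []
        self._arr = bytearray(seq.seq.encode("ascii"))
        self._L = seq.length
        self._mask_bytes = (bytes(mask.include.astype(np.uint8))
                            if mask is not None else None)
        if mask is not None and mask.genome_length != seq.length:
            raise InputError("mask length != genome length")
        self._pos_buf: list = []
        self._pos_i = 0
        self._ter_buf: list = []
        self._ter_i = 0

    # -- buffered draws ----------------------------------------------------
    def _next_position_block(self) -> tuple:
        """One cycle's fixed-size block of candidate positions (0-based)."""
        if self._pos_i >= len(self._pos_buf):
            self._pos_buf = self._pos_rng.integers(
                0, self._L, size=_POS_PER_CYCLE * _CYCLES_PER_CHUNK,
                dtype=np.int64).tolist()
            self._pos_i = 0
        block = self._pos_buf[self._pos_i:self._pos_i + _POS_PER_CYCLE]
        self._pos_i += _POS_PER_CYCLE
        return block

    def _next_terminus(self) -> int:
        if self._ter_i >= len(self._ter_buf):
            n = min(_POS_PER_CYCLE * _CYCLES_PER_CHUNK,
                    max(1, self.max_cycles - self.cycle))
            self._ter_buf = self.model.sample_batch(self._L, self.rng,
                                                    n).tolist()
            self._ter_i = 0
        t = self._ter_buf[self._ter_i]
        self._ter_i += 1
        return t

    # -- views -------------------------------------------------------------
    def sequence(self) -> CircularSequence:
        return CircularSequence(self.source_id + "|sim",
                                self._arr.decode("ascii"))

    def _eligible_positions(self, ori0: int, arm1_len: int) -> np.ndarray:
        arr = np.frombuffer(bytes(self._arr), dtype=np.uint8)
        d = (np.arange(self._L) - ori0) % self._L
        in_arm1 = d < arm1_len
        eligible = np.where(in_arm1, arr == _C, arr == _G)
        if self._mask_bytes is not None:
            eligible &= np.frombuffer(self._mask_bytes,
                                      dtype=np.uint8).astype(bool)
        return np.flatnonzero(eligible)


def mutate_one_cycle(state: SimulationState) -> SimulationState:
    """Apply one terminus draw and one leading-strand C→G flip in place."""
    if state.cycle >= state.max_cycles:
        raise InputError("simulation already at max_cycles")
    ter = state._next_terminus()
    L = state._L
    ori0 = state.ori - 1
    arm1_len = (ter - state.ori) % L
    if arm1_len == 0:
        raise DegenerateSignalError("sampled terminus equals ori")
    arr = state._arr
    mask = state._mask_bytes
    for pos in state._next_position_block():
        base = arr[pos]
        if (pos - ori0) % L < arm1_len:
            if base == _C and (mask is None or mask[pos]):
                arr[pos] = _G
                break
        elif base == _G and (mask is None or mask[pos]):
            arr[pos] = _C
            break
    else:
        # the whole candidate block was ineligible: fall back to an exact
        # uniform draw over the eligible set (terminus stream, so the
        # per-cycle alignment of the position stream is preserved)
        eligible = state._eligible_positions(ori0, arm1_len)
        if eligible.size == 0:
            raise SimulationStallError(
                f"no eligible position at cycle {state.cycle} "
                f"(terminus {ter})")
        pos = int(eligible[state.rng.integers(0, eligible.size)])
        arr[pos] = _G if arr[pos] == _C else _C
    state.cycle += 1
    return state


def run_simulation(seq: CircularSequence, ori: int, model, max_cycles: int,
                   snapshot_cycles: Iterable[int] = (), seed: int = 0,
                   mask: Optional[CodingMask] = None,
                   window_count: Optional[int] = None) -> SimulationState:
    """Run the full mutation simulation on an already-shuffled sequence.

    ``snapshot_cycles`` lists cycle counts at which a windowed skew
    profile of the current sequence is recorded (cycle 0 is the input).
    The run is fully reproducible from ``seed``; all model draws and
    position draws come from one seeded stream.
    """
    state = SimulationState(seq, ori, model, max_cycles, seed, mask=mask)
    snaps = sorted(set(int(t) for t in snapshot_cycles))
    bad = [t for t in snaps if t < 0 or t > max_cycles]
    if bad:
        raise InputError(f"snapshot cycles outside [0, {max_cycles}]: {bad}")
    if window_count is None:
        window_count = 4096
        while window_count > seq.length:
            window_count //= 2
    if snaps and snaps[0] == 0:
        state.snapshots.append((0, gc_skew(state.sequence(), window_count,
                                           mask=mask)))
        snaps = snaps[1:]
    for _ in range(max_cycles):
        mutate_one_cycle(state)
        if snaps and state.cycle == snaps[0]:
            state.snapshots.append(
                (state.cycle, gc_skew(state.sequence(), window_count,
                                      mask=mask)))
            snaps = snaps[1:]
    return state
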