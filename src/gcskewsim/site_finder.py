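"""Ter-site discovery by degenerate consensus matching on the circle.

Matching uses 4-bit base masks (one bit per standard base), so IUPAC
codes match their base sets exactly and "free" pattern positions match
anything. Circular wrap is handled by scanning the sequence doubled by
the pattern length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import InputError
from .genome_io import CircularSequence, TerSite, circular_distance

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}
_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}
_COMPLEMENT_BIT = {1: 8, 2: 4, 4: 2, 8: 1}


@dataclass(frozen=True)
class ConsensusPattern:
    """A degenerate consensus with optional fully-free positions.

    ``free_positions`` are 1-based offsets inside the pattern where any
    base is accepted (the reading of "allows mutations at bases 1, 4 and
    16" as positions); ``max_mismatches`` switches to the alternative
    reading, a global per-match mismatch budget.
    """

    iupac: str
    free_positions: frozenset = frozenset()
    max_mismatches: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        pat = self.iupac.upper()
        if not pat:
            raise InputError("empty consensus pattern")
        bad = set(pat) - set(IUPAC_SETS)
        if bad:
            raise InputError(f"invalid IUPAC characters {sorted(bad)}")
        if not set(self.free_positions) <= set(range(1, len(pat) + 1)):
            raise InputError("free_positions outside the pattern")
        object.__setattr__(self, "iupac", pat)
        object.__setattr__(self, "free_positions",
                           frozenset(self.free_positions))

    def __len__(self) -> int:
        return len(self.iupac)

    def bitmasks(self) -> np.ndarray:
        """Per-position acceptance bitmask (free positions accept all)."""
        masks = np.empty(len(self.iupac), dtype=np.uint8)
        for i, ch in enumerate(self.iupac):
            if (i + 1) in self.free_positions:
                masks[i] = 15
            else:
                masks[i] = sum(_BITS[b] for b in IUPAC_SETS[ch])
        return masks

    def reverse_complement_bitmasks(self) -> np.ndarray:
        fwd = self.bitmasks()
        rc = np.zeros_like(fwd)
        for i, m in enumerate(fwd[::-1]):
            out = 0
            for bit in (1, 2, 4, 8):
                if m & bit:
                    out |= _COMPLEMENT_BIT[bit]
            rc[i] = out
        return rc


# Tus-bound consensus of E. coli; positions 1, 4 and 16 are free
# (position 3 is already N).
ECOLI_TER = ConsensusPattern("AGNATGTTGTAAYKAA",
                             free_positions=frozenset({1, 4, 16}),
                             name="Ecoli_Tus")
# RTP-bound consensus of B. subtilis.
BSUBTILIS_TER = ConsensusPattern("KMACTAANWNNWCTATGTACYAAATNTTC",
                                 name="Bsubtilis_RTP")
TER_PRESETS = {"ecoli": ECOLI_TER, "bsubtilis": BSUBTILIS_TER}


def _seq_bits(seq: CircularSequence) -> np.ndarray:
    arr = seq.to_array()
    bits = np.zeros(arr.size, dtype=np.uint8)
    for base, bit in _BITS.items():
        bits[arr == ord(base)] = bit
    for code, bases in IUPAC_SETS.items():
        if code in _BITS:
            continue
        mask = sum(_BITS[b] for b in bases)
        bits[arr == ord(code)] = mask
    return bits


def _scan(bits_doubled: np.ndarray, pattern_bits: np.ndarray,
          genome_length: int, budget: int) -> np.ndarray:
    """0-based start offsets of circular matches with ≤ budget mismatches."""
    m = pattern_bits.size
    mism = np.zeros(genome_length, dtype=np.int32)
    for j in range(m):
        window = bits_doubled[j:j + genome_length]
        mism += ((window & pattern_bits[j]) == 0)
    return np.flatnonzero(mism <= budget)


def find_ter_sites(seq: CircularSequence,
                   pattern: ConsensusPattern) -> List[Tuple[int, str]]:
    """All circular matches of the consensus on both strands.

    Returns ``(position, strand)`` pairs, position being the match's
    first base (1-based) in published-strand coordinates for both
    orientations; ``strand`` is ``"+"`` or ``"-"``.
    """
    m = len(pattern)
    if m > seq.length:
        return []
    bits = _seq_bits(seq)
    doubled = np.concatenate([bits, bits[:m - 1]])
    hits = []
    for strand, pbits in (("+", pattern.bitmasks()),
                          ("-", pattern.reverse_complement_bitmasks())):
        for start in _scan(doubled, pbits, seq.length,
                           pattern.max_mismatches):
            hits.append((int(start) + 1, strand))
    hits.sort()
    return hits


def assign_blocking_arms(sites: Sequence, ori: int, genome_length: int,
                         names: Optional[Sequence[str]] = None
                         ) -> List[TerSite]:
    """Label matches with the replichore arm they arrest and order them.

    A ``+``-strand match presents its non-permissive face to the fork
    travelling in increasing coordinates (the "clockwise" fork); a
    ``-``-strand match arrests the opposite fork. Sites are ordered by
    circular distance from the locus opposite the origin, so the
    innermost trap — the one furthermost from the origin and first
    encountered by an over-travelling fork — sorts first.
    """
    if not (1 <= ori <= genome_length):
        raise InputError(f"ori {ori} outside [1, {genome_length}]")
    opposite = (ori - 1 + genome_length // 2) % genome_length + 1
    out = []
    for k, (pos, strand) in enumerate(sites):
        arm = "clockwise" if strand == "+" else "counterclockwise"
        name = names[k] if names is not None else f"Ter{k + 1}"
        out.append(TerSite(name=name, position=int(pos), blocking_arm=arm))
    out.sort(key=lambda t: (circular_distance(t.position, opposite,
                                              genome_length), t.position))
    return out
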