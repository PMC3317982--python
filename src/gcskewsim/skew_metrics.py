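"""GC-skew curves, origin/terminus prediction, GCSI and RMSE.

Sign convention: skew is (C−G)/(C+G), so the cumulative curve *falls*
from origin to terminus along the replichore whose leading strand is the
published strand (leading strands are G-rich). A config flag flips the
convention for interoperability with (G−C)/(G+C) tools.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateSignalError, InputError
from .genome_io import CircularSequence, CodingMask

#: default window count for whole-genome GCSI (power of two for the FFT)
DEFAULT_WINDOW_COUNT = 4096
#: window count used for plasmid screening
PLASMID_WINDOW_COUNT = 64
#: normalization constants of the GC skew index (see docs/methods.md)
GCSI_SR_NORM = 6000.0
GCSI_DIST_NORM = 600.0
#: default multiplier applied to raw-skew RMSE (skew expressed in percent)
RMSE_SCALE = 100.0

_C, _G = ord("C"), ord("G")


@dataclass(frozen=True)
class SkewProfile:
    """Windowed GC-skew curve of one replicon.

    ``skew[k]`` is (C−G)/(C+G) over the masked-in positions of window
    ``k``; ``cumulative`` is its running sum. Windows tile the circle
    evenly; the last window absorbs the division remainder.
    """

    window_count: int
    window_size: int
    skew: np.ndarray
    source_id: str = ""
    convention: str = "C-G"
    cumulative: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        skew = np.asarray(self.skew, dtype=float)
        if skew.size != self.window_count:
            raise InputError("skew vector length != window_count")
        object.__setattr__(self, "skew", skew)
        object.__setattr__(self, "cumulative", np.cumsum(skew))

    def to_frame(self) -> pd.DataFrame:
        starts = np.arange(self.window_count) * self.window_size + 1
        ends = np.append(starts[1:] - 1,
                         starts[0] + self.window_count * self.window_size - 1)
        return pd.DataFrame({"window_start": starts, "window_end": ends,
                             "skew": self.skew,
                             "cumulative": self.cumulative})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class GcsiResult:
    """GC skew index and its two ingredients.

    ``spectral_ratio`` is the power at one cycle per genome divided by the
    mean spectral power; ``strand_distance`` is the per-mil Euclidean
    distance between the (G, C) content of the leading and lagging
    strands. GCSI > 0.05 marks visible skew, ≥ 0.1 the strict threshold.
    """

    gcsi: float
    spectral_ratio: float
    strand_distance: float
    sr_norm: float = GCSI_SR_NORM
    dist_norm: float = GCSI_DIST_NORM

    def to_json(self) -> str:
        return json.dumps({"gcsi": self.gcsi,
                           "spectral_ratio": self.spectral_ratio,
                           "strand_distance": self.strand_distance,
                           "sr_norm": self.sr_norm,
                           "dist_norm": self.dist_norm})


# ---------------------------------------------------------------------------
# skew curves
# ---------------------------------------------------------------------------

def gc_skew(seq: CircularSequence, window_count: int = DEFAULT_WINDOW_COUNT,
            mask: Optional[CodingMask] = None,
            convention: str = "C-G") -> SkewProfile:
    """Windowed GC skew of the published strand.

    Windows with no C or G among masked-in positions score 0. With a
    GC3/non-coding mask, only third codon positions and intergenic
    positions contribute.
    """
    if window_count < 2:
        raise InputError("window_count must be >= 2")
    if window_count > seq.length:
        raise InputError(f"window_count {window_count} exceeds genome "
                         f"length {seq.length}")
    if convention not in ("C-G", "G-C"):
        raise ConfigError(f"unknown skew convention {convention!r}")
    arr = seq.to_array()
    c = (arr == _C).astype(np.int64)
    g = (arr == _G).astype(np.int64)
    if mask is not None:
        if mask.genome_length != seq.length:
            raise InputError("mask length != genome length")
        c = c * mask.include
        g = g * mask.include
    w = seq.length // window_count
    bounds = np.arange(window_count) * w  # last window absorbs remainder
    c_w = np.add.reduceat(c, bounds).astype(float)
    g_w = np.add.reduceat(g, bounds).astype(float)
    denom = c_w + g_w
    with np.errstate(invalid="ignore", divide="ignore"):
        skew = np.where(denom > 0, (c_w - g_w) / denom, 0.0)
    if convention == "G-C":
        skew = -skew
    return SkewProfile(window_count=window_count, window_size=w, skew=skew,
                       source_id=seq.id, convention=convention)


def cumulative_skew(seq: CircularSequence) -> np.ndarray:
    """Per-base cumulative (C−G) curve: +1 for C, −1 for G, 0 otherwise."""
    arr = seq.to_array()
    step = (arr == _C).astype(np.int64) - (arr == _G).astype(np.int64)
    return np.cumsum(step)


def find_ori_ter(seq: CircularSequence) -> Tuple[int, int]:
    """Predict origin and terminus from the cumulative skew at 1-bp
    resolution.

    Under the (C−G) convention the leading strand is G-rich, so the
    cumulative curve falls from origin to terminus: the origin is the
    argmax, the terminus the argmin. Ties break toward the smallest
    coordinate; positions are 1-based.
    """
    cum = cumulative_skew(seq)
    hi, lo = cum.max(), cum.min()
    if hi == lo:
        raise DegenerateSignalError("cumulative skew is flat; no origin/"
                                    "terminus signal")
    return int(np.argmax(cum)) + 1, int(np.argmin(cum)) + 1


# ---------------------------------------------------------------------------
# leading-strand accounting
# ---------------------------------------------------------------------------

def leading_strand_counts(seq: CircularSequence, ori: int, ter: int,
                          mask: Optional[CodingMask] = None) -> dict:
    """Base counts of the combined leading strands.

    The arm running from ``ori`` (inclusive) forward to ``ter``
    (exclusive) has its leading strand on the published strand; on the
    complementary arm the leading strand is the complement, so published
    C counts as leading G and vice versa. The two arm boundaries are
    half-open at ``ter`` and at ``ori``. With a mask, only masked-in
    positions are counted (used for GC3/non-coding cycle counting).
    """
    L = seq.length
    if ori == ter:
        raise InputError("ori == ter gives no strand partition")
    arr = seq.to_array()
    d = (np.arange(L) - (ori - 1)) % L
    arm1 = d < ((ter - ori) % L)
    keep = np.ones(L, dtype=bool)
    if mask is not None:
        if mask.genome_length != L:
            raise InputError("mask length != genome length")
        keep = mask.include
    out = {}
    for base, comp in (("A", "T"), ("C", "G"), ("G", "C"), ("T", "A")):
        pub = int(((arr == ord(base)) & arm1 & keep).sum())
        rev = int(((arr == ord(comp)) & ~arm1 & keep).sum())
        out[base] = pub + rev
    return out


# ---------------------------------------------------------------------------
# GCSI
# ---------------------------------------------------------------------------

def spectral_ratio(skew: np.ndarray) -> float:
    """Fundamental-frequency power over mean power of a skew vector."""
    spec = np.abs(np.fft.fft(np.asarray(skew, dtype=float))) ** 2
    mean_power = spec[1:].mean()
    if mean_power == 0:
        return 0.0
    return float(spec[1] / mean_power)


def spectral_amplitude(seq: CircularSequence,
                       window_count: int = PLASMID_WINDOW_COUNT) -> float:
    """One-cycle Fourier amplitude of the per-window (C−G) count vector.

    This is the quantity thresholded during plasmid screening (window
    size 64, amplitude ≥ 1000 by default).
    """
    if window_count > seq.length:
        raise InputError("window_count exceeds genome length")
    arr = seq.to_array()
    diff = (arr == _C).astype(np.int64) - (arr == _G).astype(np.int64)
    w = seq.length // window_count
    bounds = np.arange(window_count) * w
    counts = np.add.reduceat(diff, bounds).astype(float)
    return float(np.abs(np.fft.fft(counts)[1]))


def gcsi(profile: SkewProfile, seq: CircularSequence,
         ori: Optional[int] = None, ter: Optional[int] = None,
         sr_norm: float = GCSI_SR_NORM,
         dist_norm: float = GCSI_DIST_NORM) -> GcsiResult:
    """GC skew index: geometric mean of spectral and compositional terms.

    The spectral term asks how closely the windowed skew conforms to one
    sine cycle per genome (FFT power concentration at the fundamental);
    the compositional term is the per-mil Euclidean distance between the
    leading- and lagging-strand (G, C) content. When ``ori``/``ter`` are
    not supplied they are predicted from the cumulative skew.
    """
    n = profile.window_count
    if n < 2 or (n & (n - 1)) != 0:
        raise ConfigError(f"GCSI requires a power-of-two window count, "
                          f"got {n}")
    sr = spectral_ratio(profile.skew)
    if ori is None or ter is None:
        ori, ter = find_ori_ter(seq)
    lead = leading_strand_counts(seq, ori, ter)
    L = seq.length
    g_lead, c_lead = lead["G"] / L, lead["C"] / L
    # lagging strand is the complement read of the same arms: G and C swap
    dist = float(np.hypot(g_lead - c_lead, c_lead - g_lead)) * 1000.0
    value = float(np.sqrt(max(sr, 0.0) / sr_norm * dist / dist_norm))
    return GcsiResult(gcsi=value, spectral_ratio=sr, strand_distance=dist,
                      sr_norm=sr_norm, dist_norm=dist_norm)


# ---------------------------------------------------------------------------
# RMSE
# ---------------------------------------------------------------------------

def rmse(a: SkewProfile, b: SkewProfile, scale: float = RMSE_SCALE) -> float:
    """Root-mean-square difference between two skew curves.

    ``scale`` multiplies the raw skew difference; the default 100
    expresses skew in percent, the convention under which a flat curve
    versus a typical natural genome scores in the single digits.
    """
    if a.window_count != b.window_count:
        raise InputError(f"window counts differ: {a.window_count} vs "
                         f"{b.window_count}")
    diff = (a.skew - b.skew) * scale
    return float(np.sqrt(np.mean(diff ** 2)))
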