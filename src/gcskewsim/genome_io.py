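"""Sequence and annotation I/O for circular bacterial replicons.

Coordinates are 1-based inclusive on the published (record) strand
throughout the package; circular intervals wrap through position 1.
Ambiguity codes (N, R, Y, ...) are retained on input but are excluded
from skew numerators/denominators and from mutation eligibility
downstream, since only unambiguous C/G calls carry skew information.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import FormatError, InputError

STANDARD_BASES = ("A", "C", "G", "T")

# byte codes used by the mutation engine and the counting routines
_A, _C, _G, _T = (ord(b) for b in STANDARD_BASES)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CircularSequence:
    """A circular replicon sequence on its published strand.

    Parameters
    ----------
    id
        Record identifier (FASTA/GenBank accession or a synthetic label).
    seq
        Upper-cased nucleotide string. Standard bases are ``A C G T``;
        IUPAC ambiguity codes are tolerated but treated as uninformative.
    """

    id: str
    seq: str
    topology: str = "circular"

    def __post_init__(self) -> None:
        if len(self.seq) == 0:
            raise InputError(f"empty sequence for record {self.id!r}")
        object.__setattr__(self, "seq", self.seq.upper())

    @property
    def length(self) -> int:
        return len(self.seq)

    def to_array(self) -> np.ndarray:
        """Sequence as a uint8 byte array (zero-copy view of the ASCII)."""
        return np.frombuffer(self.seq.encode("ascii"), dtype=np.uint8)

    def rotated(self, offset: int) -> "CircularSequence":
        """Sequence rotated so old position ``offset+1`` becomes position 1."""
        k = offset % self.length
        return CircularSequence(self.id, self.seq[k:] + self.seq[:k],
                                self.topology)


@dataclass(frozen=True)
class TerSite:
    """A replication-fork trap element (Ter/Tus or Ter/RTP site).

    ``blocking_arm`` names the replichore whose fork the site arrests:
    ``"clockwise"`` for the fork travelling in increasing published-strand
    coordinates, ``"counterclockwise"`` for the opposite fork.
    """

    name: str
    position: int
    blocking_arm: str

    def __post_init__(self) -> None:
        if self.blocking_arm not in ("clockwise", "counterclockwise"):
            raise InputError(
                f"blocking_arm must be clockwise/counterclockwise, "
                f"got {self.blocking_arm!r}")


@dataclass(frozen=True)
class SiteAnnotation:
    """Replication landmark positions for one replicon.

    ``ori`` is the replication origin, ``dif`` the chromosome-dimer
    resolution site, ``shift_point`` the GC-skew shift point used by the
    shift-point control model. All positions are 1-based.
    """

    genome_length: int
    ori: int
    dif: Optional[int] = None
    shift_point: Optional[int] = None
    ter_sites: Tuple[TerSite, ...] = ()

    def __post_init__(self) -> None:
        for pos in (self.ori, self.dif, self.shift_point,
                    *(t.position for t in self.ter_sites)):
            if pos is not None and not (1 <= pos <= self.genome_length):
                raise InputError(
                    f"position {pos} outside [1, {self.genome_length}]")
        names = [t.name for t in self.ter_sites]
        if len(names) != len(set(names)):
            raise InputError("Ter site names must be unique")

    @property
    def opposite_ori(self) -> int:
        """Locus diametrically opposite the origin (1-based)."""
        return (self.ori - 1 + self.genome_length // 2) % self.genome_length + 1


@dataclass(frozen=True)
class CdsFeature:
    """A protein-coding feature used for GC3/non-coding mask building.

    ``parts`` are (start, end) 1-based inclusive genomic intervals listed
    in coding order for the forward strand and in genomic order for the
    reverse strand (Biopython convention); ``frame`` is the 0-based offset
    of the first complete codon (``codon_start`` − 1). A feature wrapping
    through position 1 must set ``wraps=True`` on the wrapping part.
    """

    parts: Tuple[Tuple[int, int], ...]
    strand: int  # +1 or -1
    frame: int = 0
    wraps: bool = False

    def __post_init__(self) -> None:
        if self.strand not in (1, -1):
            raise InputError(f"strand must be +1/-1, got {self.strand}")
        for start, end in self.parts:
            if end < start and not self.wraps:
                raise InputError(
                    f"CDS part end {end} < start {start} without wrap flag")

    def genomic_positions_coding_order(self, genome_length: int) -> np.ndarray:
        """1-based genomic positions of the CDS in coding (5'→3') order."""
        spans = []
        for start, end in self.parts:
            if end >= start:
                spans.append(np.arange(start, end + 1))
            else:  # wraps through the origin of coordinates
                spans.append(np.concatenate(
                    [np.arange(start, genome_length + 1),
                     np.arange(1, end + 1)]))
        pos = np.concatenate(spans)
        if self.strand == -1:
            pos = pos[::-1]
        return pos


@dataclass(frozen=True)
class CodingMask:
    """Boolean inclusion vector: third codon positions plus intergenic."""

    include: np.ndarray  # bool, one entry per genome position

    def __post_init__(self) -> None:
        object.__setattr__(self, "include",
                           np.asarray(self.include, dtype=bool))

    @property
    def genome_length(self) -> int:
        return int(self.include.size)

    def cardinality(self) -> int:
        return int(self.include.sum())


# ---------------------------------------------------------------------------
# circular interval helpers
# ---------------------------------------------------------------------------

def circular_interval_positions(start: int, end: int,
                                genome_length: int) -> np.ndarray:
    """1-based positions of the inclusive circular interval start..end."""
    _check_pos(start, genome_length)
    _check_pos(end, genome_length)
    if end >= start:
        return np.arange(start, end + 1)
    return np.concatenate([np.arange(start, genome_length + 1),
                           np.arange(1, end + 1)])


def circular_interval_length(start: int, end: int, genome_length: int) -> int:
    return (end - start) % genome_length + 1


def _check_pos(pos: int, genome_length: int) -> None:
    if not (1 <= pos <= genome_length):
        raise InputError(f"position {pos} outside [1, {genome_length}]")


def circular_distance(a: int, b: int, genome_length: int) -> int:
    """Shortest circular distance in bp between positions ``a`` and ``b``."""
    d = abs(a - b) % genome_length
    return min(d, genome_length - d)


# ---------------------------------------------------------------------------
# sequence reading
# ---------------------------------------------------------------------------

def read_sequences(path, format: str = "fasta"):
    """Read replicon sequences (and CDS features for GenBank input).

    Parameters
    ----------
    path
        File path or open text handle.
    format
        ``"fasta"`` or ``"genbank"``.

    Returns
    -------
    list of CircularSequence
        For ``fasta`` input. Record order is preserved.
    list of (CircularSequence, list of CdsFeature)
        For ``genbank`` input.
    """
    if format not in ("fasta", "genbank"):
        raise FormatError(f"unsupported format {format!r}")
    try:
        records = list(SeqIO.parse(path, format))
    except Exception as exc:  # Biopython raises assorted ValueErrors
        raise FormatError(f"could not parse {path!r} as {format}: {exc}")
    if not records:
        raise FormatError(f"no records found in {path!r}")
    out = []
    for rec in records:
        seq = str(rec.seq).upper()
        if not seq:
            raise InputError(f"empty record {rec.id!r} in {path!r}")
        cs = CircularSequence(rec.id, seq)
        if format == "genbank":
            out.append((cs, _extract_cds(rec, cs.length)))
        else:
            out.append(cs)
    return out


def _extract_cds(record, genome_length: int):
    feats = []
    for feat in record.features:
        if feat.type != "CDS":
            continue
        strand = 1 if (feat.location.strand or 1) >= 0 else -1
        parts = tuple((int(p.start) + 1, int(p.end))
                      for p in feat.location.parts)
        codon_start = feat.qualifiers.get("codon_start", ["1"])[0]
        frame = int(codon_start) - 1
        wraps = any(e < s for s, e in parts)
        feats.append(CdsFeature(parts=parts, strand=strand, frame=frame,
                                wraps=wraps))
    return feats


def write_fasta(seqs: Union[CircularSequence, Iterable[CircularSequence]],
                path, width: int = 70) -> None:
    if isinstance(seqs, CircularSequence):
        seqs = [seqs]
    handle = open(path, "w") if not isinstance(path, io.TextIOBase) else path
    close = handle is not path
    try:
        for s in seqs:
            handle.write(f">{s.id}\n")
            for i in range(0, s.length, width):
                handle.write(s.seq[i:i + width] + "\n")
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# counting and shuffling
# ---------------------------------------------------------------------------

def base_counts(seq: CircularSequence,
                region: Optional[Tuple[int, int]] = None) -> dict:
    """Counts of each base on the published strand.

    ``region`` is a 1-based inclusive circular interval ``(start, end)``;
    ``end < start`` wraps through position 1. Counts of all characters
    present are returned, with the four standard bases always included.
    """
    arr = seq.to_array()
    if region is not None:
        start, end = region
        _check_pos(start, seq.length)
        _check_pos(end, seq.length)
        if end >= start:
            arr = arr[start - 1:end]
        else:
            arr = np.concatenate([arr[start - 1:], arr[:end]])
    values, counts = np.unique(arr, return_counts=True)
    out = {base: 0 for base in STANDARD_BASES}
    for v, c in zip(values, counts):
        out[chr(v)] = int(c)
    return out


def shuffle_sequence(seq: CircularSequence, seed: int) -> CircularSequence:
    """Composition-preserving random permutation of the sequence.

    Uses a seeded Fisher–Yates shuffle (numpy ``Generator.permutation``),
    so the same ``(seq, seed)`` always yields the same output and the base
    multiset is exactly preserved. This is the step that erases all
    replication strand bias before a simulation starts.
    """
    rng = np.random.default_rng(seed)
    arr = rng.permutation(seq.to_array())
    return CircularSequence(seq.id + "|shuffled", arr.tobytes().decode("ascii"))


# ---------------------------------------------------------------------------
# GC3 / non-coding mask
# ---------------------------------------------------------------------------

def build_gc3_noncoding_mask(seq_or_length,
                             cds_features: Sequence[CdsFeature]) -> CodingMask:
    """Mask keeping third codon positions and intergenic positions.

    A position inside one or more CDS is kept only if every covering CDS
    places it at a third codon position on its own coding strand; frame
    conflicts between overlapping CDS therefore exclude the position.
    Positions covered by no CDS (intergenic) are always kept.
    """
    length = (seq_or_length.length
              if isinstance(seq_or_length, CircularSequence)
              else int(seq_or_length))
    covered = np.zeros(length, dtype=np.int32)
    third = np.zeros(length, dtype=np.int32)
    for feat in cds_features:
        pos = feat.genomic_positions_coding_order(length)
        idx = pos - 1
        covered_slice = np.zeros(length, dtype=bool)
        covered_slice[idx] = True  # overlapping self-parts counted once
        covered += covered_slice
        coding_index = np.arange(pos.size)
        is_third = (coding_index >= feat.frame) & \
                   ((coding_index - feat.frame) % 3 == 2)
        third_idx = idx[is_third]
        third[third_idx] += 1
    include = (covered == 0) | ((covered > 0) & (third == covered))
    return CodingMask(include=include)


def mask_to_bed(mask: CodingMask, chrom: str) -> str:
    """Serialize included runs as BED (0-based half-open on export only)."""
    inc = mask.include
    edges = np.flatnonzero(np.diff(np.concatenate([[0], inc.view(np.int8),
                                                   [0]])))
    starts, ends = edges[0::2], edges[1::2]
    lines = [f"{chrom}\t{s}\t{e}" for s, e in zip(starts, ends)]
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# annotation tables
# ---------------------------------------------------------------------------

_SITE_COLUMNS = ["replicon_id", "site_type", "name", "position",
                 "blocking_arm"]


def read_site_annotations(path,
                          genome_lengths: Mapping[str, int]) -> dict:
    """Read a site-annotation TSV into SiteAnnotation objects per replicon.

    Expected columns: replicon_id, site_type (ori|dif|shift|ter), name,
    position, blocking_arm (Ter rows only).
    """
    df = pd.read_csv(path, sep="\t", dtype={"replicon_id": str, "name": str})
    missing = set(_SITE_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise FormatError(f"annotation table missing columns {sorted(missing)}")
    out = {}
    for rid, grp in df.groupby("replicon_id", sort=False):
        if rid not in genome_lengths:
            raise InputError(f"no genome length supplied for {rid!r}")
        ori = dif = shift = None
        ters = []
        for _, row in grp.iterrows():
            stype = str(row["site_type"]).lower()
            pos = int(row["position"])
            if stype == "ori":
                ori = pos
            elif stype == "dif":
                dif = pos
            elif stype == "shift":
                shift = pos
            elif stype == "ter":
                ters.append(TerSite(str(row["name"]), pos,
                                    str(row["blocking_arm"])))
            else:
                raise FormatError(f"unknown site_type {stype!r}")
        if ori is None:
            raise InputError(f"replicon {rid!r} has no ori row")
        out[rid] = SiteAnnotation(genome_length=int(genome_lengths[rid]),
                                  ori=ori, dif=dif, shift_point=shift,
                                  ter_sites=tuple(ters))
    return out


def write_site_annotations(annotations: Mapping[str, SiteAnnotation],
                           path) -> None:
    rows = []
    for rid, ann in annotations.items():
        rows.append((rid, "ori", "ori", ann.ori, ""))
        if ann.dif is not None:
            rows.append((rid, "dif", "dif", ann.dif, ""))
        if ann.shift_point is not None:
            rows.append((rid, "shift", "shift", ann.shift_point, ""))
        for t in ann.ter_sites:
            rows.append((rid, "ter", t.name, t.position, t.blocking_arm))
    pd.DataFrame(rows, columns=_SITE_COLUMNS).to_csv(path, sep="\t",
                                                     index=False)
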