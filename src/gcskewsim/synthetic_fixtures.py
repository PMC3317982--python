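"""Planted-truth synthetic genomes and calibration data.

The generator runs the forward process the simulator models: draw an
i.i.d. circular sequence with a chosen composition (no strand bias),
then apply a known number of leading-strand C→G mutations under a known
termination model. The planted parameters are returned as a truth
record, so origin/terminus recovery, cycle-count recovery and model
discrimination can all be tested without any real genome.

Default geometry mimics an E. coli-like replicon scaled to the fixture
length: the innermost trap sits just past the locus opposite the origin,
the second trap ~5.7% of the genome away on the other arm, further traps
outward, and the dif site slightly origin-proximal of the midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .errors import ConfigError
from .genome_io import CircularSequence, SiteAnnotation, TerSite
from .mutation_simulator import run_simulation
from .termination_models import (CollisionModel, ForkTrapModel, MixtureModel,
                                 PointModel)

#: mutation load as a fraction of genome length when planted_cycles is not
#: given: E. coli's leading-strand G excess is ~0.84% of its genome
DEFAULT_CYCLE_FRACTION = 0.0084

#: Ter geometry as signed offsets from the locus opposite the origin, in
#: fractions of genome length, with the arm each site blocks
DEFAULT_TER_GEOMETRY: Tuple[Tuple[str, float, str], ...] = (
    ("Ter1", +0.00073, "clockwise"),
    ("Ter2", -0.0569, "counterclockwise"),
    ("Ter3", +0.0169, "clockwise"),
    ("Ter4", -0.0700, "counterclockwise"),
    ("Ter5", -0.0850, "counterclockwise"),
)

#: one concrete realization of the Tus-bound consensus (free positions
#: and degenerate codes resolved), used when planting findable Ter copies
TER_CONSENSUS_REALIZATION = "AGAATGTTGTAATTAA"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one planted-truth genome."""

    length: int = 200_000
    base_composition: Tuple[float, float, float, float] = \
        (0.25, 0.25, 0.25, 0.25)  # A, C, G, T
    ori: int = 1
    terminus_model: Optional[object] = None
    planted_cycles: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1000:
            raise ConfigError("fixture length must be >= 1 kb")
        comp = np.asarray(self.base_composition, dtype=float)
        if comp.size != 4 or np.any(comp < 0) or \
                abs(comp.sum() - 1.0) > 1e-9:
            raise ConfigError("base_composition must be 4 probabilities "
                              "summing to 1")
        if not (1 <= self.ori <= self.length):
            raise ConfigError("ori outside the genome")

    @property
    def cycles(self) -> int:
        if self.planted_cycles is not None:
            return int(self.planted_cycles)
        return int(round(DEFAULT_CYCLE_FRACTION * self.length))


def expected_terminus(model, genome_length: int) -> int:
    """Central terminus locus implied by a termination model."""
    if isinstance(model, PointModel):
        return model.locus
    if isinstance(model, CollisionModel):
        return (int(round(model.mu * genome_length)) - 1) % genome_length + 1
    if isinstance(model, ForkTrapModel):
        k = int(np.argmax(model.pause_rates))
        return model.ter_sites[k].position
    if isinstance(model, MixtureModel):
        heaviest = max(model.components, key=lambda mw: mw[1])[0]
        return expected_terminus(heaviest, genome_length)
    raise ConfigError(f"unknown model type {type(model).__name__}")


def default_annotation(length: int, ori: int = 1,
                       dif: Optional[int] = None,
                       shift_point: Optional[int] = None) -> SiteAnnotation:
    """E. coli-like annotation scaled to a fixture genome."""
    opposite = (ori - 1 + length // 2) % length + 1
    ters = tuple(
        TerSite(name, (opposite - 1 + int(round(off * length))) % length + 1,
                arm)
        for name, off, arm in DEFAULT_TER_GEOMETRY)
    if dif is None:
        dif = (opposite - 1 - int(round(0.0032 * length))) % length + 1
    if shift_point is None:
        shift_point = opposite
    return SiteAnnotation(genome_length=length, ori=ori, dif=dif,
                          shift_point=shift_point, ter_sites=ters)


def make_fixture_genome(spec: FixtureSpec, plant_consensus: bool = False):
    """Generate a biased genome with a known origin, terminus and history.

    Returns ``(sequence, annotation, truth)``. The annotation carries the
    default Ter geometry and places both the dif site and the shift point
    at the planted model's expected terminus, so the dif-stop and
    shift-point control models interrogate the true terminus exactly (the
    paper-style dif-vs-trap question). ``truth`` records the planted
    parameters for recovery tests.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.length
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    arr = rng.choice(bases, size=L, p=spec.base_composition)
    opposite = (spec.ori - 1 + L // 2) % L + 1
    model = spec.terminus_model
    if model is None:
        model = PointModel(opposite, label="planted-point")
    ter = expected_terminus(model, L)
    ann = default_annotation(L, ori=spec.ori, dif=ter, shift_point=ter)
    if isinstance(model, ForkTrapModel):
        ann = SiteAnnotation(genome_length=L, ori=spec.ori, dif=ter,
                             shift_point=ter, ter_sites=model.ter_sites)
    if plant_consensus:
        arr = _plant_consensus(arr, ann)
    seq0 = CircularSequence(f"fixture-{spec.seed}", arr.tobytes().decode())
    c_count = int((arr == ord("C")).sum())
    if spec.cycles >= c_count:
        raise ConfigError(f"planted_cycles {spec.cycles} >= C count "
                          f"{c_count}")
    sim_seed = int(rng.integers(0, 2**31 - 1))
    state = run_simulation(seq0, spec.ori, model, max_cycles=spec.cycles,
                           seed=sim_seed)
    out = CircularSequence(seq0.id, state.sequence().seq)
    truth = {"ori": spec.ori, "ter": ter, "planted_cycles": spec.cycles,
             "model": type(model).__name__, "seed": spec.seed,
             "sim_seed": sim_seed, "length": L}
    return out, ann, truth


def _plant_consensus(arr: np.ndarray, ann: SiteAnnotation) -> np.ndarray:
    """Overwrite a findable Tus-consensus copy at each Ter position.

    Clockwise-blocking sites receive the forward-strand realization,
    counterclockwise-blocking sites its reverse complement.
    """
    fwd = np.frombuffer(TER_CONSENSUS_REALIZATION.encode(), dtype=np.uint8)
    comp = {ord("A"): ord("T"), ord("T"): ord("A"),
            ord("C"): ord("G"), ord("G"): ord("C")}
    rev = np.array([comp[b] for b in fwd[::-1]], dtype=np.uint8)
    arr = arr.copy()
    L = arr.size
    for site in ann.ter_sites:
        word = fwd if site.blocking_arm == "clockwise" else rev
        idx = (site.position - 1 + np.arange(word.size)) % L
        arr[idx] = word
    return arr


def make_plasmid_offsets(n: int, mu: float = 0.5, sigma: float = 0.03,
                         seed: int = 0) -> np.ndarray:
    """Gaussian terminus offsets (fractions of length) for calibration
    tests; sigma = 0 is allowed and flags as degenerate downstream."""
    if n < 3:
        raise ConfigError("need n >= 3 offsets")
    rng = np.random.default_rng(seed)
    return rng.normal(mu, sigma, size=n)
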