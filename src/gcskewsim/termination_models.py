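"""Replication-termination models and their parameter derivations.

Four models describe where a replication round ends on the circle:

* fork-collision — the two forks meet near the locus opposite the
  origin; the meeting point fluctuates as a Gaussian whose parameters
  are calibrated from theta-replicating plasmids,
* fork-trap — termination at Ter sites, each arresting a fork with its
  own pausing rate derived from stall/leakiness physiology,
* dif-stop — a single finite terminus at the dif site,
* shift-point control — a single finite terminus at the GC-skew shift
  point,

plus weighted probabilistic mixtures of any of these. Every model is a
sampler of the per-cycle terminus position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (ConfigError, DegenerateSignalError, InputError,
                     ModelConstructionError)
from .genome_io import CircularSequence, SiteAnnotation, TerSite, \
    circular_distance
from .skew_metrics import (PLASMID_WINDOW_COUNT, RMSE_SCALE, SkewProfile,
                           find_ori_ter, rmse, spectral_amplitude)
from .site_finder import BSUBTILIS_TER, ECOLI_TER, ConsensusPattern, \
    find_ter_sites


def _wrap(positions: np.ndarray, genome_length: int) -> np.ndarray:
    return (np.asarray(positions, dtype=np.int64) - 1) % genome_length + 1


# ---------------------------------------------------------------------------
# the four models and their mixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CollisionModel:
    """Gaussian terminus around the locus opposite the origin.

    ``mu`` and ``sigma`` are fractions of genome length; samples wrap
    circularly rather than truncating at the replichore boundaries.
    """

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not (0.0 < self.sigma < 0.5):
            raise ModelConstructionError(
                f"sigma must lie in (0, 0.5), got {self.sigma}")

    def sample_batch(self, genome_length: int, rng: np.random.Generator,
                     n: int) -> np.ndarray:
        draws = rng.normal(self.mu, self.sigma, size=n)
        return _wrap(np.rint(draws * genome_length), genome_length)


@dataclass(frozen=True)
class ForkTrapModel:
    """Categorical terminus over Ter sites weighted by pausing rates.

    Rates are normalized to sum to one at construction, so injected raw
    pausing-rate vectors (e.g. the literature's 72/10.5/16/1.152/0.23
    percentages) are accepted verbatim.
    """

    ter_sites: Tuple[TerSite, ...]
    pause_rates: Tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.ter_sites:
            raise ModelConstructionError("fork-trap model needs >=1 Ter site")
        rates = np.asarray(self.pause_rates, dtype=float)
        if rates.size != len(self.ter_sites):
            raise ModelConstructionError("one pause rate per Ter site "
                                         "required")
        if np.any(rates < 0) or rates.sum() <= 0:
            raise ModelConstructionError("pause rates must be >=0 with a "
                                         "positive sum")
        object.__setattr__(self, "pause_rates",
                           tuple(rates / rates.sum()))

    @classmethod
    def from_rate_mapping(cls, ter_sites: Sequence[TerSite],
                          rates: Mapping[str, float]) -> "ForkTrapModel":
        return cls(tuple(ter_sites),
                   tuple(rates[t.name] for t in ter_sites))

    def sample_batch(self, genome_length: int, rng: np.random.Generator,
                     n: int) -> np.ndarray:
        positions = np.array([t.position for t in self.ter_sites],
                             dtype=np.int64)
        idx = rng.choice(positions.size, size=n, p=self.pause_rates)
        return positions[idx]


@dataclass(frozen=True)
class PointModel:
    """Deterministic terminus at a single finite locus (dif site for the
    dif-stop model, GC-skew shift point for the control model)."""

    locus: int
    label: str = "point"

    def __post_init__(self) -> None:
        if self.locus < 1:
            raise ModelConstructionError("locus must be a 1-based position")

    def sample_batch(self, genome_length: int, rng: np.random.Generator,
                     n: int) -> np.ndarray:
        if self.locus > genome_length:
            raise ModelConstructionError(
                f"locus {self.locus} exceeds genome length {genome_length}")
        return np.full(n, self.locus, dtype=np.int64)


@dataclass(frozen=True)
class MixtureModel:
    """Per-cycle probabilistic combination of termination models."""

    components: Tuple[Tuple[object, float], ...]

    def __post_init__(self) -> None:
        if not self.components:
            raise ModelConstructionError("mixture needs >=1 component")
        weights = np.array([w for _, w in self.components], dtype=float)
        if np.any(weights < 0) or weights.sum() <= 0:
            raise ModelConstructionError("mixture weights must be >=0 with "
                                         "a positive sum")
        object.__setattr__(self, "components",
                           tuple((m, float(w / weights.sum()))
                                 for (m, _), w in
                                 zip(self.components, weights)))

    def sample_batch(self, genome_length: int, rng: np.random.Generator,
                     n: int) -> np.ndarray:
        weights = [w for _, w in self.components]
        which = rng.choice(len(self.components), size=n, p=weights)
        out = np.empty(n, dtype=np.int64)
        for k, (model, _) in enumerate(self.components):
            sel = which == k
            cnt = int(sel.sum())
            if cnt:
                out[sel] = model.sample_batch(genome_length, rng, cnt)
        return out


TerminationModel = Union[CollisionModel, ForkTrapModel, PointModel,
                         MixtureModel]


def sample_terminus(model: TerminationModel, genome_length: int,
                    rng: np.random.Generator) -> int:
    """Draw one replication-terminus position (1-based) from a model."""
    return int(model.sample_batch(genome_length, rng, 1)[0])


# ---------------------------------------------------------------------------
# fork-trap physiology and pause-rate derivation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrapPhysiology:
    """Replisome parameters behind the pause-rate calculus.

    ``stall_probability`` is the per-replication probability of a stall
    long enough (≥ δ) for the opposing fork to over-travel to the second
    furthermost Ter site — about 20% of replication events in E. coli.
    ``trap_efficiency`` is the per-site arrest probability (~80%; the
    complement is the site's leakiness). ``fork_speed`` is replisome
    progression in bp/s; stall durations are modelled as
    Normal(``stall_mean_s``, ``stall_sd_s``), centred on the ~5 min
    restart time.
    """

    stall_probability: float = 0.20
    trap_efficiency: float = 0.80
    fork_speed: float = 1000.0
    stall_mean_s: float = 300.0
    stall_sd_s: float = 60.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.stall_probability <= 1.0):
            raise ConfigError("stall_probability must be in [0, 1]")
        if not (0.0 <= self.trap_efficiency <= 1.0):
            raise ConfigError("trap_efficiency must be in [0, 1]")
        if self.fork_speed <= 0:
            raise ConfigError("fork_speed must be positive")


def delta_seconds(ann: SiteAnnotation, phys: TrapPhysiology) -> float:
    """Over-travel stall time δ: how long the fork on the second-furthest
    site's arm must stall for the opposing fork to over-travel from the
    locus opposite the origin to that site."""
    sites = ann.ter_sites
    if len(sites) < 2:
        raise ModelConstructionError("delta needs >=2 Ter sites")
    by_dist = sorted(sites,
                     key=lambda t: -circular_distance(t.position, ann.ori,
                                                      ann.genome_length))
    first_arm = by_dist[0].blocking_arm
    other = [t for t in by_dist if t.blocking_arm != first_arm]
    if not other:
        raise ModelConstructionError("delta needs Ter sites on both arms")
    second = other[0]
    dist = circular_distance(second.position, ann.opposite_ori,
                             ann.genome_length)
    return dist / phys.fork_speed


def long_stall_probability(delta_s: float, phys: TrapPhysiology,
                           reference_delta_s: float = 300.0) -> float:
    """Species-specific probability of a stall long enough to use the
    second-furthest Ter site.

    Rescales the calibrated ``stall_probability`` by the survival of the
    normal stall-duration model at this species' δ relative to the
    reference δ (the ~5 min E. coli value), so the reference species
    keeps its calibrated probability exactly.
    """
    dist = stats.norm(phys.stall_mean_s, phys.stall_sd_s)
    ref = dist.sf(reference_delta_s)
    if ref == 0:
        raise ConfigError("reference delta has zero survival under the "
                          "stall-duration model")
    return float(min(1.0, phys.stall_probability * dist.sf(delta_s) / ref))


def derive_pause_rates(ann: SiteAnnotation,
                       phys: TrapPhysiology = TrapPhysiology(),
                       normalize: bool = False) -> Dict[str, float]:
    """Per-Ter-site arrest probabilities from the stall/leak calculus.

    The fork heading for the furthermost Ter site reaches it first in
    ``(1 − s) + s/2`` of replication rounds (no long stall, plus long
    stalls on its own arm) and is arrested there with probability ``e``;
    in the remaining ``s/2`` of rounds the opposing fork over-travels and
    meets the first trap on the other arm. Forks leaking through a trap
    (probability ``1 − e``) cascade outward to the next site on their
    arm. By default the raw probabilities are returned (they need not sum
    to one — the residual is fork-collision past the last trap);
    ``normalize=True`` folds the residual back proportionally.
    """
    sites = ann.ter_sites
    if not sites:
        raise ModelConstructionError("annotation has no Ter sites")
    s = phys.stall_probability
    e = phys.trap_efficiency
    L = ann.genome_length

    def travel(site: TerSite) -> int:
        if site.blocking_arm == "clockwise":
            return (site.position - ann.ori) % L
        return (ann.ori - site.position) % L

    arms: Dict[str, List[TerSite]] = {"clockwise": [], "counterclockwise": []}
    for t in sites:
        arms[t.blocking_arm].append(t)
    for chain in arms.values():
        chain.sort(key=travel)

    furthermost = max(sites, key=lambda t: (circular_distance(
        t.position, ann.ori, L), -t.position))
    first_arm = furthermost.blocking_arm
    second_arm = ("counterclockwise" if first_arm == "clockwise"
                  else "clockwise")
    arm_weight = {first_arm: (1.0 - s) + s / 2.0, second_arm: s / 2.0}

    rates: Dict[str, float] = {}
    for arm, chain in arms.items():
        p = arm_weight[arm]
        for site in chain:
            rates[site.name] = p * e
            p *= (1.0 - e)
    # restore annotation order
    rates = {t.name: rates[t.name] for t in sites}
    if normalize:
        total = sum(rates.values())
        if total == 0:
            raise ModelConstructionError("all pause rates are zero")
        rates = {k: v / total for k, v in rates.items()}
    return rates


# ---------------------------------------------------------------------------
# pause-rate grid search
# ---------------------------------------------------------------------------

def enumerate_rate_patterns(n_sites: int, step: float = 0.05,
                            top_k: int = 4,
                            min_top_fraction: float = 0.80
                            ) -> List[Tuple[float, ...]]:
    """All arrest-rate vectors on the grid, farthest-first site order.

    Rates move in ``step`` increments and the first ``min(top_k,
    n_sites)`` sites (the ones farthest from the origin) must jointly
    carry at least ``min_top_fraction`` of the total; any remainder is
    split equally over the remaining sites.
    """
    units = round(1.0 / step)
    if abs(units * step - 1.0) > 1e-9:
        raise ConfigError(f"step {step} does not divide 1 evenly")
    top = min(top_k, n_sites)
    rest = n_sites - top
    max_rest_units = int(np.floor(units * (1.0 - min_top_fraction) + 1e-9))
    if rest == 0:
        max_rest_units = 0
    patterns = []
    for rest_units in range(max_rest_units + 1):
        top_units = units - rest_units
        for combo in _compositions(top_units, top):
            vec = [u * step for u in combo]
            if rest:
                vec += [rest_units * step / rest] * rest
            patterns.append(tuple(vec))
    if not patterns:
        raise ConfigError("no feasible rate pattern under the constraints")
    patterns.sort(reverse=True)
    return patterns


def _compositions(total: int, parts: int):
    """All ordered non-negative integer compositions of ``total``."""
    if parts == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for tail in _compositions(total - first, parts - 1):
            yield (first,) + tail


@dataclass(frozen=True)
class SimulationSettings:
    """Inputs the grid search needs to score one candidate rate vector."""

    shuffled_seq: CircularSequence
    cycles: int
    seed: int
    window_count: int = 256
    rmse_scale: float = RMSE_SCALE
    step: float = 0.05
    top_k: int = 4
    min_top_fraction: float = 0.80


def optimize_pause_rates(ann: SiteAnnotation, natural: SkewProfile,
                         sim: SimulationSettings
                         ) -> Tuple[Dict[str, float], float]:
    """Grid search for the pausing rates best reconstructing the skew.

    Every candidate vector is simulated from the same shuffled sequence
    and seed and scored by RMSE against the natural profile; the best
    vector (ties broken by grid order) is returned with its RMSE.
    Deterministic for a fixed seed.
    """
    from .mutation_simulator import run_simulation
    from .skew_metrics import gc_skew

    sites = sorted(ann.ter_sites,
                   key=lambda t: (-circular_distance(t.position, ann.ori,
                                                     ann.genome_length),
                                  t.position))
    if not sites:
        raise ModelConstructionError("annotation has no Ter sites")
    if len(sites) == 1:
        return {sites[0].name: 1.0}, float("nan")
    patterns = enumerate_rate_patterns(len(sites), step=sim.step,
                                       top_k=sim.top_k,
                                       min_top_fraction=sim.min_top_fraction)
    best_rates, best_score = None, np.inf
    for pattern in patterns:
        if sum(pattern) == 0:
            continue
        model = ForkTrapModel(tuple(sites), pattern)
        state = run_simulation(sim.shuffled_seq, ann.ori, model,
                               max_cycles=sim.cycles, seed=sim.seed)
        profile = gc_skew(state.sequence(),
                          window_count=natural.window_count)
        score = rmse(profile, natural, scale=sim.rmse_scale)
        if score < best_score:
            best_score = score
            best_rates = {t.name: r for t, r in zip(sites, pattern)}
    return best_rates, float(best_score)


# ---------------------------------------------------------------------------
# fork-collision calibration from plasmids
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CollisionFit:
    mu: float
    sigma: float
    ks_p: float
    n: int
    degenerate: bool = False


def fit_collision_distribution(offsets: Sequence[float],
                               min_sigma: float = 1e-4) -> CollisionFit:
    """Gaussian fit of terminus offsets (fractions of replicon length).

    Returns the sample mean and SD plus a Kolmogorov–Smirnov
    goodness-of-fit p-value against the fitted normal. Because the
    parameters are estimated from the same sample, null p-values are
    conservative (stochastically large), matching how the fit was
    validated on plasmid shift points.
    """
    x = np.asarray(list(offsets), dtype=float)
    if x.size < 3:
        raise InputError(f"need >=3 offsets, got {x.size}")
    mu = float(x.mean())
    sigma = float(x.std(ddof=1))
    degenerate = sigma < min_sigma
    if degenerate:
        warnings.warn("offset spread below the sigma floor; using the "
                      "configured minimum", stacklevel=2)
        sigma = min_sigma
    ks_p = float(stats.kstest(x, "norm", args=(mu, sigma)).pvalue)
    return CollisionFit(mu=mu, sigma=sigma, ks_p=ks_p, n=int(x.size),
                        degenerate=degenerate)


# ---------------------------------------------------------------------------
# plasmid screening
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlasmidRecord:
    """One candidate plasmid with the annotation flags the screen needs."""

    seq: CircularSequence
    has_repC: Optional[bool] = None
    has_dif: Optional[bool] = None
    iteron_intervals: Optional[Tuple[Tuple[int, int], ...]] = None

    @property
    def id(self) -> str:
        return self.seq.id


_FILTERS = ["size_and_amplitude", "no_ter_no_dif", "no_repC",
            "no_iteron_near_ori"]


def screen_plasmids(records: Sequence[PlasmidRecord],
                    ter_patterns: Sequence[ConsensusPattern] = (
                        ECOLI_TER, BSUBTILIS_TER),
                    min_length: int = 10_000,
                    min_amplitude: float = 1000.0,
                    window_count: int = PLASMID_WINDOW_COUNT,
                    iteron_zone_fraction: float = 0.05
                    ) -> Tuple[List[PlasmidRecord], pd.DataFrame]:
    """Select plasmids plausibly terminated purely by fork collision.

    Filters, applied in order with a per-filter audit trail:
    1. larger than ``min_length`` with one-cycle spectral amplitude of
       the (C−G) count vector ≥ ``min_amplitude`` (64 windows),
    2. no Ter consensus match (either preset) and no dif site,
    3. no repC gene (theta, not rolling-circle, replication),
    4. no iteron interval within ±``iteron_zone_fraction`` of replicon
       length around the skew-predicted origin.
    """
    rows = []
    accepted = []
    for rec in records:
        if rec.has_repC is None or rec.has_dif is None or \
                rec.iteron_intervals is None:
            raise InputError(f"record {rec.id!r} is missing annotation flags")
        checks: Dict[str, Optional[bool]] = {f: None for f in _FILTERS}
        reason = ""
        L = rec.seq.length
        ok = L > min_length and (
            spectral_amplitude(rec.seq, window_count=min(window_count, L))
            >= min_amplitude)
        checks["size_and_amplitude"] = ok
        if ok:
            has_ter = any(find_ter_sites(rec.seq, p) for p in ter_patterns)
            ok = not has_ter and not rec.has_dif
            checks["no_ter_no_dif"] = ok
        if ok and checks["no_ter_no_dif"]:
            ok = not rec.has_repC
            checks["no_repC"] = ok
        if ok and checks["no_repC"]:
            ok = not _iteron_near_ori(rec, iteron_zone_fraction)
            checks["no_iteron_near_ori"] = ok
        passed = all(checks[f] is True for f in _FILTERS)
        if not passed:
            reason = next(f for f in _FILTERS if checks[f] is not True)
        else:
            accepted.append(rec)
        rows.append({"id": rec.id, **checks, "accepted": passed,
                     "reject_reason": reason})
    audit = pd.DataFrame(rows)
    return accepted, audit


def _iteron_near_ori(rec: PlasmidRecord, zone_fraction: float) -> bool:
    if not rec.iteron_intervals:
        return False
    L = rec.seq.length
    try:
        ori, _ = find_ori_ter(rec.seq)
    except DegenerateSignalError:
        return False
    half = int(round(zone_fraction * L))
    zone_start = (ori - 1 - half) % L  # 0-based arc start
    zone_len = 2 * half + 1
    for start, end in rec.iteron_intervals:
        arc_start = (start - 1) % L
        arc_len = (end - start) % L + 1
        if ((arc_start - zone_start) % L) < zone_len or \
                ((zone_start - arc_start) % L) < arc_len:
            return True
    return False
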