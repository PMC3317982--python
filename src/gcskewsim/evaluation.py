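"""Model comparison across replicons: RMSE scoring, mixture grids,
paired nonparametric tests and rank correlations.

All simulations for one replicon reuse the same shuffled input sequence
and the same mutation seed, so model comparisons are paired: RMSE
differences between models reflect terminus placement, not shuffling or
sampling noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, InputError
from .genome_io import (CircularSequence, SiteAnnotation, base_counts,
                        shuffle_sequence)
from .mutation_simulator import required_cycles, run_simulation
from .skew_metrics import (RMSE_SCALE, find_ori_ter, gc_skew, gcsi,
                           leading_strand_counts, rmse)
from .termination_models import (CollisionModel, ForkTrapModel, MixtureModel,
                                 PointModel, TrapPhysiology,
                                 derive_pause_rates)

#: fallback Gaussian spread of the fork-collision model, as a fraction of
#: genome length, used when no plasmid calibration is supplied
DEFAULT_COLLISION_SIGMA = 0.03


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RepliconInput:
    """One replicon to evaluate: natural sequence plus site annotation."""

    id: str
    seq: CircularSequence
    annotation: SiteAnnotation


@dataclass(frozen=True)
class ModelScore:
    replicon_id: str
    model_label: str
    rmse: float
    gcsi_sim: float
    gcsi_nat: float
    seed: int
    cycles: int

    def __post_init__(self) -> None:
        if self.rmse < 0:
            raise InputError("rmse must be >= 0")


@dataclass(frozen=True)
class MixtureGrid:
    """All mixture-weight patterns on a simplex grid."""

    step: float
    min_weight: float
    patterns: Tuple[Tuple[float, ...], ...]

    def __len__(self) -> int:
        return len(self.patterns)


@dataclass(frozen=True)
class EvaluationSettings:
    """Shared simulation/scoring settings for one evaluation run.

    The default 64 scoring windows keep per-window counting noise at the
    percent level on megabase replicons while still resolving the
    differences between terminus distributions; GCSI is computed on the
    same (power-of-two) windowing.
    """

    window_count: int = 64
    rmse_scale: float = RMSE_SCALE
    seed: int = 0
    cycles: Union[str, int] = "auto"


# ---------------------------------------------------------------------------
# mixture enumeration
# ---------------------------------------------------------------------------

def enumerate_mixtures(step: float = 0.10, min_weight: float = 0.10,
                       n_components: int = 3) -> MixtureGrid:
    """All ordered weight vectors on the simplex grid.

    Weights move in ``step`` increments, each component keeps at least
    ``min_weight``, and vectors sum to one; patterns are returned in
    lexicographic order. With a 10% step and 10% floor over three
    components this yields the canonical 36 patterns.
    """
    units = round(1.0 / step)
    if abs(units * step - 1.0) > 1e-9:
        raise ConfigError(f"step {step} does not divide 1 evenly")
    floor_units = round(min_weight / step)
    if abs(floor_units * step - min_weight) > 1e-9:
        raise ConfigError(f"min_weight {min_weight} is not a multiple of "
                          f"step {step}")
    if n_components * floor_units > units:
        raise ConfigError(
            f"infeasible: {n_components} components x floor {min_weight} "
            f"exceeds total weight 1")
    patterns = []
    for combo in _compositions_at_least(units, n_components, floor_units):
        patterns.append(tuple(u * step for u in combo))
    return MixtureGrid(step=step, min_weight=min_weight,
                       patterns=tuple(sorted(patterns)))


def _compositions_at_least(total: int, parts: int, floor: int):
    if parts == 1:
        if total >= floor:
            yield (total,)
        return
    for first in range(floor, total - floor * (parts - 1) + 1):
        for tail in _compositions_at_least(total - first, parts - 1, floor):
            yield (first,) + tail


# ---------------------------------------------------------------------------
# standard model set
# ---------------------------------------------------------------------------

def build_standard_models(ann: SiteAnnotation,
                          collision_sigma: float = DEFAULT_COLLISION_SIGMA,
                          phys: TrapPhysiology = TrapPhysiology(),
                          pause_rates: Optional[Mapping[str, float]] = None
                          ) -> Dict[str, object]:
    """The four canonical models an annotation supports.

    ``collision`` is always built (Gaussian at the locus opposite the
    origin); ``forktrap``, ``difstop`` and ``shiftstop`` require Ter
    sites, a dif position and a shift point respectively. Pause rates
    default to the stall/leak derivation but an injected vector wins.
    """
    models: Dict[str, object] = {
        "collision": CollisionModel(
            mu=ann.opposite_ori / ann.genome_length, sigma=collision_sigma)}
    if ann.ter_sites:
        rates = (dict(pause_rates) if pause_rates is not None
                 else derive_pause_rates(ann, phys))
        models["forktrap"] = ForkTrapModel.from_rate_mapping(
            ann.ter_sites, rates)
    if ann.dif is not None:
        models["difstop"] = PointModel(ann.dif, label="difstop")
    if ann.shift_point is not None:
        models["shiftstop"] = PointModel(ann.shift_point, label="shiftstop")
    return models


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def score_models(replicons: Sequence[RepliconInput],
                 models: Mapping[str, object],
                 settings: EvaluationSettings = EvaluationSettings()
                 ) -> List[ModelScore]:
    """Simulate every model on every replicon and score against nature.

    Per replicon: one shuffled sequence (shared by all models), the
    auto-determined cycle count (whole-genome vs leading-strand G
    difference, terminus taken from the annotated shift point or the
    skew-predicted terminus), one shared mutation seed — then for each
    model an independent simulation, its RMSE against the natural
    profile, and both GCSI values. Pure function of (inputs, seed).
    """
    scores: List[ModelScore] = []
    root = np.random.SeedSequence(settings.seed)
    children = root.spawn(len(replicons))
    for r, child in zip(replicons, children):
        shuffle_seed, sim_seed = (int(s) for s in
                                  child.generate_state(2, dtype=np.uint32))
        ann = r.annotation
        shuffled = shuffle_sequence(r.seq, shuffle_seed)
        natural_profile = gc_skew(r.seq, settings.window_count)
        ter_ref = ann.shift_point
        if ter_ref is None:
            ter_ref = find_ori_ter(r.seq)[1]
        if settings.cycles == "auto":
            cycles = required_cycles(
                base_counts(r.seq),
                leading_strand_counts(r.seq, ann.ori, ter_ref))
        else:
            cycles = int(settings.cycles)
        gcsi_nat = gcsi(natural_profile, r.seq, ori=ann.ori,
                        ter=ter_ref).gcsi
        for label, model in models.items():
            state = run_simulation(shuffled, ann.ori, model,
                                   max_cycles=cycles, seed=sim_seed,
                                   window_count=settings.window_count)
            sim_seq = state.sequence()
            sim_profile = gc_skew(sim_seq, settings.window_count)
            scores.append(ModelScore(
                replicon_id=r.id, model_label=label,
                rmse=rmse(sim_profile, natural_profile,
                          scale=settings.rmse_scale),
                gcsi_sim=gcsi(sim_profile, sim_seq, ori=ann.ori,
                              ter=ter_ref).gcsi,
                gcsi_nat=gcsi_nat, seed=sim_seed, cycles=cycles))
    return scores


def scores_to_frame(scores: Sequence[ModelScore]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in scores])


def score_mixture_grid(replicons: Sequence[RepliconInput],
                       component_labels: Sequence[str],
                       grid: MixtureGrid,
                       settings: EvaluationSettings = EvaluationSettings(),
                       models_per_replicon: Optional[Mapping[
                           str, Mapping[str, object]]] = None
                       ) -> pd.DataFrame:
    """RMSE of every mixture pattern on every replicon (long format).

    ``component_labels`` name the models mixed (in pattern order);
    ``models_per_replicon`` maps replicon id to its standard model set
    (built from its annotation when omitted).
    """
    rows = []
    for r in replicons:
        base = (models_per_replicon[r.id] if models_per_replicon is not None
                else build_standard_models(r.annotation))
        missing = [lbl for lbl in component_labels if lbl not in base]
        if missing:
            raise InputError(f"replicon {r.id!r} lacks models {missing}")
        mixtures = {
            _pattern_label(component_labels, pat): MixtureModel(
                tuple((base[lbl], w)
                      for lbl, w in zip(component_labels, pat)))
            for pat in grid.patterns}
        for s in score_models([r], mixtures, settings):
            rows.append({"replicon_id": s.replicon_id,
                         "pattern": s.model_label, "rmse": s.rmse})
    return pd.DataFrame(rows)


def _pattern_label(labels: Sequence[str], pattern: Sequence[float]) -> str:
    return "+".join(f"{lbl}:{w:.2f}" for lbl, w in zip(labels, pattern))


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def paired_model_test(scores_a: Union[Sequence[ModelScore],
                                      Mapping[str, float]],
                      scores_b: Union[Sequence[ModelScore],
                                      Mapping[str, float]]) -> float:
    """Two-sided Wilcoxon signed-rank p-value on paired per-replicon RMSE.

    Zero differences are dropped (the standard zero-drop convention);
    identical vectors degenerate to p = 1 with a warning. The exact null
    distribution is used at small n without ties, the normal
    approximation otherwise (scipy's switching rule).
    """
    a = _as_rmse_map(scores_a)
    b = _as_rmse_map(scores_b)
    if set(a) != set(b):
        raise InputError("replicon id sets differ between the two models")
    ids = sorted(a)
    x = np.array([a[i] for i in ids])
    y = np.array([b[i] for i in ids])
    if np.all(x == y):
        warnings.warn("all paired scores identical; Wilcoxon test is "
                      "degenerate", stacklevel=2)
        return 1.0
    res = stats.wilcoxon(x, y, zero_method="wilcox",
                         alternative="two-sided")
    return float(res.pvalue)


def _as_rmse_map(scores) -> Dict[str, float]:
    if isinstance(scores, Mapping):
        return dict(scores)
    out: Dict[str, float] = {}
    for s in scores:
        if s.replicon_id in out:
            raise InputError(f"duplicate replicon id {s.replicon_id!r}")
        out[s.replicon_id] = s.rmse
    return out


def rank_correlation(rates_a: Mapping[str, float],
                     rates_b: Mapping[str, float]) -> float:
    """Spearman rank correlation between two pause-rate assignments."""
    if set(rates_a) != set(rates_b):
        raise InputError("site sets differ between the two rate vectors")
    keys = sorted(rates_a)
    if len(keys) < 3:
        raise InputError("need >=3 paired sites for a rank correlation")
    rho = stats.spearmanr([rates_a[k] for k in keys],
                          [rates_b[k] for k in keys]).statistic
    return float(rho)
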