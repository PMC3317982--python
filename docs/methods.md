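# Methods

## Model and assumptions

`gcskewsim` treats replication-associated strand bias as the only
mutational force: every simulated event is a C→G substitution on the
leading strand of whichever replichore the mutated position belongs to.
This is a deliberate idealization. Strand bias in most bacteria is
dominated by leading-strand G enrichment, and the GC-skew curve carries
no A/T information, so C↔G flips are the minimal process that can
re-form it. Everything else real genomes experience — indels,
inversions, horizontal transfer, transcription-coupled asymmetries —
is out of scope; their strand effects are assumed to cancel unless
mechanistically tied to replication.

Coordinates are 1-based and inclusive on the published strand, and all
intervals wrap through position 1 (the replicon is circular).
Ambiguity codes are preserved on input but are invisible to the
process: they are never mutated and never counted in skew numerators
or denominators.

The per-cycle procedure is memoryless: a terminus is drawn fresh from
the termination model every cycle, the two arms are re-partitioned at
`(ori, terminus)` with half-open boundaries at both loci (so no
position is counted twice), and one uniformly random eligible position
is flipped. A previously mutated position may mutate again, in
whichever direction its current base allows.

### Cycle count

The simulation length is the leading-strand G excess
`|G_leading − G_whole|`, which equals `|C_whole − C_leading|`
identically (each flip adds one leading-strand G and removes one
leading-strand C; A and T are untouched). `required_cycles` asserts
that equality and rejects inconsistent count pairs. In masked
(GC3/non-coding) mode the same rule is applied to masked-in positions
only.

A statistical point worth knowing: measured on a finite unbiased
starting sequence, this estimator is not exactly zero — an i.i.d.
(or shuffled) genome carries a random per-arm C−G imbalance of
standard deviation ≈ `√(0.25·L)`, and the arm-1/arm-2 split of `N`
mutations adds a further `√N`. Round-trip recovery of a planted cycle
count is therefore accurate to a small fraction of *genome length*
(≈0.05% at 1 Mb in practice), not to a fraction of `N` itself.

## Termination models

* **Fork-collision** `X ~ N(μ, σ²)`, both parameters as fractions of
  genome length, samples rounded to integer positions and *wrapped*
  around the circle (not truncated at the replichore boundaries; with
  the default σ the wrap is never exercised in practice). μ defaults to
  the locus opposite the origin. σ should come from
  `fit_collision_distribution` applied to plasmid shift-point offsets;
  where no calibration set is supplied the package uses σ = 0.03,
  chosen as a plausible few-percent-of-length spread for collision
  termini, and states it in run metadata.
* **Fork-trap** a categorical distribution over Ter positions.
  `ForkTrapModel` normalizes whatever rate vector it is given, so raw
  literature percentages can be injected verbatim.
* ***dif*-stop / shift-point control** constant loci, supplied by the
  site-annotation table (dif prediction itself is out of scope).
* **Mixture** components are drawn per cycle, matching the
  interpretation of interleaved machinery usage; a sequential-blocks
  variant can be emulated by running segments with different models on
  the same state.

### Pausing-rate calculus

`derive_pause_rates` implements the stall/leakiness accounting with
three parameters (`TrapPhysiology`):

| parameter | default | meaning |
|---|---|---|
| `stall_probability` s | 0.20 | per-round probability of a stall long enough (≥ δ) for the opposing fork to over-travel to the other arm's first trap |
| `trap_efficiency` e | 0.80 | per-site arrest probability; `1−e` is the site's leakiness |
| `fork_speed` | 1000 bp/s | replisome speed, used to convert over-travel distance to δ |
| stall duration | N(300 s, 60 s) | distribution of stall times, centred on the ~5 min restart time |

The fork heading for the furthermost Ter site reaches it first in
`(1−s) + s/2` of rounds and arrests there with probability `e`
(0.9 × 0.8 = 72% at the defaults); the other arm's chain starts with
`s/2`; leaked forks cascade outward, each successive site arresting
`e` of what reaches it. Rates are returned **raw** by default — they
need not sum to one, the residual being fork-collision past the last
trap — because that is the scale on which per-site arrest
probabilities are quoted and validated; `normalize=True` folds the
residual back proportionally for use as a sampling distribution
(`ForkTrapModel` does this internally regardless).

`stall_probability` is a species-calibrated quantity.
`long_stall_probability` transfers it to another replichore geometry by
rescaling with the survival of the stall-duration model at that
species' δ (over-travel distance / fork speed) relative to the
reference δ of 300 s, so the reference geometry keeps its calibrated
value exactly. The rescaling is deliberately *not* applied inside
`derive_pause_rates`: applying it to the reference species itself would
contradict the calibrated 20%.

The grid search (`optimize_pause_rates`) scores rate vectors in 5%
increments, constraining the four sites farthest from the origin to
carry at least 80% of the total (any remainder is split evenly over
the remaining sites), every candidate simulated from the same shuffled
sequence and seed and scored by RMSE; ties break toward the
lexicographically earlier (more furthermost-concentrated) vector.

### Plasmid screening

Candidates for collision-model calibration must (1) exceed 10 kb with
a one-cycle spectral amplitude ≥ 1000 of the 64-window (C−G) count
vector, (2) contain neither a Ter consensus match (both the Tus and
RTP presets are searched) nor a *dif* site, (3) lack *repC*, and
(4) have no iteron interval within ±5% of length around the
skew-predicted origin. Filters run in order with a per-filter audit
trail; `has_repC`, `has_dif` and iteron intervals are annotation
inputs, not sequence predictions.

## Skew metrics

Skew is `(C−G)/(C+G)` per window (a flag flips to the `(G−C)`
convention); windows tile the circle evenly with the remainder absorbed
by the last window, and zero-denominator windows score 0 to keep
vectors finite. The cumulative curve at 1-bp resolution (+1 per C, −1
per G) predicts the origin at its maximum and the terminus at its
minimum, ties breaking to the smallest coordinate; a flat curve raises
a degenerate-signal error rather than returning arbitrary positions.

RMSE between two profiles is computed on the raw skew difference times
a configurable scale, default ×100 (skew in percent); every exported
record embeds the convention. GCSI is
`sqrt((SR/6000) · (dist/600))` where `SR` is the power at one cycle per
genome divided by the mean spectral power of the (power-of-two,
default 4096) window vector, and `dist` is the per-mil Euclidean
distance between the leading- and lagging-strand (G, C) content. The
two normalization constants are configuration values; the composite
behaves as required — invariant under rotation, increasing in signal
strength, ≈0 for shuffled sequences — but its absolute calibration
against published full-genome values can only be checked with a real
genome, which is not bundled.

## Model comparison design

All simulations for one replicon reuse a single shuffled sequence, and
the package extends that logic to the mutation randomness itself: the
engine draws candidate positions from a dedicated stream that consumes
a fixed 64-draw block per cycle, separate from the terminus stream.
Two models run with the same seed therefore propose identical
candidates cycle for cycle and produce different mutations only where
their terminus draws genuinely dispute a region. This common-random-
numbers coupling makes per-replicon RMSE differences between models
reflect terminus placement rather than Monte-Carlo noise — without it,
distinguishing the fork-collision and fork-trap models on single
megabase replicons is statistically hopeless. The fallback when an
entire candidate block is ineligible (probability ~1e-8 per cycle at
normal composition) is an exact uniform draw over the eligible set,
taken from the terminus stream so block alignment is preserved; an
empty eligible set raises a stall error rather than silently skipping
the cycle.

Scoring uses 64 windows by default: at 1 Mb this keeps per-window
counting noise near 1% skew while still resolving the shapes that
separate terminus distributions. Wilcoxon signed-rank comparisons drop
zero differences and return p = 1 with a warning for identical score
vectors; Spearman correlations require at least three paired sites.

## The synthetic generator

`make_fixture_genome` draws an i.i.d. circular sequence from a chosen
base composition, then runs the forward process itself — a known
termination model for a known number of cycles — and emits the biased
genome, a consistent annotation and a truth record. Defaults are
chosen to emulate an E. coli-like study condition scaled to the
fixture length: mutation load 0.84% of genome length (the E. coli
leading-strand G excess fraction), an innermost trap just past the
midpoint (+0.073% of length), the second trap 5.7% into the other
arm, further traps outward, collision σ = 0.03. The dif site and
shift point are planted at the generating model's expected terminus,
so the dif-stop and control models interrogate the true terminus
exactly — which also means those two models coincide on point-terminus
fixtures and can only tie, not be separated.

What the generator does *not* emulate: real genomes are not i.i.d.
(coding structure, oligomer biases, GC heterogeneity), their skew
curves carry non-replicative structure that dominates absolute RMSE
values, and their annotations carry uncertainty. Passing fixture tests
therefore demonstrates that the machinery recovers planted truth under
the stated noise model, not that any particular biological conclusion
transfers to a given real genome.

Fixture and study sizes used by the test suite — 1 Mb genomes, ten
seeds per generating model, 200 kb for unit-level checks — were chosen
so the whole suite exercises the full pipeline at realistic mutation
loads while remaining quick to run.

## Degenerate inputs and numerical conventions

* `ori == ter` (or a terminus draw landing on the origin) raises a
  degenerate-partition error.
* Offset sets with zero spread floor σ at a configurable minimum
  (default 1e-4) with a warning, rather than fitting a delta function.
* The KS goodness-of-fit p-value in `fit_collision_distribution` is
  computed against the *fitted* normal; because the parameters come
  from the same sample the test is conservative under the null
  (p-values stochastically large), which is the appropriate reading
  when quoting it as "consistent with a Gaussian".
* Frame conflicts between overlapping CDS exclude a position from the
  GC3/non-coding mask (conservative); BED export converts to 0-based
  half-open coordinates at the boundary only.
* The Ter consensus wording "mutations allowed at bases 1, 4, 16" is
  read as fully-free pattern positions (consistent with the N already
  at position 3); a per-match mismatch budget is available as the
  alternative reading via `ConsensusPattern(max_mismatches=...)`.
* Mixture "best pattern" summaries report the median RMSE across
  replicons (means are also derivable from the long-format table).

## Known limitations

* Absolute GCSI/RMSE values on real full-size genomes depend on
  windowing and scaling conventions; this package fixes and logs its
  conventions but published numbers computed under other conventions
  are only comparable up to those choices.
* The leak-cascade is one deterministic reading of the stall/leak
  evidence; per-site literature rates that disagree with it can and
  should be injected directly.
* Tus–Ter binding kinetics, transcription–replication conflicts and
  multi-chromosome replicons are not modelled.
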