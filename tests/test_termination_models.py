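import itertools

import numpy as np
import pytest
from scipy import stats

from gcskewsim import (CircularSequence, CollisionModel, ForkTrapModel,
                       InputError, MixtureModel, ModelConstructionError,
                       PlasmidRecord, PointModel, SimulationSettings,
                       SiteAnnotation, TerSite, TrapPhysiology,
                       derive_pause_rates, enumerate_rate_patterns,
                       fit_collision_distribution, long_stall_probability,
                       make_fixture_genome, make_plasmid_offsets,
                       optimize_pause_rates, sample_terminus,
                       screen_plasmids, shuffle_sequence)
from gcskewsim.synthetic_fixtures import (FixtureSpec,
                                          TER_CONSENSUS_REALIZATION)
from gcskewsim.skew_metrics import gc_skew

from conftest import random_sequence


class TestSamplers:
    L = 1_000_000

    def test_point_model_is_constant(self):
        rng = np.random.default_rng(0)
        model = PointModel(1234)
        draws = model.sample_batch(self.L, rng, 1000)
        assert np.all(draws == 1234)

    def test_forktrap_frequencies_within_3se(self):
        rng = np.random.default_rng(1)
        sites = (TerSite("A", 100, "clockwise"),
                 TerSite("B", 900, "counterclockwise"))
        model = ForkTrapModel(sites, (0.72, 0.28))
        n = 100_000
        draws = model.sample_batch(self.L, rng, n)
        for pos, p in ((100, 0.72), (900, 0.28)):
            freq = np.mean(draws == pos)
            assert abs(freq - p) <= 3 * np.sqrt(p * (1 - p) / n)

    def test_collision_mean_within_3se(self):
        rng = np.random.default_rng(2)
        model = CollisionModel(mu=0.5, sigma=0.03)
        n = 100_000
        draws = model.sample_batch(self.L, rng, n)
        se = 0.03 * self.L / np.sqrt(n)
        assert abs(draws.mean() - 0.5 * self.L) <= 3 * se

    def test_all_samplers_in_range(self):
        rng = np.random.default_rng(3)
        models = [PointModel(1), PointModel(self.L),
                  CollisionModel(0.99, 0.05),
                  ForkTrapModel((TerSite("A", 5, "clockwise"),), (1.0,))]
        models.append(MixtureModel(tuple((m, 0.25) for m in models)))
        for m in models:
            draws = m.sample_batch(self.L, rng, 10_000)
            assert draws.min() >= 1 and draws.max() <= self.L

    def test_single_component_mixture_equals_component(self):
        rng_a, rng_b = (np.random.default_rng(s) for s in (4, 4))
        base = CollisionModel(0.5, 0.02)
        mix = MixtureModel(((base, 1.0),))
        a = base.sample_batch(self.L, rng_a, 20_000)
        b = mix.sample_batch(self.L, rng_b, 20_000)
        assert stats.ks_2samp(a, b).pvalue > 0.001

    def test_sample_terminus_scalar(self):
        assert sample_terminus(PointModel(7), 100,
                               np.random.default_rng(0)) == 7

    def test_invalid_models(self):
        with pytest.raises(ModelConstructionError):
            CollisionModel(0.5, 0.6)
        with pytest.raises(ModelConstructionError):
            ForkTrapModel((), ())
        with pytest.raises(ModelConstructionError):
            MixtureModel(((PointModel(1), -0.5), (PointModel(2), 1.5)))


class TestDerivePauseRates:
    def test_ecoli_furthermost_is_72_percent(self, ecoli_like_annotation):
        rates = derive_pause_rates(ecoli_like_annotation)
        assert rates["TerC"] == pytest.approx(0.72, abs=1e-12)

    def test_ecoli_cascade_values(self, ecoli_like_annotation):
        rates = derive_pause_rates(ecoli_like_annotation)
        # leak cascade: TerB = 0.9*0.2*0.8, TerA = 0.1*0.8, then onward
        assert rates["TerB"] == pytest.approx(0.144)
        assert rates["TerA"] == pytest.approx(0.08)
        assert rates["TerD"] == pytest.approx(0.016)
        assert rates["TerE"] == pytest.approx(0.0032)

    def test_perfect_traps_split_by_stall_probability(self):
        ann = SiteAnnotation(genome_length=1000, ori=1, ter_sites=(
            TerSite("near", 501, "clockwise"),
            TerSite("far", 499, "counterclockwise")))
        phys = TrapPhysiology(stall_probability=0.2, trap_efficiency=1.0)
        rates = derive_pause_rates(ann, phys)
        assert rates == {"near": pytest.approx(0.9),
                         "far": pytest.approx(0.1)}

    def test_no_stall_perfect_trap_is_point_mass(self):
        ann = SiteAnnotation(genome_length=1000, ori=1, ter_sites=(
            TerSite("near", 501, "clockwise"),
            TerSite("far", 499, "counterclockwise")))
        phys = TrapPhysiology(stall_probability=0.0, trap_efficiency=1.0)
        rates = derive_pause_rates(ann, phys)
        assert rates["near"] == 1.0 and rates["far"] == 0.0

    def test_three_site_toy_matches_exhaustive_enumeration(self):
        # independent oracle: enumerate (stall arm, leak outcomes) paths
        s, e = 0.2, 0.8
        ann = SiteAnnotation(genome_length=1000, ori=1, ter_sites=(
            TerSite("inner1", 510, "clockwise"),
            TerSite("outer1", 600, "clockwise"),
            TerSite("other", 480, "counterclockwise")))
        expected = {"inner1": 0.0, "outer1": 0.0, "other": 0.0}
        for arm_w, chain in (((1 - s) + s / 2, ["inner1", "outer1"]),
                             (s / 2, ["other"])):
            p = arm_w
            for name in chain:
                expected[name] += p * e
                p *= (1 - e)
        rates = derive_pause_rates(ann)
        for name in expected:
            assert rates[name] == pytest.approx(expected[name])

    def test_normalized_sums_to_one(self, ecoli_like_annotation):
        rates = derive_pause_rates(ecoli_like_annotation, normalize=True)
        assert sum(rates.values()) == pytest.approx(1.0)
        assert min(rates.values()) >= 0

    def test_rotation_invariance(self, ecoli_like_annotation):
        ann = ecoli_like_annotation
        L = ann.genome_length
        r = 1_000_000
        rot = SiteAnnotation(
            genome_length=L, ori=(ann.ori - r - 1) % L + 1,
            ter_sites=tuple(
                TerSite(t.name, (t.position - r - 1) % L + 1,
                        t.blocking_arm) for t in ann.ter_sites))
        assert derive_pause_rates(rot) == \
            pytest.approx(derive_pause_rates(ann))

    def test_no_sites_raises(self):
        ann = SiteAnnotation(genome_length=100, ori=1)
        with pytest.raises(ModelConstructionError):
            derive_pause_rates(ann)


class TestStallCalculus:
    def test_reference_delta_keeps_calibrated_probability(self):
        phys = TrapPhysiology()
        assert long_stall_probability(300.0, phys) == pytest.approx(0.20)

    def test_monotone_decreasing_in_delta(self):
        phys = TrapPhysiology()
        ps = [long_stall_probability(d, phys)
              for d in (120.0, 240.0, 300.0, 420.0)]
        assert all(a > b for a, b in zip(ps, ps[1:]))


class TestRatePatternGrid:
    def test_four_site_grid_matches_brute_force(self):
        patterns = enumerate_rate_patterns(4, step=0.05, top_k=4)
        # oracle: compositions of 20 units into 4 ordered parts
        brute = [c for c in itertools.product(range(21), repeat=4)
                 if sum(c) == 20]
        assert len(patterns) == len(brute)

    def test_rest_bucket_constrained(self):
        patterns = enumerate_rate_patterns(5, step=0.25, top_k=4,
                                           min_top_fraction=0.75)
        for p in patterns:
            assert sum(p[:4]) >= 0.75 - 1e-9
            assert sum(p) == pytest.approx(1.0)


class TestOptimizePauseRates:
    def test_planted_rate_recovery_rank_correlates(self):
        L = 100_000
        opposite = L // 2 + 1
        sites = tuple(
            TerSite(name, (opposite - 1 + int(off * L)) % L + 1, arm)
            for name, off, arm in (("T1", 0.001, "clockwise"),
                                   ("T2", -0.057, "counterclockwise"),
                                   ("T3", 0.017, "clockwise"),
                                   ("T4", -0.070, "counterclockwise")))
        ann = SiteAnnotation(genome_length=L, ori=1, ter_sites=sites)
        planted = derive_pause_rates(ann, normalize=True)
        model = ForkTrapModel.from_rate_mapping(sites, planted)
        seq, _, truth = make_fixture_genome(
            FixtureSpec(length=L, seed=21, terminus_model=model))
        natural = gc_skew(seq, 64)
        shuffled = shuffle_sequence(seq, 22)
        best, best_rmse = optimize_pause_rates(
            ann, natural, SimulationSettings(
                shuffled_seq=shuffled, cycles=truth["planted_cycles"],
                seed=23, step=0.10))
        rho = stats.spearmanr([planted[k] for k in sorted(planted)],
                              [best[k] for k in sorted(best)]).statistic
        assert rho > 0.7

    def test_single_site_trivial(self):
        ann = SiteAnnotation(genome_length=1000, ori=1, ter_sites=(
            TerSite("only", 500, "clockwise"),))
        best, _ = optimize_pause_rates(
            ann, gc_skew(random_sequence(1000, 0), 8),
            SimulationSettings(shuffled_seq=random_sequence(1000, 0),
                               cycles=10, seed=0))
        assert best == {"only": 1.0}


class TestCollisionFit:
    def test_recovery_within_3se(self):
        offsets = make_plasmid_offsets(98, mu=0.5, sigma=0.03, seed=10)
        fit = fit_collision_distribution(offsets)
        assert abs(fit.mu - 0.5) <= 3 * 0.03 / np.sqrt(98)
        assert abs(fit.sigma - 0.03) <= 3 * 0.03 / np.sqrt(2 * 97)
        assert fit.n == 98 and not fit.degenerate

    def test_degenerate_offsets_floor_sigma(self):
        with pytest.warns(UserWarning):
            fit = fit_collision_distribution([0.5, 0.5, 0.5])
        assert fit.degenerate and fit.sigma > 0

    def test_too_few_offsets(self):
        with pytest.raises(InputError):
            fit_collision_distribution([0.5, 0.4])

    def test_null_pvalues_stochastically_large(self):
        # parameters are estimated from the sample, so the KS test is
        # conservative under the null: p-values sit far from zero
        ps = []
        for rep in range(100):
            x = make_plasmid_offsets(98, 0.5, 0.03, seed=500 + rep)
            ps.append(fit_collision_distribution(x).ks_p)
        ps = np.asarray(ps)
        assert ps.mean() > 0.5
        assert ps.min() > 1e-3


def _skewed_plasmid(length=20_000, seed=0, id="plasmid"):
    """Strongly skewed circular plasmid: C-rich then G-rich half."""
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    half = length // 2
    a = rng.choice(bases, size=half, p=[0.25, 0.32, 0.18, 0.25])
    b = rng.choice(bases, size=length - half, p=[0.25, 0.18, 0.32, 0.25])
    return CircularSequence(id, np.concatenate([a, b]).tobytes().decode())


class TestScreenPlasmids:
    def _record(self, seq, **kw):
        defaults = dict(has_repC=False, has_dif=False, iteron_intervals=())
        defaults.update(kw)
        return PlasmidRecord(seq=seq, **defaults)

    def test_small_plasmid_rejected_by_size(self):
        rec = self._record(_skewed_plasmid(9_900, 1))
        accepted, audit = screen_plasmids([rec])
        assert accepted == []
        assert audit.loc[0, "reject_reason"] == "size_and_amplitude"

    def test_planted_ter_rejected(self):
        seq = _skewed_plasmid(20_000, 2)
        planted = seq.seq[:5000] + TER_CONSENSUS_REALIZATION + \
            seq.seq[5000 + 16:]
        rec = self._record(CircularSequence("ter-plasmid", planted))
        accepted, audit = screen_plasmids([rec])
        assert accepted == []
        assert audit.loc[0, "reject_reason"] == "no_ter_no_dif"

    def test_repc_and_iteron_filters(self):
        seq = _skewed_plasmid(20_000, 3)
        rec_repc = self._record(seq, has_repC=True)
        _, audit = screen_plasmids([rec_repc])
        assert audit.loc[0, "reject_reason"] == "no_repC"
        from gcskewsim import find_ori_ter
        ori, _ = find_ori_ter(seq)
        rec_iter = self._record(
            seq, iteron_intervals=((ori, ori + 50),))
        _, audit = screen_plasmids([rec_iter])
        assert audit.loc[0, "reject_reason"] == "no_iteron_near_ori"

    def test_compliant_plasmid_accepted_with_clean_audit(self):
        seq = _skewed_plasmid(20_000, 4)
        ori, _ = __import__("gcskewsim").find_ori_ter(seq)
        far = (ori - 1 + 10_000 - 2000) % 20_000 + 1
        rec = self._record(seq, iteron_intervals=((far, far + 50),))
        accepted, audit = screen_plasmids([rec])
        assert len(accepted) == 1
        row = audit.iloc[0]
        assert row["accepted"] and all(
            row[f] for f in ("size_and_amplitude", "no_ter_no_dif",
                             "no_repC", "no_iteron_near_ori"))

    def test_missing_flags_raise(self):
        with pytest.raises(InputError):
            screen_plasmids([PlasmidRecord(seq=_skewed_plasmid(20_000, 5))])
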