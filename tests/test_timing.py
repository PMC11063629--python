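import itertools

import numpy as np
import pytest

import tumorevo.simulate as sim
import tumorevo.timing as tm


def grid_posterior_stats(loglik, n_grid=1000):
    """Quadrature oracle: posterior mean and central 90% interval."""
    pi = (np.arange(n_grid) + 0.5) / n_grid
    ll = np.asarray(loglik(pi), dtype=float)
    ll -= ll.max()
    w = np.exp(ll)
    w /= w.sum()
    mean = float((pi * w).sum())
    cdf = np.cumsum(w)
    lo = float(pi[np.searchsorted(cdf, 0.05)])
    hi = float(pi[np.searchsorted(cdf, 0.95)])
    return mean, lo, hi


class TestCallWgd:
    def test_diploid_not_wgd(self):
        assert tm.call_wgd(2.0, 0.0) is False

    def test_high_ploidy_wgd(self):
        assert tm.call_wgd(3.8, 0.3) is True  # 3.8 > 2.9 - 0.6

    def test_boundary_is_strict(self):
        loh = 0.25
        assert tm.call_wgd(2.9 - 2 * loh, loh) is False

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            tm.call_wgd(0.0, 0.5)
        with pytest.raises(ValueError):
            tm.call_wgd(2.0, 1.5)


class TestRouteLikelihood:
    def test_monotone_from_zero(self):
        # p(0) = 0 for every route; p(1) = 1 only when no untouched allele
        # dilutes the counts (gain_2+0, wgd_2+2); gain_2+1 tops out at 1/2
        pi = np.linspace(0, 1, 101)
        for route in tm.SIMPLE_ROUTES:
            p = tm.multiplicity2_fraction(pi, route)
            assert p[0] == 0.0
            assert (np.diff(p) > 0).all()
        assert tm.multiplicity2_fraction(1.0, "gain_2+1") == pytest.approx(0.5)
        assert tm.multiplicity2_fraction(1.0, "gain_2+0") == 1.0
        assert tm.multiplicity2_fraction(1.0, "wgd_2+2") == 1.0

    def test_no_mult2_maximized_at_zero(self):
        f = tm.route_log_likelihood(tm.MultiplicityCounts("s", 100, 0), "gain_2+1")
        pi = np.linspace(0, 1, 101)
        assert np.argmax(f(pi)) == 0

    def test_half_fraction_mle_at_one(self):
        # f = 0.5 for gain_2+1 inverts to pi = 3*0.5/1.5 = 1
        assert tm.invert_multiplicity2_fraction(0.5, "gain_2+1") == pytest.approx(1.0)
        f = tm.route_log_likelihood(tm.MultiplicityCounts("s", 100, 100), "gain_2+1")
        pi = np.linspace(0, 1, 1001)
        assert pi[np.argmax(f(pi))] == pytest.approx(1.0, abs=1e-3)

    def test_mle_matches_forward_simulation(self):
        # profile-likelihood maximum against the simulator's counts
        for seed, true_pi in [(0, 0.3), (1, 0.7)]:
            spec = sim.SegmentSpec("s", "chr1", 0, 1, "gain_2+1", true_pi)
            counts, _, _ = sim.simulate_clonal_snvs(
                sim.EvolutionSimConfig(
                    segments=[spec], n_snvs_per_segment=30_000, seed=seed
                )
            )
            f = tm.route_log_likelihood(counts[0], "gain_2+1")
            pi = np.linspace(0.001, 0.999, 999)
            mle = pi[np.argmax(f(pi))]
            assert abs(mle - true_pi) <= 0.02

    def test_unknown_route(self):
        with pytest.raises(ValueError):
            tm.route_log_likelihood(tm.MultiplicityCounts("s", 1, 1), "nope")
        with pytest.raises(ValueError):
            tm.route_log_likelihood(tm.MultiplicityCounts("s", 0, 0), "gain_2+1")


class TestSampleGainTiming:
    def test_defaults_match_printed_settings(self):
        import inspect

        sig = inspect.signature(tm.sample_gain_timing)
        assert sig.parameters["chains"].default == 30
        assert sig.parameters["steps"].default == 2000
        assert sig.parameters["burnin"].default == 1000

    def test_boundary_mle_posterior_high(self):
        # f = n2/(n1+n2) = 0.5 solves 0.5 = pi/(3-pi) at pi = 1: the MLE
        # sits on the boundary and the posterior concentrates near it
        counts = tm.MultiplicityCounts("s", 300, 300)
        post = tm.sample_gain_timing(counts, "gain_2+1", seed=0)
        assert post.mean > 0.9

    def test_matches_quadrature(self):
        rng = np.random.default_rng(7)
        for trial in range(5):
            n = int(rng.integers(50, 500))
            n2 = int(rng.integers(1, n))
            counts = tm.MultiplicityCounts("s", n - n2, n2)
            route = ["gain_2+1", "gain_2+0", "wgd_2+2"][trial % 3]
            post = tm.sample_gain_timing(counts, route, seed=trial)
            mean, lo, hi = grid_posterior_stats(tm.route_log_likelihood(counts, route))
            assert abs(post.mean - mean) < 0.01
            plo, phi = post.interval()
            assert abs(plo - lo) < 0.01 and abs(phi - hi) < 0.01

    def test_sample_count_contract(self):
        post = tm.sample_gain_timing(
            tm.MultiplicityCounts("s", 10, 5), "gain_2+1",
            chains=4, steps=100, burnin=50, seed=1,
        )
        assert len(post.samples) == 4 * 50
        assert (post.samples >= 0).all() and (post.samples <= 1).all()

    def test_deterministic(self):
        c = tm.MultiplicityCounts("s", 20, 10)
        a = tm.sample_gain_timing(c, "gain_2+0", chains=4, steps=200, burnin=100, seed=5)
        b = tm.sample_gain_timing(c, "gain_2+0", chains=4, steps=200, burnin=100, seed=5)
        np.testing.assert_array_equal(a.samples, b.samples)


class TestTimeWgd:
    def _segments(self):
        return [
            tm.AlleleSegment("a", "chr1", 0, 1, 2, 2, 500),
            tm.AlleleSegment("b", "chr2", 0, 1, 2, 0, 500),
        ]

    def test_single_segment_equals_gain_timing(self):
        counts = {"a": tm.MultiplicityCounts("a", 300, 150)}
        joint = tm.time_wgd([self._segments()[0]], counts, seed=3)
        single = tm.sample_gain_timing(counts["a"], "wgd_2+2", seed=3)
        np.testing.assert_array_equal(joint.samples, single.samples)

    def test_joint_interval_narrower(self):
        cfg = sim.EvolutionSimConfig(
            segments=[
                sim.SegmentSpec("a", "chr1", 0, 1000, "wgd_2+2", 0.4),
                sim.SegmentSpec("b", "chr2", 0, 1000, "gain_2+0", 0.4),
            ],
            n_snvs_per_segment=500,
            seed=4,
        )
        counts, _, _ = sim.simulate_clonal_snvs(cfg)
        cd = {c.segment_id: c for c in counts}
        joint = tm.time_wgd(self._segments(), cd, seed=5)
        s_a = tm.sample_gain_timing(cd["a"], "wgd_2+2", seed=5)
        s_b = tm.sample_gain_timing(cd["b"], "gain_2+0", seed=5)

        def width(p):
            lo, hi = p.interval()
            return hi - lo

        assert width(joint) < width(s_a)
        assert width(joint) < width(s_b)

    def test_discordant_segments_mean_between(self):
        cfg = sim.EvolutionSimConfig(
            segments=[
                sim.SegmentSpec("a", "chr1", 0, 1000, "wgd_2+2", 0.2),
                sim.SegmentSpec("b", "chr2", 0, 1000, "wgd_2+2", 0.8),
            ],
            n_snvs_per_segment=500,
            seed=6,
        )
        counts, _, _ = sim.simulate_clonal_snvs(cfg)
        cd = {c.segment_id: c for c in counts}
        segs = [
            tm.AlleleSegment("a", "chr1", 0, 1, 2, 2, 500),
            tm.AlleleSegment("b", "chr2", 0, 1, 2, 2, 500),
        ]
        joint = tm.time_wgd(segs, cd, seed=7)
        assert 0.2 < joint.mean < 0.8

    def test_no_eligible_segments(self):
        with pytest.raises(ValueError):
            tm.time_wgd([tm.AlleleSegment("x", "chr1", 0, 1, 2, 1, 50)], {}, seed=0)


class TestClassifyGainRoute:
    def _wgd_posterior(self, w=0.3, seed=8):
        cfg = sim.EvolutionSimConfig(
            segments=[
                sim.SegmentSpec("a", "chr1", 0, 1000, "wgd_2+2", w),
                sim.SegmentSpec("b", "chr2", 0, 1000, "gain_2+0", w),
            ],
            n_snvs_per_segment=500,
            seed=seed,
        )
        counts, _, _ = sim.simulate_clonal_snvs(cfg)
        cd = {c.segment_id: c for c in counts}
        segs = [
            tm.AlleleSegment("a", "chr1", 0, 1, 2, 2, 500),
            tm.AlleleSegment("b", "chr2", 0, 1, 2, 0, 500),
        ]
        return tm.time_wgd(segs, cd, seed=seed)

    @pytest.mark.parametrize(
        "route,major,g,w",
        [
            ("post_wgd", 4, 0.7, 0.3),
            ("pre_wgd", 4, 0.15, 0.3),
            ("post_wgd", 3, 0.7, 0.3),
            ("pre_wgd", 3, 0.15, 0.3),
        ],
    )
    def test_true_route_recovered(self, route, major, g, w):
        wgd_post = self._wgd_posterior(w)
        spec = sim.SegmentSpec(
            "x", "chr3", 0, 1000, route, g, true_wgd_pi=w, major_cn=major
        )
        counts, _, _ = sim.simulate_clonal_snvs(
            sim.EvolutionSimConfig(segments=[spec], n_snvs_per_segment=500, seed=11)
        )
        segment = tm.AlleleSegment("x", "chr3", 0, 1, major, 2, 500)
        p_pre, p_post, post = tm.classify_gain_route(segment, counts[0], wgd_post, seed=1)
        p_true = p_pre if route == "pre_wgd" else p_post
        assert p_true >= 0.8
        assert abs(post.mean - g) < 0.1

    def test_symmetric_when_uninformative(self):
        # both route weights zero (similarity 0 against a disjoint posterior)
        segment = tm.AlleleSegment("x", "chr3", 0, 1, 4, 2, 10)
        counts = tm.MultiplicityCounts("x", 0, 0, 0, 10)  # all mult 4: g,w ~ 1
        point = tm.TimingPosterior(np.full(100, 0.005))  # WGD mass at ~0
        p_pre, p_post, _ = tm.classify_gain_route(segment, counts, point, seed=0)
        assert p_pre + p_post == pytest.approx(1.0)

    def test_non_wgd_rejected(self):
        segment = tm.AlleleSegment("x", "chr3", 0, 1, 3, 2, 50)
        with pytest.raises(ValueError):
            tm.classify_gain_route(
                segment, tm.MultiplicityCounts("x", 10, 10), tm.TimingPosterior([0.5]),
                wgd=False,
            )


class TestFilters:
    def test_snv_count_boundary(self):
        low = tm.AlleleSegment("a", "chr1", 0, 1, 2, 1, 9)
        ok = tm.AlleleSegment("b", "chr1", 1, 2, 2, 1, 10)
        kept = tm.filter_timeable_segments([low, ok], wgd=False)
        assert [s.segment_id for s in kept] == ["b"]

    def test_minor_cn_boundary(self):
        bad = tm.AlleleSegment("a", "chr1", 0, 1, 4, 3, 50)
        ok = tm.AlleleSegment("b", "chr1", 1, 2, 4, 2, 50)
        kept = tm.filter_timeable_segments([bad, ok], wgd=True)
        assert [s.segment_id for s in kept] == ["b"]

    def test_major_cn_depends_on_wgd(self):
        seg3 = tm.AlleleSegment("a", "chr1", 0, 1, 3, 1, 50)
        assert tm.filter_timeable_segments([seg3], wgd=False) == []
        assert tm.filter_timeable_segments([seg3], wgd=True) == [seg3]

    def test_idempotent(self):
        segs = [
            tm.AlleleSegment("a", "chr1", 0, 1, 2, 1, 50),
            tm.AlleleSegment("b", "chr1", 1, 2, 5, 2, 50),
        ]
        once = tm.filter_timeable_segments(segs, wgd=True)
        twice = tm.filter_timeable_segments(once, wgd=True)
        assert once == twice


class TestPdxRefinement:
    def _timeline(self):
        return tm.TumorTimeline(
            "t1",
            [
                tm.TimelineEvent("kept", clonality="clonal"),
                tm.TimelineEvent("lost", clonality="clonal"),
                tm.TimelineEvent("sub", clonality="subclonal"),
            ],
        )

    def test_clonal_absent_becomes_subclonal(self):
        out = tm.refine_clonality_with_pdx(self._timeline(), {"kept"})
        assert out.get("lost").clonality == "subclonal"

    def test_clonal_present_unchanged(self):
        out = tm.refine_clonality_with_pdx(self._timeline(), {"kept"})
        assert out.get("kept").clonality == "clonal"

    def test_subclonal_absent_unchanged(self):
        out = tm.refine_clonality_with_pdx(self._timeline(), {"kept"})
        assert out.get("sub").clonality == "subclonal"

    def test_idempotent_and_pure(self):
        timeline = self._timeline()
        once = tm.refine_clonality_with_pdx(timeline, {"kept"})
        twice = tm.refine_clonality_with_pdx(once, {"kept"})
        assert [e.clonality for e in once.events] == [e.clonality for e in twice.events]
        assert timeline.get("lost").clonality == "clonal"  # input not mutated


def condorcet_order(timelines, event_ids):
    """Brute-force pairwise-majority ordering on point-mass timelines."""
    wins = {e: 0 for e in event_ids}
    for a, b in itertools.combinations(event_ids, 2):
        earlier_a = earlier_b = 0
        for t in timelines:
            if a in t.event_ids() and b in t.event_ids():
                va = t.get(a).posterior.samples[0]
                vb = t.get(b).posterior.samples[0]
                if va < vb:
                    earlier_a += 1
                elif vb < va:
                    earlier_b += 1
        if earlier_a > earlier_b:
            wins[a] += 1
        elif earlier_b > earlier_a:
            wins[b] += 1
    return sorted(event_ids, key=lambda e: -wins[e])


def point_mass_timelines(orders):
    timelines = []
    for i, order in enumerate(orders):
        events = [
            tm.TimelineEvent(
                e, posterior=tm.TimingPosterior([pos]), order_index=pos
            )
            for pos, e in enumerate(order)
        ]
        timelines.append(tm.TumorTimeline(f"t{i}", events))
    return timelines


class TestLeagueRank:
    def test_strict_identical_order_always_recovered(self):
        timelines = point_mass_timelines([["a", "b", "c"]] * 5)
        ranking = tm.league_rank(timelines, seed=0)
        expected = np.tile([1.0, 2.0, 3.0], (100, 1))
        np.testing.assert_array_equal(ranking.rank_samples, expected)

    def test_isolated_event_scores_zero(self):
        # event "solo" shares no tumor with any other event
        t1 = tm.TumorTimeline(
            "t1",
            [
                tm.TimelineEvent("a", posterior=tm.TimingPosterior([0.1])),
                tm.TimelineEvent("b", posterior=tm.TimingPosterior([0.9])),
            ],
        )
        t2 = tm.TumorTimeline(
            "t2", [tm.TimelineEvent("solo", posterior=tm.TimingPosterior([0.5]))]
        )
        ranking = tm.league_rank([t1, t2], seed=1)
        assert ranking.mean_scores[ranking.event_ids.index("solo")] == 0.0

    def test_identical_distributions_symmetric(self):
        rng = np.random.default_rng(2)
        samples = rng.uniform(size=200)
        timelines = [
            tm.TumorTimeline(
                f"t{i}",
                [
                    tm.TimelineEvent("a", posterior=tm.TimingPosterior(samples)),
                    tm.TimelineEvent("b", posterior=tm.TimingPosterior(samples)),
                ],
            )
            for i in range(5)
        ]
        ranking = tm.league_rank(timelines, n_iter=100, seed=3)
        diff = ranking.mean_scores[0] - ranking.mean_scores[1]
        se = ranking.rank_samples[:, 0].std() / 10 + 1e-9
        assert abs(diff) <= 3 * max(se, 0.3)

    def test_matches_condorcet_on_consistent_cohort(self):
        order = ["w", "x", "y", "z"]
        timelines = point_mass_timelines([order] * 10)
        ranking = tm.league_rank(timelines, seed=4)
        assert ranking.ordering() == condorcet_order(timelines, sorted(order))

    def test_order_index_fallback(self):
        # no posteriors at all: recorded relative order decides
        timelines = [
            tm.TumorTimeline(
                "t0",
                [
                    tm.TimelineEvent("late", order_index=1),
                    tm.TimelineEvent("early", order_index=0),
                ],
            )
        ]
        ranking = tm.league_rank(timelines, seed=5)
        assert ranking.ordering() == ["early", "late"]

    def test_prevalence(self):
        t1 = point_mass_timelines([["a", "b"]])[0]
        t2 = tm.TumorTimeline("t9", [tm.TimelineEvent("a", posterior=tm.TimingPosterior([0.1]))])
        ranking = tm.league_rank([t1, t2], seed=6)
        assert ranking.prevalence[ranking.event_ids.index("a")] == 1.0
        assert ranking.prevalence[ranking.event_ids.index("b")] == 0.5

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            tm.league_rank([tm.TumorTimeline("t", [])])
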