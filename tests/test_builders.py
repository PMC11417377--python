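"""Universe builders: worked examples, identities, and decoding oracles."""

import numpy as np
import pytest
from sklearn.base import clone

from flexiverse import (
    CoverageCutoffBuilder,
    CoverageStats,
    FixedInterval,
    FlexibleCutoffBuilder,
    FlexibleInterval,
    FixtureSpec,
    HMMBuilder,
    MaxLikelihoodBuilder,
    RegionSet,
    RegionSetCollection,
    TilesBuilder,
    TrackModels,
    UnionBuilder,
    cc_universe,
    ccf_universe,
    compute_tracks,
    filter_universe,
    generate_collection,
    hmm_universe,
    intersection_universe,
    lh_universe,
    optimal_cutoff,
    tiles_universe,
    union_universe,
)
from flexiverse.builders import DEFAULT_TRANSITIONS, _viterbi

from conftest import random_collection
from oracles import best_hmm_path_score, best_labeling_score


def spans(universe):
    return [(r.chrom, r.outer_start, r.outer_end) for r in universe]


def coll_of(*span_lists):
    return RegionSetCollection(
        [
            RegionSet(f"s{i}", [FixedInterval("chr1", a, b) for a, b in sl])
            for i, sl in enumerate(span_lists)
        ]
    )


class TestUnionIntersectionTiles:
    def test_union_merges_overlap(self, two_set_collection, chr1_20):
        assert spans(union_universe(two_set_collection, chr1_20)) == [("chr1", 0, 15)]

    def test_union_single_set_identity(self, chr1_20):
        coll = coll_of([(0, 5), (3, 8), (12, 15)])
        assert spans(union_universe(coll, chr1_20)) == [("chr1", 0, 8), ("chr1", 12, 15)]

    def test_union_empty_collection_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            u = union_universe(RegionSetCollection([]), {"chr1": 10})
        assert len(u) == 0

    def test_intersection_examples(self, two_set_collection, chr1_20):
        assert spans(intersection_universe(two_set_collection, chr1_20)) == [
            ("chr1", 5, 10)
        ]
        same = coll_of([(2, 8)], [(2, 8)])
        assert spans(intersection_universe(same, chr1_20)) == [("chr1", 2, 8)]
        disjoint = coll_of([(0, 4)], [(10, 14)])
        assert len(intersection_universe(disjoint, chr1_20)) == 0

    def test_tiles_partial_final_tile(self):
        u = tiles_universe({"chr1": 2500})
        assert spans(u) == [("chr1", 0, 1000), ("chr1", 1000, 2000), ("chr1", 2000, 2500)]
        assert len(tiles_universe({"chr1": 1000})) == 1
        assert len(tiles_universe({"chr1": 37}, tile_size=1)) == 37


class TestCoverageCutoff:
    def test_optimal_cutoff_examples(self):
        assert optimal_cutoff(CoverageStats(10, 10), 5) == 1
        assert optimal_cutoff(CoverageStats(55, 10), 8) == 6
        assert optimal_cutoff(CoverageStats(0, 100), 4) == 1

    def test_threshold_runs(self):
        # coverage profile [0,1,2,2,1,0]
        coll = coll_of([(1, 5)], [(2, 4)])
        tr = compute_tracks(coll, {"chr1": 6})
        assert spans(cc_universe(tr, 2)) == [("chr1", 2, 4)]

    def test_cutoff_extremes_match_union_and_intersection(self, rng):
        sizes = {"chr1": 120}
        for _ in range(15):
            coll = random_collection(rng, n_sets=int(rng.integers(1, 5)), genome_len=110)
            tr = compute_tracks(coll, sizes)
            assert spans(cc_universe(tr, 1)) == spans(union_universe(coll, sizes))
            assert spans(cc_universe(tr, coll.n)) == spans(
                intersection_universe(coll, sizes)
            )

    def test_covered_bases_anti_monotone_in_cutoff(self, rng):
        coll = random_collection(rng, n_sets=5, genome_len=100)
        tr = compute_tracks(coll, {"chr1": 100})
        prev = None
        for x in range(1, 6):
            bases = {
                (c, i) for c, a, b in spans(cc_universe(tr, x)) for i in range(a, b)
            }
            if prev is not None:
                assert bases <= prev
            prev = bases

    def test_cutoff_above_max_coverage_warns_empty(self, two_set_collection, chr1_20):
        tr = compute_tracks(two_set_collection, chr1_20)
        with pytest.warns(UserWarning, match="exceeds"):
            assert len(cc_universe(tr, 5)) == 0


class TestFlexibleCutoff:
    def test_two_threshold_worked_example(self):
        # coverage profile [0,1,2,3,3,2,1,0]
        coll = coll_of([(1, 7)], [(2, 6)], [(3, 5)])
        tr = compute_tracks(coll, {"chr1": 8})
        u = ccf_universe(tr, 2, 3)
        assert u.regions == (FlexibleInterval("chr1", 2, 3, 5, 6),)

    def test_equal_cutoffs_collapse_to_cc(self):
        coll = coll_of([(1, 5)], [(2, 4)])
        tr = compute_tracks(coll, {"chr1": 6})
        u = ccf_universe(tr, 2, 2)
        (r,) = u.regions
        assert (r.start_start, r.start_end, r.end_start, r.end_end) == (2, 2, 4, 4)

    def test_run_without_core_is_dropped(self):
        # coverage profile [1,2,2,1]
        coll = coll_of([(0, 4)], [(1, 3)])
        tr = compute_tracks(coll, {"chr1": 4})
        assert len(ccf_universe(tr, 2, 3)) == 0

    def test_cores_equal_cc_upper_spans(self, rng):
        """Each flexible core reproduces the plain cutoff universe at x_upper."""
        for _ in range(15):
            coll = random_collection(rng, n_sets=5, genome_len=80)
            tr = compute_tracks(coll, {"chr1": 80})
            for lower, upper in ((1, 2), (2, 3), (2, 4)):
                u = ccf_universe(tr, lower, upper)
                cores = [(r.chrom, *r.core) for r in u]
                assert cores == spans(cc_universe(tr, upper))
                # outer spans tile the lower-cutoff runs
                for r in u:
                    assert r.start_start <= r.start_end <= r.end_start <= r.end_end


class TestMaxLikelihood:
    def test_single_region_path(self):
        coll = coll_of([(1, 3)], [(1, 3)])
        tr = compute_tracks(coll, {"chr1": 4})
        u = lh_universe(tr)
        assert u.regions == (FlexibleInterval("chr1", 1, 2, 2, 3),)

    def test_all_zero_tracks_give_empty_universe(self):
        coll = RegionSetCollection([RegionSet("empty", [])])
        tr = compute_tracks(coll, {"chr1": 10})
        assert len(lh_universe(tr)) == 0

    def test_abutting_regions_via_end_start_transition(self):
        coll = coll_of([(0, 2), (2, 4)], [(0, 2), (2, 4)])
        tr = compute_tracks(coll, {"chr1": 4})
        u = lh_universe(tr)
        assert u.regions == (
            FlexibleInterval("chr1", 0, 1, 1, 2),
            FlexibleInterval("chr1", 2, 3, 3, 4),
        )

    def test_dp_score_matches_exhaustive_enumeration(self, rng):
        """The DP optimum equals the brute-force max over all valid labelings."""
        for _ in range(30):
            coll = random_collection(rng, n_sets=int(rng.integers(1, 4)), genome_len=8)
            tr = compute_tracks(coll, {"chr1": 8})
            builder = MaxLikelihoodBuilder().fit(coll, chrom_sizes={"chr1": 8})
            sigma = builder.models_.score_matrix("chr1")
            assert builder.path_scores_["chr1"] == pytest.approx(
                best_labeling_score(sigma), abs=1e-9
            )


class TestHMM:
    def test_matches_lh_under_sharp_emissions(self):
        coll = coll_of([(1, 3)], [(1, 3)])
        tr = compute_tracks(coll, {"chr1": 4})
        sharp = {
            "B": (0.01, 0.01, 0.01),
            "S": (0.99, 0.99, 0.01),
            "C": (0.01, 0.99, 0.01),
            "E": (0.01, 0.99, 0.99),
        }
        assert hmm_universe(tr, emissions=sharp).regions == lh_universe(tr).regions

    def test_all_zero_tracks_default_params_empty(self):
        coll = RegionSetCollection([RegionSet("e1", []), RegionSet("e2", [])])
        tr = compute_tracks(coll, {"chr1": 20})
        assert len(hmm_universe(tr)) == 0

    def test_background_persistence_never_adds_regions(self, rng):
        """Raising the B self-transition cannot increase the region count."""
        coll = random_collection(rng, n_sets=4, genome_len=60)
        tr = compute_tracks(coll, {"chr1": 60})
        counts = []
        for b_self in (0.3, 0.6, 0.9, 0.99):
            trans = np.array(DEFAULT_TRANSITIONS)
            trans[0] = [b_self, 1 - b_self, 0, 0]
            counts.append(len(hmm_universe(tr, transitions=trans)))
        assert counts == sorted(counts, reverse=True)

    def test_viterbi_matches_brute_force_path_max(self, rng):
        trans_log = np.log(np.where(DEFAULT_TRANSITIONS > 0, DEFAULT_TRANSITIONS, 1))
        trans_log[DEFAULT_TRANSITIONS == 0] = -np.inf
        init_log = np.array([np.log(0.9), np.log(0.1), -np.inf, -np.inf])
        final_log = np.array([0.0, -np.inf, -np.inf, 0.0])
        for _ in range(20):
            emit = rng.normal(size=(8, 4))
            _, score = _viterbi(emit, trans_log, init_log, final_log)
            assert score == pytest.approx(
                best_hmm_path_score(emit, trans_log, init_log), abs=1e-9
            )

    @pytest.mark.parametrize(
        "bad",
        [
            {"transitions": np.eye(4)},  # no B->S, rows fine
            {"transitions": np.full((4, 4), 0.25)},  # forbidden transitions
            {"emissions": {"B": (0.0, 0.5, 0.5), "S": (0.5,) * 3, "C": (0.5,) * 3, "E": (0.5,) * 3}},
        ],
        ids=["unreachable-start", "forbidden-mass", "theta-out-of-range"],
    )
    def test_degenerate_params_rejected(self, two_set_collection, chr1_20, bad):
        with pytest.raises(ValueError):
            HMMBuilder(**bad).fit(two_set_collection, chrom_sizes=chr1_20)


class TestFilter:
    def test_min_width(self):
        u = filter_universe(
            pytest.importorskip("flexiverse").Universe(
                [FixedInterval("chr1", 0, 5), FixedInterval("chr1", 10, 60)]
            ),
            min_width=10,
        )
        assert spans(u) == [("chr1", 10, 60)]

    def test_defaults_are_identity(self, two_set_collection, chr1_20):
        base = union_universe(two_set_collection, chr1_20)
        assert filter_universe(base).regions == base.regions

    def test_region_over_empty_tracks_has_negative_loglik(self):
        coll = coll_of([(0, 3)], [(0, 3)])
        tr = compute_tracks(coll, {"chr1": 20})
        models = TrackModels(tr)
        from flexiverse import Universe

        u = Universe([FixedInterval("chr1", 5, 8)])
        filtered = filter_universe(u, min_region_loglik=0.0, models=models)
        assert len(filtered) == 0
        kept = filter_universe(
            Universe([FixedInterval("chr1", 0, 3)]), min_region_loglik=0.0, models=models
        )
        assert len(kept) == 1

    def test_likelihood_filter_needs_models(self):
        from flexiverse import Universe

        with pytest.raises(ValueError, match="models"):
            filter_universe(Universe([]), min_region_loglik=0.0)


class TestRecoveryAndInvariants:
    def test_all_builders_emit_non_overlapping_sorted_universes(self, rng):
        sizes = {"chr1": 100}
        for _ in range(5):
            coll = random_collection(rng, n_sets=4, genome_len=90)
            tr = compute_tracks(coll, sizes)
            universes = [
                union_universe(coll, sizes),
                intersection_universe(coll, sizes),
                cc_universe(tr),
                ccf_universe(tr),
                lh_universe(tr),
                hmm_universe(tr),
                tiles_universe(sizes, 30),
            ]
            for u in universes:
                for a, b in zip(u.regions, u.regions[1:]):
                    assert a.chrom < b.chrom or a.outer_end <= b.outer_start

    def test_noiseless_fixture_recovered_exactly(self):
        """With no jitter/dropout/noise, LH and HMM recover the loci exactly."""
        spec = FixtureSpec(
            genome={"chr1": 10_000}, k=8, n_sets=5, jitter_sd=0.0,
            dropout_p=0.0, noise_rate=0.0, seed=7,
        )
        coll, truth = generate_collection(spec)
        tr = compute_tracks(coll, dict(spec.genome))
        for u in (lh_universe(tr), hmm_universe(tr)):
            assert [(r.chrom, r.outer_start, r.outer_end) for r in u] == [
                (t.chrom, t.outer_start, t.outer_end) for t in truth
            ]
            # true boundaries sit inside the built boundary intervals
            for r, t in zip(u, truth):
                assert r.start_start <= t.start_end <= r.start_end
                assert r.end_start <= t.end_start <= r.end_end

    def test_jittered_boundary_intervals_overlap_truth_window(self):
        """At 1 bp jitter the built boundary intervals land inside the
        ground-truth jitter window (count recovered, windows intersect)."""
        hits = 0
        reps = 12
        for seed in range(reps):
            spec = FixtureSpec(
                genome={"chr1": 12_000}, k=10, n_sets=10, jitter_sd=1.0,
                dropout_p=0.0, noise_rate=0.0, seed=seed,
            )
            coll, truth = generate_collection(spec)
            tr = compute_tracks(coll, dict(spec.genome))
            for u in (lh_universe(tr), hmm_universe(tr)):
                if len(u) != spec.k:
                    continue
                if all(
                    r.start_start <= t.start_end
                    and t.start_start <= r.start_end
                    and r.end_start <= t.end_end
                    and t.end_start <= r.end_end
                    for r, t in zip(u, truth)
                ):
                    hits += 1
        assert hits >= 2 * reps - 1


class TestSklearnProtocol:
    def test_get_set_params_and_clone(self):
        b = CoverageCutoffBuilder(cutoff=3)
        assert b.get_params() == {"cutoff": 3}
        b2 = clone(b).set_params(cutoff=None)
        assert b2.get_params()["cutoff"] is None
        assert clone(FlexibleCutoffBuilder(lower=1, upper=4)).get_params() == {
            "lower": 1,
            "upper": 4,
        }

    def test_transform_tokenizes_and_score_is_mean_f10(self, two_set_collection, chr1_20):
        b = UnionBuilder().fit(two_set_collection, chrom_sizes=chr1_20)
        res = b.transform(two_set_collection[0])
        assert res.assignments == [[0]]
        from flexiverse import f10_collection

        assert b.score(two_set_collection) == pytest.approx(
            f10_collection(b.universe_, two_set_collection).mean
        )

    def test_unfitted_raises(self, two_set_collection):
        with pytest.raises(RuntimeError):
            TilesBuilder().transform(two_set_collection[0])
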