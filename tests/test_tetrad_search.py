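"""Null thresholds, verification, the search phases, and the full pipeline."""

import numpy as np
import pytest

import tetradkit.info_measures as im
from tetradkit.config import ReconstructionConfig
from tetradkit.sim_meiosis import SimConfig, simulate
from tetradkit.tetrad_search import (
    NullThresholds,
    SearchState,
    build_null,
    direct_search,
    find_pairs,
    find_triplets,
    run_pipeline,
    shadow_search,
    threshold_from_null,
    verify_tetrad,
    verify_triplet,
)

from conftest import matrix_from_calls


def _lenient_thresholds(**overrides):
    base = dict(d4_threshold=1e-10, d3_threshold=-1e-10, mi_threshold=0.01,
                n_permutations=1000, p4=0.05, p3=0.01, p2=0.05)
    base.update(overrides)
    return NullThresholds(**base)


def _independent_matrix(n_spores, n_markers, seed=0):
    rng = np.random.default_rng(seed)
    return matrix_from_calls(rng.integers(0, 2, (n_spores, n_markers)).astype(np.int8))


def _tetrad_block_matrix(n_tetrads, n_markers, seed=0):
    """Spores drawn marker-wise from the ideal 2:2 distribution per tetrad."""
    rng = np.random.default_rng(seed)
    pats = im.ideal_tetrad_patterns()
    blocks = [pats[rng.integers(0, 6, n_markers)].T for _ in range(n_tetrads)]
    return matrix_from_calls(np.vstack(blocks))


class TestThresholdFromNull:
    def test_right_tail_quantile_element(self):
        null = np.arange(1, 101, dtype=float)
        assert threshold_from_null(null, 0.05, "right") == 95.0

    def test_median(self):
        null = np.arange(1, 102, dtype=float)
        assert threshold_from_null(null, 0.5, "right") == 51.0

    def test_symmetric_mirror(self):
        null = np.concatenate([np.arange(-50, 0), np.arange(1, 51)]).astype(float)
        right = threshold_from_null(null, 0.05, "right")
        left = threshold_from_null(-null, 0.05, "left")
        assert left == -right

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            threshold_from_null(np.arange(10.0), 0.0, "right")


class TestBuildNull:
    def test_independent_data_null_centred_on_zero(self):
        m = _independent_matrix(40, 400, seed=3)
        null = build_null(m, 4, 2000, seed=1)
        assert abs(np.median(null)) < 1e-8

    def test_same_seed_identical(self):
        m = _independent_matrix(20, 100, seed=4)
        a = build_null(m, 3, 1500, seed=9)
        b = build_null(m, 3, 1500, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_too_few_spores(self):
        m = _independent_matrix(3, 50)
        with pytest.raises(ValueError):
            build_null(m, 4, 1000, seed=0)

    def test_null_separates_true_tetrads(self):
        # every true tetrad's delta exceeds the p=0.05 right-tail threshold
        m = _tetrad_block_matrix(25, 500, seed=5)
        null = build_null(m, 4, 5000, seed=2)
        thr = threshold_from_null(null, 0.05, "right")
        quads = np.array([[4 * t + k for k in range(4)] for t in range(25)])
        d4 = im.score_quads(m.calls, quads)[0]
        assert (d4 > thr).all()


class TestVerification:
    def test_true_tetrad_passes(self, clean_sim):
        matrix, _ = clean_sim
        ok, frac = verify_tetrad(matrix, (0, 1, 2, 3))
        assert ok and frac == 1.0

    def test_independent_quad_near_six_sixteenths(self):
        # all 16 patterns equally often -> exactly 6/16 markers are 2:2
        cols = [[(p >> j) & 1 for j in range(4)] for p in range(16)]
        m = matrix_from_calls(np.array(cols, dtype=np.int8).T)
        ok, frac = verify_tetrad(m, (0, 1, 2, 3))
        assert not ok
        assert frac == pytest.approx(6 / 16)

    def test_zero_complete_case_fails(self):
        # every marker is missing in at least one group member
        m = matrix_from_calls([[0, -1], [-1, 0], [1, 1], [1, 1]])
        ok, frac = verify_tetrad(m, (0, 1, 2, 3))
        assert not ok and np.isnan(frac)

    def test_triplet_of_clean_tetrad_passes(self, clean_sim):
        matrix, _ = clean_sim
        ok, frac = verify_triplet(matrix, (0, 1, 2))
        assert ok and frac == 1.0

    def test_identical_triplet_fails(self):
        m = matrix_from_calls([[0, 1, 0, 1]] * 3)
        ok, frac = verify_triplet(m, (0, 1, 2))
        assert not ok and frac == 0.0

    def test_independent_triplet_six_eighths(self):
        cols = [[(p >> j) & 1 for j in range(3)] for p in range(8)]
        m = matrix_from_calls(np.array(cols, dtype=np.int8).T)
        ok, frac = verify_triplet(m, (0, 1, 2), cutoff=0.95)
        assert not ok
        assert frac == pytest.approx(6 / 8)


class TestSearchPhases:
    def test_direct_recovers_two_tetrads(self):
        m = _tetrad_block_matrix(2, 400, seed=7)
        state = SearchState(m)
        direct_search(state, range(8), _lenient_thresholds())
        found = {g.indices for g in state.accepted}
        assert found == {(0, 1, 2, 3), (4, 5, 6, 7)}

    def test_direct_leaves_stray(self):
        m = _tetrad_block_matrix(2, 400, seed=8)
        state = SearchState(m)
        direct_search(state, range(5), _lenient_thresholds())  # tetrad 0 + 1 stray
        assert {g.indices for g in state.accepted} == {(0, 1, 2, 3)}
        assert 4 in state.pool

    def test_failed_verification_returns_spores_to_pool(self):
        # strongly dependent but 3:1-segregating group (one B rotating
        # through the four spores): positive delta, zero 2:2 fraction
        pats = np.array([[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 0], [0, 0, 0, 1]])
        cols = np.tile(pats, (100, 1))
        m = matrix_from_calls(cols.T.astype(np.int8))
        state = SearchState(m)
        direct_search(state, range(4), _lenient_thresholds())
        assert not state.accepted
        assert state.pool == {0, 1, 2, 3}
        assert any(e["outcome"] == "rejected_2:2" for e in state.audit)

    def test_shadow_recovers_three_tetrads(self):
        m = _tetrad_block_matrix(3, 400, seed=9)
        state = SearchState(m)
        shadow_search(state, range(12), range(12), _lenient_thresholds())
        assert {g.indices for g in state.accepted} == {
            (0, 1, 2, 3), (4, 5, 6, 7), (8, 9, 10, 11)
        }

    def test_shadow_cross_cluster_repair(self):
        # three sisters in the searched set, the fourth only in the extension
        m = _tetrad_block_matrix(1, 400, seed=10)
        state = SearchState(m)
        shadow_search(state, [0, 1, 2], [3], _lenient_thresholds())
        assert {g.indices for g in state.accepted} == {(0, 1, 2, 3)}

    def test_shadow_empty_extension_finds_nothing(self):
        m = _tetrad_block_matrix(1, 400, seed=11)
        state = SearchState(m)
        shadow_search(state, [0, 1, 2], [], _lenient_thresholds())
        assert not state.accepted

    def test_find_triplets_on_truncated_tetrad(self):
        m = _tetrad_block_matrix(1, 400, seed=12).subset_spores([0, 1, 2])
        state = SearchState(m)
        find_triplets(state, _lenient_thresholds())
        assert {g.indices for g in state.accepted} == {(0, 1, 2)}
        assert state.accepted[0].kind == "triplet"
        assert state.accepted[0].score < 0  # sister triplets are negative

    def test_find_triplets_ignores_independent_spores(self):
        m = _independent_matrix(9, 400, seed=13)
        state = SearchState(m)
        null3 = build_null(m, 3, 2000, seed=3)
        thr = _lenient_thresholds(
            d3_threshold=threshold_from_null(null3, 0.01, "left")
        )
        find_triplets(state, thr)
        assert len(state.accepted) <= 1  # at most false-positive expectation

    def test_find_pairs_on_truncated_tetrad(self):
        m = _tetrad_block_matrix(1, 400, seed=14).subset_spores([0, 1])
        state = SearchState(m)
        find_pairs(state, _lenient_thresholds())
        assert {g.indices for g in state.accepted} == {(0, 1)}
        assert state.accepted[0].score == pytest.approx(im.IDEAL_PAIR_MI, abs=0.05)


class TestRunPipeline:
    def test_noise_free_recovery(self, clean_sim, centromeres):
        matrix, truth = clean_sim
        from tetradkit.evaluation import score_against_truth

        assignment, report = run_pipeline(
            matrix, centromeres, ReconstructionConfig(seed=5)
        )
        ev = score_against_truth(assignment, truth)
        assert ev.detected_tetrads_pct == 100.0
        assert ev.false_tetrads == 0
        assert report["group_counts"]["tetrad"] == truth.n_tetrads

    def test_spore_conservation(self, noisy_sim, centromeres):
        matrix, _ = noisy_sim
        assignment, _ = run_pipeline(matrix, centromeres, ReconstructionConfig(seed=5))
        assert sorted(assignment.spore_ids) == sorted(matrix.spore_ids)

    def test_accepted_groups_pass_verification(self, noisy_sim, centromeres):
        matrix, _ = noisy_sim
        config = ReconstructionConfig(seed=5)
        assignment, _ = run_pipeline(matrix, centromeres, config)
        row = {sid: i for i, sid in enumerate(matrix.spore_ids)}
        for g in assignment.groups_of_kind("tetrad"):
            ok, _ = verify_tetrad(
                matrix, [row[s] for s in g.spore_ids], config.seg_cutoff_d4
            )
            assert ok
        for g in assignment.groups_of_kind("triplet"):
            ok, _ = verify_triplet(
                matrix, [row[s] for s in g.spore_ids], config.seg_cutoff_d3
            )
            assert ok

    def test_seed_determinism(self, centromeres):
        matrix, _ = simulate(
            SimConfig(n_tetrads=12, n_markers=300, noise_rate=0.01,
                      missing_rate=0.05, seed=31)
        )
        cfg = ReconstructionConfig(seed=17)
        a1, _ = run_pipeline(matrix, centromeres, cfg)
        a2, _ = run_pipeline(matrix, centromeres, cfg)
        assert [(g.group_id, g.kind, g.spore_ids) for g in a1.groups] == [
            (g.group_id, g.kind, g.spore_ids) for g in a2.groups
        ]

    def test_partial_tetrads_labelled(self, centromeres):
        # remove one spore from one tetrad and two from another; enough
        # tetrads that random sister sampling does not dominate the nulls
        matrix, truth = simulate(
            SimConfig(n_tetrads=20, n_markers=400, noise_rate=0, missing_rate=0, seed=33)
        )
        keep = [i for i, s in enumerate(matrix.spore_ids) if s not in
                {"T0000_0", "T0001_0", "T0001_1"}]
        sub = matrix.subset_spores(keep)
        assignment, _ = run_pipeline(sub, centromeres, ReconstructionConfig(seed=5))
        kinds = {k: len(assignment.groups_of_kind(k)) for k in
                 ("tetrad", "triplet", "pair", "single")}
        assert kinds["tetrad"] == 18
        assert kinds["triplet"] == 1
        triplet = assignment.groups_of_kind("triplet")[0]
        assert {s.split("_")[0] for s in triplet.spore_ids} == {"T0000"}
        # the two leftover sisters are never mis-grouped: they come out as a
        # pair or as singles (their pooled marker-wise MI is weak because
        # pole mates agree near centromeres but anti-correlate distally)
        leftovers = [g for g in assignment.groups if g.kind in ("pair", "single")]
        leftover_spores = {s for g in leftovers for s in g.spore_ids}
        assert leftover_spores == {"T0001_2", "T0001_3"}
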