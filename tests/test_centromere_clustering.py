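"""Centromere calling, similarity, clustering, and the recombination model."""

import numpy as np
import pytest

from tetradkit.centromere_clustering import (
    CentromereProfiles,
    RecombinationModel,
    call_centromeres,
    centromere_posterior,
    cluster_spores,
    estimate_cos_per_mega,
    haldane_r,
    pattern_collision_probability,
    similarity,
    similarity_matrix,
)
from tetradkit.genotype_io import CentromereTable
from tetradkit.sim_meiosis import SimConfig, simulate

from conftest import matrix_from_calls


class TestHaldane:
    def test_zero_distance(self):
        assert haldane_r(0, RecombinationModel(6.0)) == 0.0

    def test_large_distance_limit(self):
        assert haldane_r(10**9, RecombinationModel(6.0)) == pytest.approx(0.5, abs=1e-9)

    def test_closed_form(self):
        # cpm=6, 100 kb -> m=0.3 Morgan, r=(1-e^-0.6)/2
        r = haldane_r(100_000, RecombinationModel(6.0))
        assert r == pytest.approx((1 - np.exp(-0.6)) / 2, abs=1e-12)
        assert r == pytest.approx(0.22559, abs=5e-6)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            haldane_r(-1, RecombinationModel(6.0))


class TestEstimateCosPerMega:
    def test_no_switches_gives_zero(self):
        m = matrix_from_calls([[0, 0, 0], [1, 1, 1]], positions=[1, 500_000, 1_000_000])
        assert estimate_cos_per_mega(m).cos_per_mega == 0.0

    def test_dilute_limit_matches_naive_formula(self):
        # 2 markers 1 Mb apart, 4 spores, exactly 1 switch: the naive
        # count-based estimate is 2 * 1/4 = 0.5; the saturation-corrected
        # estimator agrees in the dilute limit up to the small transient
        m = matrix_from_calls(
            [[0, 0], [0, 0], [1, 1], [1, 0]], positions=[1, 1_000_001]
        )
        est = estimate_cos_per_mega(m)
        assert est.source == "estimated"
        assert est.cos_per_mega == pytest.approx(0.5, rel=0.10)

    def test_single_marker_falls_back_to_default(self):
        m = matrix_from_calls([[0], [1]])
        with pytest.warns(UserWarning, match="falling back"):
            est = estimate_cos_per_mega(m)
        assert est.source == "default"

    def test_recovers_simulator_parameter(self):
        matrix, _ = simulate(
            SimConfig(n_tetrads=300, n_markers=1000, noise_rate=0, missing_rate=0,
                      cos_per_mega=6.0, seed=21)
        )
        est = estimate_cos_per_mega(matrix)
        assert est.cos_per_mega == pytest.approx(6.0, rel=0.1)


class TestCentromerePosterior:
    def test_certain_flanks(self):
        assert centromere_posterior((0, 0.0), (0, 0.0)) == pytest.approx(1.0)

    def test_contradicting_equidistant_flanks(self):
        assert centromere_posterior((0, 0.1), (1, 0.1)) == pytest.approx(0.5)

    def test_single_flank_likelihood(self):
        assert centromere_posterior((0, 0.1), None) == pytest.approx(0.9)

    def test_no_flanks_uninformative(self):
        assert centromere_posterior(None, None) == pytest.approx(0.5)


class TestCallCentromeres:
    def _setup(self, calls, positions, cen_pos=100):
        m = matrix_from_calls(calls, positions=positions)
        cens = CentromereTable({"chr1": cen_pos})
        return m, cens

    def test_tight_flanks_give_certainty(self):
        m, cens = self._setup([[0, 0], [1, 1]], positions=[99, 101])
        prof = call_centromeres(m, cens, RecombinationModel(6.0))
        assert prof.p_a[0, 0] > 0.99
        assert prof.p_a[1, 0] < 0.01

    def test_missing_chromosome_gets_half(self):
        m, cens = self._setup([[-1, -1]], positions=[99, 101])
        prof = call_centromeres(m, cens, RecombinationModel(6.0))
        assert prof.p_a[0, 0] == 0.5

    def test_single_left_flank(self):
        m, cens = self._setup([[0]], positions=[50], cen_pos=100)
        model = RecombinationModel(6.0)
        r = haldane_r(50, model)
        prof = call_centromeres(m, cens, model)
        assert prof.p_a[0, 0] == pytest.approx((1 - r) / ((1 - r) + r))

    def test_marker_at_centromere_used_with_zero_distance(self):
        m, cens = self._setup([[1]], positions=[100], cen_pos=100)
        prof = call_centromeres(m, cens, RecombinationModel(6.0))
        assert prof.p_a[0, 0] < 1e-6


class TestSimilarity:
    def test_identical_certain_profiles(self):
        p = np.array([1.0, 0.0, 1.0, 0.0])
        assert similarity(p, p) == pytest.approx(1.0)

    def test_mirror_profiles(self):
        p = np.array([1.0, 0.0, 1.0, 1.0])
        assert similarity(p, 1 - p) == pytest.approx(1.0)

    def test_uninformative_partner(self):
        p = np.array([1.0, 0.0, 1.0])
        q = np.full(3, 0.5)
        assert similarity(p, q) == 0.0

    def test_symmetric_and_flip_invariant(self):
        rng = np.random.default_rng(4)
        p, q = rng.random(16), rng.random(16)
        assert similarity(p, q) == pytest.approx(similarity(q, p))
        assert similarity(1 - p, q) == pytest.approx(similarity(p, q))

    def test_chromosome_set_mismatch(self):
        with pytest.raises(ValueError, match="chromosome"):
            similarity(np.zeros(3), np.zeros(4))


class TestClusterSpores:
    def _profiles(self, p_a):
        n = p_a.shape[0]
        return CentromereProfiles(
            spore_ids=[f"s{i}" for i in range(n)],
            chromosomes=[f"c{j}" for j in range(p_a.shape[1])],
            p_a=p_a,
        )

    def test_tetrads_cluster_on_noise_free_data(self, centromeres):
        # with the absolute-mean-correlation similarity, random 16-chromosome
        # profiles overlap up to ~0.7, so whole-tetrad containment needs a
        # threshold above that background (sister pairs sit near 1)
        matrix, truth = simulate(
            SimConfig(n_tetrads=30, n_markers=600, noise_rate=0, missing_rate=0, seed=13)
        )
        model = estimate_cos_per_mega(matrix)
        prof = call_centromeres(matrix, centromeres, model)
        clusters, _ = cluster_spores(prof, threshold=0.6)
        cluster_of = {}
        for ci, members in enumerate(clusters):
            for i in members:
                cluster_of[i] = ci
        whole = 0
        for t in range(30):
            ids = {cluster_of.get(4 * t + k) for k in range(4)}
            if len(ids) == 1 and None not in ids:
                whole += 1
        assert whole >= 29  # >= ~99% of tetrads wholly inside one cluster

    def test_threshold_ceiling_leaves_unclustered(self):
        rng = np.random.default_rng(6)
        p_a = np.clip(rng.random((12, 16)), 0.01, 0.99)
        clusters, unclustered = cluster_spores(self._profiles(p_a), threshold=1.0)
        assert not clusters
        assert len(unclustered) == 12

    def test_identical_patterns_merge(self):
        # two tetrads sharing a segregation pattern land in one cluster
        base = np.tile(np.array([1.0, 0, 1, 0, 1, 0, 1, 0] * 2), (8, 1))
        base[2:4] = 1 - base[2:4]  # mirror pair within tetrad 1
        base[6:8] = 1 - base[6:8]
        clusters, unclustered = cluster_spores(self._profiles(base), threshold=0.9)
        assert len(clusters) == 1
        assert clusters[0] == list(range(8))

    def test_edge_count_monotone_in_threshold(self):
        rng = np.random.default_rng(8)
        p_a = rng.random((30, 16))
        s = similarity_matrix(self._profiles(p_a))
        edges = [
            int(np.triu(s >= thr, k=1).sum()) for thr in (0.1, 0.2, 0.3, 0.5)
        ]
        assert edges == sorted(edges, reverse=True)


def test_pattern_collision_probability_enumeration():
    # S. cerevisiae: 16 chromosomes -> 1/2^15 up to mirror imaging
    assert pattern_collision_probability(16) == pytest.approx(2.0**-15, abs=0, rel=1e-12)
    # S. pombe-like: 3 chromosomes -> 1/4
    assert pattern_collision_probability(3) == pytest.approx(0.25)
    assert pattern_collision_probability(1) == pytest.approx(1.0)
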