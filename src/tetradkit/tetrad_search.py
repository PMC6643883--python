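"""Delta-score tetrad search: permutation nulls, direct and shadow searches,
segregation verification, and the staged pipeline.

Stages of :func:`run_pipeline`:

1. preprocessing (duplicate and high-missingness removal);
2. optional empirical estimation of the crossover density;
3. centromere calling and similarity clustering;
4. per-cluster search — exhaustive over 4-spore groups for clusters of at
   most five spores, otherwise a *shadow* search that seeds on strong
   3-spore groups and extends them within the cluster;
5. cross-cluster repair — triple seeds inside each cluster extended with
   every still-unassigned spore, catching tetrads split by clustering;
6. a global phase over all remaining spores (shadow, then direct when the
   4-group space is small enough);
7. triplet and pair phases for partial tetrads; leftovers become singles.

Thresholds are empirical quantiles of null score distributions obtained by
scoring uniformly random spore groups: right tail for the 4-spore delta and
for pair MI, left tail for the 3-spore delta (true triplets are negative
under the package's sign convention).  Every accepted tetrad must in
addition pass 2:2 segregation verification, and every triplet 2:1
verification; candidates that fail go back into the search pool.
"""

from __future__ import annotations

import itertools
import time
from dataclasses import dataclass, field
from math import comb

import numpy as np

from . import info_measures as im
from .centromere_clustering import (
    RecombinationModel,
    call_centromeres,
    cluster_spores,
    estimate_cos_per_mega,
)
from .config import ReconstructionConfig
from .genotype_io import CentromereTable, GenotypeMatrix, Group, TetradAssignment
from .preprocess import preprocess

_GROUP_CHUNK = 200_000  # candidate groups scored per batch


@dataclass
class NullThresholds:
    d4_threshold: float
    d3_threshold: float
    mi_threshold: float
    n_permutations: int
    p4: float
    p3: float
    p2: float


@dataclass
class AcceptedGroup:
    kind: str
    indices: tuple[int, ...]
    score: float
    seg_fraction: float | None


class SearchState:
    """Pool of unassigned spores, accepted groups and an audit log."""

    def __init__(self, matrix: GenotypeMatrix):
        self.matrix = matrix
        self.pool: set[int] = set(range(matrix.n_spores))
        self.accepted: list[AcceptedGroup] = []
        self.audit: list[dict] = []

    @property
    def assigned(self) -> set[int]:
        return {i for g in self.accepted for i in g.indices}

    def accept(self, kind: str, indices, score: float, seg: float | None) -> None:
        indices = tuple(int(i) for i in indices)
        if not set(indices) <= self.pool:
            raise ValueError(f"cannot accept {indices}: spores not all in pool")
        self.accepted.append(AcceptedGroup(kind, indices, float(score), seg))
        self.pool -= set(indices)

    def log(self, **entry) -> None:
        self.audit.append(entry)


# ---------------------------------------------------------------------------
# null distributions and thresholds


def build_null(
    matrix: GenotypeMatrix, level: int, n: int, seed: int
) -> np.ndarray:
    """Scores of ``n`` uniformly random distinct-spore groups of ``level``
    spores: delta for levels 3 and 4, MI for level 2."""
    if level not in (2, 3, 4):
        raise ValueError("level must be 2, 3 or 4")
    if matrix.n_spores < level:
        raise ValueError(f"need at least {level} spores to build a level-{level} null")
    rng = np.random.default_rng(seed)
    keys = rng.random((n, matrix.n_spores))
    groups = np.sort(np.argpartition(keys, level - 1, axis=1)[:, :level], axis=1)
    if level == 4:
        scores = im.score_quads(matrix.calls, groups)[0]
    elif level == 3:
        scores = im.score_triples(matrix.calls, groups)[0]
    else:
        scores = im.score_pairs(matrix.calls, groups)[0]
    return scores[np.isfinite(scores)]


def threshold_from_null(null: np.ndarray, p: float, tail: str) -> float:
    """Empirical-quantile threshold: ``1 - p`` quantile for the right tail,
    ``p`` quantile for the left tail."""
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0, 1)")
    null = np.asarray(null, dtype=float)
    if tail == "right":
        return float(np.quantile(null, 1.0 - p, method="lower"))
    if tail == "left":
        return float(np.quantile(null, p, method="higher"))
    raise ValueError("tail must be 'left' or 'right'")


def build_thresholds(
    matrix: GenotypeMatrix, config: ReconstructionConfig
) -> NullThresholds:
    """Draw the three null samples once per run (seeded) and take their
    tail quantiles at the configured p-values."""
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
             np.random.SeedSequence(config.seed).spawn(3)]
    null4 = build_null(matrix, 4, config.n_permutations, seeds[0])
    null3 = build_null(matrix, 3, config.n_permutations, seeds[1])
    null2 = build_null(matrix, 2, config.n_permutations, seeds[2])
    return NullThresholds(
        d4_threshold=threshold_from_null(null4, config.d4_pvalue, "right"),
        d3_threshold=threshold_from_null(null3, config.d3_pvalue, "left"),
        mi_threshold=threshold_from_null(null2, config.mi_pvalue, "right"),
        n_permutations=config.n_permutations,
        p4=config.d4_pvalue,
        p3=config.d3_pvalue,
        p2=config.mi_pvalue,
    )


# ---------------------------------------------------------------------------
# verification


def verify_tetrad(
    matrix: GenotypeMatrix, group, cutoff: float = 0.9
) -> tuple[bool, float]:
    """Fraction of complete-case markers segregating exactly 2:2; the group
    passes iff the fraction strictly exceeds the cutoff."""
    quad = np.asarray([sorted(int(i) for i in group)])
    if quad.shape[1] != 4:
        raise ValueError("verify_tetrad needs exactly 4 spores")
    frac = float(im.score_quads(matrix.calls, quad)[2][0])
    if np.isnan(frac):
        return False, frac
    return frac > cutoff, frac


def verify_triplet(
    matrix: GenotypeMatrix, group, cutoff: float = 0.95
) -> tuple[bool, float]:
    """Fraction of complete-case markers with a 2:1 or 1:2 split (not 3:0)."""
    triple = np.asarray([sorted(int(i) for i in group)])
    if triple.shape[1] != 3:
        raise ValueError("verify_triplet needs exactly 3 spores")
    frac = float(im.score_triples(matrix.calls, triple)[2][0])
    if np.isnan(frac):
        return False, frac
    return frac > cutoff, frac


# ---------------------------------------------------------------------------
# candidate generation helpers


def _combination_chunks(items, k: int, chunk: int = _GROUP_CHUNK):
    """Yield (chunk, k) index arrays covering all k-combinations of items."""
    items = list(items)
    total = comb(len(items), k)
    it = itertools.combinations(items, k)
    produced = 0
    while produced < total:
        take = min(chunk, total - produced)
        flat = np.fromiter(
            itertools.chain.from_iterable(itertools.islice(it, take)),
            dtype=np.int64,
            count=take * k,
        )
        produced += take
        yield flat.reshape(take, k)


def _greedy_accept_quads(
    state: SearchState,
    candidates: list[tuple[float, tuple[int, ...], float]],
    seg_cutoff: float,
    stage: str,
) -> int:
    """Accept non-overlapping 4-groups, each subject to 2:2 verification;
    rejected candidates stay in the pool.

    Candidates are ranked by 2:2 fraction first and delta second: among
    groups that already cleared the delta threshold, the segregation
    fraction separates true tetrads from chimeric groups (which cannot
    sustain genome-wide 2:2) more sharply than the delta magnitude, whose
    ordering degrades under genotyping noise.
    """
    n_accepted = 0
    candidates.sort(key=lambda c: (-c[2], -c[0], c[1]))
    for delta4, indices, seg in candidates:
        if not set(indices) <= state.pool:
            continue
        if np.isnan(seg) or seg <= seg_cutoff:
            state.log(stage=stage, kind="tetrad", indices=indices,
                      delta=delta4, seg_fraction=seg, outcome="rejected_2:2")
            continue
        state.accept("tetrad", indices, delta4, seg)
        state.log(stage=stage, kind="tetrad", indices=indices,
                  delta=delta4, seg_fraction=seg, outcome="accepted")
        n_accepted += 1
    return n_accepted


def _score_passing_quads(
    state: SearchState, quads_iter, d4_threshold: float
) -> list[tuple[float, tuple[int, ...], float]]:
    out = []
    for quads in quads_iter:
        delta4, _, seg, _ = im.score_quads(state.matrix.calls, quads)
        keep = np.nonzero(np.isfinite(delta4) & (delta4 > d4_threshold))[0]
        for i in keep:
            out.append((float(delta4[i]), tuple(int(v) for v in quads[i]), float(seg[i])))
    return out


def _passing_triples(
    state: SearchState, spores, d3_threshold: float, with_seg: bool = False
):
    """All 3-combinations of ``spores`` whose delta is at or below the left
    threshold; optionally returns 2:1 fractions too."""
    out = []
    for triples in _combination_chunks(spores, 3):
        delta3, _, seg, _ = im.score_triples(state.matrix.calls, triples)
        keep = np.nonzero(np.isfinite(delta3) & (delta3 <= d3_threshold))[0]
        for i in keep:
            rec = (float(delta3[i]), tuple(int(v) for v in triples[i]))
            out.append(rec + ((float(seg[i]),) if with_seg else ()))
    return out


# ---------------------------------------------------------------------------
# search phases


def direct_search(
    state: SearchState,
    spores,
    thresholds: NullThresholds,
    seg_cutoff: float = 0.9,
    stage: str = "direct",
) -> SearchState:
    """Exhaustive delta search over all 4-spore combinations of ``spores``."""
    spores = sorted(set(int(s) for s in spores) & state.pool)
    if len(spores) < 4:
        return state
    candidates = _score_passing_quads(
        state, _combination_chunks(spores, 4), thresholds.d4_threshold
    )
    _greedy_accept_quads(state, candidates, seg_cutoff, stage)
    return state


def shadow_search(
    state: SearchState,
    spores,
    extension_pool,
    thresholds: NullThresholds,
    seg_cutoff: float = 0.9,
    stage: str = "shadow",
    max_seeds: int = 20_000,
) -> SearchState:
    """Two-step search: strong 3-spore seeds within ``spores`` extended by
    every spore of ``extension_pool``, then scored and verified as tetrads.

    When more triples pass the seed threshold than ``max_seeds`` (large
    pools at lenient p-values), only the strongest (most negative) seeds
    are extended; true sister triples sit far below the threshold, so the
    budget trims borderline false seeds, not real ones.
    """
    spores = sorted(set(int(s) for s in spores) & state.pool)
    if len(spores) < 3:
        return state
    seeds = _passing_triples(state, spores, thresholds.d3_threshold)
    if not seeds:
        return state
    if len(seeds) > max_seeds:
        seeds.sort(key=lambda s: (s[0], s[1]))
        seeds = seeds[:max_seeds]
    ext = sorted(set(int(s) for s in extension_pool) & state.pool)
    quads = sorted(
        {
            tuple(sorted((*seed, e)))
            for _, seed in seeds
            for e in ext
            if e not in seed
        }
    )
    if not quads:
        return state

    def chunks():
        arr = np.asarray(quads, dtype=np.int64)
        for start in range(0, arr.shape[0], _GROUP_CHUNK):
            yield arr[start : start + _GROUP_CHUNK]

    candidates = _score_passing_quads(state, chunks(), thresholds.d4_threshold)
    _greedy_accept_quads(state, candidates, seg_cutoff, stage)
    return state


def _pair_exchange_sweep(
    state: SearchState, thresholds: NullThresholds, seg_cutoff: float
) -> bool:
    """Repartition the spores of pairs of accepted tetrads.

    Two centromere-collided tetrads can be accepted as two complementary
    chimeras that hold all eight spores between them, out of reach of
    pool exchanges.  For every pair of accepted tetrads this scores all 35
    ways to split their eight spores 4+4; a repartition replaces the pair
    when both halves pass the delta threshold and verification and the
    pair strictly improves both the summed 2:2 fraction and summed delta.
    """
    improved = False
    calls = state.matrix.calls
    for g1, g2 in itertools.combinations(
        sorted(
            (g for g in state.accepted if g.kind == "tetrad"),
            key=lambda g: g.indices,
        ),
        2,
    ):
        if g1 not in state.accepted or g2 not in state.accepted:
            continue  # already replaced earlier in this sweep
        members = sorted(g1.indices + g2.indices)
        first, rest = members[0], members[1:]
        halves = [tuple(sorted((first, *c))) for c in itertools.combinations(rest, 3)]
        comps = [tuple(sorted(set(members) - set(h))) for h in halves]
        arr = np.asarray(halves + comps, dtype=np.int64)
        d4, _, seg, _ = im.score_quads(calls, arr)
        n = len(halves)
        d4h, d4c = d4[:n], d4[n:]
        sgh, sgc = seg[:n], seg[n:]
        base_seg = g1.seg_fraction + g2.seg_fraction
        base_delta = g1.score + g2.score
        ok = (
            np.isfinite(d4h) & np.isfinite(d4c)
            & (d4h > thresholds.d4_threshold) & (d4c > thresholds.d4_threshold)
            & (sgh > seg_cutoff) & (sgc > seg_cutoff)
            & (sgh + sgc > base_seg) & (d4h + d4c > base_delta)
        )
        if not ok.any():
            continue
        cands = sorted(
            (-float(sgh[i] + sgc[i]), -float(d4h[i] + d4c[i]), halves[i], comps[i], i)
            for i in np.nonzero(ok)[0]
        )
        _, _, h, c, i = cands[0]
        state.accepted.remove(g1)
        state.accepted.remove(g2)
        state.pool |= set(members)
        state.accept("tetrad", h, float(d4h[i]), float(sgh[i]))
        state.accept("tetrad", c, float(d4c[i]), float(sgc[i]))
        state.log(stage="refine_pair", kind="tetrad", indices=h + c,
                  delta=float(d4h[i] + d4c[i]),
                  seg_fraction=float(sgh[i] + sgc[i]),
                  outcome="repartitioned",
                  displaced=(g1.indices, g2.indices))
        improved = True
    return improved


def refine_tetrads(
    state: SearchState,
    thresholds: NullThresholds,
    seg_cutoff: float = 0.9,
    max_sweeps: int = 5,
) -> SearchState:
    """Local-improvement pass over accepted tetrads.

    Greedy staged acceptance can let a chimeric group assembled from two
    centromere-collided tetrads claim spores before the true tetrads are
    ever co-candidates.  This pass challenges each accepted tetrad with
    every quad obtained by exchanging one or two of its spores for pool
    spores; a challenger must pass the delta threshold and *strictly
    dominate* the incumbent on both the 2:2 fraction and delta to replace
    it.  Requiring joint dominance keeps single-score noise (fraction
    differences of a few percent are within sampling error at a few
    hundred markers) from displacing true tetrads, while a chimera beaten
    by the tetrad it robbed loses on both axes; on noise-free data true
    tetrads sit at fraction 1.0 where no challenger can improve.
    Displaced spores return to the pool.  Sweeps repeat until stable.
    """
    for _ in range(max_sweeps):
        improved = False
        order = sorted(
            (g for g in state.accepted if g.kind == "tetrad"),
            key=lambda g: (g.seg_fraction, g.indices),
        )
        for group in order:
            pool = sorted(state.pool)
            if not pool:
                break
            members = list(group.indices)
            quads = []
            for keep3 in itertools.combinations(members, 3):
                for p in pool:
                    quads.append(tuple(sorted((*keep3, p))))
            if len(pool) >= 2:
                for keep2 in itertools.combinations(members, 2):
                    for pp in itertools.combinations(pool, 2):
                        quads.append(tuple(sorted(keep2 + pp)))
            arr = np.asarray(sorted(set(quads)), dtype=np.int64)
            delta4, _, seg, _ = im.score_quads(state.matrix.calls, arr)
            ok = (
                np.isfinite(delta4)
                & (delta4 > thresholds.d4_threshold)
                & (delta4 > group.score)
                & (seg > group.seg_fraction)
                & (seg > seg_cutoff)
            )
            if not ok.any():
                continue
            cands = sorted(
                (
                    (-float(seg[i]), -float(delta4[i]), tuple(int(v) for v in arr[i]))
                    for i in np.nonzero(ok)[0]
                )
            )
            neg_seg, neg_delta, indices = cands[0]
            state.accepted.remove(group)
            state.pool |= set(group.indices)
            state.accept("tetrad", indices, -neg_delta, -neg_seg)
            state.log(stage="refine", kind="tetrad", indices=indices,
                      delta=-neg_delta, seg_fraction=-neg_seg,
                      outcome="replaced", displaced=group.indices)
            improved = True
        if _pair_exchange_sweep(state, thresholds, seg_cutoff):
            improved = True
        if not improved:
            break
    return state


def find_triplets(
    state: SearchState,
    thresholds: NullThresholds,
    seg_cutoff: float = 0.95,
) -> SearchState:
    """Partial tetrads of three sister spores among the remaining pool."""
    spores = sorted(state.pool)
    if len(spores) < 3:
        return state
    candidates = _passing_triples(state, spores, thresholds.d3_threshold, with_seg=True)
    # rank by 2:1 fraction, then most-negative delta (true triplets are negative)
    candidates.sort(key=lambda c: (-c[2], c[0], c[1]))
    for delta3, indices, seg in candidates:
        if not set(indices) <= state.pool:
            continue
        if np.isnan(seg) or seg <= seg_cutoff:
            state.log(stage="triplets", kind="triplet", indices=indices,
                      delta=delta3, seg_fraction=seg, outcome="rejected_2:1")
            continue
        state.accept("triplet", indices, delta3, seg)
        state.log(stage="triplets", kind="triplet", indices=indices,
                  delta=delta3, seg_fraction=seg, outcome="accepted")
    return state


def find_pairs(state: SearchState, thresholds: NullThresholds) -> SearchState:
    """Sister pairs among the remaining pool, by mutual information."""
    spores = sorted(state.pool)
    if len(spores) < 2:
        return state
    candidates = []
    for pairs in _combination_chunks(spores, 2):
        mi, _ = im.score_pairs(state.matrix.calls, pairs)
        keep = np.nonzero(np.isfinite(mi) & (mi > thresholds.mi_threshold))[0]
        for i in keep:
            candidates.append((float(mi[i]), tuple(int(v) for v in pairs[i])))
    candidates.sort(key=lambda c: (-c[0], c[1]))
    for mi_val, indices in candidates:
        if not set(indices) <= state.pool:
            continue
        state.accept("pair", indices, mi_val, None)
        state.log(stage="pairs", kind="pair", indices=indices,
                  delta=mi_val, seg_fraction=None, outcome="accepted")
    return state


# ---------------------------------------------------------------------------
# orchestration


def _canonical_assignment(
    state: SearchState, matrix: GenotypeMatrix
) -> TetradAssignment:
    prefix = {"tetrad": "T", "triplet": "R", "pair": "P", "single": "S"}
    order = {"tetrad": 0, "triplet": 1, "pair": 2, "single": 3}
    records = []
    for g in state.accepted:
        sids = sorted(matrix.spore_ids[i] for i in g.indices)
        records.append((order[g.kind], sids, g.kind, g.score, g.seg_fraction))
    for i in sorted(state.pool):
        records.append((order["single"], [matrix.spore_ids[i]], "single", None, None))
    records.sort(key=lambda r: (r[0], r[1]))
    counters = dict.fromkeys(prefix, 0)
    groups = []
    for _, sids, kind, score, seg in records:
        counters[kind] += 1
        groups.append(
            Group(
                group_id=f"{prefix[kind]}{counters[kind]:04d}",
                kind=kind,
                spore_ids=sids,
                delta_score=score,
                segregation_fraction=seg,
            )
        )
    return TetradAssignment(groups=groups)


def run_pipeline(
    matrix: GenotypeMatrix,
    cens: CentromereTable,
    config: ReconstructionConfig | None = None,
) -> tuple[TetradAssignment, dict]:
    """Full reconstruction: preprocessing, clustering, staged delta searches,
    and final assignment.  Returns the assignment and a run report."""
    if config is None:
        config = ReconstructionConfig()
    report: dict = {"n_input_spores": matrix.n_spores}
    t0 = time.perf_counter()

    work, prep = preprocess(matrix, config.dup_cutoff, config.max_missing)
    report["n_removed_duplicates"] = len(prep.removed_duplicates)
    report["n_removed_high_missing"] = len(prep.removed_high_missing)
    report["n_spores"] = work.n_spores

    if config.cen_calling:
        model = estimate_cos_per_mega(work)
    else:
        model = RecombinationModel(config.cos_per_mega, source="default")
    report["cos_per_mega"] = model.cos_per_mega
    report["cos_per_mega_source"] = model.source

    state = SearchState(work)
    if work.n_spores < 2:
        report["runtime_seconds"] = time.perf_counter() - t0
        return _canonical_assignment(state, work), report

    thresholds = build_thresholds(work, config)
    report["thresholds"] = {
        "d4": thresholds.d4_threshold,
        "d3": thresholds.d3_threshold,
        "mi": thresholds.mi_threshold,
    }

    if config.clustering:
        profiles = call_centromeres(work, cens, model)
        clusters, unclustered = cluster_spores(profiles, config.similarity_coefficient)
    else:
        clusters, unclustered = [], list(range(work.n_spores))
    report["n_clusters"] = len(clusters)
    report["cluster_sizes"] = sorted((len(c) for c in clusters), reverse=True)
    report["n_unclustered"] = len(unclustered)

    # divide and conquer within clusters
    for cluster in clusters:
        if len(set(cluster) & state.pool) <= 5:
            direct_search(state, cluster, thresholds, config.seg_cutoff_d4,
                          stage="cluster_direct")
        else:
            shadow_search(state, cluster, cluster, thresholds,
                          config.seg_cutoff_d4, stage="cluster_shadow",
                          max_seeds=config.shadow_seed_limit)
    report["tetrads_after_clusters"] = len(state.accepted)

    # repair tetrads split by clustering: in-cluster seeds, global extension
    for cluster in clusters:
        remaining = set(cluster) & state.pool
        if len(remaining) >= 3:
            shadow_search(state, remaining, state.pool, thresholds,
                          config.seg_cutoff_d4, stage="repair",
                          max_seeds=config.shadow_seed_limit)
    report["tetrads_after_repair"] = len(state.accepted)

    # exhaustive phase over everything still unassigned
    pool = sorted(state.pool)
    shadow_search(state, pool, pool, thresholds, config.seg_cutoff_d4,
                  stage="global_shadow", max_seeds=config.shadow_seed_limit)
    pool = sorted(state.pool)
    if len(pool) >= 4 and comb(len(pool), 4) <= config.direct_search_limit:
        direct_search(state, pool, thresholds, config.seg_cutoff_d4,
                      stage="global_direct")

    # challenge accepted tetrads with pool exchanges, then give the freed
    # spores one more exhaustive chance
    n_before = len(state.accepted)
    refine_tetrads(state, thresholds, config.seg_cutoff_d4)
    report["refinement_replacements"] = sum(
        1 for e in state.audit if e.get("stage") in ("refine", "refine_pair")
    )
    pool = sorted(state.pool)
    if len(pool) >= 4 and comb(len(pool), 4) <= config.direct_search_limit:
        direct_search(state, pool, thresholds, config.seg_cutoff_d4,
                      stage="post_refine_direct")
    report["tetrads_total"] = len(state.accepted)

    find_triplets(state, thresholds, config.seg_cutoff_d3)
    find_pairs(state, thresholds)

    assignment = _canonical_assignment(state, work)
    counts = {k: len(assignment.groups_of_kind(k)) for k in
              ("tetrad", "triplet", "pair", "single")}
    report["group_counts"] = counts
    report["runtime_seconds"] = time.perf_counter() - t0
    return assignment, report
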