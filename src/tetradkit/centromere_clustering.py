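"""Centromere-segregation clustering of spores.

Within a tetrad, two spores carry identical centromere alleles on every
chromosome and the other two carry the mirror image.  The haplotype of each
centromere is not observed directly; it is inferred probabilistically from
the nearest flanking markers and the recombination fraction between them and
the centromere (Haldane map of a globally estimated crossover density).
Spores are then connected when the absolute mean haplotype correlation of
their centromere profiles exceeds a threshold — high for perfect matches and
for complete mismatches alike — and communities of the resulting weighted
graph, found by greedy modularity maximization, become the search clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .genotype_io import CentromereTable, GenotypeMatrix

_MIN_R = 1e-9  # keeps flank likelihoods away from exact zero


@dataclass
class RecombinationModel:
    """Global crossover density in crossovers / Mb / meiosis."""

    cos_per_mega: float
    source: str = "default"  # "estimated" or "default"

    def __post_init__(self) -> None:
        if self.cos_per_mega < 0:
            raise ValueError("cos_per_mega must be >= 0")


@dataclass
class CentromereProfiles:
    """P(centromere haplotype = A) per spore per chromosome.

    Chromosomes with no informative flanking marker carry 0.5.
    """

    spore_ids: list[str]
    chromosomes: list[str]
    p_a: np.ndarray  # shape (n_spores, n_chromosomes)

    def __post_init__(self) -> None:
        self.p_a = np.asarray(self.p_a, dtype=float)
        if self.p_a.shape != (len(self.spore_ids), len(self.chromosomes)):
            raise ValueError("p_a shape does not match spores x chromosomes")
        if ((self.p_a < 0) | (self.p_a > 1)).any():
            raise ValueError("centromere probabilities must be in [0, 1]")

    def profile(self, i: int) -> np.ndarray:
        return self.p_a[i]


def _expected_switches_per_mb(span_mb: float, d_near_mb: float, c: float) -> float:
    """Expected observed allele switches on one chromatid over an interval.

    Under the no-interference model a crossover exchanges the distal arms
    of one "A"-centromere and one "B"-centromere chromatid; the exchange is
    *observable* on a chromatid only when its partner carries the opposite
    allele at that point.  Solving the four-chromatid exchange chain gives
    the per-chromatid switch intensity at distance ``d`` (Mb) from the
    centromere::

        lambda(d) = c/3 + (c/6) * exp(-3 c d / 2)

    which is ``c/2`` in the dilute limit (every exchange visible) and
    saturates at ``c/3``.  This integrates it over one interval lying on a
    single chromosome arm, from distance ``d_near`` to ``d_near + span``.
    """
    if span_mb <= 0:
        return 0.0
    if c <= 0:
        return 0.0
    far = d_near_mb + span_mb
    return c / 3.0 * span_mb + (1.0 / 9.0) * (
        np.exp(-1.5 * c * d_near_mb) - np.exp(-1.5 * c * far)
    )


def estimate_cos_per_mega(
    matrix: GenotypeMatrix, cens: CentromereTable | None = None
) -> RecombinationModel:
    """Estimate the crossover density from allele switches along chromosomes.

    Counts switches between consecutive non-missing markers per spore, then
    inverts the expected-switch model of :func:`_expected_switches_per_mb`
    (bisection), which corrects for exchanges rendered invisible by earlier
    crossovers.  When no centromere table is given the packaged default is
    used; chromosomes absent from it anchor the model at the midpoint of
    their marker span.
    """
    from .genotype_io import default_centromeres
    from .sim_meiosis import DEFAULT_COS_PER_MEGA

    if cens is None:
        cens = default_centromeres()
    total_switches = 0
    spans: list[tuple[float, float]] = []  # (span_mb, d_near_mb) per arm piece

    def add_span(x1: int, x2: int, cen: float) -> None:
        # split the marker span [x1, x2] at the centromere into arm pieces
        for a, b in (((min(x1, cen)), min(x2, cen)), (max(x1, cen), max(x2, cen))):
            if b > a:
                spans.append(((b - a) / 1e6, (min(abs(a - cen), abs(b - cen))) / 1e6))

    for chrom in matrix.markers.chromosome_names:
        sl = matrix.markers.chromosome_slice(chrom)
        pos = matrix.markers.positions[sl]
        if pos.size < 2:
            continue
        block = matrix.calls[:, sl]
        cen = float(cens.get(chrom, (pos[0] + pos[-1]) / 2.0))
        if (block >= 0).all():
            total_switches += int((block[:, 1:] != block[:, :-1]).sum())
            for _ in range(matrix.n_spores):
                add_span(int(pos[0]), int(pos[-1]), cen)
        else:
            for row in block:
                idx = np.nonzero(row >= 0)[0]
                if idx.size < 2:
                    continue
                vals = row[idx]
                total_switches += int((vals[1:] != vals[:-1]).sum())
                add_span(int(pos[idx[0]]), int(pos[idx[-1]]), cen)
    if not spans:
        warnings.warn(
            "no adjacent marker pairs to estimate recombination from; "
            "falling back to the default crossover density",
            stacklevel=2,
        )
        return RecombinationModel(DEFAULT_COS_PER_MEGA, source="default")
    if total_switches == 0:
        return RecombinationModel(0.0, source="estimated")

    span_mb = np.array([s for s, _ in spans])
    d_near = np.array([d for _, d in spans])

    def expected(c: float) -> float:
        if c <= 0:
            return 0.0
        far = d_near + span_mb
        return float(
            (c / 3.0 * span_mb
             + (1.0 / 9.0) * (np.exp(-1.5 * c * d_near) - np.exp(-1.5 * c * far))
             ).sum()
        )

    lo, hi = 0.0, 1.0
    while expected(hi) < total_switches and hi < 1e4:
        hi *= 2.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if expected(mid) < total_switches:
            lo = mid
        else:
            hi = mid
    return RecombinationModel(0.5 * (lo + hi), source="estimated")


def haldane_r(distance_bp: int, model: RecombinationModel) -> float:
    """Recombination fraction over a physical distance, Haldane map.

    ``r = (1 - exp(-2m)) / 2`` with ``m`` in Morgans; per-chromatid map
    distance is half the crossover density times the physical distance.
    """
    if distance_bp < 0:
        raise ValueError("distance must be >= 0")
    m = model.cos_per_mega * (distance_bp / 1e6) / 2.0
    return float((1.0 - np.exp(-2.0 * m)) / 2.0)


def centromere_posterior(
    left: tuple[int, float] | None, right: tuple[int, float] | None
) -> float:
    """P(centromere = A) from up to two flanking (allele, r) observations.

    Each flank contributes likelihood ``1 - r`` for the matching haplotype
    and ``r`` for the other; an absent flank contributes 1.
    """
    l_a = l_b = 1.0
    for flank in (left, right):
        if flank is None:
            continue
        allele, r = flank
        r = min(max(float(r), _MIN_R), 0.5)
        if allele == 0:  # "A"
            l_a *= 1.0 - r
            l_b *= r
        elif allele == 1:  # "B"
            l_a *= r
            l_b *= 1.0 - r
        else:
            raise ValueError(f"flank allele must be 0 or 1, got {allele!r}")
    return l_a / (l_a + l_b)


def call_centromeres(
    matrix: GenotypeMatrix, cens: CentromereTable, model: RecombinationModel
) -> CentromereProfiles:
    """Posterior centromere-haplotype probabilities for every spore.

    For each spore and chromosome the nearest non-missing marker on each
    side of the centromere (a marker exactly at the centromere counts as a
    left flank with zero distance) feeds a two-flank likelihood; chromosomes
    with no informative marker get 0.5.
    """
    chroms = matrix.markers.chromosome_names
    missing_cen = [c for c in chroms if c not in cens]
    if missing_cen:
        raise ValueError(f"no centromere position for chromosomes {missing_cen}")
    n = matrix.n_spores
    p_a = np.full((n, len(chroms)), 0.5)
    for ci, chrom in enumerate(chroms):
        sl = matrix.markers.chromosome_slice(chrom)
        pos = matrix.markers.positions[sl]
        block = matrix.calls[:, sl]
        cen = cens[chrom]
        left_cols = np.nonzero(pos <= cen)[0]
        right_cols = np.nonzero(pos > cen)[0]
        l_a = np.ones(n)
        l_b = np.ones(n)
        for cols, nearest_last in ((left_cols, True), (right_cols, False)):
            if cols.size == 0:
                continue
            sub = block[:, cols]
            nm = sub >= 0
            if nearest_last:
                # last non-missing column = closest to the centromere
                rank = np.where(nm, np.arange(1, cols.size + 1), 0)
                pick = rank.max(axis=1) - 1
            else:
                rank = np.where(nm, np.arange(cols.size, 0, -1), 0)
                pick = np.where(rank.max(axis=1) > 0, cols.size - rank.max(axis=1), -1)
            has = pick >= 0
            if not has.any():
                continue
            rows = np.nonzero(has)[0]
            flank_cols = cols[pick[rows]]  # block-column of each spore's flank
            alleles = block[rows, flank_cols]
            dist = np.abs(pos[flank_cols] - cen)
            m = model.cos_per_mega * (dist / 1e6) / 2.0
            r = np.clip((1.0 - np.exp(-2.0 * m)) / 2.0, _MIN_R, 0.5)
            pa = np.where(alleles == 0, 1.0 - r, r)
            pb = np.where(alleles == 1, 1.0 - r, r)
            l_a[rows] *= pa
            l_b[rows] *= pb
        p_a[:, ci] = l_a / (l_a + l_b)
    return CentromereProfiles(
        spore_ids=list(matrix.spore_ids), chromosomes=list(chroms), p_a=p_a
    )


def similarity(p: np.ndarray, q: np.ndarray) -> float:
    """Absolute mean haplotype correlation of two centromere profiles.

    High both for matching and for mirrored segregation patterns;
    uninformative chromosomes (p = 0.5) contribute nothing.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("profiles cover different chromosome sets")
    return float(np.abs(np.mean((2.0 * p - 1.0) * (2.0 * q - 1.0))))


def similarity_matrix(profiles: CentromereProfiles) -> np.ndarray:
    """All pairwise similarities; the diagonal is zeroed."""
    u = 2.0 * profiles.p_a - 1.0
    s = np.abs(u @ u.T / u.shape[1])
    np.fill_diagonal(s, 0.0)
    return s


def cluster_spores(
    profiles: CentromereProfiles, threshold: float
) -> tuple[list[list[int]], list[int]]:
    """Cluster spores by thresholded centromere similarity.

    Builds a weighted graph with an edge for every pair at or above the
    threshold and extracts communities by greedy modularity maximization.
    Returns ``(clusters, unclustered)``; singleton communities and isolated
    spores are reported as unclustered.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    s = similarity_matrix(profiles)
    n = s.shape[0]
    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    ii, jj = np.nonzero(np.triu(s >= threshold, k=1))
    graph.add_weighted_edges_from(
        (int(i), int(j), float(s[i, j])) for i, j in zip(ii, jj)
    )
    if graph.number_of_edges() == 0:
        return [], list(range(n))
    communities = nx.community.greedy_modularity_communities(graph, weight="weight")
    clusters: list[list[int]] = []
    unclustered: list[int] = []
    for com in communities:
        members = sorted(int(v) for v in com)
        if len(members) >= 2:
            clusters.append(members)
        else:
            unclustered.extend(members)
    clusters.sort(key=lambda c: c[0])
    return clusters, sorted(unclustered)


def pattern_collision_probability(n_chromosomes: int) -> float:
    """Probability that two independent tetrads share a centromere
    segregation pattern, up to mirror imaging, by exact enumeration.

    Each tetrad draws one of ``2**N`` equiprobable patterns; a pattern and
    its complement are the same tetrad signature.
    """
    if not 1 <= n_chromosomes <= 24:
        raise ValueError("exact enumeration supported for 1..24 chromosomes")
    n = n_chromosomes
    patterns = np.arange(1 << n, dtype=np.int64)
    mask = (1 << n) - 1
    canon = np.minimum(patterns, ~patterns & mask)
    _, counts = np.unique(canon, return_counts=True)
    probs = counts / float(1 << n)
    return float((probs**2).sum())
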