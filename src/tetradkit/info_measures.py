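"""Plug-in information measures over groups of spore allele vectors.

Dependencies among sister spores are quantified with Shannon information
measures estimated from marker-wise allele patterns:

* mutual information (MI) between two spores,
* interaction information (II) over 3 or 4 spores, with the sign convention
  ``II(S) = sum over nonempty subsets T of S of (-1)^(|T|+1) H(T)``,
  which reduces exactly to MI for two variables, is negative for a triple of
  sister spores and positive for a full tetrad,
* "delta", the product over every group member of the differential
  interaction information obtained by removing that member:
  ``delta(S) = prod_i [II(S) - II(S \\ {i})]``.

All estimators are plug-in (maximum-likelihood) in log base 2, computed on
the *complete-case* marker set of the group: markers at which every group
member has a non-missing call.  Subset entropies and subset IIs inside a
delta reuse the full group's complete-case markers so that all factors live
on one sample space.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from .genotype_io import GenotypeMatrix, MarkerMap

#: closed-form scores of the ideal 2:2 tetrad distribution (six equiprobable
#: patterns of two "A" and two "B" alleles across the four spores)
IDEAL_PAIR_MI = 5.0 / 3.0 - math.log2(3.0)  # 0.08170 bits
IDEAL_TRIPLE_II = 3.0 - 2.0 * math.log2(3.0)  # -0.16993 bits
IDEAL_QUAD_II = 5.0 - 3.0 * math.log2(3.0)  # +0.24511 bits
IDEAL_QUAD_DELTA = (IDEAL_QUAD_II - IDEAL_TRIPLE_II) ** 4  # 0.02967
IDEAL_TRIPLE_DELTA = (IDEAL_TRIPLE_II - IDEAL_PAIR_MI) ** 3  # -0.01594


class UnscorableGroupError(ValueError):
    """Raised when a spore group has no complete-case markers."""


def _popcount(values: np.ndarray) -> np.ndarray:
    out = np.zeros_like(values)
    v = values.copy()
    while v.any():
        out += v & 1
        v >>= 1
    return out


def ideal_tetrad_patterns() -> np.ndarray:
    """The six 2:2 allele patterns over four spores, one row per pattern."""
    patterns = []
    for a_pos in itertools.combinations(range(4), 2):
        row = np.ones(4, dtype=np.int8)
        row[list(a_pos)] = 0
        patterns.append(row)
    return np.array(patterns, dtype=np.int8)


def ideal_tetrad_matrix(n_repeats: int = 1) -> GenotypeMatrix:
    """A 4-spore matrix whose empirical marker distribution is exactly the
    ideal 2:2 distribution (each of the six patterns appears ``n_repeats``
    times)."""
    pats = np.repeat(ideal_tetrad_patterns(), n_repeats, axis=0)
    n = pats.shape[0]
    markers = MarkerMap(
        ids=[f"chr1:{i + 1}" for i in range(n)],
        chromosomes=np.array(["chr1"] * n, dtype=object),
        positions=np.arange(1, n + 1),
    )
    return GenotypeMatrix(
        spore_ids=[f"s{i}" for i in range(4)],
        markers=markers,
        calls=pats.T.copy(),
    )


# ---------------------------------------------------------------------------
# scalar API


def joint_counts(matrix: GenotypeMatrix, group) -> tuple[np.ndarray, int]:
    """Contingency table of allele patterns over the group's complete-case
    markers.

    Returns ``(counts, n_complete)`` where ``counts`` has shape ``(2,)*k``
    indexed by the alleles of the group members in the given order.
    """
    group = tuple(int(i) for i in group)
    if len(set(group)) != len(group):
        raise ValueError("group indices must be distinct")
    sub = matrix.calls[list(group)]
    complete = (sub >= 0).all(axis=0)
    n = int(complete.sum())
    if n == 0:
        raise UnscorableGroupError(f"group {group} has no complete-case markers")
    sub = sub[:, complete]
    k = len(group)
    code = np.zeros(n, dtype=np.int64)
    for j in range(k):
        # first group member is the slowest-varying (leading) axis
        code = code * 2 + sub[j]
    counts = np.bincount(code, minlength=2**k).reshape((2,) * k)
    return counts, n


def entropy(counts: np.ndarray) -> float:
    """Plug-in Shannon entropy in bits of a contingency table."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("entropy of an empty table is undefined")
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def _subset_entropy(counts: np.ndarray, subset: tuple[int, ...]) -> float:
    k = counts.ndim
    drop = tuple(ax for ax in range(k) if ax not in subset)
    return entropy(counts.sum(axis=drop) if drop else counts)


def _ii_from_counts(counts: np.ndarray, axes: tuple[int, ...]) -> float:
    ii = 0.0
    for r in range(1, len(axes) + 1):
        sign = 1.0 if r % 2 == 1 else -1.0
        for subset in itertools.combinations(axes, r):
            ii += sign * _subset_entropy(counts, subset)
    return ii


def interaction_information(matrix: GenotypeMatrix, group) -> float:
    """Interaction information of a group of 2-4 spores, in bits."""
    group = tuple(group)
    if not 2 <= len(group) <= 4:
        raise ValueError("interaction information is defined for 2-4 spores here")
    counts, _ = joint_counts(matrix, group)
    return _ii_from_counts(counts, tuple(range(len(group))))


def mutual_information(matrix: GenotypeMatrix, pair) -> float:
    """Mutual information between two spores, in bits."""
    pair = tuple(pair)
    if len(pair) != 2:
        raise ValueError("mutual information needs exactly two spores")
    return interaction_information(matrix, pair)


def delta(matrix: GenotypeMatrix, group) -> float:
    """Delta dependency score of a group of 3 or 4 spores.

    The product over group members of the change in interaction information
    when that member is removed; every subset II is evaluated on the full
    group's complete-case markers.
    """
    group = tuple(group)
    if len(group) not in (3, 4):
        raise ValueError("delta is defined for groups of 3 or 4 spores")
    counts, _ = joint_counts(matrix, group)
    axes = tuple(range(len(group)))
    ii_full = _ii_from_counts(counts, axes)
    out = 1.0
    for ax in axes:
        rest = tuple(a for a in axes if a != ax)
        out *= ii_full - _ii_from_counts(counts, rest)
    return out


# ---------------------------------------------------------------------------
# batch API (vectorized over many groups; used by the search phases)

_CELL_BUDGET = 25_000_000  # elements handled per chunk


def _pattern_counts(calls: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Counts of allele patterns for many groups at once.

    ``groups`` is an (m, k) array of spore indices.  Returns an (m, 2**k)
    int64 array; member ``j`` of a group contributes bit ``j`` (member 0 is
    the least-significant bit).  Markers with any missing call in a group are
    excluded from that group's counts.
    """
    groups = np.asarray(groups, dtype=np.int64)
    m, k = groups.shape
    n_markers = calls.shape[1]
    cells = 1 << k
    counts = np.empty((m, cells), dtype=np.int64)
    chunk = max(1, _CELL_BUDGET // max(n_markers, 1))
    for start in range(0, m, chunk):
        g = groups[start : start + chunk]
        pat = np.zeros((g.shape[0], n_markers), dtype=np.int16)
        valid = np.ones((g.shape[0], n_markers), dtype=bool)
        for j in range(k):
            cj = calls[g[:, j]]
            valid &= cj >= 0
            pat += cj.astype(np.int16) << j
        np.copyto(pat, cells, where=~valid)  # overflow bin for invalid markers
        offsets = (np.arange(g.shape[0], dtype=np.int64) * (cells + 1))[:, None]
        flat = (pat.astype(np.int64) + offsets).ravel()
        bc = np.bincount(flat, minlength=g.shape[0] * (cells + 1))
        counts[start : start + g.shape[0]] = bc.reshape(g.shape[0], cells + 1)[:, :cells]
    return counts


def _batch_subset_entropies(counts: np.ndarray, k: int) -> dict[int, np.ndarray]:
    """Marginal entropies for every nonempty subset of the k axes.

    Subsets are keyed by bitmask over group members (bit j = member j).
    Groups with zero complete-case markers get NaN entropies.
    """
    m = counts.shape[0]
    n = counts.sum(axis=1).astype(float)
    tensor = counts.reshape((m,) + (2,) * k)
    entropies: dict[int, np.ndarray] = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        for mask in range(1, 1 << k):
            # member j lives on tensor axis j+1
            drop = tuple(j + 1 for j in range(k) if not (mask >> j) & 1)
            marg = tensor.sum(axis=drop).reshape(m, -1).astype(float)
            p = marg / n[:, None]
            plogp = np.where(marg > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
            h = -plogp.sum(axis=1)
            h[n == 0] = np.nan
            entropies[mask] = h
    return entropies


def _batch_ii(entropies: dict[int, np.ndarray], mask: int) -> np.ndarray:
    ii = 0.0
    sub = mask
    # iterate over all nonempty submasks of mask
    while sub:
        sign = 1.0 if bin(sub).count("1") % 2 == 1 else -1.0
        ii = ii + sign * entropies[sub]
        sub = (sub - 1) & mask
    return ii


def _seg_fraction(counts: np.ndarray, k: int, balanced: tuple[int, ...]) -> np.ndarray:
    popc = _popcount(np.arange(1 << k))
    keep = np.isin(popc, balanced)
    n = counts.sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = counts[:, keep].sum(axis=1) / n
    frac[n == 0] = np.nan
    return frac


def score_pairs(calls: np.ndarray, pairs: np.ndarray):
    """Mutual information for many spore pairs.

    Returns ``(mi, n_complete)``; unscorable pairs get NaN.
    """
    counts = _pattern_counts(calls, pairs)
    h = _batch_subset_entropies(counts, 2)
    mi = h[0b01] + h[0b10] - h[0b11]
    return mi, counts.sum(axis=1)


def score_triples(calls: np.ndarray, triples: np.ndarray):
    """Delta, II and 2:1 segregation fraction for many spore triples.

    Returns ``(delta3, ii3, seg21_fraction, n_complete)``.
    """
    counts = _pattern_counts(calls, triples)
    h = _batch_subset_entropies(counts, 3)
    full = 0b111
    ii3 = _batch_ii(h, full)
    d = np.ones_like(ii3)
    for j in range(3):
        rest = full & ~(1 << j)
        d = d * (ii3 - _batch_ii(h, rest))
    seg = _seg_fraction(counts, 3, balanced=(1, 2))
    return d, ii3, seg, counts.sum(axis=1)


def score_quads(calls: np.ndarray, quads: np.ndarray):
    """Delta, II and 2:2 segregation fraction for many 4-spore groups.

    Returns ``(delta4, ii4, seg22_fraction, n_complete)``.
    """
    counts = _pattern_counts(calls, quads)
    h = _batch_subset_entropies(counts, 4)
    full = 0b1111
    ii4 = _batch_ii(h, full)
    d = np.ones_like(ii4)
    for j in range(4):
        rest = full & ~(1 << j)
        d = d * (ii4 - _batch_ii(h, rest))
    seg = _seg_fraction(counts, 4, balanced=(2,))
    return d, ii4, seg, counts.sum(axis=1)
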