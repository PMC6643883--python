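"""Input hygiene: duplicate-spore removal and high-missingness filtering.

Duplicates are detected with a normalized mismatch distance over the marker
positions where both spores have a call (allele vectors are position-aligned,
so mismatch counting is the natural edit distance here).  Both filters keep
the first occurrence and preserve input order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .genotype_io import GenotypeMatrix

DEFAULT_DUP_CUTOFF = 0.05
DEFAULT_MAX_MISSING = 0.5


@dataclass
class PreprocessReport:
    removed_duplicates: list[tuple[str, str, float]] = field(default_factory=list)
    removed_high_missing: list[tuple[str, float]] = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return len(self.removed_duplicates) + len(self.removed_high_missing)


def allele_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Fraction of shared non-missing positions at which two allele vectors
    differ; 1.0 (with a warning) when no position is shared."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError(f"allele vector lengths differ: {x.shape} vs {y.shape}")
    shared = (x >= 0) & (y >= 0)
    n = int(shared.sum())
    if n == 0:
        warnings.warn("no shared non-missing positions; distance undefined, using 1.0",
                      stacklevel=2)
        return 1.0
    return float((x[shared] != y[shared]).sum() / n)


def deduplicate(
    matrix: GenotypeMatrix, dup_cutoff: float = DEFAULT_DUP_CUTOFF
) -> tuple[GenotypeMatrix, PreprocessReport]:
    """Greedy first-kept duplicate removal.

    A spore whose distance to an already-kept spore is below ``dup_cutoff``
    is dropped and recorded against that kept spore.
    """
    if not 0.0 <= dup_cutoff <= 1.0:
        raise ValueError("dup_cutoff must be in [0, 1]")
    report = PreprocessReport()
    kept: list[int] = []
    calls = matrix.calls
    nonmissing = calls >= 0
    for i in range(matrix.n_spores):
        duplicate_of = None
        if kept:
            kept_calls = calls[kept]
            shared = nonmissing[kept] & nonmissing[i]
            n_shared = shared.sum(axis=1)
            mismatch = ((kept_calls != calls[i]) & shared).sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                dist = np.where(n_shared > 0, mismatch / n_shared, 1.0)
            hits = np.nonzero(dist < dup_cutoff)[0]
            if hits.size:
                duplicate_of = (kept[hits[0]], float(dist[hits[0]]))
        if duplicate_of is None:
            kept.append(i)
        else:
            j, d = duplicate_of
            report.removed_duplicates.append(
                (matrix.spore_ids[j], matrix.spore_ids[i], d)
            )
    return matrix.subset_spores(kept), report


def drop_high_missing(
    matrix: GenotypeMatrix, max_missing: float = DEFAULT_MAX_MISSING
) -> tuple[GenotypeMatrix, PreprocessReport]:
    """Remove spores whose missing fraction strictly exceeds ``max_missing``."""
    if not 0.0 <= max_missing <= 1.0:
        raise ValueError("max_missing must be in [0, 1]")
    report = PreprocessReport()
    frac = matrix.missing_fraction()
    kept = []
    for i in range(matrix.n_spores):
        if frac[i] > max_missing:
            report.removed_high_missing.append((matrix.spore_ids[i], float(frac[i])))
        else:
            kept.append(i)
    return matrix.subset_spores(kept), report


def preprocess(
    matrix: GenotypeMatrix,
    dup_cutoff: float = DEFAULT_DUP_CUTOFF,
    max_missing: float = DEFAULT_MAX_MISSING,
) -> tuple[GenotypeMatrix, PreprocessReport]:
    """Duplicate removal followed by high-missingness filtering."""
    matrix, rep1 = deduplicate(matrix, dup_cutoff)
    matrix, rep2 = drop_high_missing(matrix, max_missing)
    report = PreprocessReport(
        removed_duplicates=rep1.removed_duplicates,
        removed_high_missing=rep2.removed_high_missing,
    )
    return matrix, report
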