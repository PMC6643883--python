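"""Ground-truthed simulation of yeast meiosis for tetrad-reconstruction tests.

The model is the standard minimal one: for each tetrad and chromosome the
four chromatids start as two copies of parental haplotype "A" and two of
"B"; the number of crossovers is Poisson with mean ``length_Mb *
cos_per_mega`` (no interference), each crossover sits at a uniform position
and reciprocally exchanges the chromosome arm distal to that position
between one uniformly chosen "A" chromatid and one uniformly chosen "B"
chromatid.  Centromeres never change hands, so sister centromeres
co-segregate at meiosis I and split at meiosis II: spores 0,1 of a tetrad
receive the chromatids of one pole and spores 2,3 the other, giving the
two-plus-two mirrored centromere pattern on every chromosome.

Genotyping noise flips each call independently; missingness then masks each
call independently.  All randomness is driven by a single seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genotype_io import GenotypeMatrix, MarkerMap, default_centromeres

#: sacCer3 chromosome lengths in bp
SACCER3_CHROMOSOME_LENGTHS: dict[str, int] = {
    "chrI": 230218,
    "chrII": 813184,
    "chrIII": 316620,
    "chrIV": 1531933,
    "chrV": 576874,
    "chrVI": 270161,
    "chrVII": 1090940,
    "chrVIII": 562643,
    "chrIX": 439888,
    "chrX": 745751,
    "chrXI": 666816,
    "chrXII": 1078177,
    "chrXIII": 924431,
    "chrXIV": 784333,
    "chrXV": 1091291,
    "chrXVI": 948066,
}

#: default crossover density, crossovers / Mb / meiosis
DEFAULT_COS_PER_MEGA = 6.0


@dataclass
class SimConfig:
    """Parameters of a simulated cross.

    ``noise_rate`` is the per-call probability of a genotyping error (allele
    flip); ``missing_rate`` the per-call probability of a masked call.
    """

    n_tetrads: int = 100
    n_markers: int = 1000
    noise_rate: float = 0.01
    missing_rate: float = 0.05
    cos_per_mega: float = DEFAULT_COS_PER_MEGA
    chromosome_lengths: dict[str, int] = field(
        default_factory=lambda: dict(SACCER3_CHROMOSOME_LENGTHS)
    )
    centromeres: dict[str, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tetrads < 1:
            raise ValueError("n_tetrads must be >= 1")
        if self.n_markers < 1:
            raise ValueError("n_markers must be >= 1")
        for name, rate in (("noise_rate", self.noise_rate), ("missing_rate", self.missing_rate)):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.cos_per_mega < 0:
            raise ValueError("cos_per_mega must be >= 0")
        if any(l <= 0 for l in self.chromosome_lengths.values()):
            raise ValueError("chromosome lengths must be > 0")
        if self.centromeres is None:
            default = default_centromeres()
            self.centromeres = {
                c: default[c] for c in self.chromosome_lengths if c in default
            }
        missing = set(self.chromosome_lengths) - set(self.centromeres)
        if missing:
            raise ValueError(f"no centromere position for chromosomes {sorted(missing)}")


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset."""

    spore_to_tetrad: dict[str, tuple[str, int]]
    tetrads: dict[str, list[str]]
    breakpoints: list[tuple[str, str, int, tuple[int, int]]]  # tetrad, chrom, pos, chromatids

    def __post_init__(self) -> None:
        for tid, spores in self.tetrads.items():
            if len(spores) != 4:
                raise ValueError(f"tetrad {tid!r} does not map exactly 4 spores")

    @property
    def n_tetrads(self) -> int:
        return len(self.tetrads)


def _place_markers(rng: np.random.Generator, config: SimConfig) -> MarkerMap:
    chroms = sorted(config.chromosome_lengths)
    lengths = np.array([config.chromosome_lengths[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    placed: set[tuple[int, int]] = set()
    out: list[tuple[int, int]] = []
    while len(out) < config.n_markers:
        need = config.n_markers - len(out)
        ci = rng.choice(len(chroms), size=need, p=probs)
        pos = rng.integers(1, lengths[ci].astype(np.int64) + 1)
        for c, p in zip(ci, pos):
            key = (int(c), int(p))
            if key not in placed:  # resample colliding positions
                placed.add(key)
                out.append(key)
    out.sort()
    return MarkerMap(
        ids=[f"{chroms[c]}:{p}" for c, p in out],
        chromosomes=np.array([chroms[c] for c, p in out], dtype=object),
        positions=np.array([p for c, p in out], dtype=np.int64),
    )


def simulate(config: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Simulate a cross and return the genotype matrix plus ground truth.

    Spores are named ``T####_0`` .. ``T####_3``; spores of one tetrad occupy
    consecutive rows.
    """
    rng = np.random.default_rng(config.seed)
    markers = _place_markers(rng, config)
    chroms = sorted(config.chromosome_lengths)
    empty = [c for c in chroms if c not in set(markers.chromosomes)]
    if empty:
        warnings.warn(
            f"chromosomes {empty} carry no markers and contribute no signal",
            stacklevel=2,
        )

    n_spores = 4 * config.n_tetrads
    calls = np.empty((n_spores, len(markers)), dtype=np.int8)
    spore_ids: list[str] = []
    spore_to_tetrad: dict[str, tuple[str, int]] = {}
    tetrads: dict[str, list[str]] = {}
    breakpoints: list[tuple[str, str, int, tuple[int, int]]] = []

    chrom_cols = {
        c: markers.chromosome_slice(c) for c in chroms if c in set(markers.chromosomes)
    }

    for t in range(config.n_tetrads):
        tid = f"T{t:04d}"
        sids = [f"{tid}_{k}" for k in range(4)]
        tetrads[tid] = sids
        for k, sid in enumerate(sids):
            spore_ids.append(sid)
            spore_to_tetrad[sid] = (tid, k)
        rows = slice(4 * t, 4 * t + 4)
        for chrom in chroms:
            length = config.chromosome_lengths[chrom]
            cen = config.centromeres[chrom]
            cols = chrom_cols.get(chrom)
            pos = markers.positions[cols] if cols is not None else np.empty(0, np.int64)
            content = np.zeros((4, pos.size), dtype=np.int8)
            content[2:] = 1  # chromatids 0,1 carry "A", 2,3 carry "B"
            n_cx = rng.poisson(length / 1e6 * config.cos_per_mega)
            cx_pos = rng.integers(1, length + 1, size=n_cx)
            # follow each molecule outward from its centromere: exchanges
            # are encountered in order of distance from the centromere
            # (left- and right-arm exchanges act on disjoint regions)
            cx_pos = cx_pos[np.argsort(np.abs(cx_pos - cen), kind="stable")]
            for p in cx_pos:
                i = int(rng.integers(0, 2))
                j = 2 + int(rng.integers(0, 2))
                # exchange the arm distal to p (the side away from the
                # centromere); the centromere itself never changes hands
                mask = pos > p if p >= cen else pos < p
                if mask.any():
                    tmp = content[i, mask].copy()
                    content[i, mask] = content[j, mask]
                    content[j, mask] = tmp
                breakpoints.append((tid, chrom, int(p), (i, j)))
            # meiosis I: homolog pairs to opposite poles, chosen at random;
            # meiosis II: sisters split within a pole, in random order
            pole_a, pole_b = ([0, 1], [2, 3])
            if rng.integers(0, 2):
                pole_a, pole_b = pole_b, pole_a
            o1 = rng.permutation(2)
            o2 = rng.permutation(2)
            order = [pole_a[o1[0]], pole_a[o1[1]], pole_b[o2[0]], pole_b[o2[1]]]
            if cols is not None:
                calls[rows, cols] = content[order]

    if config.noise_rate > 0:
        flip = rng.random(calls.shape) < config.noise_rate
        calls = np.where(flip, 1 - calls, calls).astype(np.int8)
    if config.missing_rate > 0:
        miss = rng.random(calls.shape) < config.missing_rate
        calls[miss] = -1

    matrix = GenotypeMatrix(spore_ids=spore_ids, markers=markers, calls=calls)
    truth = SimTruth(
        spore_to_tetrad=spore_to_tetrad, tetrads=tetrads, breakpoints=breakpoints
    )
    return matrix, truth


def segregation_spectrum(matrix: GenotypeMatrix, truth: SimTruth) -> dict[str, float]:
    """Per-tetrad fraction of complete-case markers that segregate 2:2.

    Markers with a missing call in any of the four sister spores are
    excluded; a tetrad with no complete-case marker gets NaN.
    """
    row_of = {sid: i for i, sid in enumerate(matrix.spore_ids)}
    out: dict[str, float] = {}
    for tid in sorted(truth.tetrads):
        sids = truth.tetrads[tid]
        missing = [s for s in sids if s not in row_of]
        if missing:
            raise ValueError(f"truth spores {missing} absent from matrix")
        sub = matrix.calls[[row_of[s] for s in sids]]
        complete = (sub >= 0).all(axis=0)
        if not complete.any():
            out[tid] = float("nan")
            continue
        out[tid] = float((sub[:, complete].sum(axis=0) == 2).mean())
    return out


# ---------------------------------------------------------------------------
# truth TSV plumbing for the command line


def write_truth(truth: SimTruth, path) -> None:
    with Path(path).open("w") as fh:
        fh.write("spore_id\ttetrad_id\tspore_index\n")
        for sid in sorted(truth.spore_to_tetrad):
            tid, k = truth.spore_to_tetrad[sid]
            fh.write(f"{sid}\t{tid}\t{k}\n")


def read_truth(path) -> SimTruth:
    spore_to_tetrad: dict[str, tuple[str, int]] = {}
    tetrads: dict[str, list[str]] = {}
    with Path(path).open() as fh:
        header = fh.readline()
        if not header.startswith("spore_id"):
            raise ValueError(f"{path}: unexpected truth header")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            sid, tid, k = line.split("\t")
            spore_to_tetrad[sid] = (tid, int(k))
            tetrads.setdefault(tid, []).append(sid)
    for sids in tetrads.values():
        sids.sort()
    return SimTruth(spore_to_tetrad=spore_to_tetrad, tetrads=tetrads, breakpoints=[])
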