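"""Readers and writers for the tab-delimited genotype dialects used by tetradkit.

A genotype file is a TSV with a header row of marker identifiers formatted
``chromosome:position`` (1-based bp), one row per spore, the first column
holding the spore identifier.  Allele calls may be coded ``A``/``B`` or
``0``/``1``; missing calls are ``NA`` or ``-``.  Internally calls are stored
as an ``int8`` matrix with ``A = 0``, ``B = 1`` and ``MISSING = -1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

A = np.int8(0)
B = np.int8(1)
MISSING = np.int8(-1)

_SYMBOL_TO_CODE = {"A": 0, "B": 1, "0": 0, "1": 1, "NA": -1, "-": -1}
_CODE_TO_SYMBOL = {0: "A", 1: "B", -1: "-"}

KINDS = ("tetrad", "triplet", "pair", "single")
_KIND_SIZE = {"tetrad": 4, "triplet": 3, "pair": 2, "single": 1}


class GenotypeParseError(ValueError):
    """Raised when an input file violates the tetradkit TSV dialect."""


@dataclass
class MarkerMap:
    """Genomic coordinates of the genotyped markers.

    Markers are kept grouped by chromosome with strictly increasing positions
    within each chromosome.
    """

    ids: list[str]
    chromosomes: np.ndarray  # dtype=object, one entry per marker
    positions: np.ndarray  # dtype=int64, 1-based bp

    def __post_init__(self) -> None:
        self.chromosomes = np.asarray(self.chromosomes, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if not (len(self.ids) == self.chromosomes.size == self.positions.size):
            raise ValueError("marker id / chromosome / position lengths differ")
        if len(set(self.ids)) != len(self.ids):
            raise GenotypeParseError("duplicate marker ids in marker map")
        self._slices: dict[str, slice] = {}
        start = 0
        for i in range(1, len(self.ids) + 1):
            if i == len(self.ids) or self.chromosomes[i] != self.chromosomes[start]:
                chrom = str(self.chromosomes[start])
                if chrom in self._slices:
                    raise GenotypeParseError(
                        f"markers of chromosome {chrom!r} are not contiguous"
                    )
                self._slices[chrom] = slice(start, i)
                pos = self.positions[start:i]
                if np.any(np.diff(pos) <= 0):
                    raise GenotypeParseError(
                        f"marker positions not strictly increasing on {chrom!r}"
                    )
                start = i

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def chromosome_names(self) -> list[str]:
        return list(self._slices)

    def chromosome_slice(self, chrom: str) -> slice:
        return self._slices[chrom]


@dataclass
class GenotypeMatrix:
    """Spores x markers allele calls with their marker map.

    ``input_columns`` records, for each (sorted) marker column, the column
    index it occupied in the source file, so output can be re-emitted in the
    original order.
    """

    spore_ids: list[str]
    markers: MarkerMap
    calls: np.ndarray  # int8, shape (n_spores, n_markers)
    input_columns: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D matrix")
        if self.calls.shape != (len(self.spore_ids), len(self.markers)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.spore_ids)} spores x {len(self.markers)} markers"
            )
        bad = ~np.isin(self.calls, (-1, 0, 1))
        if bad.any():
            raise ValueError("calls contain symbols outside {A, B, MISSING}")
        if len(set(self.spore_ids)) != len(self.spore_ids):
            raise GenotypeParseError("duplicate spore ids")
        if self.input_columns is None:
            self.input_columns = np.arange(len(self.markers))

    @property
    def n_spores(self) -> int:
        return len(self.spore_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def subset_spores(self, indices) -> "GenotypeMatrix":
        indices = list(indices)
        return GenotypeMatrix(
            spore_ids=[self.spore_ids[i] for i in indices],
            markers=self.markers,
            calls=self.calls[indices].copy(),
            input_columns=self.input_columns,
        )

    def missing_fraction(self) -> np.ndarray:
        """Per-spore fraction of missing calls."""
        return (self.calls == MISSING).mean(axis=1)


class CentromereTable(dict):
    """Mapping chromosome name -> centromere midpoint (1-based bp)."""

    def __init__(self, entries):
        super().__init__()
        for chrom, pos in dict(entries).items():
            self[str(chrom)] = int(pos)


@dataclass
class Group:
    group_id: str
    kind: str
    spore_ids: list[str]
    delta_score: float | None
    segregation_fraction: float | None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown group kind {self.kind!r}")
        if len(self.spore_ids) != _KIND_SIZE[self.kind]:
            raise ValueError(
                f"{self.kind} group {self.group_id!r} has "
                f"{len(self.spore_ids)} spores"
            )


@dataclass
class TetradAssignment:
    """Final labelling of every spore into a tetrad, triplet, pair or single."""

    groups: list[Group] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.groups:
            for sid in g.spore_ids:
                if sid in seen:
                    raise ValueError(f"spore {sid!r} appears in more than one group")
                seen.add(sid)

    @property
    def spore_ids(self) -> list[str]:
        return [sid for g in self.groups for sid in g.spore_ids]

    def groups_of_kind(self, kind: str) -> list[Group]:
        return [g for g in self.groups if g.kind == kind]

    def partition(self) -> set[frozenset]:
        """The assignment as a set of frozensets of spore ids (id-free view)."""
        return {frozenset(g.spore_ids) for g in self.groups}


# ---------------------------------------------------------------------------
# genotype matrices


def _parse_marker_header(cells: list[str]) -> tuple[list[str], list[str], list[int]]:
    ids, chroms, positions = [], [], []
    for j, cell in enumerate(cells):
        chrom, sep, pos = cell.rpartition(":")
        if not sep or not chrom:
            raise GenotypeParseError(
                f"header column {j + 2}: marker id {cell!r} is not 'chrom:position'"
            )
        try:
            p = int(pos)
        except ValueError:
            raise GenotypeParseError(
                f"header column {j + 2}: position {pos!r} of marker {cell!r} "
                "is not an integer"
            ) from None
        ids.append(cell)
        chroms.append(chrom)
        positions.append(p)
    return ids, chroms, positions


def read_genotypes(path) -> GenotypeMatrix:
    """Read a spores x markers genotype TSV.

    Markers are sorted by (chromosome, position); the column permutation from
    the input file is recorded on the returned matrix.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise GenotypeParseError(f"{path}: empty file")
        ids, chroms, positions = _parse_marker_header(header.split("\t")[1:])
        if not ids:
            raise GenotypeParseError(f"{path}: no marker columns in header")
        spore_ids: list[str] = []
        rows: list[np.ndarray] = []
        for i, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != len(ids) + 1:
                raise GenotypeParseError(
                    f"{path} line {i}: expected {len(ids) + 1} columns, "
                    f"found {len(cells)}"
                )
            sid = cells[0]
            if sid in spore_ids:
                raise GenotypeParseError(f"{path} line {i}: duplicate spore id {sid!r}")
            row = np.empty(len(ids), dtype=np.int8)
            for j, cell in enumerate(cells[1:]):
                code = _SYMBOL_TO_CODE.get(cell)
                if code is None:
                    raise GenotypeParseError(
                        f"{path} line {i} (spore {sid!r}), marker {ids[j]!r}: "
                        f"unknown allele symbol {cell!r}"
                    )
                row[j] = code
            spore_ids.append(sid)
            rows.append(row)
    calls = np.vstack(rows) if rows else np.empty((0, len(ids)), dtype=np.int8)
    order = np.lexsort((positions, chroms))
    markers = MarkerMap(
        ids=[ids[k] for k in order],
        chromosomes=np.array(chroms, dtype=object)[order],
        positions=np.array(positions, dtype=np.int64)[order],
    )
    return GenotypeMatrix(
        spore_ids=spore_ids,
        markers=markers,
        calls=calls[:, order],
        input_columns=order,
    )


def write_genotypes(matrix: GenotypeMatrix, path, original_order: bool = False) -> None:
    """Write a genotype matrix in the tetradkit TSV dialect (A/B/- coding)."""
    cols = np.arange(matrix.n_markers)
    if original_order and matrix.input_columns is not None:
        # input_columns[j] = source column of sorted column j; invert it
        cols = np.argsort(matrix.input_columns)
    with Path(path).open("w") as fh:
        fh.write("spore\t" + "\t".join(matrix.markers.ids[j] for j in cols) + "\n")
        for i, sid in enumerate(matrix.spore_ids):
            row = (_CODE_TO_SYMBOL[int(c)] for c in matrix.calls[i, cols])
            fh.write(sid + "\t" + "\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# centromere tables


def read_centromeres(path) -> CentromereTable:
    """Read a two-column chromosome / centromere-position TSV."""
    path = Path(path)
    table: dict[str, int] = {}
    with path.open() as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cells = line.split("\t")
            if len(cells) != 2:
                raise GenotypeParseError(
                    f"{path} line {i}: expected 2 columns, found {len(cells)}"
                )
            chrom, pos = cells
            if chrom in table:
                raise GenotypeParseError(
                    f"{path} line {i}: duplicate chromosome {chrom!r}"
                )
            try:
                table[chrom] = int(pos)
            except ValueError:
                raise GenotypeParseError(
                    f"{path} line {i}: position {pos!r} is not an integer"
                ) from None
    return CentromereTable(table)


def default_centromeres() -> CentromereTable:
    """The packaged S. cerevisiae (sacCer3) centromere table."""
    res = resources.files("tetradkit").joinpath("data/sacCer3_centromeres.tsv")
    with resources.as_file(res) as p:
        return read_centromeres(p)


# ---------------------------------------------------------------------------
# assignments

_ASSIGNMENT_HEADER = [
    "spore_id",
    "group_id",
    "kind",
    "delta_score",
    "segregation_fraction",
]


def _fmt(x: float | None) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    return format(float(x), ".12g")


def write_assignment(assignment: TetradAssignment, path) -> None:
    """Write one row per spore, ordered by (group_id, spore_id)."""
    rows = []
    for g in assignment.groups:
        for sid in g.spore_ids:
            rows.append(
                (sid, g.group_id, g.kind, _fmt(g.delta_score), _fmt(g.segregation_fraction))
            )
    rows.sort(key=lambda r: (r[1], r[0]))
    with Path(path).open("w") as fh:
        fh.write("\t".join(_ASSIGNMENT_HEADER) + "\n")
        for r in rows:
            fh.write("\t".join(r) + "\n")


def read_assignment(path) -> TetradAssignment:
    """Read an assignment TSV written by :func:`write_assignment`."""
    path = Path(path)
    by_group: dict[str, dict] = {}
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _ASSIGNMENT_HEADER:
            raise GenotypeParseError(f"{path}: unexpected assignment header")
        for i, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != 5:
                raise GenotypeParseError(f"{path} line {i}: expected 5 columns")
            sid, gid, kind, delta, seg = cells
            rec = by_group.setdefault(
                gid,
                {
                    "kind": kind,
                    "spore_ids": [],
                    "delta": None if delta == "NA" else float(delta),
                    "seg": None if seg == "NA" else float(seg),
                },
            )
            rec["spore_ids"].append(sid)
    groups = [
        Group(gid, rec["kind"], rec["spore_ids"], rec["delta"], rec["seg"])
        for gid, rec in sorted(by_group.items())
    ]
    return TetradAssignment(groups=groups)
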