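"""Genomic interval types, BED input/output, and overlap tokenization.

Coordinates are 0-based, half-open throughout (BED convention).  A
*fixed* interval is the classical BED region ``[start, end)``.  A
*flexible* interval represents boundary uncertainty of a consensus
region with four ordered coordinates::

    start_start <= start_end <= end_start <= end_end

The region start lies somewhere in ``[start_start, start_end]``, the end
somewhere in ``[end_start, end_end]``, and the always-covered core is
``[start_end, end_start)``.  A flexible interval with
``start_start == start_end`` and ``end_start == end_end`` degenerates
exactly to the fixed interval ``[start_start, end_end)``.

On disk, flexible intervals use an extended BED8 dialect: the first
three columns hold the outer span, and the ``thickStart``/``thickEnd``
columns (7 and 8) hold ``start_end`` and ``end_start``.

Strand is ignored everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence, Union

import numpy as np

__all__ = [
    "BedParseError",
    "FixedInterval",
    "FlexibleInterval",
    "RegionSet",
    "RegionSetCollection",
    "Universe",
    "read_bed",
    "read_chrom_sizes",
    "read_flexible_bed",
    "read_universe",
    "write_flexible_bed",
    "tokenize",
    "TokenizedRegions",
]


class BedParseError(ValueError):
    """A malformed line in a BED-like file, reported with its line number."""


@dataclass(frozen=True, order=True)
class FixedInterval:
    """A genomic span ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "start must be < end"
            )
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def outer_start(self) -> int:
        return self.start

    @property
    def outer_end(self) -> int:
        return self.end


@dataclass(frozen=True, order=True)
class FlexibleInterval:
    """A consensus region whose boundaries are intervals, not points.

    ``start_start``/``end_end`` delimit the outer span (half-open);
    ``[start_start, start_end]`` is the start interval,
    ``[end_start, end_end]`` the end interval (in end-coordinate space),
    and ``[start_end, end_start)`` the core.
    """

    chrom: str
    start_start: int
    start_end: int
    end_start: int
    end_end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        c = (self.start_start, self.start_end, self.end_start, self.end_end)
        if not (c[0] <= c[1] <= c[2] <= c[3]):
            raise ValueError(f"flexible interval coordinates out of order: {c}")
        if not c[0] < c[3]:
            raise ValueError(f"empty outer span: {c}")
        if c[0] < 0:
            raise ValueError(f"negative start {c[0]}")

    @property
    def outer_start(self) -> int:
        return self.start_start

    @property
    def outer_end(self) -> int:
        return self.end_end

    @property
    def width(self) -> int:
        return self.end_end - self.start_start

    @property
    def core(self) -> tuple[int, int]:
        return self.start_end, self.end_start

    def to_fixed(self) -> FixedInterval:
        """Collapse to the outer span."""
        return FixedInterval(self.chrom, self.start_start, self.end_end)


AnyInterval = Union[FixedInterval, FlexibleInterval]


def _merge_sorted(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge strictly overlapping sorted intervals (touching kept apart)."""
    if len(starts) == 0:
        return starts, ends
    out_s = [int(starts[0])]
    out_e = [int(ends[0])]
    for s, e in zip(starts[1:], ends[1:]):
        if s < out_e[-1]:  # strict overlap only
            if e > out_e[-1]:
                out_e[-1] = int(e)
        else:
            out_s.append(int(s))
            out_e.append(int(e))
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


@dataclass
class RegionSet:
    """A named, sorted collection of fixed intervals (one experiment)."""

    name: str
    intervals: tuple[FixedInterval, ...]

    def __init__(self, name: str, intervals: Iterable[FixedInterval]):
        self.name = name
        self.intervals = tuple(sorted(intervals))

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[FixedInterval]:
        return iter(self.intervals)

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends) arrays, sorted."""
        out: dict[str, tuple[list[int], list[int]]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, ([], []))
            out[iv.chrom][0].append(iv.start)
            out[iv.chrom][1].append(iv.end)
        return {
            c: (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64))
            for c, (s, e) in out.items()
        }

    def merged_by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome arrays with overlapping intervals merged.

        One experiment contributes at most once to any genomic position;
        abutting intervals remain distinct regions.
        """
        return {c: _merge_sorted(s, e) for c, (s, e) in self.by_chrom().items()}

    def total_bases(self) -> int:
        return int(
            sum((e - s).sum() for s, e in self.merged_by_chrom().values())
        )


@dataclass
class RegionSetCollection:
    """The input collection: a sequence of region sets."""

    sets: tuple[RegionSet, ...]

    def __init__(self, sets: Iterable[RegionSet]):
        self.sets = tuple(sets)

    @property
    def n(self) -> int:
        return len(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[RegionSet]:
        return iter(self.sets)

    def __getitem__(self, i: int) -> RegionSet:
        return self.sets[i]

    @classmethod
    def from_files(cls, paths: Iterable[Union[str, Path]]) -> "RegionSetCollection":
        return cls(read_bed(p) for p in paths)


class Universe:
    """A sorted, non-overlapping consensus region set.

    Regions are homogeneous: all :class:`FixedInterval` or all
    :class:`FlexibleInterval`.  Outer spans never overlap; consecutive
    regions on one chromosome satisfy ``prev.outer_end <= next.outer_start``.
    """

    def __init__(
        self,
        regions: Iterable[AnyInterval],
        method: str = "external",
        params: Mapping | None = None,
        validate: bool = True,
    ):
        regions = sorted(regions, key=lambda r: (r.chrom, r.outer_start, r.outer_end))
        self.regions: tuple[AnyInterval, ...] = tuple(regions)
        self.method = method
        self.params = dict(params or {})
        if validate:
            self._validate()

    def _validate(self) -> None:
        kinds = {type(r) for r in self.regions}
        if len(kinds) > 1:
            raise ValueError("universe regions must be homogeneous (fixed or flexible)")
        for a, b in zip(self.regions, self.regions[1:]):
            if a.chrom == b.chrom and a.outer_end > b.outer_start:
                raise ValueError(
                    f"overlapping universe regions on {a.chrom}: "
                    f"[{a.outer_start},{a.outer_end}) and [{b.outer_start},{b.outer_end})"
                )

    @property
    def is_flexible(self) -> bool:
        return bool(self.regions) and isinstance(self.regions[0], FlexibleInterval)

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[AnyInterval]:
        return iter(self.regions)

    def __getitem__(self, i: int) -> AnyInterval:
        return self.regions[i]

    def chroms(self) -> list[str]:
        return sorted({r.chrom for r in self.regions})

    def outer_arrays(self) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
        """Per chromosome: (outer starts, outer ends, global region indices)."""
        out: dict[str, tuple[list[int], list[int], list[int]]] = {}
        for i, r in enumerate(self.regions):
            out.setdefault(r.chrom, ([], [], []))
            out[r.chrom][0].append(r.outer_start)
            out[r.chrom][1].append(r.outer_end)
            out[r.chrom][2].append(i)
        return {
            c: (
                np.asarray(s, dtype=np.int64),
                np.asarray(e, dtype=np.int64),
                np.asarray(idx, dtype=np.int64),
            )
            for c, (s, e, idx) in out.items()
        }

    def total_bases(self) -> int:
        return sum(r.outer_end - r.outer_start for r in self.regions)

    def to_fixed(self) -> "Universe":
        """Collapse flexible regions to their outer spans."""
        if not self.is_flexible:
            return self
        return Universe(
            (r.to_fixed() for r in self.regions),
            method=self.method,
            params={**self.params, "collapsed": True},
            validate=False,
        )

    def write(self, path: Union[str, Path]) -> None:
        """Write BED3 (fixed) or the flexible BED8 dialect."""
        if self.is_flexible:
            write_flexible_bed(self, path)
            return
        with open(path, "w") as fh:
            for r in self.regions:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")


def read_chrom_sizes(path: Union[str, Path]) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>length`` file, preserving order."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise BedParseError(f"{path}:{lineno}: expected 'chrom<TAB>length'")
            try:
                length = int(fields[1])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer length {fields[1]!r}") from exc
            if length <= 0:
                raise BedParseError(f"{path}:{lineno}: non-positive length {length}")
            sizes[fields[0]] = length
    return sizes


def _bed_lines(path: Union[str, Path]):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def read_bed(path: Union[str, Path], name: str | None = None) -> RegionSet:
    """Read a BED3+ file into a sorted :class:`RegionSet`.

    Extra columns are ignored; ``track``/``browser``/comment lines are
    skipped.  Malformed lines raise :class:`BedParseError` naming the
    line number.
    """
    intervals = []
    for lineno, fields in _bed_lines(path):
        if len(fields) < 3:
            raise BedParseError(f"{path}:{lineno}: expected >=3 tab-separated columns")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
        try:
            intervals.append(FixedInterval(fields[0], start, end))
        except ValueError as exc:
            raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    if name is None:
        name = Path(path).stem
    return RegionSet(name, intervals)


def read_flexible_bed(path: Union[str, Path]) -> Universe:
    """Read a flexible universe from the extended BED8 dialect.

    Columns 2/3 hold the outer span, columns 7/8 (thickStart/thickEnd)
    hold the end of the flexible start and the start of the flexible end.
    """
    regions = []
    for lineno, fields in _bed_lines(path):
        if len(fields) < 8:
            raise BedParseError(
                f"{path}:{lineno}: flexible BED needs >=8 columns, got {len(fields)}"
            )
        try:
            ss, ee = int(fields[1]), int(fields[2])
            se, es = int(fields[6]), int(fields[7])
        except ValueError as exc:
            raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
        if not (ss <= se <= es <= ee):
            raise BedParseError(
                f"{path}:{lineno}: thickStart/thickEnd ({se},{es}) must lie inside "
                f"[{ss},{ee}] in order start_start<=start_end<=end_start<=end_end"
            )
        try:
            regions.append(FlexibleInterval(fields[0], ss, se, es, ee))
        except ValueError as exc:
            raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return Universe(regions, method="external")


def write_flexible_bed(universe: Universe, path: Union[str, Path]) -> None:
    """Write a flexible universe as BED8 (name '.', score 0, strand '.')."""
    if not universe.is_flexible and len(universe) > 0:
        raise ValueError("write_flexible_bed requires a flexible universe")
    with open(path, "w") as fh:
        for r in universe.regions:
            fh.write(
                f"{r.chrom}\t{r.start_start}\t{r.end_end}\t.\t0\t.\t"
                f"{r.start_end}\t{r.end_start}\n"
            )


def read_universe(path: Union[str, Path]) -> Universe:
    """Read a universe, sniffing BED3 (fixed) vs BED8 (flexible)."""
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            ncol = len(line.split("\t"))
            if ncol >= 8:
                return read_flexible_bed(path)
            break
    rs = read_bed(path)
    return Universe(rs.intervals, method="external")


@dataclass
class TokenizedRegions:
    """Result of projecting a query region set onto a universe.

    ``assignments[i]`` lists the universe region indices whose outer
    span overlaps query interval ``i`` by at least one base.
    """

    assignments: list[list[int]]
    query: RegionSet = field(repr=False)
    universe: Universe = field(repr=False)

    @property
    def n_untokenized(self) -> int:
        return sum(1 for a in self.assignments if not a)

    def __iter__(self):
        return iter(self.assignments)

    def __len__(self) -> int:
        return len(self.assignments)


def tokenize(query: RegionSet, universe: Universe) -> TokenizedRegions:
    """Map each query interval to the universe regions it overlaps.

    A query interval maps to every universe region whose outer span
    shares at least one base with it; intervals overlapping nothing map
    to an empty list (counted as untokenized, not an error).
    """
    per_chrom = universe.outer_arrays()
    assignments: list[list[int]] = []
    for iv in query.intervals:
        if iv.chrom not in per_chrom:
            assignments.append([])
            continue
        us, ue, idx = per_chrom[iv.chrom]
        # regions with u.start < q.end and u.end > q.start
        lo = int(np.searchsorted(ue, iv.start, side="right"))
        hi = int(np.searchsorted(us, iv.end, side="left"))
        assignments.append([int(i) for i in idx[lo:hi]])
    return TokenizedRegions(assignments, query, universe)
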