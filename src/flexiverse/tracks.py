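"""Plane-sweep computation of collection signal tracks.

Three base-resolution integer tracks summarize a region set collection:

* ``s(i)`` — number of sets with a (merged) region starting at ``i``;
* ``c(i)`` — number of sets covering ``i`` (the core/coverage track);
* ``e(i)`` — number of sets whose region's *last covered base* is ``i``.

End events sit at ``end - 1`` rather than the exclusive end coordinate,
so every position with ``e(i) > 0`` is itself covered; the likelihood
model relies on a position being simultaneously covered and an end.
With that convention the tracks obey the balance identity
``c(i) - c(i-1) = s(i) - e(i-1)``.

The sweep is event-sorted: memory and time scale with the number of
intervals, not the genome.  Coverage is stored run-length encoded;
start/end tracks as sparse position/count pairs.  Dense per-chromosome
vectors are materialized on demand.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Union

import numpy as np

from .intervals import RegionSetCollection

__all__ = ["SignalTracks", "CoverageStats", "compute_tracks", "coverage_stats"]


@dataclass
class CoverageStats:
    """Aggregate coverage of the genome by a collection.

    ``s_c`` is the total base-coverage (sum of ``c(i)`` over the genome,
    in base x set units), ``g`` the genome size.
    """

    s_c: int
    g: int

    @property
    def mean_coverage(self) -> float:
        return self.s_c / self.g


class SignalTracks:
    """Per-chromosome start / coverage / end tracks of a collection."""

    def __init__(
        self,
        n: int,
        chrom_sizes: Mapping[str, int],
        starts: Mapping[str, tuple[np.ndarray, np.ndarray]],
        ends: Mapping[str, tuple[np.ndarray, np.ndarray]],
        coverage: Mapping[str, tuple[np.ndarray, np.ndarray]],
    ):
        self.n = n
        self.chrom_sizes = dict(chrom_sizes)
        self._starts = dict(starts)  # chrom -> (positions, counts)
        self._ends = dict(ends)
        self._coverage = dict(coverage)  # chrom -> (edges[m+1], values[m])

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_sizes)

    def start_events(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        return self._starts.get(
            chrom, (np.empty(0, np.int64), np.empty(0, np.int64))
        )

    def end_events(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        return self._ends.get(chrom, (np.empty(0, np.int64), np.empty(0, np.int64)))

    def coverage_rle(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """Run-length encoded coverage: (edges, values) with
        ``values[j]`` holding on ``[edges[j], edges[j+1])``."""
        if chrom in self._coverage:
            return self._coverage[chrom]
        L = self.chrom_sizes[chrom]
        return np.array([0, L], np.int64), np.array([0], np.int64)

    def coverage_runs(self, chrom: str, min_value: int) -> tuple[np.ndarray, np.ndarray]:
        """Maximal runs where ``c(i) >= min_value`` as (starts, ends)."""
        edges, values = self.coverage_rle(chrom)
        keep = values >= min_value
        if not keep.any():
            return np.empty(0, np.int64), np.empty(0, np.int64)
        # merge adjacent qualifying runs
        boundaries = np.flatnonzero(np.diff(keep.astype(np.int8)))
        run_edges = np.concatenate([[0], boundaries + 1, [len(keep)]])
        out_s, out_e = [], []
        for a, b in zip(run_edges[:-1], run_edges[1:]):
            if keep[a]:
                out_s.append(int(edges[a]))
                out_e.append(int(edges[b]))
        return np.asarray(out_s, np.int64), np.asarray(out_e, np.int64)

    def dense(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Materialize (s, c, e) as dense int vectors over the chromosome."""
        L = self.chrom_sizes[chrom]
        s = np.zeros(L, np.int64)
        e = np.zeros(L, np.int64)
        pos, cnt = self.start_events(chrom)
        s[pos] = cnt
        pos, cnt = self.end_events(chrom)
        e[pos] = cnt
        edges, values = self.coverage_rle(chrom)
        c = np.repeat(values, np.diff(edges))
        return s, c, e

    def total_coverage(self) -> int:
        """Sum of c(i) over the whole genome (base x set units)."""
        total = 0
        for chrom in self.chrom_sizes:
            edges, values = self.coverage_rle(chrom)
            total += int((values * np.diff(edges)).sum())
        return total

    def max_coverage(self) -> int:
        m = 0
        for chrom in self.chrom_sizes:
            _, values = self.coverage_rle(chrom)
            if len(values):
                m = max(m, int(values.max()))
        return m

    def to_bedgraph(self, track: str, path: Union[str, Path]) -> None:
        """Export one track ('start', 'core' or 'end') as bedGraph runs.

        Zero-valued runs are omitted, as is conventional.
        """
        if track not in ("start", "core", "end"):
            raise ValueError(f"unknown track {track!r}")
        with open(path, "w") as fh:
            for chrom in self.chrom_sizes:
                if track == "core":
                    edges, values = self.coverage_rle(chrom)
                    for a, b, v in zip(edges[:-1], edges[1:], values):
                        if v:
                            fh.write(f"{chrom}\t{a}\t{b}\t{v}\n")
                else:
                    pos, cnt = (
                        self.start_events(chrom)
                        if track == "start"
                        else self.end_events(chrom)
                    )
                    for p, v in zip(pos, cnt):
                        fh.write(f"{chrom}\t{p}\t{p + 1}\t{v}\n")


def compute_tracks(
    collection: RegionSetCollection, chrom_sizes: Mapping[str, int]
) -> SignalTracks:
    """Sweep a collection into its three signal tracks.

    Each set is first merged (strict overlaps only) so one experiment
    contributes at most 1 to any track position; abutting fragments stay
    separate regions.  Intervals on chromosomes missing from
    ``chrom_sizes``, or extending past a chromosome end, raise
    ``ValueError`` naming the offender.
    """
    start_acc: dict[str, list[np.ndarray]] = {}
    end_acc: dict[str, list[np.ndarray]] = {}
    for rs in collection:
        for chrom, (s, e) in rs.merged_by_chrom().items():
            if chrom not in chrom_sizes:
                raise ValueError(
                    f"region set {rs.name!r} has intervals on unknown chromosome "
                    f"{chrom!r} (not in chrom sizes)"
                )
            L = chrom_sizes[chrom]
            if len(e) and int(e.max()) > L:
                raise ValueError(
                    f"region set {rs.name!r}: interval end {int(e.max())} exceeds "
                    f"length {L} of {chrom!r}"
                )
            start_acc.setdefault(chrom, []).append(s)
            end_acc.setdefault(chrom, []).append(e)

    starts, ends, coverage = {}, {}, {}
    for chrom, s_lists in start_acc.items():
        L = chrom_sizes[chrom]
        all_s = np.concatenate(s_lists)
        all_e = np.concatenate(end_acc[chrom])
        pos, cnt = np.unique(all_s, return_counts=True)
        starts[chrom] = (pos.astype(np.int64), cnt.astype(np.int64))
        pos, cnt = np.unique(all_e - 1, return_counts=True)
        ends[chrom] = (pos.astype(np.int64), cnt.astype(np.int64))
        # coverage via +1/-1 events
        ev_pos = np.concatenate([all_s, all_e])
        ev_val = np.concatenate(
            [np.ones(len(all_s), np.int64), -np.ones(len(all_e), np.int64)]
        )
        uniq, inv = np.unique(ev_pos, return_inverse=True)
        net = np.zeros(len(uniq), np.int64)
        np.add.at(net, inv, ev_val)
        values = np.cumsum(net)
        edges = uniq
        if len(edges) == 0 or edges[0] != 0:
            edges = np.concatenate([[0], edges])
            values = np.concatenate([[0], values])
        else:
            values = values  # first event at 0 already defines value from 0
        if edges[-1] != L:
            edges = np.concatenate([edges, [L]])
        else:
            values = values[:-1]
        # drop zero-width runs and merge equal neighbours
        widths = np.diff(edges)
        keep = widths > 0
        run_starts = edges[:-1][keep]
        run_values = values[keep]
        change = np.concatenate([[True], np.diff(run_values) != 0])
        run_starts = run_starts[change]
        run_values = run_values[change]
        coverage[chrom] = (
            np.concatenate([run_starts, [L]]).astype(np.int64),
            run_values.astype(np.int64),
        )
    return SignalTracks(collection.n, chrom_sizes, starts, ends, coverage)


def coverage_stats(tracks: SignalTracks) -> CoverageStats:
    """Total base-coverage ``S_c`` and genome size ``g`` of the tracks."""
    g = int(sum(tracks.chrom_sizes.values()))
    if g <= 0:
        raise ValueError("genome size must be positive")
    return CoverageStats(s_c=tracks.total_coverage(), g=g)
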