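"""Universe fit metrics: base-level F10, boundary distances, likelihood.

Three complementary views of how well a universe represents a
collection of region sets:

* **F10** treats the universe as a base-level predictor of each query
  set and combines precision and recall with beta = 10, weighting
  recall a hundredfold in the squared-beta sense — missing covered
  bases hurts far more than including extra ones.
* **RBD** (region boundary distance) scores boundary placement: the
  median distance from query boundaries to the nearest same-type
  universe boundary, and the reverse direction, are folded into a
  weighted harmonic mean of closenesses ``1 / (1 + d)``; 1 is a
  perfect boundary match.  For flexible universes a query boundary
  anywhere inside the corresponding boundary interval counts as
  distance zero.
* **Likelihood** scores the universe as a labeling of the genome under
  the collection's track models (see :mod:`flexiverse.likelihood`),
  reported as the gain over an empty universe.

F10 and RBD are per-set scores averaged over the collection; the
likelihood is a single collection-level number.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Union

import numpy as np

from .intervals import FlexibleInterval, RegionSet, RegionSetCollection, Universe
from .likelihood import LikelihoodScore, TrackModels
from .tracks import SignalTracks, compute_tracks

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "BoundaryDistanceSummary",
    "CollectionScore",
    "AssessmentReport",
    "confusion",
    "f10_collection",
    "boundary_distances",
    "rbd_collection",
    "universe_likelihood",
    "assess",
]

F_BETA = 10.0


def f_beta(precision: float, recall: float, beta: float = F_BETA) -> float:
    denom = beta**2 * precision + recall
    if denom == 0:
        return 0.0
    return (1 + beta**2) * precision * recall / denom


@dataclass
class ConfusionCounts:
    """Base-level confusion of a universe predicting a query region set."""

    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        if self.tp + self.fp == 0:
            # empty universe: no positive predictions, vacuously precise
            return 1.0
        return self.tp / (self.tp + self.fp)

    @property
    def recall(self) -> float:
        if self.tp + self.fn == 0:
            # empty query: nothing to recover, vacuously recalled
            logger.debug("empty query; recall defined as 1")
            return 1.0
        return self.tp / (self.tp + self.fn)

    @property
    def f10(self) -> float:
        return f_beta(self.precision, self.recall)


@dataclass
class BoundaryDistanceSummary:
    """Median boundary distances in both directions and the RBD score."""

    d_qu: float
    d_uq: float
    rbd: float


@dataclass
class CollectionScore:
    """A per-set metric averaged over a collection."""

    mean: float
    per_set: dict[str, float]


def _overlap_bases(
    a: dict[str, tuple[np.ndarray, np.ndarray]],
    b: dict[str, tuple[np.ndarray, np.ndarray]],
) -> int:
    """Total intersection of two per-chromosome merged interval maps."""
    total = 0
    for chrom, (as_, ae) in a.items():
        if chrom not in b:
            continue
        bs, be = b[chrom]
        i = j = 0
        while i < len(as_) and j < len(bs):
            lo = max(as_[i], bs[j])
            hi = min(ae[i], be[j])
            if hi > lo:
                total += int(hi - lo)
            if ae[i] <= be[j]:
                i += 1
            else:
                j += 1
    return total


def _universe_cover(universe: Universe) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Covered span per chromosome; flexible regions count their full
    outer span (the region asserts it may extend that far)."""
    return {c: (s, e) for c, (s, e, _) in universe.outer_arrays().items()}


def confusion(universe: Universe, query: RegionSet) -> ConfusionCounts:
    """Base-level TP/FP/FN of a universe predicting one region set."""
    ucov = _universe_cover(universe)
    qcov = query.merged_by_chrom()
    tp = _overlap_bases(ucov, qcov)
    u_total = universe.total_bases()
    q_total = int(sum((e - s).sum() for s, e in qcov.values()))
    return ConfusionCounts(tp=tp, fp=u_total - tp, fn=q_total - tp)


def f10_collection(universe: Universe, collection: RegionSetCollection) -> CollectionScore:
    """Mean F10 of the universe over every set in the collection."""
    if collection.n == 0:
        raise ValueError("cannot score an empty collection")
    per_set = {rs.name: confusion(universe, rs).f10 for rs in collection}
    return CollectionScore(float(np.mean(list(per_set.values()))), per_set)


# -- boundary distances ----------------------------------------------------


def _boundary_intervals(
    universe: Universe, which: str
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Universe boundary positions as closed intervals [lo, hi].

    Fixed regions give degenerate intervals; flexible regions give their
    start interval or end interval (the latter in end-coordinate space).
    """
    out: dict[str, tuple[list[int], list[int]]] = {}
    for r in universe:
        if isinstance(r, FlexibleInterval):
            lo, hi = (
                (r.start_start, r.start_end)
                if which == "start"
                else (r.end_start, r.end_end)
            )
        else:
            lo = hi = r.start if which == "start" else r.end
        out.setdefault(r.chrom, ([], []))
        out[r.chrom][0].append(lo)
        out[r.chrom][1].append(hi)
    return {
        c: (np.asarray(lo, np.int64), np.asarray(hi, np.int64))
        for c, (lo, hi) in out.items()
    }


def _query_boundaries(query: RegionSet, which: str) -> dict[str, np.ndarray]:
    out: dict[str, list[int]] = {}
    for iv in query:
        out.setdefault(iv.chrom, []).append(iv.start if which == "start" else iv.end)
    return {c: np.asarray(sorted(v), np.int64) for c, v in out.items()}


def _point_to_intervals(b: int, lo: np.ndarray, hi: np.ndarray) -> float:
    """Distance from a point to the nearest of sorted disjoint [lo, hi]."""
    i = int(np.searchsorted(lo, b, side="right")) - 1
    best = math.inf
    if i >= 0:
        if hi[i] >= b:
            return 0.0
        best = b - int(hi[i])
    if i + 1 < len(lo):
        best = min(best, int(lo[i + 1]) - b)
    return float(best)


def _interval_to_points(lo: int, hi: int, points: np.ndarray) -> float:
    """Distance from a closed interval to the nearest of sorted points."""
    i = int(np.searchsorted(points, lo, side="left"))
    if i < len(points) and points[i] <= hi:
        return 0.0
    best = math.inf
    if i > 0:
        best = lo - int(points[i - 1])
    if i < len(points):
        best = min(best, int(points[i]) - hi)
    return float(best)


def boundary_distances(
    query: RegionSet,
    universe: Universe,
    flexible: bool = False,
    weights: tuple[float, float] = (10.0, 1.0),
) -> BoundaryDistanceSummary:
    """Median boundary distances between a query set and a universe.

    Start boundaries match only start boundaries and ends only ends.
    With ``flexible=True``, a query boundary inside a universe boundary
    interval is distance zero, else the distance runs to the interval's
    nearest edge.  ``weights`` are the (query->universe, universe->query)
    weights of the harmonic mean; the default 10:1 mirrors the
    recall-over-precision asymmetry of F10.

    Boundaries on chromosomes where the other side has no regions get
    infinite distance (logged); the medians absorb them unless they are
    the majority.
    """
    if len(universe) == 0:
        raise ValueError("boundary distances are undefined for an empty universe")
    if len(query) == 0:
        raise ValueError("boundary distances are undefined for an empty query")
    if flexible and not universe.is_flexible:
        flexible = False  # fixed universes have point boundaries regardless

    qu: list[float] = []
    uq: list[float] = []
    for which in ("start", "end"):
        u_int = _boundary_intervals(universe, which)
        q_pts = _query_boundaries(query, which)
        for chrom, pts in q_pts.items():
            if chrom not in u_int:
                qu.extend([math.inf] * len(pts))
                continue
            lo, hi = u_int[chrom]
            if not flexible:
                # fixed treatment: collapse to the outer-span edge
                pt = lo if which == "start" else hi
                lo = hi = pt
            for b in pts:
                qu.append(_point_to_intervals(int(b), lo, hi))
        for chrom, (lo, hi) in u_int.items():
            if chrom not in q_pts:
                uq.extend([math.inf] * len(lo))
                continue
            pts = q_pts[chrom]
            if not flexible:
                edges = lo if which == "start" else hi
                for b in edges:
                    uq.append(_point_to_intervals(int(b), pts, pts))
            else:
                for a, b in zip(lo, hi):
                    uq.append(_interval_to_points(int(a), int(b), pts))

    d_qu = float(np.median(qu))
    d_uq = float(np.median(uq))
    w_qu, w_uq = weights
    rbd = (w_qu + w_uq) / (w_qu * (1.0 + d_qu) + w_uq * (1.0 + d_uq))
    return BoundaryDistanceSummary(d_qu=d_qu, d_uq=d_uq, rbd=float(rbd))


def rbd_collection(
    universe: Universe,
    collection: RegionSetCollection,
    flexible: bool = False,
    weights: tuple[float, float] = (10.0, 1.0),
) -> CollectionScore:
    """Mean RBD score of the universe over every set in the collection."""
    if collection.n == 0:
        raise ValueError("cannot score an empty collection")
    per_set = {
        rs.name: boundary_distances(rs, universe, flexible=flexible, weights=weights).rbd
        for rs in collection
    }
    return CollectionScore(float(np.mean(list(per_set.values()))), per_set)


def universe_likelihood(
    universe: Universe, models: TrackModels, flexible: bool = False
) -> LikelihoodScore:
    """Universe log-likelihood under the track models, delta-normalized."""
    return models.universe_score(universe, flexible=flexible)


@dataclass
class AssessmentReport:
    """All requested fit scores for one universe/collection pair."""

    method: str
    flexible: bool
    n_sets: int
    aggregate: dict[str, float]
    per_set: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "flexible": self.flexible,
            "n_sets": self.n_sets,
            "aggregate": {k: round(v, 6) for k, v in self.aggregate.items()},
            "per_set": {
                name: {k: round(v, 6) for k, v in row.items()}
                for name, row in self.per_set.items()
            },
        }

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def to_tsv(self, path: Union[str, Path]) -> None:
        metrics = sorted({m for row in self.per_set.values() for m in row})
        with open(path, "w") as fh:
            fh.write("set\t" + "\t".join(metrics) + "\n")
            for name, row in self.per_set.items():
                fh.write(
                    name
                    + "\t"
                    + "\t".join(f"{row.get(m, float('nan')):.6f}" for m in metrics)
                    + "\n"
                )
            fh.write(
                "__aggregate__\t"
                + "\t".join(
                    f"{self.aggregate[m]:.6f}" if m in self.aggregate else ""
                    for m in metrics
                )
                + "\n"
            )


ALL_METRICS = ("f10", "rbd", "likelihood")


def assess(
    universe: Universe,
    collection: RegionSetCollection,
    chrom_sizes: Mapping[str, int] | None = None,
    metrics: Iterable[str] = ALL_METRICS,
    flexible: bool = False,
    alpha: float = 1.0,
    weights: tuple[float, float] = (10.0, 1.0),
    tracks: SignalTracks | None = None,
) -> AssessmentReport:
    """Compute the requested fit metrics of a universe to a collection.

    ``likelihood`` needs the collection's signal tracks: pass
    precomputed ``tracks`` or ``chrom_sizes`` to sweep them here.
    Assessment is fully deterministic.
    """
    metrics = tuple(metrics)
    unknown = set(metrics) - set(ALL_METRICS)
    if unknown:
        raise ValueError(f"unknown metrics: {sorted(unknown)}")
    per_set: dict[str, dict[str, float]] = {rs.name: {} for rs in collection}
    aggregate: dict[str, float] = {}

    if "f10" in metrics:
        score = f10_collection(universe, collection)
        aggregate["f10"] = score.mean
        for rs in collection:
            cc = confusion(universe, rs)
            per_set[rs.name].update(
                precision=cc.precision, recall=cc.recall, f10=cc.f10
            )
    if "rbd" in metrics:
        score = rbd_collection(universe, collection, flexible=flexible, weights=weights)
        aggregate["rbd"] = score.mean
        for rs in collection:
            summary = boundary_distances(rs, universe, flexible=flexible, weights=weights)
            per_set[rs.name].update(
                d_qu=summary.d_qu, d_uq=summary.d_uq, rbd=summary.rbd
            )
    if "likelihood" in metrics:
        if tracks is None:
            if chrom_sizes is None:
                raise ValueError("likelihood metric needs tracks or chrom_sizes")
            tracks = compute_tracks(collection, chrom_sizes)
        models = TrackModels(tracks, alpha=alpha)
        score = universe_likelihood(universe, models, flexible=flexible)
        aggregate["likelihood_delta"] = score.delta
        aggregate["likelihood"] = score.loglik

    report = AssessmentReport(
        method=universe.method,
        flexible=flexible,
        n_sets=collection.n,
        aggregate=aggregate,
        per_set=per_set,
    )
    logger.info(
        "assessed %s universe against %d sets: %s",
        universe.method,
        collection.n,
        ", ".join(f"{k}={v:.4g}" for k, v in aggregate.items()),
    )
    return report
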