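"""Universe builders, presented as scikit-learn style estimators.

Every builder follows the same protocol: configure in ``__init__``,
``fit(collection, chrom_sizes=...)`` computes the signal tracks and the
consensus universe, and the result lands in the fitted attributes
``universe_`` (plus ``tracks_``, ``stats_`` and method-specific extras
such as ``cutoff_``).  ``transform`` tokenizes a query region set
against the fitted universe and ``score`` returns the mean F10 of the
universe against a collection, so builders compose with scikit-learn
model selection out of the box.  Module-level functions wrap the
estimators for one-shot use.

Builders
--------
union / intersection
    Bases covered by at least one / by every set.
tiles
    Fixed-width genome binning, data-independent.
coverage cutoff (CC)
    Bases with collection coverage >= x.  The default cutoff is the
    smallest integer satisfying ``x >= S_c / g`` (total base-coverage
    over genome size), clamped to [1, n]: x=1 reproduces the union,
    x=n the intersection.
flexible coverage cutoff (CCF)
    Two cutoffs: runs above the lower cutoff give the outer span,
    runs above the upper cutoff the core; the stretches in between
    become flexible boundary intervals.
maximum likelihood (LH)
    The highest-scoring background/start/core/end labeling of each
    chromosome under the track likelihood model, found by dynamic
    programming over the region grammar ``B* (S+ C* E+)* B*``.
HMM
    Viterbi decoding of a four-state hidden Markov model whose states
    are the parts of a flexible region and whose emissions are
    per-track Binomial(n, theta) counts; transitions and emissions are
    user-tunable, giving a dial the data-determined LH universe lacks.
"""

from __future__ import annotations

import logging
import math
import warnings
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .intervals import (
    FixedInterval,
    FlexibleInterval,
    RegionSet,
    RegionSetCollection,
    TokenizedRegions,
    Universe,
    tokenize,
)
from .likelihood import B, C, E, S, TrackModels
from .tracks import CoverageStats, SignalTracks, compute_tracks, coverage_stats

logger = logging.getLogger(__name__)

__all__ = [
    "UniverseBuilder",
    "UnionBuilder",
    "IntersectionBuilder",
    "TilesBuilder",
    "CoverageCutoffBuilder",
    "FlexibleCutoffBuilder",
    "MaxLikelihoodBuilder",
    "HMMBuilder",
    "optimal_cutoff",
    "default_ccf_cutoffs",
    "filter_universe",
    "union_universe",
    "intersection_universe",
    "tiles_universe",
    "cc_universe",
    "ccf_universe",
    "lh_universe",
    "hmm_universe",
    "DEFAULT_TRANSITIONS",
    "DEFAULT_EMISSIONS",
]

# transitions structurally allowed by the region grammar
_ALLOWED = np.array(
    [
        # B  S  C  E
        [1, 1, 0, 0],  # from B
        [0, 1, 1, 1],  # from S
        [0, 0, 1, 1],  # from C
        [1, 1, 0, 1],  # from E
    ],
    dtype=bool,
)

DEFAULT_TRANSITIONS = np.array(
    [
        [0.9, 0.1, 0.0, 0.0],
        [0.0, 0.5, 0.25, 0.25],
        [0.0, 0.0, 0.9, 0.1],
        [0.25, 0.25, 0.0, 0.5],
    ]
)

# theta[state][track] for tracks (start, core, end): expected fraction of
# sets signalling that track while in the state
DEFAULT_EMISSIONS = {
    "B": (0.02, 0.02, 0.02),
    "S": (0.5, 0.5, 0.02),
    "C": (0.02, 0.5, 0.02),
    "E": (0.02, 0.5, 0.5),
}

_INIT_STATES = (B, S)  # a chromosome may open in background or a region start
_FINAL_STATES = (B, E)  # and must close every region


def optimal_cutoff(stats_: CoverageStats, n: int) -> int:
    """Smallest integer cutoff satisfying ``x >= S_c / g``, clamped to [1, n].

    The bound admits every cutoff at or above the mean collection
    coverage; taking the smallest admissible integer maximizes recall
    among admissible cutoffs.
    """
    x = math.ceil(stats_.s_c / stats_.g)
    return int(min(max(x, 1), max(n, 1)))


def default_ccf_cutoffs(x_star: int, n: int) -> tuple[int, int]:
    """Poisson-style +-1 sd band around the optimal cutoff."""
    half = math.ceil(math.sqrt(x_star))
    lower = max(1, x_star - half)
    upper = min(max(n, 1), x_star + half)
    return lower, max(lower, upper)


def _viterbi(
    emit: np.ndarray,
    trans_log: np.ndarray,
    init_log: np.ndarray,
    final_log: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Best-path decoding over the four states.

    Ties prefer the earliest state in the order B < S < C < E, both for
    the chosen state and for its predecessor, so decoding is
    deterministic and biased against spurious regions.
    """
    L = emit.shape[0]
    back = np.empty((L, 4), np.int8)
    dp = init_log + emit[0]
    cols = np.arange(4)
    for t in range(1, L):
        m = dp[:, None] + trans_log
        b = np.argmax(m, axis=0)  # argmax takes the smallest index on ties
        dp = emit[t] + m[b, cols]
        back[t] = b
    final = dp + final_log
    last = int(np.argmax(final))
    score = float(final[last])
    labels = np.empty(L, np.int8)
    labels[-1] = last
    for t in range(L - 1, 0, -1):
        labels[t - 1] = back[t, labels[t]]
    return labels, score


def _labels_to_regions(chrom: str, labels: np.ndarray) -> list[FlexibleInterval]:
    """Convert a decoded state path into flexible regions.

    Each maximal ``S+ C* E+`` block becomes one region: the S run is the
    start interval, the E run the end interval, the C run (possibly
    empty) the core.
    """
    regions: list[FlexibleInterval] = []
    L = len(labels)
    i = 0
    while i < L:
        if labels[i] != S:
            i += 1
            continue
        ss = i
        while i < L and labels[i] == S:
            i += 1
        se = i  # first position after the S run == core start
        while i < L and labels[i] == C:
            i += 1
        es = i  # first E position
        if i >= L or labels[i] != E:
            raise AssertionError("decoded path violates the region grammar")
        while i < L and labels[i] == E:
            i += 1
        ee = i
        regions.append(FlexibleInterval(chrom, ss, se, es, ee))
    return regions


def _runs_to_fixed(chrom: str, run_s: np.ndarray, run_e: np.ndarray) -> list[FixedInterval]:
    return [FixedInterval(chrom, int(a), int(b)) for a, b in zip(run_s, run_e)]


class UniverseBuilder(BaseEstimator):
    """Base class: fits signal tracks, delegates universe construction."""

    method: str = "abstract"

    def fit(self, X: RegionSetCollection, y=None, *, chrom_sizes: Mapping[str, int]):
        """Compute tracks for the collection and build the universe.

        Parameters
        ----------
        X : RegionSetCollection
            The input collection of region sets.
        chrom_sizes : mapping
            Chromosome name to length; defines the genome.
        """
        self.n_sets_ = X.n
        self.chrom_sizes_ = dict(chrom_sizes)
        self.tracks_ = compute_tracks(X, chrom_sizes)
        self.stats_ = coverage_stats(self.tracks_)
        if X.n == 0:
            warnings.warn("empty collection: building an empty universe")
        self.universe_ = self._build()
        return self

    def _build(self) -> Universe:  # pragma: no cover - abstract
        raise NotImplementedError

    def transform(self, X: RegionSet) -> TokenizedRegions:
        """Tokenize a query region set against the fitted universe."""
        self._check_fitted()
        return tokenize(X, self.universe_)

    def score(self, X: RegionSetCollection, y=None) -> float:
        """Mean F10 of the fitted universe against a collection."""
        from .assessment import f10_collection

        self._check_fitted()
        return f10_collection(self.universe_, X).mean

    def _check_fitted(self) -> None:
        if not hasattr(self, "universe_"):
            raise RuntimeError(f"{type(self).__name__} is not fitted yet")

    def _threshold_universe(self, x: int, method: str, **params) -> Universe:
        if x > self.tracks_.max_coverage():
            warnings.warn(
                f"cutoff {x} exceeds the maximum coverage "
                f"{self.tracks_.max_coverage()}; universe is empty"
            )
        regions: list[FixedInterval] = []
        for chrom in self.chrom_sizes_:
            run_s, run_e = self.tracks_.coverage_runs(chrom, x)
            regions.extend(_runs_to_fixed(chrom, run_s, run_e))
        return Universe(regions, method=method, params=dict(params, cutoff=x))


class UnionBuilder(UniverseBuilder):
    """Merge of all bases covered by at least one set."""

    method = "union"

    def _build(self) -> Universe:
        return self._threshold_universe(1, "union")


class IntersectionBuilder(UniverseBuilder):
    """Bases covered by every set in the collection."""

    method = "intersection"

    def _build(self) -> Universe:
        return self._threshold_universe(max(self.n_sets_, 1), "intersection")


class TilesBuilder(UniverseBuilder):
    """Non-overlapping fixed-width tiles; ignores the collection."""

    method = "tiles"

    def __init__(self, tile_size: int = 1000):
        self.tile_size = tile_size

    def fit(self, X=None, y=None, *, chrom_sizes: Mapping[str, int]):
        if self.tile_size < 1:
            raise ValueError("tile_size must be >= 1")
        self.chrom_sizes_ = dict(chrom_sizes)
        regions = []
        for chrom, length in chrom_sizes.items():
            edges = list(range(0, length, self.tile_size)) + [length]
            regions.extend(
                FixedInterval(chrom, a, b) for a, b in zip(edges[:-1], edges[1:])
            )
        self.universe_ = Universe(regions, "tiles", {"tile_size": self.tile_size})
        return self


class CoverageCutoffBuilder(UniverseBuilder):
    """Coverage cutoff (CC) universe.

    ``cutoff=None`` selects the optimal cutoff ``x* = clamp(ceil(S_c/g),
    1, n)`` from the collection itself.
    """

    method = "cc"

    def __init__(self, cutoff: int | None = None):
        self.cutoff = cutoff

    def _build(self) -> Universe:
        if self.cutoff is None:
            x = optimal_cutoff(self.stats_, self.n_sets_)
            logger.info("CC universe: optimal cutoff x*=%d", x)
        else:
            # explicit cutoffs are honored (floored at 1), not capped at n:
            # a cutoff above the observed coverage legitimately empties the universe
            x = max(int(self.cutoff), 1)
        self.cutoff_ = x
        return self._threshold_universe(x, "cc")


class FlexibleCutoffBuilder(UniverseBuilder):
    """Flexible coverage cutoff (CCF) universe.

    Runs above ``lower`` form outer spans; maximal runs above ``upper``
    inside them form cores, one flexible region per core.  Runs that
    never reach ``upper`` have no core and are dropped.  When one
    ``lower`` run holds several cores it is split between consecutive
    cores at the leftmost position of minimum coverage, keeping outer
    spans disjoint and cores identical to the plain cutoff universe at
    ``upper``.  Defaults place a ``ceil(sqrt(x*))`` band around the
    optimal cutoff.
    """

    method = "ccf"

    def __init__(self, lower: int | None = None, upper: int | None = None):
        self.lower = lower
        self.upper = upper

    def _build(self) -> Universe:
        if self.lower is None or self.upper is None:
            x_star = optimal_cutoff(self.stats_, self.n_sets_)
            d_lower, d_upper = default_ccf_cutoffs(x_star, self.n_sets_)
            lower = d_lower if self.lower is None else int(self.lower)
            upper = d_upper if self.upper is None else int(self.upper)
            logger.info("CCF universe: cutoffs (%d, %d) around x*=%d", lower, upper, x_star)
        else:
            lower, upper = int(self.lower), int(self.upper)
        lower = max(lower, 1)
        upper = max(upper, 1)
        if lower > upper:
            raise ValueError(f"lower cutoff {lower} exceeds upper cutoff {upper}")
        self.lower_, self.upper_ = lower, upper
        if upper > self.tracks_.max_coverage():
            warnings.warn(
                f"upper cutoff {upper} exceeds the maximum coverage; universe is empty"
            )
        regions: list[FlexibleInterval] = []
        for chrom in self.chrom_sizes_:
            edges, values = self.tracks_.coverage_rle(chrom)
            lo_s, lo_e = self.tracks_.coverage_runs(chrom, lower)
            hi_s, hi_e = self.tracks_.coverage_runs(chrom, upper)
            for a, b in zip(lo_s, lo_e):
                inside = [
                    (int(cs), int(ce))
                    for cs, ce in zip(hi_s, hi_e)
                    if cs >= a and ce <= b
                ]
                if not inside:
                    continue  # no core, no region
                splits = [int(a)]
                for (c0, c1), (d0, _) in zip(inside, inside[1:]):
                    splits.append(self._min_coverage_pos(edges, values, c1, d0))
                splits.append(int(b))
                for (c0, c1), lo_bound, hi_bound in zip(inside, splits, splits[1:]):
                    regions.append(FlexibleInterval(chrom, lo_bound, c0, c1, hi_bound))
        return Universe(regions, "ccf", {"lower": lower, "upper": upper})

    @staticmethod
    def _min_coverage_pos(edges: np.ndarray, values: np.ndarray, a: int, b: int) -> int:
        """Leftmost position of minimum coverage in [a, b)."""
        lo = int(np.searchsorted(edges, a, side="right")) - 1
        best_pos, best_val = a, None
        for j in range(lo, len(values)):
            run_start = max(int(edges[j]), a)
            if run_start >= b:
                break
            v = int(values[j])
            if best_val is None or v < best_val:
                best_val, best_pos = v, run_start
        return best_pos


class _DecodingBuilder(UniverseBuilder):
    """Shared machinery: per-chromosome decode into flexible regions."""

    def _decode_genome(
        self,
        emit_fn,
        trans_log: np.ndarray,
        init_log: np.ndarray,
        final_log: np.ndarray,
    ) -> tuple[Universe, dict[str, float]]:
        regions: list[FlexibleInterval] = []
        scores: dict[str, float] = {}
        for chrom in self.chrom_sizes_:
            emit = emit_fn(chrom)
            labels, score = _viterbi(emit, trans_log, init_log, final_log)
            scores[chrom] = score
            regions.extend(_labels_to_regions(chrom, labels))
        return regions, scores


class MaxLikelihoodBuilder(_DecodingBuilder):
    """Maximum likelihood (LH) flexible universe.

    Finds, per chromosome, the labeling maximizing the summed position
    scores under the track likelihood model, over all paths obeying the
    region grammar; the optimum is exact (dynamic programming).
    """

    method = "lh"

    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha

    def _build(self) -> Universe:
        self.models_ = TrackModels(self.tracks_, alpha=self.alpha)
        neg = -np.inf
        trans_log = np.where(_ALLOWED, 0.0, neg)
        init_log = np.full(4, neg)
        init_log[list(_INIT_STATES)] = 0.0
        final_log = np.full(4, neg)
        final_log[list(_FINAL_STATES)] = 0.0
        regions, scores = self._decode_genome(
            self.models_.score_matrix, trans_log, init_log, final_log
        )
        self.path_scores_ = scores
        return Universe(regions, "lh", {"alpha": self.alpha})


class HMMBuilder(_DecodingBuilder):
    """Tunable HMM flexible universe (Viterbi decoding).

    States are the parts of a flexible region; each state emits, per
    track, a Binomial(n, theta) count.  ``transitions`` is a 4x4
    row-stochastic matrix over (B, S, C, E) restricted to the region
    grammar; ``emissions`` maps state name to per-track theta.
    ``em_iterations > 0`` enables Viterbi-style re-estimation of the
    emission thetas from the decoded segmentation (off by default; the
    model is meant to be tuned, not trained).
    """

    method = "hmm"

    def __init__(
        self,
        transitions: Sequence[Sequence[float]] | None = None,
        emissions: Mapping[str, Sequence[float]] | None = None,
        em_iterations: int = 0,
    ):
        self.transitions = transitions
        self.emissions = emissions
        self.em_iterations = em_iterations

    def _validated_params(self) -> tuple[np.ndarray, np.ndarray]:
        trans = (
            DEFAULT_TRANSITIONS
            if self.transitions is None
            else np.asarray(self.transitions, dtype=float)
        )
        if trans.shape != (4, 4):
            raise ValueError("transition matrix must be 4x4 over (B,S,C,E)")
        if not np.allclose(trans.sum(axis=1), 1.0):
            raise ValueError("transition matrix rows must sum to 1")
        if np.any(trans[~_ALLOWED] != 0.0):
            raise ValueError("transition matrix has mass on a forbidden transition")
        if np.any(trans < 0):
            raise ValueError("transition probabilities must be non-negative")
        if trans[B, S] == 0.0:
            raise ValueError("required transition B->S has zero probability")
        if trans[S, E] == 0.0 and (trans[S, C] == 0.0 or trans[C, E] == 0.0):
            raise ValueError("no path from S to E: regions can never close")
        emissions = DEFAULT_EMISSIONS if self.emissions is None else self.emissions
        theta = np.empty((4, 3))
        for i, name in enumerate("BSCE"):
            row = np.asarray(emissions[name], dtype=float)
            if row.shape != (3,) or np.any(row <= 0) or np.any(row >= 1):
                raise ValueError(
                    f"emission thetas for state {name} must be three values in (0,1)"
                )
            theta[i] = row
        return trans, theta

    def _emission_tables(self, theta: np.ndarray) -> np.ndarray:
        """(4 states, 3 tracks, n+1 counts) Binomial log-pmf lookup."""
        n = max(self.n_sets_, 1)
        counts = np.arange(n + 1)
        table = np.empty((4, 3, n + 1))
        for st in range(4):
            for tr in range(3):
                table[st, tr] = stats.binom.logpmf(counts, n, theta[st, tr])
        return table

    def _emit_fn(self, table: np.ndarray):
        def emit(chrom: str) -> np.ndarray:
            s, c, e = self.tracks_.dense(chrom)
            out = np.empty((len(s), 4))
            for st in range(4):
                out[:, st] = table[st, 0][s] + table[st, 1][c] + table[st, 2][e]
            return out

        return emit

    def _build(self) -> Universe:
        trans, theta = self._validated_params()
        with np.errstate(divide="ignore"):
            trans_log = np.where(trans > 0, np.log(np.where(trans > 0, trans, 1.0)), -np.inf)
        init = np.array([0.9, 0.1, 0.0, 0.0])
        init_log = np.where(init > 0, np.log(np.where(init > 0, init, 1.0)), -np.inf)
        final_log = np.full(4, -np.inf)
        final_log[list(_FINAL_STATES)] = 0.0

        for _ in range(max(0, int(self.em_iterations))):
            regions, _ = self._decode_genome(
                self._emit_fn(self._emission_tables(theta)), trans_log, init_log, final_log
            )
            theta = self._reestimate(theta, regions)
        self.theta_ = theta
        self.transitions_ = trans
        regions, scores = self._decode_genome(
            self._emit_fn(self._emission_tables(theta)), trans_log, init_log, final_log
        )
        self.path_scores_ = scores
        return Universe(
            regions,
            "hmm",
            {"em_iterations": self.em_iterations},
        )

    def _reestimate(self, theta: np.ndarray, regions: list[FlexibleInterval]) -> np.ndarray:
        """Viterbi-training update of emission thetas from a segmentation."""
        n = max(self.n_sets_, 1)
        sums = np.zeros((4, 3))
        lens = np.zeros(4)
        genome = 0
        for chrom in self.chrom_sizes_:
            s, c, e = self.tracks_.dense(chrom)
            genome += len(s)
            for st, (lo, hi) in self._state_spans(regions, chrom):
                lens[st] += hi - lo
                sums[st] += (s[lo:hi].sum(), c[lo:hi].sum(), e[lo:hi].sum())
            # background totals filled in below from the remainder
            sums[B] += (s.sum(), c.sum(), e.sum())
        sums[B] -= sums[S] + sums[C] + sums[E]
        lens[B] = genome - lens[S] - lens[C] - lens[E]
        new = theta.copy()
        for st in range(4):
            if lens[st] > 0:
                new[st] = np.clip(sums[st] / (lens[st] * n), 1e-3, 1 - 1e-3)
        return new

    @staticmethod
    def _state_spans(regions, chrom):
        for r in regions:
            if r.chrom != chrom:
                continue
            yield S, (r.start_start, r.start_end)
            if r.end_start > r.start_end:
                yield C, (r.start_end, r.end_start)
            yield E, (r.end_start, r.end_end)


def filter_universe(
    universe: Universe,
    min_width: int = 0,
    min_region_loglik: float | None = None,
    models: TrackModels | None = None,
) -> Universe:
    """Drop universe regions by outer width and/or likelihood contribution.

    The likelihood criterion removes regions whose score gain over an
    all-background labeling of their span falls below the threshold;
    it requires the collection's track models.
    """
    if min_region_loglik is not None and models is None:
        raise ValueError("likelihood filtering requires track models")
    kept = []
    for r in universe:
        if r.outer_end - r.outer_start < min_width:
            continue
        if min_region_loglik is not None:
            if models.region_delta(r) < min_region_loglik:
                continue
        kept.append(r)
    return Universe(
        kept,
        method=universe.method,
        params={
            **universe.params,
            "min_width": min_width,
            "min_region_loglik": min_region_loglik,
        },
        validate=False,
    )


# -- functional wrappers ---------------------------------------------------


def union_universe(collection: RegionSetCollection, chrom_sizes: Mapping[str, int]) -> Universe:
    return UnionBuilder().fit(collection, chrom_sizes=chrom_sizes).universe_


def intersection_universe(
    collection: RegionSetCollection, chrom_sizes: Mapping[str, int]
) -> Universe:
    return IntersectionBuilder().fit(collection, chrom_sizes=chrom_sizes).universe_


def tiles_universe(chrom_sizes: Mapping[str, int], tile_size: int = 1000) -> Universe:
    return TilesBuilder(tile_size=tile_size).fit(chrom_sizes=chrom_sizes).universe_


def _from_tracks(builder: UniverseBuilder, tracks: SignalTracks) -> Universe:
    """Build from precomputed tracks, skipping the sweep."""
    builder.n_sets_ = tracks.n
    builder.chrom_sizes_ = dict(tracks.chrom_sizes)
    builder.tracks_ = tracks
    builder.stats_ = coverage_stats(tracks)
    builder.universe_ = builder._build()
    return builder.universe_


def cc_universe(tracks: SignalTracks, cutoff: int | None = None) -> Universe:
    return _from_tracks(CoverageCutoffBuilder(cutoff=cutoff), tracks)


def ccf_universe(
    tracks: SignalTracks, lower: int | None = None, upper: int | None = None
) -> Universe:
    return _from_tracks(FlexibleCutoffBuilder(lower=lower, upper=upper), tracks)


def lh_universe(tracks: SignalTracks, alpha: float = 1.0) -> Universe:
    return _from_tracks(MaxLikelihoodBuilder(alpha=alpha), tracks)


def hmm_universe(
    tracks: SignalTracks,
    transitions=None,
    emissions=None,
    em_iterations: int = 0,
) -> Universe:
    return _from_tracks(
        HMMBuilder(
            transitions=transitions, emissions=emissions, em_iterations=em_iterations
        ),
        tracks,
    )
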