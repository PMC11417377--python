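"""Positional probability models over signal tracks, and universe likelihood.

For each track ``t`` in {start, core, end} the model assigns position
``i`` a probability of being that part of a region, smoothed with a
pseudocount ``alpha``::

    p_t(i) = (t(i) + alpha) / (n + 2 * alpha)

with ``n`` the number of sets in the collection; for ``alpha > 0`` every
probability is strictly inside (0, 1), so all log terms stay finite.

A labeling of the genome assigns each position one of four states —
background (B), start (S), core (C), end (E).  Each state asserts a
subset of the tracks "on" (S: start+core, C: core, E: end+core, B:
none), and scores

    sigma(i, l) = sum_t [ on(l,t) * log p_t(i) + (1 - on(l,t)) * log(1 - p_t(i)) ]

A fixed universe region labels its first base S, last base E and the
interior C (width-1 regions are S only, width-2 S then E).  The universe
log-likelihood is the sum of sigma over the genome under that labeling,
and the reported ``delta`` subtracts the all-background likelihood of
the empty universe, so an empty universe scores exactly 0.

Flexible regions replace the point boundary terms: the start-track term
becomes ``log(min(1 - eps, sum of p_start over the start interval))``,
the per-base start-track "off" terms inside the interval are dropped,
and the core track stays on per-base across the whole outer span
(symmetric for the end interval, shifted to last-covered-base space).
Widening a boundary interval inward can therefore only raise the score,
and a flexible region never scores below its fixed collapse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .intervals import FixedInterval, FlexibleInterval, Universe
from .tracks import SignalTracks

__all__ = ["TrackModels", "LikelihoodScore"]

# state indices; order encodes the tie-break preference B < S < C < E
B, S, C, E = 0, 1, 2, 3
STATE_NAMES = ("B", "S", "C", "E")
# on-sets per state over tracks (start, core, end)
_ON = np.array(
    [
        [0, 0, 0],  # B
        [1, 1, 0],  # S
        [0, 1, 0],  # C
        [0, 1, 1],  # E
    ],
    dtype=bool,
)

EPS = 1e-12


@dataclass
class LikelihoodScore:
    """Universe log-likelihood and its empty-universe-normalized delta."""

    loglik: float
    delta: float


class TrackModels:
    """Per-position Bernoulli models for the three signal tracks."""

    def __init__(self, tracks: SignalTracks, alpha: float = 1.0):
        if alpha <= 0:
            raise ValueError("alpha must be > 0 to keep probabilities inside (0,1)")
        if tracks.n < 1:
            raise ValueError("track models need a collection with at least one set")
        self.tracks = tracks
        self.alpha = float(alpha)
        self.n = tracks.n
        self._cache: dict[str, tuple[np.ndarray, ...]] = {}

    def probs(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Dense (p_start, p_core, p_end) over the chromosome."""
        key = f"p:{chrom}"
        if key not in self._cache:
            s, c, e = self.tracks.dense(chrom)
            denom = self.n + 2 * self.alpha
            self._cache[key] = tuple(
                (t + self.alpha) / denom for t in (s, c, e)
            )
        return self._cache[key]  # type: ignore[return-value]

    def log_terms(self, chrom: str) -> tuple[np.ndarray, ...]:
        """(log p, log(1-p)) for each track, dense."""
        key = f"l:{chrom}"
        if key not in self._cache:
            ps, pc, pe = self.probs(chrom)
            self._cache[key] = (
                np.log(ps), np.log1p(-ps),
                np.log(pc), np.log1p(-pc),
                np.log(pe), np.log1p(-pe),
            )
        return self._cache[key]

    def score_matrix(self, chrom: str) -> np.ndarray:
        """(L, 4) matrix of sigma(i, state), columns ordered B, S, C, E."""
        ls_on, ls_off, lc_on, lc_off, le_on, le_off = self.log_terms(chrom)
        L = len(ls_on)
        out = np.empty((L, 4))
        on = (ls_on, lc_on, le_on)
        off = (ls_off, lc_off, le_off)
        for state in range(4):
            acc = np.zeros(L)
            for t in range(3):
                acc += on[t] if _ON[state, t] else off[t]
            out[:, state] = acc
        return out

    def background_loglik(self) -> float:
        """Log-likelihood of the empty universe (all positions background)."""
        total = 0.0
        for chrom in self.tracks.chrom_sizes:
            _, ls_off, _, lc_off, _, le_off = self.log_terms(chrom)
            total += float(ls_off.sum() + lc_off.sum() + le_off.sum())
        return total

    # -- per-region contributions (relative to background) ----------------

    def _logit(self, chrom: str, track: int, i: int) -> float:
        terms = self.log_terms(chrom)
        return float(terms[2 * track][i] - terms[2 * track + 1][i])

    def region_delta_fixed(self, region: FixedInterval) -> float:
        """sigma gain over background of one fixed region's labeling."""
        chrom = region.chrom
        terms = self.log_terms(chrom)
        lc_on, lc_off = terms[2], terms[3]
        span = slice(region.start, region.end)
        delta = float((lc_on[span] - lc_off[span]).sum())
        delta += self._logit(chrom, 0, region.start)  # start track at first base
        if region.width >= 2:
            delta += self._logit(chrom, 2, region.end - 1)  # end track at last base
        return delta

    def region_delta_flexible(self, region: FlexibleInterval) -> float:
        """Gain over background of one flexible region.

        Boundary intervals contribute an aggregated probability that the
        boundary falls anywhere inside them; the end interval is shifted
        by one into last-covered-base space so a degenerate flexible
        region reproduces the fixed score exactly.
        """
        chrom = region.chrom
        ps, pc, pe = self.probs(chrom)
        terms = self.log_terms(chrom)
        ls_off, lc_on, lc_off, le_off = terms[1], terms[2], terms[3], terms[5]
        si = slice(region.start_start, region.start_end + 1)
        ei = slice(max(0, region.end_start - 1), region.end_end)
        span = slice(region.start_start, region.end_end)
        delta = float((lc_on[span] - lc_off[span]).sum())
        delta += float(np.log(min(1.0 - EPS, ps[si].sum())) - ls_off[si].sum())
        delta += float(np.log(min(1.0 - EPS, pe[ei].sum())) - le_off[ei].sum())
        return delta

    def region_delta(self, region, flexible: bool | None = None) -> float:
        """Dispatch on region type; ``flexible`` forces a scoring mode.

        A fixed region scored flexibly is treated as degenerate
        (point boundary intervals); a flexible region scored fixed is
        collapsed to its outer span.
        """
        is_flex = isinstance(region, FlexibleInterval)
        if flexible is None:
            flexible = is_flex
        if flexible:
            if not is_flex:
                region = FlexibleInterval(
                    region.chrom, region.start, region.start, region.end, region.end
                )
            return self.region_delta_flexible(region)
        if is_flex:
            region = region.to_fixed()
        return self.region_delta_fixed(region)

    def universe_score(self, universe: Universe, flexible: bool | None = None) -> LikelihoodScore:
        """Log-likelihood of a universe and its delta over the empty universe."""
        if flexible is None:
            flexible = universe.is_flexible
        for r in universe:
            if r.chrom not in self.tracks.chrom_sizes:
                raise ValueError(
                    f"universe region on {r.chrom!r} outside the modeled genome"
                )
        delta = sum(self.region_delta(r, flexible=flexible) for r in universe)
        return LikelihoodScore(loglik=self.background_loglik() + delta, delta=float(delta))
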