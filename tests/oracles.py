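"""Independent brute-force oracles used to cross-check the implementation.

Everything here works per-base or by exhaustive enumeration and never
calls the code paths it verifies.
"""

from __future__ import annotations

import numpy as np

# state indices mirrored from the package but fixed here independently
B, S, C, E = 0, 1, 2, 3
ALLOWED = {
    B: (B, S),
    S: (S, C, E),
    C: (C, E),
    E: (E, B, S),
}
INIT = (B, S)
FINAL = (B, E)


def brute_tracks(collection, chrom_sizes):
    """Per-base start/coverage/end counts, counting each set at most once.

    Returns {chrom: (s, c, e)} dense integer arrays.  Ends are recorded
    at the last covered base.  Overlapping intervals within one set are
    merged; abutting intervals stay distinct.
    """
    out = {
        chrom: (
            np.zeros(L, np.int64),
            np.zeros(L, np.int64),
            np.zeros(L, np.int64),
        )
        for chrom, L in chrom_sizes.items()
    }
    for rs in collection:
        spans = sorted((iv.chrom, iv.start, iv.end) for iv in rs)
        merged = []
        for chrom, a, b in spans:
            if merged and merged[-1][0] == chrom and a < merged[-1][2]:
                prev = merged[-1]
                merged[-1] = (chrom, prev[1], max(prev[2], b))
            else:
                merged.append((chrom, a, b))
        for chrom, a, b in merged:
            s, c, e = out[chrom]
            s[a] += 1
            e[b - 1] += 1
            for i in range(a, b):
                c[i] += 1
    return out


def brute_confusion(universe_spans, query_spans, genome):
    """Per-base TP/FP/FN from explicit base sets.

    ``universe_spans``/``query_spans``: iterables of (chrom, start, end).
    """
    u_bases = {(c, i) for c, a, b in universe_spans for i in range(a, b)}
    q_bases = {(c, i) for c, a, b in query_spans for i in range(a, b)}
    tp = len(u_bases & q_bases)
    return tp, len(u_bases - q_bases), len(q_bases - u_bases)


def brute_tokenize(query_spans, universe_spans):
    """All-pairs overlap: query index -> sorted universe indices."""
    out = []
    for qc, qs, qe in query_spans:
        hits = [
            i
            for i, (uc, us, ue) in enumerate(universe_spans)
            if uc == qc and us < qe and ue > qs
        ]
        out.append(hits)
    return out


def _valid_paths(length):
    """Yield every state path obeying the region grammar."""
    def rec(path):
        if len(path) == length:
            if path[-1] in FINAL:
                yield tuple(path)
            return
        for nxt in ALLOWED[path[-1]]:
            path.append(nxt)
            yield from rec(path)
            path.pop()

    for first in INIT:
        yield from rec([first])


def best_labeling_score(score_matrix):
    """Exhaustive maximum of sum(score[i, path[i]]) over valid paths."""
    best = -np.inf
    for path in _valid_paths(score_matrix.shape[0]):
        total = sum(score_matrix[i, st] for i, st in enumerate(path))
        if total > best:
            best = total
    return best


def best_hmm_path_score(emit, trans_log, init_log, final_ok=FINAL):
    """Exhaustive maximum of init + transitions + emissions over paths."""
    best = -np.inf
    for path in _valid_paths(emit.shape[0]):
        if path[-1] not in final_ok:
            continue
        total = init_log[path[0]] + emit[0, path[0]]
        for i in range(1, len(path)):
            total += trans_log[path[i - 1], path[i]] + emit[i, path[i]]
        if total > best:
            best = total
    return best
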