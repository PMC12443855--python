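"""Independent brute-force oracles used by the test suite.

Every function here is a deliberately naive reference implementation —
double loops, exhaustive enumeration — kept independent of the package code
paths it checks.
"""

from __future__ import annotations

from itertools import combinations
from math import factorial

import numpy as np


def brute_presence_filter(reports: dict, min_coverage: int, context: str | None):
    """Double loop over (coordinate, sample): retained iff covered everywhere."""
    all_coords = set()
    for df in reports.values():
        for row in df.itertuples(index=False):
            if context is None or row.context == context:
                all_coords.add((row.chrom, row.pos))
    retained = []
    for chrom, pos in sorted(all_coords):
        ok = True
        for df in reports.values():
            cov = 0
            found = False
            for row in df.itertuples(index=False):
                if row.chrom == chrom and row.pos == pos and (
                    context is None or row.context == context
                ):
                    cov = row.n_meth + row.n_unmeth
                    found = True
                    break
            if not found or cov < min_coverage:
                ok = False
                break
        if ok:
            retained.append((chrom, pos))
    return retained


def brute_cluster(positions, gap_max: int, min_cytosines: int):
    """Naive second-pass scan: start a new cluster whenever the gap exceeds gap_max."""
    clusters = []
    current: list[int] = []
    for p in sorted(positions):
        if current and p - current[-1] > gap_max:
            if len(current) >= min_cytosines:
                clusters.append(tuple(current))
            current = []
        current.append(p)
    if len(current) >= min_cytosines:
        clusters.append(tuple(current))
    return clusters


def brute_majority_vote(votes, class_order):
    """Count-and-argmax with explicit tie-break by class-order index."""
    best, best_count = None, -1
    for c in class_order:
        count = sum(1 for v in votes if v == c)
        if count > best_count:
            best, best_count = c, count
    return best


def brute_metrics(cm):
    """Per-cell-loop accuracy / precision / recall / F1 with the 0/0 -> 0 rule."""
    cm = np.asarray(cm)
    k = cm.shape[0]
    total = sum(cm[i, j] for i in range(k) for j in range(k))
    trace = sum(cm[i, i] for i in range(k))
    acc = trace / total if total else 0.0
    prec, rec, f1 = [], [], []
    for i in range(k):
        col = sum(cm[r, i] for r in range(k))
        row = sum(cm[i, c] for c in range(k))
        p = cm[i, i] / col if col else 0.0
        r = cm[i, i] / row if row else 0.0
        f = 2 * p * r / (p + r) if (p + r) else 0.0
        prec.append(p)
        rec.append(r)
        f1.append(f)
    return acc, prec, rec, f1


def brute_shapley(predict_raw, X_fore, X_back, n_feat: int, n_out: int):
    """Exhaustive 2^|F| interventional Shapley enumeration.

    f_S(x) = mean over background z of predict_raw(x on S, z elsewhere);
    phi_i = sum over S not containing i of |S|!(|F|-|S|-1)!/|F|! *
            [f_{S+i} - f_S].
    """
    phi = np.zeros((len(X_fore), n_feat, n_out))
    feats = list(range(n_feat))
    for xi, x in enumerate(np.asarray(X_fore, dtype=float)):
        vals = {}
        for r in range(n_feat + 1):
            for S in combinations(feats, r):
                Xm = np.asarray(X_back, dtype=float).copy()
                for j in S:
                    Xm[:, j] = x[j]
                vals[S] = predict_raw(Xm).mean(axis=0)
        for i in feats:
            rest = [f for f in feats if f != i]
            for r in range(len(rest) + 1):
                for S in combinations(rest, r):
                    w = (
                        factorial(len(S))
                        * factorial(n_feat - len(S) - 1)
                        / factorial(n_feat)
                    )
                    phi[xi, i] += w * (vals[tuple(sorted(S + (i,)))] - vals[S])
    return phi


def brute_overlap(a_start, a_end, b_start, b_end) -> bool:
    """>= 1 shared bp between two half-open intervals."""
    return max(a_start, b_start) < min(a_end, b_end)


def brute_assign_context(feature, tracks, precedence):
    """All-pairs interval scan for the primary-context precedence rule."""
    chrom, start, end = feature
    hit_kinds = set()
    for kind, intervals in tracks.items():
        for c, s, e in intervals:
            if c == chrom and brute_overlap(start, end, s, e):
                hit_kinds.add(kind)
    for kind in precedence:
        if kind in hit_kinds:
            return kind
    return "intergenic"


def brute_union_fraction(intervals, total: int) -> float:
    """Per-base boolean painting of TE coverage."""
    covered = {}
    for chrom, s, e in intervals:
        arr = covered.setdefault(chrom, set())
        arr.update(range(s, e))
    return sum(len(v) for v in covered.values()) / total


def brute_density(features, chrom_lengths, window):
    """Floor-division window counts keyed on feature start."""
    counts = {}
    for chrom, start, kind in features:
        counts[(chrom, start // window, kind)] = counts.get((chrom, start // window, kind), 0) + 1
    return counts
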