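"""Independent brute-force re-implementations used as test oracles.

Everything here is plain-Python loop/dict code transcribed directly from
the mathematical definitions, deliberately sharing no code path with the
package implementation.
"""

from __future__ import annotations

import math


def _isnan(v: float) -> bool:
    return v != v


def naive_consensus(
    rows: list[tuple[str, str, str, float]],
    polarities: dict[str, str],
    expert_weights: dict[str, float],
    m5_weights: dict[str, float] | None = None,
    q: float = 1.0,
):
    """Direct transcription of the scale -> mirror -> impute -> fuse sequence.

    ``rows``: (domain1, domain2, method, raw).  Returns
    ``(imputed_view, original_view, post_scores)`` where the views map
    (d1, d2) -> [m1, m2, m3, m4, m5, median] and post_scores maps
    (d1, d2, method) -> imputed scaled score.
    """
    methods = sorted({m for _, _, m, _ in rows})
    domains = sorted({d for d1, d2, _, _ in rows for d in (d1, d2)})

    # dissimilarity conversion
    X = {}
    for d1, d2, m, raw in rows:
        X[(d1, d2, m)] = raw if polarities[m] == "dissimilarity" else -raw

    # per-method autoscaled logistic sigmoid (population SD, pre-mirroring)
    S = {}
    for m in methods:
        xs = [x for (a, b, mm), x in X.items() if mm == m and not _isnan(x)]
        mu = sum(xs) / len(xs)
        sigma = math.sqrt(sum((v - mu) ** 2 for v in xs) / len(xs))
        for (a, b, mm), x in X.items():
            if mm != m:
                continue
            if _isnan(x):
                S[(a, b, mm)] = float("nan")
            elif sigma == 0:
                S[(a, b, mm)] = 0.5
            else:
                S[(a, b, mm)] = 1.0 - 1.0 / (1.0 + math.exp(-(x - mu) / sigma))

    # mirroring
    for (d1, d2, m) in list(S):
        if (d2, d1, m) not in S:
            S[(d2, d1, m)] = S[(d1, d2, m)]

    pairs = [(a, b) for a in domains for b in domains if a != b]
    pre = {(a, b, m): S.get((a, b, m), float("nan")) for a, b in pairs for m in methods}

    # local-average fill: first-domain set union second-domain set, else global mean
    post = dict(pre)
    for m in methods:
        vals = [v for (a, b, mm), v in pre.items() if mm == m and not _isnan(v)]
        gmean = sum(vals) / len(vals)
        for a, b in pairs:
            if _isnan(post[(a, b, m)]):
                set1 = [v for (x, y, mm), v in pre.items() if mm == m and x == a and not _isnan(v)]
                set2 = [v for (x, y, mm), v in pre.items() if mm == m and y == b and not _isnan(v)]
                union = set1 + set2
                post[(a, b, m)] = sum(union) / len(union) if union else gmean

    # global weights
    P = len(pairs)
    cov = {
        m: sum(1 for a, b in pairs if not _isnan(pre[(a, b, m)])) / P for m in methods
    }
    w2 = dict(cov)
    w3 = {m: cov[m] * expert_weights.get(m, 1.0) for m in methods}
    M = len(methods)
    if M >= 2:
        rmsd = {}
        for i, mi in enumerate(methods):
            for mj in methods[i + 1:]:
                diffs = [
                    (pre[(a, b, mi)] - pre[(a, b, mj)]) ** 2
                    for a, b in pairs
                    if not _isnan(pre[(a, b, mi)]) and not _isnan(pre[(a, b, mj)])
                ]
                rmsd[(mi, mj)] = rmsd[(mj, mi)] = math.sqrt(sum(diffs) / len(diffs))
        r = {mi: sum(rmsd.get((mi, mj), 0.0) for mj in methods) / M for mi in methods}
        rmax = max(r.values())
        # same degeneracy tolerance as the implementation under test
        w4 = {m: 1.0 for m in methods} if rmax <= 1e-12 else {m: r[m] / rmax for m in methods}
    else:
        w4 = {m: 1.0 for m in methods}
    w5 = dict(m5_weights) if m5_weights else {m: 1.0 for m in methods}

    def fuse(scores: dict[str, float], avail: list[str]):
        m1 = (sum(scores[m] ** q for m in avail) / len(avail)) ** (1.0 / q)

        def wavg(w):
            tot = sum(w[m] for m in avail)
            return sum(w[m] * scores[m] for m in avail) / tot

        ms = [m1, wavg(w2), wavg(w3), wavg(w4), wavg(w5)]
        return ms + [sorted(ms)[2]]

    imputed_view = {}
    original_view = {}
    for a, b in pairs:
        post_scores = {m: post[(a, b, m)] for m in methods}
        imputed_view[(a, b)] = fuse(post_scores, methods)
        avail = [m for m in methods if not _isnan(pre[(a, b, m)])]
        if avail:
            pre_scores = {m: pre[(a, b, m)] for m in methods}
            original_view[(a, b)] = fuse(pre_scores, avail)
    return imputed_view, original_view, post


def roc_auc_bruteforce(scores: list[float], positives: list[bool]) -> float:
    """Exhaustive threshold sweep (strict >) plus trapezoidal integration."""
    n_pos = sum(positives)
    n_neg = len(positives) - n_pos
    thresholds = [float("inf")] + sorted(set(scores), reverse=True) + [float("-inf")]
    points = []
    for t in thresholds:
        tp = sum(1 for s, y in zip(scores, positives) if s > t and y)
        fp = sum(1 for s, y in zip(scores, positives) if s > t and not y)
        points.append((fp / n_neg, tp / n_pos))
    auc = 0.0
    for (x1, y1), (x2, y2) in zip(points, points[1:]):
        auc += (x2 - x1) * (y1 + y2) / 2.0
    return auc


def nn_fraction_bruteforce(
    domains: list[str],
    dist: dict[tuple[str, str], float],
    labels: dict[str, tuple],
    level: int,
) -> float:
    """Leave-one-out NN with explicit loops and lexicographic tie-breaks."""
    correct = 0
    for q in domains:
        best = None
        best_d = float("inf")
        for other in sorted(domains):
            if other == q:
                continue
            d = dist[(q, other)]
            if d < best_d:
                best_d = d
                best = other
        if labels[q][:level] == labels[best][:level]:
            correct += 1
    return correct / len(domains)
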