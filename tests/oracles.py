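"""Independent reference implementations used as test oracles.

Deliberately naive (loops, fractions, exhaustive enumeration) and written
against the definitions directly, so they share no code path with the
package implementations they check.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


def bicor_reference(x, y):
    """Direct, loop-based evaluation of the biweight midcorrelation formula."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    pairs = [(a, b) for a, b in zip(x, y) if math.isfinite(a) and math.isfinite(b)]
    xs = [a for a, _ in pairs]
    ys = [b for _, b in pairs]

    def median(v):
        s = sorted(v)
        n = len(s)
        mid = n // 2
        return s[mid] if n % 2 else 0.5 * (s[mid - 1] + s[mid])

    def transform(v):
        m = median(v)
        mad = median([abs(a - m) for a in v])
        if mad == 0:
            mean = sum(v) / len(v)
            return [a - mean for a in v]
        out = []
        for a in v:
            u = (a - m) / (9.0 * mad)
            w = (1 - u * u) ** 2 if abs(u) < 1 else 0.0
            out.append((a - m) * w)
        return out

    tx = transform(xs)
    ty = transform(ys)
    num = sum(a * b for a, b in zip(tx, ty))
    den = math.sqrt(sum(a * a for a in tx)) * math.sqrt(sum(b * b for b in ty))
    return num / den


def pearson_reference(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    return float(np.corrcoef(x, y)[0, 1])


def bh_reference(p):
    """Step-up definition: q_(i) = min_{j >= i} min(1, p_(j) * m / j)."""
    p = list(map(float, p))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    for rank_pos, i in enumerate(order, start=1):
        candidates = [
            min(1.0, p[order[j - 1]] * m / j) for j in range(rank_pos, m + 1)
        ]
        q[i] = min(candidates)
    return q


def es_reference(weights, is_hit):
    """Running-sum enrichment score by a full walk down the ranked list.

    ``weights`` are the rank weights in list order; ``is_hit`` flags set
    membership per position. Returns the extremum of largest magnitude
    (positive preferred on exact ties).
    """
    weights = [float(w) for w in weights]
    L = len(weights)
    K = sum(bool(h) for h in is_hit)
    denom_hit = sum(abs(w) for w, h in zip(weights, is_hit) if h)
    miss = 1.0 / (L - K)
    running = 0.0
    best_pos, best_neg = 0.0, 0.0
    for w, h in zip(weights, is_hit):
        if h:
            running += (abs(w) / denom_hit) if denom_hit > 0 else 1.0 / K
        else:
            running -= miss
        best_pos = max(best_pos, running)
        best_neg = min(best_neg, running)
    return best_pos if best_pos >= -best_neg - 1e-12 else best_neg


def hypergeom_upper_tail(N, K, n, k):
    """Exact P(X >= k) by rational summation of the hypergeometric mass."""
    total = Fraction(0)
    denom = math.comb(N, n)
    for j in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, j) * math.comb(N - K, n - j), denom)
    return float(min(total, Fraction(1)))


def count_significant_pairs(mat1, mat2, alpha, same_tissue, bicor_fn, p_fn):
    """Brute-force double loop over gene pairs for connectivity counts.

    Returns (pair count, set of significant (side, index) gene nodes).
    """
    nodes = set()
    pairs = 0
    for i in range(mat1.shape[0]):
        for j in range(mat2.shape[0]):
            if same_tissue and j <= i:
                continue
            res = bicor_fn(mat1[i], mat2[j])
            if not np.isfinite(res.r):
                continue
            p = p_fn(res.r, res.n_used)
            if np.isfinite(p) and p < alpha:
                pairs += 1
                nodes.add((0, i))
                nodes.add((0, j) if same_tissue else (1, j))
    return pairs, nodes
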