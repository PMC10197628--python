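"""Biweight midcorrelation (bicor) and its significance machinery.

bicor is a robust alternative to Pearson correlation: observations are
re-weighted by Tukey's biweight on deviations from the median scaled by nine
times the (unscaled) median absolute deviation, so a single gross outlier is
down-weighted to zero instead of dominating the coefficient. For a vector x,

    u_i = (x_i - med(x)) / (9 * MAD(x)),
    w_i = (1 - u_i^2)^2 * 1(|u_i| < 1),
    x~_i = (x_i - med(x)) * w_i,

and bicor(x, y) = sum(x~ y~) / (||x~|| ||y~||), computed over complete pairs
only. If MAD(x) = 0 (more than half the values tied) the weighting is
undefined; that vector falls back to plain mean-centering with unit weights
(Pearson-style) and the result carries a fallback flag.

Significance follows the Student transform t = r sqrt((n-2)/(1-r^2)) against
the t distribution with n-2 degrees of freedom, two-sided; q-values come from
the Benjamini-Hochberg step-up.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
from scipy import stats

DEFAULT_MIN_N = 10  # complete pairs required before a coefficient is reported


@dataclass(frozen=True)
class BicorResult:
    r: float
    n_used: int
    fallback: bool = False

    @property
    def defined(self) -> bool:
        return np.isfinite(self.r)


def _transform_rows(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Biweight-transform each row of a complete (finite) 2-D array.

    Returns (normalized transformed rows, per-row fallback flags). Rows whose
    transformed norm is zero (constant vectors) come back as NaN rows.
    """
    a = np.asarray(a, dtype=float)
    med = np.median(a, axis=1, keepdims=True)
    d = a - med
    mad = np.median(np.abs(d), axis=1, keepdims=True)
    fallback = mad[:, 0] == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.divide(d, 9.0 * mad, out=np.zeros_like(d), where=mad > 0)
    w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
    t = d * w
    if fallback.any():
        t[fallback] = a[fallback] - a[fallback].mean(axis=1, keepdims=True)
    norm = np.linalg.norm(t, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(norm > 0, t / np.where(norm > 0, norm, 1.0), np.nan)
    return t, fallback


def bicor(x, y, min_n: int = DEFAULT_MIN_N) -> BicorResult:
    """Biweight midcorrelation of two vectors over their complete pairs.

    Missing entries (NaN) are allowed; only indices finite in both vectors
    enter. With fewer than ``min_n`` complete pairs the result is undefined
    (``r`` is NaN) — no exception is raised.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    n = int(mask.sum())
    if n < max(min_n, 2):
        return BicorResult(np.nan, n, False)
    tx, fx = _transform_rows(x[mask][None, :])
    ty, fy = _transform_rows(y[mask][None, :])
    r = float(np.clip(np.nansum(tx[0] * ty[0]), -1.0, 1.0))
    if not (np.isfinite(tx[0]).all() and np.isfinite(ty[0]).all()):
        r = np.nan
    return BicorResult(r, n, bool(fx[0] or fy[0]))


def bicor_matrix(
    X, Y, min_n: int = DEFAULT_MIN_N
) -> tuple[np.ndarray, np.ndarray]:
    """All pairwise bicor coefficients between rows of X and rows of Y.

    Pairwise-complete semantics: each (i, j) coefficient uses exactly the
    columns finite in both X[i] and Y[j], and the biweight transform of each
    vector is recomputed on that column subset. Rows are grouped by their
    missingness pattern so that archives with block missingness (whole
    individuals absent from a tissue) vectorize to a handful of matrix
    products.

    Returns (r, n_used), both shaped (X rows, Y rows); undefined entries are
    NaN in r.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError("X and Y must share the column (individual) axis")
    fx = np.isfinite(X)
    fy = np.isfinite(Y)

    def _groups(f: np.ndarray) -> dict[bytes, np.ndarray]:
        by: dict[bytes, list[int]] = defaultdict(list)
        for i, row in enumerate(f):
            by[row.tobytes()].append(i)
        return {k: np.asarray(v) for k, v in by.items()}

    gx = _groups(fx)
    gy = _groups(fy)
    r = np.full((X.shape[0], Y.shape[0]), np.nan)
    n_used = np.zeros((X.shape[0], Y.shape[0]), dtype=int)
    for kx, ix in gx.items():
        mx = np.frombuffer(kx, dtype=bool)
        for ky, iy in gy.items():
            my = np.frombuffer(ky, dtype=bool)
            m = mx & my
            n = int(m.sum())
            n_used[np.ix_(ix, iy)] = n
            if n < max(min_n, 2):
                continue
            tx, _ = _transform_rows(X[np.ix_(ix, np.flatnonzero(m))])
            ty, _ = _transform_rows(Y[np.ix_(iy, np.flatnonzero(m))])
            r[np.ix_(ix, iy)] = np.clip(tx @ ty.T, -1.0, 1.0)
    return r, n_used


def correlation_p(r, n_used):
    """Two-sided Student p-value for a correlation coefficient.

    Vectorized; returns NaN where ``n_used < 3`` or r is undefined, and 0
    where |r| = 1 (the degenerate limit of the t transform).
    """
    r = np.asarray(r, dtype=float)
    n = np.asarray(n_used, dtype=float)
    scalar = r.ndim == 0
    r = np.atleast_1d(r)
    n = np.broadcast_to(np.atleast_1d(n), r.shape).astype(float)
    p = np.full(r.shape, np.nan)
    ok = np.isfinite(r) & (n >= 3)
    exact = ok & (np.abs(r) >= 1.0)
    p[exact] = 0.0
    mid = ok & ~exact
    if mid.any():
        t = r[mid] * np.sqrt((n[mid] - 2.0) / (1.0 - r[mid] ** 2))
        p[mid] = 2.0 * stats.t.sf(np.abs(t), n[mid] - 2.0)
    p = np.clip(p, 0.0, 1.0, out=p, where=np.isfinite(p))
    return float(p[0]) if scalar else p


def bh_adjust(p):
    """Benjamini-Hochberg step-up q-values; NaN entries stay NaN.

    Missing p-values are excluded from the family size m; q preserves the
    ordering of p and satisfies q >= p elementwise.
    """
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    m = int(ok.sum())
    if m == 0:
        return q
    pv = p[ok]
    order = np.argsort(pv, kind="mergesort")
    adj = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum(1.0, np.minimum.accumulate(adj[::-1])[::-1])
    qq = np.empty(m)
    qq[order] = adj
    q[ok] = qq
    return q
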