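"""Signature-based cell-type deconvolution of bulk expression.

Bulk expression is modeled as a linear (linear-scale, not log) mixture of
cell-type signature profiles: for each individual's bulk vector b over the
marker genes shared with the signature A, solve

    min_f || A f - b ||^2    s.t.  f >= 0,  sum(f) = 1.

The simplex constraint is enforced by solving non-negative least squares on
an augmented system (a heavily weighted all-ones row pinning the sum) and
renormalizing; the result satisfies the constraints to 1e-8. Inferred
abundances are then related to gene expression with bicor, the same robust
coefficient used everywhere else in the package.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .archive import DataError, ExpressionTensor
from .bicor import DEFAULT_MIN_N, bh_adjust, bicor, correlation_p

_SUM_WEIGHT = 1e6  # weight of the sum-to-one row in the augmented NNLS


def validate_signature(signature: pd.DataFrame) -> None:
    if signature.index.has_duplicates:
        dup = signature.index[signature.index.duplicated()][0]
        raise DataError(f"duplicate marker gene {dup!r} in signature")
    if (signature.to_numpy() < 0).any():
        raise DataError("signature expression must be non-negative")
    zero = signature.columns[(signature == 0).all(axis=0)]
    if len(zero):
        raise DataError(f"all-zero signature column(s): {list(zero)}")


def fit_proportions(
    signature: pd.DataFrame,
    bulk: pd.DataFrame,
    min_marker_ratio: float = 2.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Estimate cell-type proportions per individual from bulk expression.

    Parameters
    ----------
    signature:
        Marker gene x cell type non-negative reference expression.
    bulk:
        Gene x individual linear-scale expression; only the gene
        intersection with the signature is used, and it must exceed
        ``min_marker_ratio`` x the number of cell types.

    Returns
    -------
    (proportions, residuals):
        Individuals x cell types proportions (rows on the simplex) and the
        per-individual residual norm ||A f - b/c|| at the solution, where c
        is the estimated overall scale of that bulk column.
    """
    validate_signature(signature)
    shared = [g for g in signature.index if g in set(bulk.index)]
    k = signature.shape[1]
    if len(shared) < min_marker_ratio * k:
        raise DataError(
            f"only {len(shared)} marker genes shared with the bulk matrix; "
            f"need at least {min_marker_ratio:g}x the {k} cell types"
        )
    A = signature.loc[shared].to_numpy(dtype=float)
    scale = np.abs(A).max() or 1.0
    A_aug = np.vstack([A / scale, np.full((1, k), _SUM_WEIGHT)])
    props = np.empty((bulk.shape[1], k))
    resid = np.empty(bulk.shape[1])
    for j, ind in enumerate(bulk.columns):
        b = bulk[ind].reindex(shared).to_numpy(dtype=float)
        if not np.isfinite(b).all():
            props[j] = np.nan
            resid[j] = np.nan
            continue
        # scale ambiguity: estimate the bulk's overall scale with an
        # unconstrained NNLS, rescale, then pin the simplex constraint
        f_free, _ = nnls(A / scale, b / scale)
        c = f_free.sum()
        if c <= 0:
            props[j] = np.nan
            resid[j] = np.nan
            continue
        b_aug = np.concatenate([b / (c * scale), [_SUM_WEIGHT]])
        f, _ = nnls(A_aug, b_aug)
        total = f.sum()
        if total <= 0:
            props[j] = np.nan
            resid[j] = np.nan
            continue
        f = f / total
        props[j] = f
        resid[j] = float(np.linalg.norm(A @ f - b / c))
    out = pd.DataFrame(props, index=list(bulk.columns), columns=list(signature.columns))
    return out, pd.Series(resid, index=list(bulk.columns), name="residual")


def celltype_gene_correlation(
    proportions: pd.DataFrame,
    tensor: ExpressionTensor,
    tissue: str,
    gene: str,
    min_n: int = DEFAULT_MIN_N,
) -> pd.DataFrame:
    """bicor of each inferred cell-type abundance against a gene's expression.

    Rows: one per cell type with r, n, p and a BH q over the cell types.
    Constant (zero-variance) abundance columns yield an undefined, flagged
    row rather than an error.
    """
    expr = tensor.expression(tissue, gene)
    shared = [i for i in proportions.index if i in set(expr.index)]
    if len(shared) < min_n:
        raise DataError(
            f"only {len(shared)} individuals shared between proportions and "
            f"the expression archive; need >= {min_n}"
        )
    x = expr.reindex(shared).to_numpy(dtype=float)
    rows = []
    for ct in proportions.columns:
        y = proportions[ct].reindex(shared).to_numpy(dtype=float)
        finite = y[np.isfinite(y)]
        if finite.size and np.ptp(finite) == 0:
            rows.append(
                {"cell_type": ct, "bicor": np.nan, "n": int(np.isfinite(y).sum()),
                 "p": np.nan, "defined": False}
            )
            continue
        res = bicor(x, y, min_n=min_n)
        p = correlation_p(res.r, res.n_used) if res.defined else np.nan
        rows.append(
            {"cell_type": ct, "bicor": res.r, "n": res.n_used, "p": p,
             "defined": bool(res.defined)}
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out
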