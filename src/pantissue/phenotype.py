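"""Clinical-trait correlation for a gene-tissue expression vector.

Each trait in a trait table is correlated (bicor, pairwise-complete) against
one gene's expression across the shared individuals; traits are ranked by
significance and the top-k reported with a direction label. For inbred-panel
data a strain mode first averages individuals to strain means so that
inter-individual differences are compared at the strain level.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .archive import DataError, ExpressionTensor
from .bicor import DEFAULT_MIN_N, bh_adjust, bicor, correlation_p


def trait_correlation(
    tensor: ExpressionTensor,
    tissue: str,
    gene: str,
    traits: pd.DataFrame,
    top_k: int = 10,
    strain_map: pd.Series | None = None,
    min_n: int = DEFAULT_MIN_N,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlate a gene's expression against every trait.

    Parameters
    ----------
    traits:
        Individual (or strain) x trait numeric table; missing cells handled
        pairwise-complete per trait.
    strain_map:
        Optional individual -> strain labels. When given, expression is
        averaged to strain means and correlated against the trait table
        indexed by strain (inbred-panel mode).

    Returns
    -------
    (top, full): both sorted ascending by p with columns
    ``trait, bicor, n, p, q, direction``; ``top`` is the first ``top_k``
    rows of ``full``.
    """
    expr = tensor.expression(tissue, gene)
    if strain_map is not None:
        strains = strain_map.reindex(expr.index)
        expr = expr.groupby(strains).mean()
    shared = [i for i in expr.index if i in set(traits.index)]
    if len(shared) < min_n:
        raise DataError(
            f"only {len(shared)} IDs shared between expression and traits; "
            f"need >= {min_n}"
        )
    x = expr.reindex(shared).to_numpy(dtype=float)
    rows = []
    for trait in traits.columns:
        y = traits[trait].reindex(shared).to_numpy(dtype=float)
        res = bicor(x, y, min_n=min_n)
        if not res.defined:
            continue
        p = correlation_p(res.r, res.n_used)
        rows.append(
            {
                "trait": trait,
                "bicor": res.r,
                "n": res.n_used,
                "p": float(p),
                "direction": "positive" if res.r >= 0 else "negative",
            }
        )
    if not rows:
        raise DataError("no trait had enough complete pairs to correlate")
    full = pd.DataFrame(rows)
    full["q"] = bh_adjust(full["p"].to_numpy())
    full = full.sort_values(["p", "trait"], kind="mergesort").reset_index(drop=True)
    full = full[["trait", "bicor", "n", "p", "q", "direction"]]
    return full.head(top_k).copy(), full
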