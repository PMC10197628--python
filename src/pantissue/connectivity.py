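"""Pathway-level cross-tissue correlation structure and its null models.

For a pathway (gene set), every gene-gene bicor correlation among pathway
members is computed within and between tissues. A tissue x tissue grid then
counts either significant correlation *pairs* or *genes* touched by at least
one significant correlation, at one or more p (or q) thresholds. Observed
pathway connectivity is judged against size-matched random-gene null draws,
and a sparsity diagnostic relates per-tissue missing-data burden to the
significant-gene counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .archive import DataError, ExpressionTensor
from .bicor import DEFAULT_MIN_N, bh_adjust, bicor, bicor_matrix, correlation_p


@dataclass
class ConnectivityMatrix:
    """Tissue x tissue grid of significant-correlation counts for one pathway."""

    pathway: str
    threshold: float
    stat: str                      # "p" or "q"
    mode: str                      # "pairs" or "genes"
    grid: pd.DataFrame             # tissue x tissue counts (NaN where omitted)
    n_pathway_genes: int
    include_within: bool

    def normalized(self) -> pd.DataFrame:
        """Counts divided by the pathway gene count."""
        return self.grid / self.n_pathway_genes

    def total_cross_tissue(self) -> float:
        """Sum over unordered distinct tissue pairs (off-diagonal, once)."""
        g = self.grid.to_numpy(dtype=float)
        iu = np.triu_indices(g.shape[0], k=1)
        return float(np.nansum(g[iu]))


def _pair_significance(
    tensor: ExpressionTensor,
    genes_by_tissue: dict[str, list[str]],
    min_n: int,
) -> dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """bicor r/p matrices for every unordered tissue pair of pathway genes.

    Returns {(t1, t2): (r, p, within_pair_mask)} with t1 <= t2 in tissue
    order; for t1 == t2 the matrices are gene x gene within the tissue and
    self-pairs sit on the diagonal.
    """
    tissues = [t for t, g in genes_by_tissue.items() if g]
    mats = {
        t: tensor.matrix(t).loc[genes_by_tissue[t]].to_numpy(dtype=float)
        for t in tissues
    }
    out = {}
    for i, t1 in enumerate(tissues):
        for t2 in tissues[i:]:
            r, n = bicor_matrix(mats[t1], mats[t2], min_n=min_n)
            p = correlation_p(r, n)
            out[(t1, t2)] = (r, p, None)
    return out


def cross_tissue_counts(
    tensor: ExpressionTensor,
    pathway_genes: list[str] | set[str],
    thresholds: tuple[float, ...] = (1e-3, 1e-6),
    mode: str = "pairs",
    stat: str = "p",
    include_within: bool = False,
    pathway_name: str = "pathway",
    min_n: int = DEFAULT_MIN_N,
) -> list[ConnectivityMatrix]:
    """Count significant pathway-gene correlations for every tissue pair.

    ``mode="pairs"`` counts significant gene-gene correlations (the heatmap
    view, within-tissue diagonal omitted unless ``include_within``);
    ``mode="genes"`` counts distinct (tissue, gene) nodes touched by at
    least one significant correlation in the cell. Within a tissue,
    self-correlations (a gene with itself) are excluded and unordered pairs
    counted once; across tissues all gene pairs count, including the same
    gene ID in both tissues. ``stat="q"`` applies a BH family over all
    correlations in the grid before thresholding.
    """
    if mode not in ("pairs", "genes"):
        raise ValueError("mode must be 'pairs' or 'genes'")
    if stat not in ("p", "q"):
        raise ValueError("stat must be 'p' or 'q'")
    pathway_genes = list(dict.fromkeys(pathway_genes))
    genes_by_tissue = {
        t: [g for g in pathway_genes if g in set(tensor.gene_index(t))]
        for t in tensor.tissues
    }
    if not any(genes_by_tissue.values()):
        raise DataError("pathway genes intersect no tissue's gene index")
    tissues = [t for t, g in genes_by_tissue.items() if g]
    sig = _pair_significance(tensor, genes_by_tissue, min_n)

    if stat == "q":
        # one family over every correlation in the grid (within pairs once)
        flat, keys = [], []
        for (t1, t2), (r, p, _) in sig.items():
            if t1 == t2:
                iu = np.triu_indices(p.shape[0], k=1)
                flat.append(p[iu])
            else:
                flat.append(p.ravel())
            keys.append((t1, t2))
        q_all = bh_adjust(np.concatenate(flat))
        off = 0
        for (t1, t2), chunk in zip(keys, flat):
            qc = q_all[off : off + len(chunk)]
            off += len(chunk)
            r, p, _ = sig[(t1, t2)]
            qm = np.full_like(p, np.nan)
            if t1 == t2:
                iu = np.triu_indices(p.shape[0], k=1)
                qm[iu] = qc
                qm[(iu[1], iu[0])] = qc
            else:
                qm = qc.reshape(p.shape)
            sig[(t1, t2)] = (r, qm, None)

    results = []
    for alpha in thresholds:
        grid = pd.DataFrame(np.nan, index=tissues, columns=tissues, dtype=float)
        for (t1, t2), (r, p, _) in sig.items():
            passing = np.isfinite(p) & (p < alpha)
            if t1 == t2:
                np.fill_diagonal(passing, False)
                if not include_within:
                    continue
                if mode == "pairs":
                    count = int(passing.sum()) // 2
                else:
                    count = int((passing.any(axis=1)).sum())
                grid.loc[t1, t1] = count
            else:
                if mode == "pairs":
                    count = int(passing.sum())
                else:
                    count = int(passing.any(axis=1).sum() + passing.any(axis=0).sum())
                grid.loc[t1, t2] = count
                grid.loc[t2, t1] = count
        results.append(
            ConnectivityMatrix(
                pathway=pathway_name,
                threshold=alpha,
                stat=stat,
                mode=mode,
                grid=grid,
                n_pathway_genes=len(pathway_genes),
                include_within=include_within,
            )
        )
    return results


@dataclass
class TissueRanking:
    """Tissues ordered by their count of significantly correlating genes."""

    pathway: str
    threshold: float
    counts: pd.Series  # tissue -> gene count, sorted descending

    @property
    def order(self) -> list[str]:
        return list(self.counts.index)


def tissue_ranking(
    tensor: ExpressionTensor,
    pathway_genes: list[str] | set[str],
    threshold: float = 0.01,
    pathway_name: str = "pathway",
    min_n: int = DEFAULT_MIN_N,
) -> TissueRanking:
    """Rank tissues by genes with >= 1 significant pathway correlation.

    A gene in tissue t counts if any of its correlations to pathway genes —
    within t or to any other tissue — passes the Student p threshold.
    """
    pathway_genes = list(dict.fromkeys(pathway_genes))
    genes_by_tissue = {
        t: [g for g in pathway_genes if g in set(tensor.gene_index(t))]
        for t in tensor.tissues
    }
    if not any(genes_by_tissue.values()):
        raise DataError("pathway genes intersect no tissue's gene index")
    tissues = [t for t, g in genes_by_tissue.items() if g]
    sig = _pair_significance(tensor, genes_by_tissue, min_n)
    hit: dict[str, np.ndarray] = {
        t: np.zeros(len(genes_by_tissue[t]), dtype=bool) for t in tissues
    }
    for (t1, t2), (r, p, _) in sig.items():
        passing = np.isfinite(p) & (p < threshold)
        if t1 == t2:
            np.fill_diagonal(passing, False)
            hit[t1] |= passing.any(axis=1)
        else:
            hit[t1] |= passing.any(axis=1)
            hit[t2] |= passing.any(axis=0)
    counts = pd.Series({t: int(h.sum()) for t, h in hit.items()}, name="genes")
    counts = counts.sort_values(ascending=False, kind="mergesort")
    return TissueRanking(pathway=pathway_name, threshold=threshold, counts=counts)


def random_gene_null(
    tensor: ExpressionTensor,
    size: int,
    n_draws: int = 100,
    seed: int | None = None,
    thresholds: tuple[float, ...] = (1e-3,),
    mode: str = "pairs",
    min_n: int = DEFAULT_MIN_N,
) -> pd.DataFrame:
    """Size-matched random-gene null for cross-tissue connectivity.

    Each draw samples ``size`` genes per tissue uniformly without
    replacement and recomputes the connectivity counts identically to
    :func:`cross_tissue_counts`. Returns one row per (draw, threshold) with
    the total cross-tissue count; quantiles are easy to take downstream.
    """
    rng = np.random.default_rng(seed)
    for t in tensor.tissues:
        if size > len(tensor.gene_index(t)):
            raise DataError(
                f"tissue {t!r} has {len(tensor.gene_index(t))} genes, "
                f"cannot sample {size}"
            )
    rows = []
    for draw in range(n_draws):
        mats = {}
        for t in tensor.tissues:
            idx = rng.choice(len(tensor.gene_index(t)), size=size, replace=False)
            mats[t] = tensor.matrix(t).iloc[np.sort(idx)].to_numpy(dtype=float)
        tissues = list(mats)
        per_alpha = {a: 0.0 for a in thresholds}
        for i, t1 in enumerate(tissues):
            for t2 in tissues[i + 1 :]:
                r, n = bicor_matrix(mats[t1], mats[t2], min_n=min_n)
                p = correlation_p(r, n)
                for a in thresholds:
                    passing = np.isfinite(p) & (p < a)
                    if mode == "pairs":
                        per_alpha[a] += int(passing.sum())
                    else:
                        per_alpha[a] += int(
                            passing.any(axis=1).sum() + passing.any(axis=0).sum()
                        )
        for a in thresholds:
            rows.append({"draw": draw, "threshold": a, "total_cross_tissue": per_alpha[a]})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SparsityResult:
    r: float
    p: float
    n: int
    defined: bool
    tissues: tuple[str, ...]


def sparsity_diagnostic(
    tensor: ExpressionTensor,
    count_table: pd.DataFrame,
    tertile: str = "bottom",
    order_by: str | None = None,
) -> SparsityResult:
    """Correlate per-tissue missing-data burden with significant-gene counts.

    ``count_table`` is tissue x pathway significant-gene counts (e.g. one
    :func:`tissue_ranking` column per pathway). Tissues are ordered by the
    ``order_by`` pathway's counts (default: row sums), split into tertiles,
    and within the requested tertile each (tissue, pathway) count is paired
    with that tissue's mean NA-entries-per-individual burden; the pairs are
    then correlated with bicor. Zero variance in either vector yields a
    flagged undefined result instead of an exception.
    """
    if tertile not in ("top", "middle", "bottom"):
        raise ValueError("tertile must be 'top', 'middle' or 'bottom'")
    key = (
        count_table[order_by]
        if order_by is not None
        else count_table.sum(axis=1)
    )
    order = list(key.sort_values(ascending=False, kind="mergesort").index)
    k = len(order)
    cut = max(k // 3, 1)
    bins = {"top": order[:cut], "middle": order[cut : k - cut], "bottom": order[k - cut :]}
    chosen = bins[tertile]
    if len(chosen) < 4:
        raise DataError(
            f"tertile {tertile!r} holds {len(chosen)} tissues; need >= 4"
        )
    burden = tensor.missing_burden()
    xs, ys = [], []
    for t in chosen:
        for pw in count_table.columns:
            xs.append(float(burden.get(t, np.nan)))
            ys.append(float(count_table.loc[t, pw]))
    x = np.asarray(xs)
    y = np.asarray(ys)
    if np.nanstd(x) == 0 or np.nanstd(y) == 0:
        return SparsityResult(np.nan, np.nan, len(x), False, tuple(chosen))
    res = bicor(x, y, min_n=4)
    if not res.defined:
        return SparsityResult(np.nan, np.nan, res.n_used, False, tuple(chosen))
    p = correlation_p(res.r, res.n_used)
    return SparsityResult(res.r, float(p), res.n_used, True, tuple(chosen))
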