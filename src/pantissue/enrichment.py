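"""Coefficient-weighted preranked gene-set enrichment and overrepresentation.

Two complementary tests over a seed-gene correlation table:

* ``gsea_preranked`` — a weighted Kolmogorov-Smirnov running-sum statistic
  over the gene list ranked by bicor coefficient (the coefficient is the
  rank weight). Significance comes from gene-label permutations with
  sign-matched counting; NES normalizes the enrichment score by the mean
  |ES| of same-sign permutation scores.
* ``ora`` — upper-tail hypergeometric overrepresentation of a selected gene
  list (e.g. the top 500 correlates in a tissue) against a background
  universe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .archive import CorrelationTable, DataError, GeneSetCollection
from .bicor import bh_adjust

DEFAULT_MIN_SET_SIZE = 5
DEFAULT_MAX_SET_SIZE = 2000


def rank_genes(table: CorrelationTable, tissue: str) -> pd.DataFrame:
    """Genes of one tissue ordered descending by bicor; ties by gene ID.

    Returns a DataFrame with columns ``gene`` and ``weight`` (the signed
    coefficient), the input to :func:`gsea_preranked`.
    """
    if tissue not in set(table.table["tissue"]):
        raise DataError(f"tissue {tissue!r} absent from the correlation table")
    sub = table.for_tissue(tissue)[["gene", "bicor"]].rename(columns={"bicor": "weight"})
    sub = sub.sort_values(["weight", "gene"], ascending=[False, True], kind="mergesort")
    return sub.reset_index(drop=True)


def _running_sum_extremum(
    pos: np.ndarray, weights: np.ndarray, L: int
) -> tuple[float, int]:
    """ES and extremum hit index for sorted hit positions in a list of L.

    ``pos`` are 0-based sorted hit positions, ``weights`` the |rank weights|
    at those positions. The running sum gains ``|w|/sum|w|`` at each hit and
    loses ``1/(L-K)`` per miss; the ES is the extremum of largest magnitude
    (ties broken toward the positive extremum). If all hit weights are zero
    the hit increments degrade to uniform ``1/K``.
    """
    K = len(pos)
    w = np.abs(weights)
    tot = w.sum()
    inc = w / tot if tot > 0 else np.full(K, 1.0 / K)
    miss = 1.0 / (L - K)
    cum_inc = np.cumsum(inc)
    j = np.arange(K)
    after = cum_inc - (pos - j) * miss       # value just after hit j
    before = after - inc                      # value just before hit j
    i_max = int(np.argmax(after))
    i_min = int(np.argmin(before))
    es_max = float(after[i_max])
    es_min = float(before[i_min])
    # ties broken toward the positive extremum; small tolerance so that
    # summation-order noise cannot flip the sign on an exact tie
    if es_max >= -es_min - 1e-12:
        return es_max, i_max
    return es_min, i_min


@dataclass(frozen=True)
class EnrichmentResult:
    name: str
    size: int
    es: float
    nes: float
    p: float
    q: float
    leading_edge: tuple[str, ...]

    @property
    def direction(self) -> str:
        return "activated" if self.es > 0 else "suppressed"


def gsea_preranked(
    ranked: pd.DataFrame,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    seed: int | None = None,
    min_set_size: int = DEFAULT_MIN_SET_SIZE,
    max_set_size: int = DEFAULT_MAX_SET_SIZE,
) -> tuple[pd.DataFrame, list[str]]:
    """Preranked GSEA over a (gene, weight) list for every eligible set.

    Permutations shuffle gene labels: under the null a set of size K
    occupies K uniformly random positions of the ranked list, inheriting the
    list's weights at those positions. The permutation p is sign-matched
    with +1 smoothing:

        p = (1 + #{same-sign perms with |ES*| >= |ES|}) / (1 + #same-sign)

    Returns (results frame sorted by p, names of skipped sets). Sets whose
    universe overlap is below ``min_set_size``, above ``max_set_size``, or
    covers the whole list are skipped and reported untested.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    genes = list(ranked["gene"])
    weights = ranked["weight"].to_numpy(dtype=float)
    L = len(genes)
    if L < 2:
        raise DataError("ranked list must contain at least 2 genes")
    index = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    rows = []
    skipped: list[str] = []
    for gs in sets:
        pos = np.array(sorted(index[g] for g in gs.genes if g in index))
        K = len(pos)
        if K < min_set_size or K > max_set_size or K >= L:
            skipped.append(gs.name)
            continue
        es, i_ext = _running_sum_extremum(pos, weights[pos], L)
        # permutation null: K uniform positions per draw, weights follow rank
        null = np.empty(n_perm)
        for b in range(n_perm):
            ppos = np.sort(rng.choice(L, size=K, replace=False))
            null[b], _ = _running_sum_extremum(ppos, weights[ppos], L)
        same = null * np.sign(es) > 0 if es != 0 else np.ones(n_perm, bool)
        n_same = int(same.sum())
        # tolerance: permutations whose |ES*| ties |ES| to floating noise count
        p = (1 + int((np.abs(null[same]) >= abs(es) - 1e-12).sum())) / (1 + n_same)
        mean_abs = float(np.abs(null[same]).mean()) if n_same else np.nan
        nes = es / mean_abs if n_same and mean_abs > 0 else np.nan
        if es >= 0:
            le = tuple(genes[i] for i in pos[: i_ext + 1])
        else:
            le = tuple(genes[i] for i in pos[i_ext:])
        rows.append(
            {
                "name": gs.name,
                "size": K,
                "es": es,
                "nes": nes,
                "p": p,
                "leading_edge": le,
                "direction": "activated" if es > 0 else "suppressed",
            }
        )
    out = pd.DataFrame(
        rows, columns=["name", "size", "es", "nes", "p", "leading_edge", "direction"]
    )
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
        out = out.sort_values("p", kind="mergesort").reset_index(drop=True)
    else:
        out["q"] = pd.Series(dtype=float)
    return out, skipped


def ora(
    selected: list[str] | set[str],
    background: list[str] | set[str],
    sets: GeneSetCollection,
) -> pd.DataFrame:
    """Hypergeometric overrepresentation of ``selected`` within each set.

    ``selected`` must be a subset of ``background``. For each set with at
    least one member in the background, p = P(X >= k) where X is
    hypergeometric with population N = |background|, successes K = |set in
    background| and draws n = |selected|.
    """
    bg = set(background)
    sel = set(selected)
    if not sel <= bg:
        missing = sorted(sel - bg)[:5]
        raise DataError(f"selected genes not in background, e.g. {missing}")
    N, n = len(bg), len(sel)
    rows = []
    for gs in sets:
        members = set(gs.genes) & bg
        K = len(members)
        if K == 0:
            continue
        overlap = sorted(members & sel)
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "name": gs.name,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "p": min(p, 1.0),
                "genes": ",".join(overlap),
            }
        )
    out = pd.DataFrame(rows, columns=["name", "k", "n", "K", "N", "p", "genes"])
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
        out = out.sort_values("p", kind="mergesort").reset_index(drop=True)
    else:
        out["q"] = pd.Series(dtype=float)
    return out


def top_correlates(
    table: CorrelationTable, tissue: str, top_n: int = 500
) -> tuple[list[str], list[str]]:
    """(selected, background) for ORA: top-|r| genes of a tissue vs all tested.

    Mirrors the 'top 500 genes in a tissue' selection; the background is
    every gene tested in that tissue.
    """
    sub = table.for_tissue(tissue)
    background = list(sub["gene"])
    ranked = sub.reindex(sub["bicor"].abs().sort_values(ascending=False, kind="mergesort").index)
    return list(ranked["gene"].head(top_n)), background
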