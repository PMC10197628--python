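"""Seed-gene pan-tissue queries and significance binning.

A seed-gene query correlates one gene's expression in one tissue against
every other gene-tissue combination over the same individuals, returning a
table of bicor coefficients with Student p-values and a single global BH
family of q-values. Tissue binning then partitions the significant rows by
tissue at fixed q thresholds — the pie-chart view of where a gene's
inter-individual covariation concentrates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .archive import CorrelationTable, DataError, ExpressionTensor
from .bicor import DEFAULT_MIN_N, bh_adjust, bicor_matrix, correlation_p

DEFAULT_Q_LEVELS = (0.1, 0.01, 0.001)


def seed_gene_query(
    tensor: ExpressionTensor,
    seed_tissue: str,
    seed_gene: str,
    min_n: int = DEFAULT_MIN_N,
) -> CorrelationTable:
    """Correlate a seed gene against all other gene-tissue combinations.

    Every gene in every tissue is a candidate row, including the seed gene's
    own ID in *other* tissues; only the identical (seed tissue, seed gene)
    pair is excluded. Rows with fewer than ``min_n`` complete pairs, or an
    undefined coefficient, are dropped before q-values are computed, so the
    BH family is exactly the set of returned rows.
    """
    seed = tensor.expression(seed_tissue, seed_gene).to_numpy(dtype=float)
    frames = []
    for tissue in tensor.tissues:
        mat = tensor.matrix(tissue)
        if mat.shape[0] == 0:
            continue
        r, n = bicor_matrix(seed[None, :], mat.to_numpy(dtype=float), min_n=min_n)
        frames.append(
            pd.DataFrame(
                {
                    "tissue": tissue,
                    "gene": list(mat.index),
                    "bicor": r[0],
                    "n": n[0],
                }
            )
        )
    tab = pd.concat(frames, ignore_index=True)
    tab = tab[~((tab["tissue"] == seed_tissue) & (tab["gene"] == seed_gene))]
    tab = tab[np.isfinite(tab["bicor"]) & (tab["n"] >= min_n)].reset_index(drop=True)
    tab["p"] = correlation_p(tab["bicor"].to_numpy(), tab["n"].to_numpy())
    tab = tab[np.isfinite(tab["p"])].reset_index(drop=True)
    tab["q"] = bh_adjust(tab["p"].to_numpy())
    return CorrelationTable(seed_tissue, seed_gene, tab)


@dataclass
class TissueBinning:
    """Per-q-threshold counts and fractions of significant rows by tissue."""

    counts: dict[float, pd.Series]
    fractions: dict[float, pd.Series | None] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for level, cnt in self.counts.items():
            frac = self.fractions.get(level)
            for tissue in cnt.index:
                rows.append(
                    {
                        "q_level": level,
                        "tissue": tissue,
                        "count": int(cnt[tissue]),
                        "fraction": float(frac[tissue]) if frac is not None else np.nan,
                    }
                )
        return pd.DataFrame(rows)


def tissue_binning(
    table: CorrelationTable, levels: tuple[float, ...] = DEFAULT_Q_LEVELS
) -> TissueBinning:
    """Count significant correlates per tissue at each q threshold.

    Fractions are normalized within each level; a level with zero passing
    rows gets ``None`` fractions (undefined, flagged rather than NaN-filled).
    """
    tab = table.table
    tissues = sorted(tab["tissue"].unique())
    counts: dict[float, pd.Series] = {}
    fractions: dict[float, pd.Series | None] = {}
    for level in levels:
        passing = tab[tab["q"] < level]
        cnt = passing.groupby("tissue").size().reindex(tissues, fill_value=0)
        counts[level] = cnt
        total = int(cnt.sum())
        fractions[level] = cnt / total if total > 0 else None
    return TissueBinning(counts=counts, fractions=fractions)


def group_summary(
    tensor: ExpressionTensor,
    tissue: str,
    gene: str,
    metadata: pd.DataFrame,
    grouping: str,
) -> pd.DataFrame:
    """Per-group expression summary (n, mean, sd) with a rank-sum test.

    ``metadata`` is indexed by individual with a label column named by
    ``grouping`` (e.g. ``sex`` or ``age_group``). A two-sided Wilcoxon
    rank-sum (Mann-Whitney) p-value is attached only when exactly two groups
    carry data; with one group the summary alone is returned.
    """
    if grouping not in metadata.columns:
        raise DataError(f"metadata has no column {grouping!r}")
    expr = tensor.expression(tissue, gene)
    labels = metadata[grouping].reindex(expr.index)
    df = pd.DataFrame({"value": expr, "group": labels}).dropna()
    if df.empty:
        raise DataError("no individuals with both expression and a group label")
    rows = []
    for label, sub in sorted(df.groupby("group"), key=lambda kv: str(kv[0])):
        rows.append(
            {
                "group": label,
                "n": len(sub),
                "mean": float(sub["value"].mean()),
                "sd": float(sub["value"].std(ddof=1)) if len(sub) > 1 else np.nan,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["rank_sum_p"] = None
    if len(rows) == 2:
        a = df[df["group"] == rows[0]["group"]]["value"]
        b = df[df["group"] == rows[1]["group"]]["value"]
        out.attrs["rank_sum_p"] = float(
            stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        )
    return out
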