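"""Domain containers and TSV/GMT I/O for multi-tissue expression archives.

The central container is :class:`ExpressionTensor`: one gene x individual
matrix per tissue, with every matrix aligned on a single shared, ordered
individual index. Individuals absent from a tissue are kept as explicit
``NaN`` columns (GTEx-style block missingness), never dropped, so that
pairwise-complete correlation counts stay meaningful.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NA_TOKEN = "NA"


class DataError(ValueError):
    """Malformed or inconsistent input data."""


# ---------------------------------------------------------------------------
# ExpressionTensor
# ---------------------------------------------------------------------------


@dataclass
class ExpressionTensor:
    """Per-tissue gene x individual expression aligned on shared individuals.

    Parameters
    ----------
    individuals:
        Ordered shared individual identifiers (columns of every matrix).
    matrices:
        Mapping tissue name -> DataFrame (genes x individuals). Missing
        measurements are ``NaN``; columns must equal ``individuals`` exactly.
    """

    individuals: list[str]
    matrices: dict[str, pd.DataFrame]

    def __post_init__(self) -> None:
        if len(self.matrices) < 1:
            raise DataError("an expression tensor needs at least one tissue")
        if len(self.individuals) < 2:
            raise DataError("an expression tensor needs at least two individuals")
        if len(set(self.individuals)) != len(self.individuals):
            raise DataError("duplicate individual identifiers")
        for tissue, mat in self.matrices.items():
            if list(mat.columns) != list(self.individuals):
                raise DataError(
                    f"tissue {tissue!r}: columns do not match the shared "
                    "individual index"
                )
            if mat.index.has_duplicates:
                dup = mat.index[mat.index.duplicated()][0]
                raise DataError(f"tissue {tissue!r}: duplicate gene ID {dup!r}")

    @property
    def tissues(self) -> list[str]:
        return list(self.matrices)

    def matrix(self, tissue: str) -> pd.DataFrame:
        try:
            return self.matrices[tissue]
        except KeyError:
            raise DataError(
                f"unknown tissue {tissue!r}; available: {', '.join(self.tissues)}"
            ) from None

    def gene_index(self, tissue: str) -> list[str]:
        return list(self.matrix(tissue).index)

    def expression(self, tissue: str, gene: str) -> pd.Series:
        """One gene's expression over the shared individuals."""
        mat = self.matrix(tissue)
        if gene not in mat.index:
            import difflib

            near = difflib.get_close_matches(gene, mat.index, n=5)
            hint = f"; nearest matches: {', '.join(near)}" if near else ""
            raise DataError(f"gene {gene!r} not found in tissue {tissue!r}{hint}")
        return mat.loc[gene]

    def subset_individuals(self, keep: Sequence[str]) -> "ExpressionTensor":
        """Restrict to a subset of individuals (e.g. one sex or diet arm)."""
        keep = [i for i in self.individuals if i in set(keep)]
        if len(keep) < 2:
            raise DataError("fewer than two individuals left after subsetting")
        return ExpressionTensor(
            individuals=keep,
            matrices={t: m[keep] for t, m in self.matrices.items()},
        )

    def missing_burden(self) -> pd.Series:
        """Mean number of missing entries per individual, per tissue."""
        out = {
            t: float(m.isna().to_numpy().sum()) / len(self.individuals)
            for t, m in self.matrices.items()
        }
        return pd.Series(out, name="na_per_individual")


# ---------------------------------------------------------------------------
# Gene sets, traits, metadata
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: tuple[str, ...]


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-derived); member lists de-duplicated, ordered."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def add(self, name: str, description: str, genes: Iterable[str]) -> None:
        if name in self.sets:
            raise DataError(f"duplicate gene-set name {name!r}")
        uniq = list(dict.fromkeys(genes))
        if not uniq:
            raise DataError(f"gene set {name!r} has no members")
        self.sets[name] = GeneSet(name, description, tuple(uniq))

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets.values())


@dataclass(frozen=True)
class CorrelationTable:
    """Result of one seed-gene query.

    ``table`` holds one row per correlated gene-tissue combination with
    columns ``tissue, gene, bicor, n, p, q`` — the seed pair itself is never
    a row, and every row has a defined p (rows with too few complete pairs
    are dropped before the BH family is formed).
    """

    seed_tissue: str
    seed_gene: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        seed_rows = (t["tissue"] == self.seed_tissue) & (t["gene"] == self.seed_gene)
        if seed_rows.any():
            raise DataError("correlation table contains the seed pair itself")

    def for_tissue(self, tissue: str) -> pd.DataFrame:
        return self.table[self.table["tissue"] == tissue]

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN)

    @staticmethod
    def from_tsv(path: str | Path, seed_tissue: str, seed_gene: str) -> "CorrelationTable":
        tab = pd.read_csv(path, sep="\t", na_values=[NA_TOKEN], keep_default_na=False)
        return CorrelationTable(seed_tissue, seed_gene, tab)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _read_matrix_tsv(path: str | Path, tissue: str) -> pd.DataFrame:
    path = Path(path)
    if path.stat().st_size == 0:
        raise DataError(f"tissue {tissue!r}: file {path} is empty")
    mat = pd.read_csv(
        path, sep="\t", index_col=0, na_values=[NA_TOKEN], keep_default_na=False
    )
    if mat.shape[0] == 0 or mat.shape[1] == 0:
        raise DataError(f"tissue {tissue!r}: file {path} has no data")
    mat.index = mat.index.astype(str).str.strip()
    mat.columns = mat.columns.astype(str).str.strip()
    if mat.index.has_duplicates:
        dup = mat.index[mat.index.duplicated()][0]
        raise DataError(f"tissue {tissue!r}: duplicate gene ID {dup!r} in {path}")
    return mat.astype(float)


def read_expression_archive(paths: Mapping[str, str | Path]) -> ExpressionTensor:
    """Read per-tissue TSV matrices and align them on the individual union.

    Each file: tab-delimited, first column gene IDs, header row individual
    IDs, ``NA`` for missing. Individuals are matched by exact string after
    whitespace trimming; the tensor's individual index is the union over all
    tissues in first-appearance order, with absent individuals held as NaN
    columns.
    """
    if not paths:
        raise DataError("no tissue files given")
    raw = {t: _read_matrix_tsv(p, t) for t, p in paths.items()}
    individuals: list[str] = []
    seen: set[str] = set()
    for mat in raw.values():
        for ind in mat.columns:
            if ind not in seen:
                seen.add(ind)
                individuals.append(ind)
    matrices = {t: m.reindex(columns=individuals) for t, m in raw.items()}
    return ExpressionTensor(individuals=individuals, matrices=matrices)


def write_expression_archive(tensor: ExpressionTensor, directory: str | Path) -> dict[str, Path]:
    """Write one TSV per tissue plus a JSON manifest; returns the path map."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for tissue, mat in tensor.matrices.items():
        p = directory / f"{tissue}.tsv"
        mat.to_csv(p, sep="\t", na_rep=NA_TOKEN)
        paths[tissue] = p
    manifest = {
        "tissues": {t: p.name for t, p in paths.items()},
        "individuals": tensor.individuals,
    }
    (directory / "archive.json").write_text(json.dumps(manifest, indent=1))
    return paths


def read_archive_directory(directory: str | Path) -> ExpressionTensor:
    """Read an archive written by :func:`write_expression_archive`."""
    directory = Path(directory)
    manifest = json.loads((directory / "archive.json").read_text())
    paths = {t: directory / name for t, name in manifest["tissues"].items()}
    return read_expression_archive(paths)


def filter_detected_genes(tensor: ExpressionTensor) -> ExpressionTensor:
    """Keep genes whose every *non-missing* value is strictly positive.

    Mirrors the count-detection rule used for population archives: a single
    zero anywhere disqualifies the gene in that tissue; missing measurements
    do not. Idempotent. A tissue left without genes is retained empty with a
    warning.
    """
    matrices = {}
    for tissue, mat in tensor.matrices.items():
        vals = mat.to_numpy()
        ok = np.nansum(vals <= 0, axis=1) == 0
        kept = mat.loc[ok]
        if kept.shape[0] == 0:
            warnings.warn(
                f"tissue {tissue!r}: no genes pass the detection filter",
                stacklevel=2,
            )
        matrices[tissue] = kept
    return ExpressionTensor(individuals=list(tensor.individuals), matrices=matrices)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, name<TAB>description<TAB>genes..."""
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, needs >= 3"
                )
            name, desc, *genes = fields
            coll.add(name.strip(), desc, [g.strip() for g in genes if g.strip()])
    return coll


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in coll:
            fh.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")


def read_trait_table(path: str | Path) -> pd.DataFrame:
    """Tab-delimited individual/strain x trait table; non-numeric cells -> NaN.

    Returns a DataFrame indexed by ID with one numeric column per trait.
    """
    tab = pd.read_csv(
        path, sep="\t", index_col=0, na_values=[NA_TOKEN], keep_default_na=False
    )
    tab.index = tab.index.astype(str).str.strip()
    if tab.columns.has_duplicates:
        dup = tab.columns[tab.columns.duplicated()][0]
        raise DataError(f"duplicate trait name {dup!r} in {path}")
    out = {}
    for col in tab.columns:
        coerced = pd.to_numeric(tab[col], errors="coerce")
        bad = coerced.isna() & tab[col].notna()
        if bad.any():
            logger.warning(
                "trait %r: %d non-numeric cell(s) treated as missing",
                col,
                int(bad.sum()),
            )
        out[col] = coerced
    return pd.DataFrame(out, index=tab.index)


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Tab-delimited per-individual labels (sex, age_group, diet...)."""
    tab = pd.read_csv(
        path, sep="\t", index_col=0, na_values=[NA_TOKEN], keep_default_na=False, dtype=str
    )
    tab.index = tab.index.astype(str).str.strip()
    if tab.index.has_duplicates:
        dup = tab.index[tab.index.duplicated()][0]
        raise DataError(f"duplicate individual {dup!r} in metadata {path}")
    return tab
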