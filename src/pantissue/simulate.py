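"""Synthetic multi-tissue expression archives with known ground truth.

The generator emulates the statistical shape of a shared-individual
multi-tissue population archive: several tissues measured on the same
individuals, block missingness (whole donors absent from a tissue), sparse
gross outliers, one or more planted cross-tissue gene modules driven by a
latent factor, a planted co-regulated pathway spanning tissues, cell-type
mixtures built from a signature matrix, and clinical traits linked to
specific gene-tissue pairs.

Planted correlation uses the latent-factor construction

    x = sqrt(rho) * z + sqrt(1 - rho) * eps,

which gives an exact population correlation of rho between any two
module members (and between a member and the seed) at O(genes) cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .archive import DataError, ExpressionTensor

# Default study conditions: a GTEx-scale slice — hundreds of individuals,
# several metabolic tissues, ~10^3 genes per tissue for desk-scale runs.
DEFAULT_N_INDIVIDUALS = 300
DEFAULT_N_GENES = 1000
DEFAULT_TISSUES = ("adipose", "liver", "muscle", "heart", "intestine")
DEFAULT_RHO = 0.8
DEFAULT_MODULE_SIZE = 50
DEFAULT_NOISE_SD = 1.0
DEFAULT_OUTLIER_KAPPA = 8.0  # beyond the 9-MAD biweight window
DEFAULT_MALE_FRACTION = 210 / 310  # self-reported sex split of the human archive


@dataclass(frozen=True)
class TissueSpec:
    name: str
    n_background_genes: int = DEFAULT_N_GENES
    missing_individual_fraction: float = 0.0


@dataclass(frozen=True)
class PlantedSignal:
    """A seed gene whose latent factor also drives a target-tissue module."""

    seed_tissue: str
    seed_gene: str
    target_tissue: str
    module_size: int = DEFAULT_MODULE_SIZE
    rho: float = DEFAULT_RHO


@dataclass(frozen=True)
class PlantedPathway:
    """A named gene set co-regulated across tissues by one latent factor."""

    name: str
    genes_per_tissue: int
    rho: float
    tissues: tuple[str, ...] = ()  # empty = all tissues


@dataclass(frozen=True)
class OutlierSpec:
    fraction: float = 0.0
    kappa: float = DEFAULT_OUTLIER_KAPPA


@dataclass(frozen=True)
class SignatureSpec:
    n_marker_genes: int = 300
    n_cell_types: int = 4


@dataclass(frozen=True)
class TraitLink:
    trait: str
    tissue: str
    gene: str
    beta: float


@dataclass(frozen=True)
class TraitSpec:
    links: tuple[TraitLink, ...] = ()
    n_noise_traits: int = 10


@dataclass
class SimulationConfig:
    n_individuals: int = DEFAULT_N_INDIVIDUALS
    tissues: tuple[TissueSpec, ...] = tuple(TissueSpec(t) for t in DEFAULT_TISSUES)
    signals: tuple[PlantedSignal, ...] = ()
    pathway: PlantedPathway | None = None
    outliers: OutlierSpec = OutlierSpec()
    noise_sd: float = DEFAULT_NOISE_SD
    signature: SignatureSpec | None = None
    traits: TraitSpec = TraitSpec()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 4:
            raise DataError("need at least 4 individuals")
        if not 0 <= self.outliers.fraction <= 1:
            raise DataError("outlier fraction must be in [0, 1]")
        for spec in self.tissues:
            if not 0 <= spec.missing_individual_fraction <= 1:
                raise DataError("missing fractions must be in [0, 1]")
        for sig in self.signals:
            if not 0 < sig.rho < 1:
                raise DataError("planted rho must be in (0, 1)")
            if sig.module_size < 1:
                raise DataError("module size must be >= 1")
        if self.pathway is not None and not 0 < self.pathway.rho < 1:
            raise DataError("pathway rho must be in (0, 1)")

    @staticmethod
    def from_yaml(path: str | Path) -> "SimulationConfig":
        """Load a config from a flat YAML mapping mirroring the fields."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        if "n_individuals" in raw:
            kwargs["n_individuals"] = int(raw["n_individuals"])
        if "seed" in raw:
            kwargs["seed"] = int(raw["seed"])
        if "noise_sd" in raw:
            kwargs["noise_sd"] = float(raw["noise_sd"])
        if "tissues" in raw:
            kwargs["tissues"] = tuple(
                TissueSpec(
                    name=t["name"],
                    n_background_genes=int(t.get("n_background_genes", DEFAULT_N_GENES)),
                    missing_individual_fraction=float(
                        t.get("missing_individual_fraction", 0.0)
                    ),
                )
                for t in raw["tissues"]
            )
        if "signals" in raw:
            kwargs["signals"] = tuple(PlantedSignal(**s) for s in raw["signals"])
        if "pathway" in raw and raw["pathway"]:
            pw = dict(raw["pathway"])
            pw["tissues"] = tuple(pw.get("tissues", ()))
            kwargs["pathway"] = PlantedPathway(**pw)
        if "outliers" in raw and raw["outliers"]:
            kwargs["outliers"] = OutlierSpec(**raw["outliers"])
        if "signature" in raw and raw["signature"]:
            kwargs["signature"] = SignatureSpec(**raw["signature"])
        if "traits" in raw and raw["traits"]:
            tr = dict(raw["traits"])
            tr["links"] = tuple(TraitLink(**l) for l in tr.get("links", ()))
            kwargs["traits"] = TraitSpec(**tr)
        return SimulationConfig(**kwargs)


@dataclass
class GroundTruth:
    """What was planted: module members, pathway members, mixtures, traits."""

    modules: dict[str, dict] = field(default_factory=dict)
    pathway_members: dict[str, list[str]] = field(default_factory=dict)
    signature: pd.DataFrame | None = None
    proportions: pd.DataFrame | None = None
    bulk: pd.DataFrame | None = None
    trait_links: tuple[TraitLink, ...] = ()


def _latent_block(rng, z: np.ndarray, rho: float, n_rows: int, sd: float) -> np.ndarray:
    eps = rng.normal(0.0, 1.0, size=(n_rows, z.size))
    return sd * (np.sqrt(rho) * z[None, :] + np.sqrt(1.0 - rho) * eps)


def simulate_archive(
    config: SimulationConfig,
) -> tuple[ExpressionTensor, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (tensor, metadata, traits, ground truth) from a config.

    Order of construction: correlation structure first, then outlier
    contamination, then block missingness — so outliers and missingness
    degrade, rather than define, the planted signal. Fully reproducible
    from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    individuals = [f"IND{i:04d}" for i in range(n)]
    sd = config.noise_sd

    tissue_names = [t.name for t in config.tissues]
    for sig in config.signals:
        for t in (sig.seed_tissue, sig.target_tissue):
            if t not in tissue_names:
                raise DataError(f"planted signal references unknown tissue {t!r}")

    matrices: dict[str, np.ndarray] = {}
    gene_names: dict[str, list[str]] = {}
    for spec in config.tissues:
        g = spec.n_background_genes
        matrices[spec.name] = rng.normal(0.0, sd, size=(g, n))
        gene_names[spec.name] = [f"G{i:04d}" for i in range(g)]

    truth = GroundTruth(trait_links=config.traits.links)

    # planted cross-tissue modules
    for sig in config.signals:
        names_t = gene_names[sig.target_tissue]
        if sig.module_size + 1 > len(names_t):
            raise DataError(
                f"module size {sig.module_size} exceeds tissue "
                f"{sig.target_tissue!r} gene count"
            )
        z = rng.normal(0.0, 1.0, size=n)
        seed_names = gene_names[sig.seed_tissue]
        if sig.seed_gene in seed_names:
            seed_idx = seed_names.index(sig.seed_gene)
        else:
            seed_idx = 0
            seed_names[seed_idx] = sig.seed_gene
        matrices[sig.seed_tissue][seed_idx] = _latent_block(rng, z, sig.rho, 1, sd)[0]
        # module occupies the tail gene indices of the target tissue, away
        # from any seed placed at index 0
        start = len(names_t) - sig.module_size
        module = names_t[start:]
        matrices[sig.target_tissue][start:] = _latent_block(
            rng, z, sig.rho, sig.module_size, sd
        )
        truth.modules[f"{sig.seed_tissue}:{sig.seed_gene}"] = {
            "target_tissue": sig.target_tissue,
            "genes": list(module),
            "rho": sig.rho,
        }

    # planted co-regulated pathway across tissues
    if config.pathway is not None:
        pw = config.pathway
        targets = list(pw.tissues) if pw.tissues else tissue_names
        z = rng.normal(0.0, 1.0, size=n)
        for t in targets:
            names_t = gene_names[t]
            if pw.genes_per_tissue > len(names_t):
                raise DataError(
                    f"pathway size {pw.genes_per_tissue} exceeds tissue {t!r}"
                )
            # distinct index range (after index 0, before any module tail)
            lo = 1
            idx = list(range(lo, lo + pw.genes_per_tissue))
            matrices[t][idx] = _latent_block(rng, z, pw.rho, len(idx), sd)
            truth.pathway_members[t] = [names_t[i] for i in idx]

    # outlier contamination: entries replaced by value +- kappa * sd
    if config.outliers.fraction > 0:
        for t in tissue_names:
            mat = matrices[t]
            total = mat.size
            n_out = int(round(config.outliers.fraction * total))
            if n_out:
                flat = rng.choice(total, size=n_out, replace=False)
                signs = rng.choice([-1.0, 1.0], size=n_out)
                mat.ravel()[flat] += signs * config.outliers.kappa * sd

    # block missingness: whole individuals absent from a tissue
    for spec in config.tissues:
        k = int(round(spec.missing_individual_fraction * n))
        if k:
            cols = rng.choice(n, size=k, replace=False)
            matrices[spec.name][:, cols] = np.nan

    tensor = ExpressionTensor(
        individuals=individuals,
        matrices={
            t: pd.DataFrame(matrices[t], index=gene_names[t], columns=individuals)
            for t in tissue_names
        },
    )

    # metadata: sex split mirroring the human archive, decade age groups
    sex = np.where(rng.random(n) < DEFAULT_MALE_FRACTION, "male", "female")
    ages = rng.integers(20, 80, size=n)
    age_group = [f"{(a // 10) * 10}-{(a // 10) * 10 + 9}" for a in ages]
    metadata = pd.DataFrame(
        {"sex": sex, "age_group": age_group}, index=individuals
    )

    # traits: linked to specific gene-tissue pairs, plus pure-noise traits
    trait_cols: dict[str, np.ndarray] = {}
    for link in config.traits.links:
        expr = tensor.matrix(link.tissue).loc[link.gene].to_numpy(dtype=float)
        zsc = (expr - np.nanmean(expr)) / (np.nanstd(expr) or 1.0)
        trait_cols[link.trait] = link.beta * np.nan_to_num(zsc) + rng.normal(
            0.0, 1.0, size=n
        )
    for i in range(config.traits.n_noise_traits):
        trait_cols[f"noise_trait_{i:02d}"] = rng.normal(0.0, 1.0, size=n)
    traits = pd.DataFrame(trait_cols, index=individuals)

    # cell-type mixtures
    if config.signature is not None:
        sig_spec = config.signature
        truth.signature = simulate_signature(
            sig_spec.n_marker_genes, sig_spec.n_cell_types, rng=rng
        )
        props = rng.dirichlet(np.ones(sig_spec.n_cell_types), size=n)
        truth.proportions = pd.DataFrame(
            props, index=individuals, columns=list(truth.signature.columns)
        )
        bulk = truth.signature.to_numpy() @ props.T + rng.normal(
            0.0, 0.1, size=(sig_spec.n_marker_genes, n)
        )
        truth.bulk = pd.DataFrame(
            np.clip(bulk, 0.0, None), index=list(truth.signature.index), columns=individuals
        )

    return tensor, metadata, traits, truth


def simulate_signature(
    n_marker_genes: int = 300,
    n_cell_types: int = 4,
    marker_high: float = 10.0,
    baseline: float = 0.5,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Non-negative marker x cell-type signature with blockwise markers.

    Each cell type gets an equal slice of the marker genes expressed at
    ``marker_high`` (lognormal-jittered) on a low shared baseline, so
    columns are well separated and the mixture problem is identifiable.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    genes = [f"M{i:04d}" for i in range(n_marker_genes)]
    types = [f"celltype_{chr(ord('A') + j)}" for j in range(n_cell_types)]
    A = baseline * rng.lognormal(0.0, 0.2, size=(n_marker_genes, n_cell_types))
    block = n_marker_genes // n_cell_types
    for j in range(n_cell_types):
        lo = j * block
        hi = n_marker_genes if j == n_cell_types - 1 else lo + block
        A[lo:hi, j] = marker_high * rng.lognormal(0.0, 0.2, size=hi - lo)
    return pd.DataFrame(A, index=genes, columns=types)


def simulate_mixture(
    signature: pd.DataFrame,
    proportions: Sequence[float],
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> pd.Series:
    """One bulk expression vector: signature . proportions + Gaussian noise."""
    f = np.asarray(proportions, dtype=float)
    if f.ndim != 1 or f.size != signature.shape[1]:
        raise DataError(
            f"proportions length {f.size} != {signature.shape[1]} cell types"
        )
    if (f < 0).any() or not np.isclose(f.sum(), 1.0):
        raise DataError("proportions must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    bulk = signature.to_numpy(dtype=float) @ f
    if noise_sd > 0:
        bulk = bulk + rng.normal(0.0, noise_sd, size=bulk.size)
    return pd.Series(bulk, index=list(signature.index), name="bulk")


def write_ground_truth(truth: GroundTruth, directory: str | Path) -> None:
    """Persist ground truth as plain TSV/JSON files."""
    import json

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "modules": truth.modules,
        "pathway_members": truth.pathway_members,
        "trait_links": [vars(l) if not isinstance(l, dict) else l for l in truth.trait_links],
    }
    (directory / "ground_truth.json").write_text(json.dumps(meta, indent=1))
    if truth.signature is not None:
        truth.signature.to_csv(directory / "signature.tsv", sep="\t")
    if truth.proportions is not None:
        truth.proportions.to_csv(directory / "true_proportions.tsv", sep="\t")
    if truth.bulk is not None:
        truth.bulk.to_csv(directory / "bulk.tsv", sep="\t")
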