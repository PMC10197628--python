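"""Cross-tissue pathway connectivity against a size-matched random null.

Plants a pathway whose 8 genes per tissue share one latent factor
(rho = 0.7) across three tissues, counts significant cross-tissue
gene-gene correlations, and compares the total with 100 random-gene draws
of the same size.
"""

from pantissue import (
    PlantedPathway, SimulationConfig, TissueSpec, cross_tissue_counts,
    random_gene_null, simulate_archive, tissue_ranking,
)

cfg = SimulationConfig(
    n_individuals=120,
    tissues=(TissueSpec("liver", 200), TissueSpec("adipose", 200),
             TissueSpec("muscle", 200)),
    pathway=PlantedPathway("OXPHOS_LIKE", genes_per_tissue=8, rho=0.7),
    seed=4,
)
tensor, _, _, truth = simulate_archive(cfg)
genes = sorted({g for gs in truth.pathway_members.values() for g in gs})

grids = cross_tissue_counts(tensor, genes, thresholds=(1e-3,), mode="pairs",
                            pathway_name="OXPHOS_LIKE")
cm = grids[0]
print(f"pathway {cm.pathway!r}, p < {cm.threshold:g}, pairs mode")
print(cm.grid.to_string(), "\n")
observed = cm.total_cross_tissue()

ranking = tissue_ranking(tensor, genes, threshold=1e-3)
print("tissues ranked by genes with >= 1 significant correlation:")
print(ranking.counts.to_string(), "\n")

null = random_gene_null(tensor, size=len(genes), n_draws=100, seed=5,
                        thresholds=(1e-3,))
q95 = null["total_cross_tissue"].quantile(0.95)
print(f"observed cross-tissue pairs: {observed:.0f}")
print(f"random-gene null 95th percentile: {q95:.1f} "
      f"(mean {null['total_cross_tissue'].mean():.1f})")

# The planted pathway's count sits far above the null's 95th percentile:
# coordinated cross-organ correlation of this strength does not arise from
# size-matched random gene sets in this archive.
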