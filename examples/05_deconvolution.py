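"""Cell-type deconvolution of bulk mixtures and abundance-gene correlation.

Simulates a 4-cell-type signature, mixes it into bulk profiles with known
Dirichlet proportions, recovers the proportions with the constrained
least-squares solver, and correlates one inferred abundance against a gene
engineered to track it.
"""

import numpy as np
import pandas as pd

from pantissue import (
    celltype_gene_correlation, fit_proportions, simulate_mixture,
    simulate_signature,
)
from pantissue.archive import ExpressionTensor

rng = np.random.default_rng(7)
signature = simulate_signature(300, 4, seed=7)
individuals = [f"IND{i:03d}" for i in range(60)]

true_props = rng.dirichlet(np.ones(4), size=60)
bulk = pd.DataFrame(
    {ind: simulate_mixture(signature, f, noise_sd=0.1,
                           seed=int(rng.integers(2**31)))
     for ind, f in zip(individuals, true_props)})

props, resid = fit_proportions(signature, bulk)
err = np.abs(props.to_numpy() - true_props).mean()
print(f"mean absolute proportion error over 60 samples: {err:.4f}")
print(f"median per-sample residual norm: {resid.median():.3f}")
print(props.head(3).round(3).to_string())

# a gene tracking cell type B's abundance (plus noise)
gene = props["celltype_B"].to_numpy() + 0.05 * rng.normal(size=60)
tensor = ExpressionTensor(
    individuals=individuals,
    matrices={"liver": pd.DataFrame(gene[None, :], index=["TRACKER"],
                                    columns=individuals)})
corr = celltype_gene_correlation(props, tensor, "liver", "TRACKER")
print("\nbicor of inferred abundances vs the tracker gene:")
print(corr[["cell_type", "bicor", "p", "q"]].round(4).to_string(index=False))

# Proportions come back within a few percent despite measurement noise, and
# the abundance-gene correlation isolates the matching cell type with
# bicor near 1 while the other types stay near zero.
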