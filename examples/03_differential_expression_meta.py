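"""Pairwise DE within each dataset and cross-dataset integration.

For one target cell type, runs positive-only DE (logFC >= 0.5, Bonferroni
padj <= 0.05) against every other type in every dataset, then aggregates
the evidence per gene: the number of contributing analyses, the mean logFC,
the geometric-mean adjusted p, and the rank score -log10(avgPadj) * avgLFC.
"""

from isletid.pipeline import PipelineParams, run_celltype_stage, run_derivation_de, run_integration
from isletid.simulate import SimulationConfig, generate_collection

config = SimulationConfig(
    n_datasets=3, cells_per_type=80, n_markers_per_type=40,
    marker_reproducibility=(1.0,) * 16 + (0.6,) * 16 + (0.3,) * 8,
    n_background_genes=300, seed=1,
)
params = PipelineParams(sim=config)
collection = generate_collection(config)

typed = [
    run_celltype_stage(adata, params, seed=i)[0]
    for i, adata in enumerate(collection.datasets)
]
de_tables = run_derivation_de(typed, params)
records = run_integration(de_tables, params)

beta = records["beta"]
print(f"{len(beta)} genes ever enriched in beta cells "
      f"(out of {3 * 3} analyses: 3 datasets x 3 opponents)")
print("\ntop of the aggregated table:")
cols = ["gene", "n_analyses", "avg_logfc", "avg_padj", "rank_score"]
print(beta[cols].head(10).to_string(index=False))
# Genes found in every analysis (n_analyses = 9 here) are the most
# reproducible identity genes; the rank score orders genes within a tier.
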