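"""Simulate a synthetic brain + transcriptome and rank genes by their
spatial association with the activation map.

A planted subset of genes shares a latent spatial factor with the
activation map, so those genes should surface at the top of the ranking.
"""

import braintx as bx

cfg = bx.SyntheticConfig(seed=7)
atlas = bx.generate_atlas(cfg)
expression = bx.generate_expression(cfg, atlas)
activation, truth = bx.generate_activation(cfg, expression, atlas)

cortex = bx.split_profile(activation, atlas, "cortex")
table = bx.correlate_genes(expression.loc[:, cortex.unit_ids], cortex)

print("Top 10 genes by Spearman rho with the cortical activation map:")
print(table.data.head(10)[["gene_id", "rho", "rank"]].to_string(index=False))

positive, negative = bx.threshold_correlations(table, rho_min=0.5)
planted = set(truth.planted_gene_ids)
recovered = len(positive & planted) / len(planted)
print(f"\n{len(positive)} genes exceed rho > 0.5 (large effect size);")
print(f"{recovered:.0%} of the {len(planted)} planted genes are among them.")
print("A recovery near 100% means the ranking finds the genes whose")
print("expression topography was built into the activation map.")
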