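"""Screen candidate accessory-subunit genes by co-expression with a channel gene.

Builds tissue and developmental RPKM tables with a planted co-regulated
module (the channel gene plus three candidates), then ranks every gene by
its mean Pearson correlation with the channel gene across both datasets.
"""

from midlink.expression import pairwise_correlation, rank_candidates
from midlink.synthetic import ExpressionSimConfig, simulate_expression

tissue = simulate_expression(
    ExpressionSimConfig(n_genes=12, n_samples=29, dataset_kind="tissue", seed=1)
)
devel = simulate_expression(
    ExpressionSimConfig(n_genes=12, n_samples=30, dataset_kind="developmental", seed=2)
)

reports = [pairwise_correlation(m) for m in (tissue, devel)]
print(f"tissue panel: {tissue.values.shape[0]} genes x {tissue.n_samples} samples")
print(f"developmental series: {devel.values.shape[0]} genes x {devel.n_samples} samples\n")

print(f"{'gene':<10} {'tissue r':>9} {'devel r':>9} {'mean r':>8}")
for cand in rank_candidates(reports, reference_gene="na"):
    print(
        f"{cand.gene:<10} {cand.per_dataset_r['tissue']:>9.3f} "
        f"{cand.per_dataset_r['developmental']:>9.3f} {cand.mean_r:>8.3f}"
    )
print(
    "\nGenes sharing the channel gene's regulatory program (the planted module:"
    "\nMid1, unc79, unc80) rank far above the independent background genes,"
    "\nwhose correlations scatter around zero."
)
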