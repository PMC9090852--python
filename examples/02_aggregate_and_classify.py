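"""Aggregate a simulated leaf TPM matrix to subgenome fractions and classify.

Builds a small synthetic dataset in which one gene (an Rca1-like activase) has
a genuinely skewed subgenome balance (22/23/55) while the others are balanced,
runs the aggregation, and prints each gene's relative subgenome expression
with its nearest-centroid balance category.
"""

import triadbalance as tb

spec = tb.SimulationSpec(
    genes=(
        tb.GeneSpec("Bsd2", base_total_tpm=40.0),
        tb.GeneSpec("Cpn60", loci_per_subgenome=(2, 2, 2), base_total_tpm=120.0),
        tb.GeneSpec("RbcS", loci_per_subgenome=(9, 8, 8), base_total_tpm=2500.0),
        tb.GeneSpec("Rca1", true_fractions=(0.22, 0.23, 0.55), base_total_tpm=150.0),
    ),
    n_samples=10,
    noise_cv=0.2,
    seed=42,
)
registry_df, matrix, truth = tb.simulate_dataset(spec)
registry = tb.load_registry(registry_df)

results, dropped = tb.analyze_gene_set(matrix, registry, [tb.Context("leaf", "control")])
calls = tb.classify_table(results, epsilon=0.05)

print(f"{'gene':<8} {'fA':>6} {'fB':>6} {'fD':>6} {'log2T':>6}  category (boundary set)")
for r, c in zip(results, calls):
    fa, fb, fd = r.fractions
    extra = f" ({','.join(c.boundary_set)})" if len(c.boundary_set) > 1 else ""
    print(f"{r.gene_name:<8} {fa:6.3f} {fb:6.3f} {fd:6.3f} {r.log2_total:6.2f}  {c.category}{extra}")

# fA/fB/fD are each subgenome's share of the triad's total expression (they
# sum to 1); log2T is log2 of the summed TPM. A gene is 'balanced' when its
# point lies nearest the simplex centre (1/3, 1/3, 1/3).
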