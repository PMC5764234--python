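"""Enumerate pathway gaps, classify them, and fill a genuine gap.

Two gaps are planted: one reaction is hidden from the baseline only (the
other resources still vote for its gene, giving a clear candidate), and
one is hidden from every resource (a genuine gap that only the fitness
data can fill, via the amino-acid rescue scan).
"""

from auxofill import (
    assign_genes, call_essential, clear_candidates, fitness_pipeline,
    flag_special, gene_insertion_stats, ledger_grid, phenotype_calls,
    predict_status, simulate_world, summarize_ledger,
)
from auxofill.classify import classify_all

world = simulate_world(
    seed=1,
    drop_spec=[
        ("ATP-PRTRANS", ["baseline"]),                       # clear candidate
        ("PRAMP-CH", ["baseline", "res1", "res2", "res3"]),  # genuine gap
    ],
)
pool = assign_genes(world.pool, world.genes)
fit = fitness_pipeline(pool, world.counts, world.experiments, world.genes)
stats = gene_insertion_stats(world.pool, world.genes, world.genome)
essentials = call_essential(stats, genome=world.genome, pool=world.pool)
ess_set = set(essentials.index[essentials["called"]])

status, gap_list = predict_status(world.pathway_db, world.annotations,
                                  world.baseline_resource)
print("predicted status per amino acid:", status)
for gap in gap_list:
    clear_candidates(gap, world.annotations, world.resources)
    flag_special(gap, pathway_db=world.pathway_db)

calls = phenotype_calls(fit, world.experiments, ess_set)
gap_list = classify_all(gap_list, calls, fit, world.experiments,
                        world.annotations, world.pathway_db)

for gap in gap_list:
    extra = f" filled_by={gap.filled_by}" if gap.filled_by else ""
    print(f"  {gap.amino_acid}/{gap.reaction_id}: {gap.classification}{extra}")
truth = world.truth.set_index("gene_id")
print("  (ground truth for the hidden step:",
      truth.index[truth['role'] == 'PRAMP-CH'][0] + ")")

print("\nledger summary:")
print(summarize_ledger(gap_list).to_string(index=False))
print("\ngrid (one code per gap; empty cell = prototroph):")
grid = ledger_grid(gap_list, amino_acids=["his", "met", "ser", "thr"])
print(grid.to_string())
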