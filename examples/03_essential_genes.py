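"""Call putatively essential genes from insertion statistics.

A gene is called essential when it is long enough that an empty central
10-90% window would be surprising, and both its GC-normalized density of
distinct insertion locations and its central reads per nucleotide fall
below 20% of the typical (median) gene's values.
"""

from auxofill import call_essential, gene_insertion_stats, simulate_world

world = simulate_world(seed=1)
stats = gene_insertion_stats(world.pool, world.genes, world.genome)
called = call_essential(stats, genome=world.genome, pool=world.pool)

truth = world.truth.set_index("gene_id")
true_ess = set(truth.index[truth["essential"]])
called_ess = set(called.index[called["called"]])
tp = len(true_ess & called_ess)

print(f"automatic length floor: {called.attrs['min_length']} nt")
print(f"called essential: {len(called_ess)} of {len(called)} genes")
print(f"sensitivity {tp / len(true_ess):.3f}   "
      f"precision {tp / len(called_ess):.3f}   "
      f"(vs {len(true_ess)} planted essentials)")
print("\ntypical vs essential gene statistics (medians):")
for label, sub in [("non-essential", called.drop(index=true_ess)),
                   ("essential", called.loc[sorted(true_ess)])]:
    print(f"  {label:14s} norm_density {sub['norm_density'].median():5.2f}  "
          f"reads/nt {sub['reads_per_nt'].median():6.2f}")
# Essential genes sit near zero on both axes because the pool cannot
# contain viable mutants with central insertions in them.
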