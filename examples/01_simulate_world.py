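"""Build a synthetic RB-TnSeq study with planted ground truth.

A world bundles a genome, gene models, a barcoded insertion pool, an
experiment design, BarSeq counts, multi-resource annotation tables and
the truth table used to score recovery.  Here we hide one histidine
pathway step (phosphoribosyl-AMP cyclohydrolase) from every annotation
resource, planting a "genuine" gap for the downstream pipeline to fill.
"""

from auxofill import simulate_world

world = simulate_world(
    seed=1,
    drop_spec=[("PRAMP-CH", ["baseline", "res1", "res2", "res3"])],
)

truth = world.truth
print(f"genes:            {len(world.genes)}")
print(f"insertion strains:{len(world.pool):>7}")
print(f"experiments:      {len(world.experiments)} (+ "
      f"{world.experiments['time0_id'].nunique()} time0 samples)")
print(f"planted essential:{int(truth['essential'].sum()):>7}")
aux = truth[truth["effect"] != 0]
per_aa = {aa: int(k) for aa, k in aux["amino_acid"].value_counts().items()}
print(f"planted auxotrophs: {len(aux)} ({per_aa})")
hidden = truth.loc[truth["role"] == "PRAMP-CH", "gene_id"].iloc[0]
print(f"hidden gap gene:  {hidden} (annotated nowhere; ground truth only)")
# Each auxotroph has true fitness -4 in defined media lacking its amino
# acid and 0 when it is supplied -- the signature the classifier hunts for.
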