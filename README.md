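# auxofill

Fill gaps in bacterial amino-acid biosynthesis pathways from genome-wide
barcoded-transposon (RB-TnSeq) mutant fitness data.

Automated annotation pipelines routinely predict that free-living bacteria
are auxotrophic for several amino acids — the pathway reconstruction is
missing a required enzymatic step — even when the organism demonstrably
grows in minimal media. Most of these *gaps* are annotation artifacts
(an ortholog the baseline missed, a promiscuous transaminase, a broken gene
model); a few are genuine holes in biological knowledge, and pooled mutant
fitness assays can find the unknown enzyme that fills them. `auxofill`
implements that audit as a tested pipeline:

1. **Gap enumeration** (`auxofill.gaps`) — from a pathway database
   (amino acid → reaction steps, with variants) and a baseline annotation
   table, select per amino acid the pathway variant with fewest missing
   steps; the missing steps are the gaps. Genes annotated with a gap's
   reaction by ≥ 2 of ≥ 3 independent annotation resources are *clear
   candidates*.
2. **Gene fitness** (`auxofill.fitness`) — for strain *s* with time0 count
   *n₀* and post-growth count *n*, raw fitness is
   `log2(n + ψ) − log2(n₀ + ψ) − log2(N/N₀)` (ψ = pseudocount, N/N₀ the
   library-size ratio). Gene fitness *f* is the weighted mean over the
   gene's central (10–90% of gene length) insertion strains, weight
   `min(n₀, 20)`, then median-centered per experiment. *f* ≈ 0 means no
   phenotype; *f* < −2 a strong growth defect.
3. **Essentiality** (`auxofill.essentials`) — genes long enough that an
   empty central window is surprising are called putatively essential when
   both their GC-normalized density of distinct insertion locations and
   their central reads per nucleotide are < 20% of the median gene's
   values.
4. **Classification** (`auxofill.classify`) — each gap lands in exactly one
   ledger category (clear candidate: auxotrophic / essential / multiple /
   no-data / redundant / other; gene-model error; transaminase; known;
   genuine). A genome-wide *rescue scan* proposes genes to fill genuine
   gaps: mean fitness under −2 in minimal media and above −1 when the
   amino acid is supplemented (strict inequalities, replicates averaged
   first).
5. **Association evidence** (`auxofill.cofit`) — cofitness (Pearson *r* of
   fitness profiles, pairwise-complete) and phylogenetic-profile
   concordance support gene–function links.
6. **Synthetic data** (`auxofill.simulate`) — generates genomes, insertion
   pools with optional GC bias and essential-gene exclusion, BarSeq counts
   under a per-strain exponential growth model, and annotation tables with
   planted gaps, so the whole pipeline is testable against known ground
   truth.

## Worked example

```python
from auxofill import (simulate_world, assign_genes, fitness_pipeline,
                      predict_status, clear_candidates, flag_special,
                      phenotype_calls, summarize_ledger)
from auxofill.classify import classify_all

# hide one histidine step from every annotation resource: a genuine gap
world = simulate_world(seed=1,
                       drop_spec=[("PRAMP-CH",
                                   ["baseline", "res1", "res2", "res3"])])
pool = assign_genes(world.pool, world.genes)
fit = fitness_pipeline(pool, world.counts, world.experiments, world.genes)

status, gaps = predict_status(world.pathway_db, world.annotations, "baseline")
for gap in gaps:
    clear_candidates(gap, world.annotations, world.resources)
    flag_special(gap, pathway_db=world.pathway_db)
calls = phenotype_calls(fit, world.experiments, essentials=set())
gaps = classify_all(gaps, calls, fit, world.experiments,
                    world.annotations, world.pathway_db)
print(gaps[0].classification, gaps[0].filled_by)
print(summarize_ledger(gaps).to_string(index=False))
```

prints

```
genuine_filled g00311
      group            subgroup  cases
Genuine gap filled (this study)      1
```

i.e. the hidden phosphoribosyl-AMP cyclohydrolase step is re-discovered:
gene `g00311` (the planted truth) is strongly sick in minimal media,
healthy when histidine is supplied, and not annotated to any other
histidine step, so the rescue scan proposes it to fill the gap. The
`examples/` directory has one short narrative script per capability
(simulation, fitness, essentiality, gap classification, cofitness), and a
thin CLI (`auxofill simulate/fitness/essential/gaps/classify/cofit/report`)
wraps the same functions for shell use.

The package also ships a transcription of a published classification
ledger of 173 amino-acid biosynthesis gaps across 10 heterotrophic
bacteria (`auxofill.classify.load_reference_ledger`), used to check the
ledger arithmetic.

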