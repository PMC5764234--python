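# Methods

## The model in one paragraph

A pooled library of randomly barcoded transposon mutants is grown from
OD 0.02 to saturation (4–8 generations) in a condition of interest, and
barcodes are counted by sequencing before (time0) and after growth.
If strain *s* carries an insertion that knocks out gene *g*, and gene *g*
has fitness effect *f* in that condition, the strain's expected abundance
grows as `a_s · 2^(g_gen + f)` where `g_gen` is the pool-wide number of
generations. Biosynthesis mutants (auxotrophs) have strongly negative *f*
in defined media lacking their amino acid and *f* ≈ 0 when it is supplied;
genes whose loss is lethal in the library-construction condition simply
never appear with central insertions. Everything in this package —
fitness estimation, essentiality calling, gap classification, rescue
scanning, cofitness — is built on this model, and the synthetic generator
simulates exactly it so that recovery can be scored against planted truth.

## Fitness estimation

Raw strain fitness: `log2(n + ψ) − log2(n₀ + ψ) − log2(N/N₀)` with
pseudocount ψ = 1 by default (bounded estimates at low counts) and the
library-size ratio `N/N₀` taken over **all** pool barcodes (a
median-of-ratios alternative is behind a flag). Strains with fewer than 3
time0 reads are dropped. Gene fitness is the weighted mean over central
strains — insertion at central fraction `fc = (pos − begin + 0.5)/len`
with `0.1 ≤ fc ≤ 0.9` — with weight `min(n₀, 20)`: the cap keeps one deep
strain from dominating. A gene × experiment entry is left missing when
the qualifying central strains carry < 30 summed time0 reads. These
coverage thresholds are package defaults: the source studies do not print
theirs, and ours are exposed as parameters everywhere.

Normalization subtracts the per-scaffold median over genes with values,
so typical genes score 0 exactly; scaffolds with < 10 valued genes fall
back to the genome-wide median. We deliberately use the median rather
than mode-finding: it is simpler, exactly testable (shift invariance,
per-scaffold median ≡ 0) and adequate for the synthetic worlds. We also
do not implement a t-like variance statistic or chromosomal-position bias
correction; downstream rules operate on thresholded fitness values.

Experiment quality is simplified to three internal-consistency metrics:
the correlation between gene fitness computed from the first- versus
second-half strains of each gene (split at fc = 0.5), the median |f|, and
the fraction of genes with |f| > 1. An experiment is flagged when the
half-gene correlation is below 0.4 or the strong-effect fraction exceeds
0.25. The full published quality-scoring system is richer; these two
cutoffs catch the failure modes the simulator can produce (no signal,
global artifacts).

## Essentiality calling

Per gene we count **distinct central insertion locations**, keyed by
(scaffold, position, strand) — transposon junctions are strand-specific
in the pool format, so the two strands at one position are two locations;
barcodes sharing a location are merged and their mapping reads summed.
Density is locations per nt of the central 80%. Expected density as a
function of gene GC is an OLS line fitted over genes of qualifying
length, floored at 10% of the median density (so normalized densities
stay finite); a GC spread below 0.01 falls back to a constant model.
A gene is called putatively essential when its length is at least the
floor **and** `norm_density < 0.2 · median(norm_density)` **and**
`reads_per_nt < 0.2 · median(reads_per_nt)`, medians over
qualifying-length genes ("typical" = median; 20% is the conventional
cutoff, with a published precedent of a 400 nt floor at realistic pool
densities). The automatic length floor is the smallest L with
`0.8 · L · d ≥ 4` (d = genome-wide distinct-site density): at that length
an empty central window has probability < ~2% under Poisson coverage, and
on realistic densities it lands near the conventional 400 nt. Calls are
invariant to uniform read scaling by construction.

## Gap enumeration and classification

Pathway databases list ordered reaction steps per (amino acid, variant).
Baseline predictions are computed from a designated baseline annotation
table rather than scraped from a prediction website, for reproducibility;
a per-amino-acid status override hook represents baselines that decline
to predict either way. Per amino acid the variant with fewest missing
steps wins (ties: lexicographically smallest variant id — the exact
variant logic of production annotation servers is opaque, so this rule is
a declared approximation). A reaction shared by several amino acids
yields one gap record per amino acid. Candidate support is the number of
non-baseline resources (≥ 3 required) annotating a gene with the gap's
reaction; support ≥ 2 is a clear candidate.

Curated pre-classifications take precedence in the order gene-model error
> transaminase > known. Transaminase steps are exempt from auxotrophy
prediction because amino-acid transaminases are typically promiscuous,
so their apparent absence is not evidence.

Phenotype calls: essential-set membership first; then `no_data` when a
gene lacks fitness in ≥ half the defined-minimal experiments;
`auxotrophic` when fitness ≤ −2 in ≥ 50% of defined-minimal experiments
with data and median amino-acid-replete fitness ≥ −0.5 (no replete data
counts as unopposed — absence of contrary evidence); otherwise
`no_phenotype`. "Most defined media" has no published numeric fraction;
50% is our operationalization and both thresholds are exposed.
Defined-minimal means a defined medium with no amino-acid supplement of
any kind; replete means rich media or casamino acids / yeast extract.
Single-amino-acid supplements belong to neither partition — they feed the
rescue scan. Casamino acids lacks tryptophan; by default this is ignored
when judging trp genes (flagged option to honor it).

The decision tree for a gap with clear candidates follows the ledger
semantics: ≥ 2 clear candidates with no auxotrophic/essential phenotype →
*multiple candidates* (possible redundancy among them); otherwise the
best candidate's phenotype decides, where "best" prefers a candidate with
a phenotype and then highest support; a candidate with no phenotype is
*other (redundant)* when another gene is also annotated with the gap's
reaction, else *other*. Without a clear candidate the gap is genuine,
and the rescue scan for the gap's amino acid proposes the strongest
rescued gene **not** already annotated to another step of that pathway —
the exclusion keeps upstream-pathway auxotrophs (e.g. homoserine
dehydrogenase, rescued by threonine) from falsely filling a downstream
gap. The exact published rule separating "auxotrophic" from "other"
involved judgment; this tree is a declared formalization, with curated
lists as the escape hatch.

Rescue semantics are strict: replicate-group means, minimal fitness
strictly under −2 and supplemented fitness strictly above −1. Results are
sorted by rescue strength (supplemented minus minimal fitness),
strongest first.

## Cofitness and profiles

Pearson r over pairwise-complete experiments; undefined below 15 shared
experiments (published comparisons use compendia of 170–270 experiments;
small-n correlations are noise) or when either profile is constant.
All-pairs computation must be restricted by a candidate list or an |r|
cutoff. Presence/absence profiles share an ordered genome list; manual
overrides (e.g. a protein present as a split gene) are applied before
computing the fraction of agreeing genomes.

## The synthetic generator

What it emulates: per-gene GC variation realized in sequence composition
(genes non-overlapping on alternating strands, one scaffold per 1000
genes); insertion probability proportional to
`max(0.05, 1 + slope·(localGC − 0.5))` over a 101-nt window; no central
insertions in essential genes (edge insertions allowed — terminal
insertions are often tolerated, and the essentiality caller only looks at
the central window); unique random 20-nt barcodes with collision re-draw
and mapping support ≥ 2 reads; log-normal time0 abundances (σ = 0.5 in
log2 units — no published abundance distribution exists, so this is a
configurable guess); exponential growth `2^(g + f)`; Poisson counts
scaled to a target depth, with an optional gamma-Poisson overdispersion
parameter (Poisson is the simplest model consistent with the qualitative
behavior of BarSeq counts, and the pipeline should be robust to either).
Truth tables plant essentials, auxotrophs (assigned to non-transaminase
steps of their amino acid's first pathway variant), and optional
redundant pairs (two genes, one shared reaction, zero effect). Neutral
"cover" genes can be attached to every remaining pathway reaction so that
the baseline is complete and gaps arise only from an explicit drop
specification.

Default study conditions (used by the test suite and the acceptance
script): 500 genes of mean length 900 nt, GC drawn in 0.40–0.65, 10%
essential, three auxotrophy genes each for his/met/ser with true effect
−4, 10 000 strains (≈ 14 central strains per gene), 50 reads/strain, two
replicates of a 16-experiment compendium (four carbon sources in defined
media, one single-amino-acid supplement per planted amino acid, rich
media), 6 generations. These sizes keep a full replicate world under a
second while leaving every downstream threshold comfortably exercised.

What it does **not** emulate: read-level errors, chimeric barcodes,
operon structure and polar effects, condition-specific essentiality,
growth-rate differences between media, or correlated (batch) noise across
experiments. Passing recovery tests therefore show the pipeline's logic
and numerics are right under the stated model, not that real compendia
are this clean; on real data the quality filters and curated-list hooks
carry the weight.

## Numerical choices and degenerate inputs

Deterministic seeding throughout (numpy `default_rng`; world generation
derives per-stage seeds from one master seed). Ties: candidates sort by
(−support, gene id); cofitness by (−r, gene id); variant selection by
(missing count, variant id). An all-zero time0 sample is an error; a gene
with zero central strains is a missing value, not an error. Medians are
exact (no interpolation surprises at our sizes). The GC model's floor
and the constant-model fallback keep `norm_density` finite on degenerate
pools.

## Known limitations

- The ledger's "other" subgroups ultimately encode curator judgment; the
  package exposes curated lists rather than trying to learn the judgment.
- The essentiality caller cannot distinguish truly essential genes from
  genes required for good growth in the library-construction medium.
- The variant-selection rule is an approximation to undocumented
  annotation-server logic.
- Fitness values for genes with very low coverage are suppressed rather
  than shrunk; there is no variance model.
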