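"""Synthetic RB-TnSeq worlds with planted ground truth.

The generator emulates, at desk scale, the data-generating process behind
pooled barcoded-transposon fitness compendia: a bacterial genome with
per-gene GC variation; an insertion pool at realistic density with an
optional GC-dependent insertion bias and no central insertions in
essential genes; time0/condition BarSeq count pairs under a per-strain
exponential-growth model in which auxotrophs lose ~2^f-fold abundance in
defined media lacking their amino acid and are rescued when it is
supplied; and multi-resource annotation tables with planted pathway gaps.

Every operation is deterministic for a fixed seed, and all outputs carry a
ground-truth table so downstream recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from auxofill import media
from auxofill.gaps import PathwayDB, load_builtin_pathways

BASES = np.array(["A", "C", "G", "T"])
#: probability weights (AT split, GC split) as a function of gc fraction
_GC_WINDOW = 101  # nt window for local GC when biasing insertions


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def simulate_genome(
    n_genes: int,
    mean_gene_len: int = 900,
    gc_range: tuple[float, float] = (0.4, 0.65),
    intergenic_len: int = 100,
    seed: int = 0,
    genes_per_scaffold: int = 1000,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Simulate a genome and its gene models.

    Genes are non-overlapping, on alternating strands, separated by
    ``intergenic_len`` nt of 50%-GC sequence; one scaffold holds up to
    ``genes_per_scaffold`` genes.  Each gene draws an intended GC fraction
    uniformly from ``gc_range`` and its sequence composition realizes it.
    Gene lengths are normal around ``mean_gene_len`` (sd = mean/6,
    floor 300 nt).

    Returns the genome as ``{scaffold_id: sequence}`` and a gene table with
    columns gene_id, scaffold_id, begin, end, strand, desc, gc_intended
    (coordinates 1-based inclusive).
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    lo, hi = gc_range
    if not (0.0 < lo <= hi < 1.0):
        raise ValueError(f"invalid gc_range {gc_range}: need 0 < low <= high < 1")
    rng = np.random.default_rng(seed)
    genome: dict[str, str] = {}
    rows = []
    gene_idx = 0
    n_scaffolds = int(np.ceil(n_genes / genes_per_scaffold))
    for sc in range(n_scaffolds):
        sid = f"scaffold{sc + 1:02d}"
        parts: list[str] = []
        pos = 0  # 0-based running length
        n_here = min(genes_per_scaffold, n_genes - gene_idx)
        for _ in range(n_here):
            gene_idx += 1
            spacer = "".join(rng.choice(BASES, size=intergenic_len))
            parts.append(spacer)
            pos += intergenic_len
            length = max(300, int(round(rng.normal(mean_gene_len, mean_gene_len / 6))))
            gc = float(rng.uniform(lo, hi))
            p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
            seq = "".join(rng.choice(BASES, size=length, p=p))
            parts.append(seq)
            rows.append({
                "gene_id": f"g{gene_idx:05d}",
                "scaffold_id": sid,
                "begin": pos + 1,
                "end": pos + length,
                "strand": "+" if gene_idx % 2 == 1 else "-",
                "desc": "simulated protein-coding gene",
                "gc_intended": gc,
            })
            pos += length
        parts.append("".join(rng.choice(BASES, size=intergenic_len)))
        genome[sid] = "".join(parts)
    genes = pd.DataFrame(rows)
    return genome, genes


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def plant_truth(
    genes: pd.DataFrame,
    pathway_db: PathwayDB,
    frac_essential: float = 0.1,
    auxotroph_spec: dict[str, int] | None = None,
    effect_size: float = -4.0,
    redundant_amino_acids: list[str] | None = None,
    cover_pathway: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Assign ground-truth roles and fitness effects to genes.

    - ``frac_essential`` of genes become essential (their mutants never
      appear centrally in the pool, so they carry no fitness effect);
    - per amino acid in ``auxotroph_spec``, the requested number of genes
      become biosynthesis (auxotrophy) genes, each assigned to a
      non-transaminase reaction of that amino acid's first pathway
      variant: true fitness ``effect_size`` in defined media lacking the
      amino acid, 0 when it is supplied or the medium is rich;
    - per amino acid in ``redundant_amino_acids``, one extra pair of genes
      is annotated to a single shared reaction with true effect 0
      (genetic redundancy);
    - with ``cover_pathway``, every pathway reaction not yet assigned gets
      one neutral *cover* gene (role set, effect 0) so the emitted
      annotation tables are complete and gaps arise only from an explicit
      drop_spec — these model correctly annotated steps whose phenotype
      the growth model does not simulate;
    - all remaining genes are neutral (effect 0 everywhere).

    Returns a truth table with columns gene_id, essential, role (reaction
    id or empty), amino_acid, effect, redundancy_partner.
    """
    rng = np.random.default_rng(seed)
    auxotroph_spec = dict(auxotroph_spec or {})
    redundant_amino_acids = list(redundant_amino_acids or [])
    gene_ids = list(genes["gene_id"])
    n = len(gene_ids)
    n_essential = int(round(frac_essential * n))
    n_cover = len(set(pathway_db.steps_df["reaction_id"])) if cover_pathway else 0
    n_roles = sum(auxotroph_spec.values()) + 2 * len(redundant_amino_acids) + n_cover
    if n_essential + n_roles > n:
        raise ValueError(
            f"requested {n_essential} essential + {n_roles} role genes "
            f"but only {n} genes available")
    order = list(rng.permutation(gene_ids))
    essential = set(order[:n_essential])
    cursor = n_essential

    truth = pd.DataFrame({
        "gene_id": gene_ids,
        "essential": [g in essential for g in gene_ids],
        "role": "",
        "amino_acid": "",
        "effect": 0.0,
        "redundancy_partner": "",
    }).set_index("gene_id", drop=False)

    for aa, count in sorted(auxotroph_spec.items()):
        variants = pathway_db.variants(aa)
        if not variants:
            raise ValueError(f"amino acid {aa!r} not in pathway database")
        steps = [r for r in pathway_db.variant_steps(aa, variants[0])
                 if not pathway_db.is_transaminase(r)]
        for i in range(count):
            g = order[cursor]
            cursor += 1
            truth.loc[g, ["role", "amino_acid", "effect"]] = (
                steps[i % len(steps)], aa, float(effect_size))
    for aa in sorted(redundant_amino_acids):
        variants = pathway_db.variants(aa)
        if not variants:
            raise ValueError(f"amino acid {aa!r} not in pathway database")
        reaction = pathway_db.variant_steps(aa, variants[0])[0]
        g1, g2 = order[cursor], order[cursor + 1]
        cursor += 2
        truth.loc[g1, ["role", "amino_acid", "redundancy_partner"]] = (reaction, aa, g2)
        truth.loc[g2, ["role", "amino_acid", "redundancy_partner"]] = (reaction, aa, g1)
    if cover_pathway:
        assigned = set(truth.loc[truth["role"] != "", "role"])
        uncovered = sorted(set(pathway_db.steps_df["reaction_id"]) - assigned)
        for reaction in uncovered:
            g = order[cursor]
            cursor += 1
            truth.loc[g, "role"] = reaction
    return truth.reset_index(drop=True)


def true_effect(truth_row, exp) -> float:
    """The planted fitness effect of a gene's mutants in one experiment."""
    if not truth_row["amino_acid"] or truth_row["effect"] == 0:
        return 0.0
    if media.is_replete(exp):
        return 0.0
    if truth_row["amino_acid"] in media.supplemented_amino_acids(exp):
        return 0.0
    return float(truth_row["effect"])


# ---------------------------------------------------------------------------
# insertion pool
# ---------------------------------------------------------------------------

def _local_gc(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_gc = ((arr == ord("G")) | (arr == ord("C"))).astype(float)
    kernel = np.ones(_GC_WINDOW) / _GC_WINDOW
    # same-length smoothed GC; edges shrink toward the interior values
    return np.convolve(is_gc, kernel, mode="same")


def _random_barcodes(rng: np.random.Generator, n: int, length: int = 20) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        codes = rng.integers(0, 4, size=(n - len(out), length))
        for row in codes:
            bc = "".join(BASES[row])
            if bc not in seen:
                seen.add(bc)
                out.append(bc)
    return out


def simulate_pool(
    genome: dict[str, str],
    genes: pd.DataFrame,
    truth: pd.DataFrame,
    target_strains: int = 10_000,
    gc_bias_slope: float = 0.0,
    seed: int = 0,
    weight_floor: float = 0.05,
) -> pd.DataFrame:
    """Simulate a barcoded insertion pool.

    Insertion positions are drawn with probability proportional to
    ``max(weight_floor, 1 + gc_bias_slope * (localGC - 0.5))`` (local GC
    over a 101-nt window).  No insertion lands in the central 10-90% of an
    essential gene; each strain gets a unique random 20-nt barcode and a
    mapping-read support of at least 2 reads.
    """
    if target_strains < 1:
        raise ValueError("target_strains must be >= 1")
    rng = np.random.default_rng(seed)
    ess = truth.loc[truth["essential"], "gene_id"]
    ess_genes = genes[genes["gene_id"].isin(set(ess))]

    scaffold_ids = sorted(genome)
    weights = []
    for sid in scaffold_ids:
        seq = genome[sid]
        w = np.maximum(weight_floor, 1.0 + gc_bias_slope * (_local_gc(seq) - 0.5))
        for row in ess_genes[ess_genes["scaffold_id"] == sid].itertuples():
            length = row.end - row.begin + 1
            # positions whose central fraction falls in [0.1, 0.9]
            lo = row.begin + int(np.ceil(0.1 * length - 0.5)) - 1
            hi = row.begin + int(np.floor(0.9 * length - 0.5))
            w[max(lo, 0):hi] = 0.0
        weights.append(w)
    lengths = np.array([len(genome[s]) for s in scaffold_ids])
    allw = np.concatenate(weights)
    allw = allw / allw.sum()
    flat = rng.choice(len(allw), size=target_strains, replace=True, p=allw)
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    sc_idx = np.searchsorted(offsets, flat, side="right") - 1
    positions = flat - offsets[sc_idx] + 1  # 1-based
    strands = np.where(rng.random(target_strains) < 0.5, "+", "-")
    n_reads = 2 + rng.poisson(10, size=target_strains)
    pool = pd.DataFrame({
        "barcode": _random_barcodes(rng, target_strains),
        "scaffold_id": [scaffold_ids[i] for i in sc_idx],
        "position": positions.astype(int),
        "strand": strands,
        "n_reads": n_reads.astype(int),
    })
    return pool


# ---------------------------------------------------------------------------
# experiment design and counts
# ---------------------------------------------------------------------------

def default_experiments(
    amino_acids: list[str],
    carbon_sources: list[str] = ("glucose", "succinate", "acetate", "pyruvate"),
    reps: int = 2,
    supplement_mM: float = 1.0,
    generations: float = 6.0,
    seed: int = 0,
) -> pd.DataFrame:
    """A default experiment design mirroring a small fitness compendium.

    Per replicate: one defined-minimal experiment per carbon source, one
    defined + single amino acid experiment per amino acid in
    ``amino_acids``, and one rich-media (LB) experiment.  Each replicate
    shares one time0 sample.  Generations are drawn uniformly in [4, 8]
    around the requested default.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for r in range(1, reps + 1):
        t0 = f"T0_r{r}"
        def add(exp_id, media_class, supplements, carbon, group):
            rows.append({
                "exp_id": exp_id, "media_class": media_class,
                "supplements": supplements, "carbon_source": carbon,
                "nitrogen_source": "ammonia", "replicate_group": group,
                "time0_id": t0,
                "generations": float(rng.uniform(4, 8)) if generations is None
                else float(generations),
            })
        for c in carbon_sources:
            add(f"defined_{c}_r{r}", "defined", "", c, f"defined_{c}")
        for aa in amino_acids:
            add(f"defined_glucose_plus_{aa}_r{r}", "defined",
                media.format_supplements({aa: supplement_mM}), "glucose",
                f"defined_plus_{aa}")
        add(f"rich_LB_r{r}", "rich", "", "LB", "rich_LB")
    return pd.DataFrame(rows)


def simulate_counts(
    pool: pd.DataFrame,
    genes: pd.DataFrame,
    truth: pd.DataFrame,
    experiments: pd.DataFrame,
    mean_depth_per_strain: float = 50.0,
    seed: int = 0,
    sigma_log2: float = 0.5,
    overdispersion: float = 0.0,
) -> pd.DataFrame:
    """Simulate BarSeq counts for time0 and condition samples.

    Time0 strain abundances are log-normal (sd ``sigma_log2`` in log2
    units).  A condition sample's strain abundance is its time0 abundance
    times ``2**(g + f)`` where ``g`` is the experiment's generations and
    ``f`` the gene's true per-condition effect (0 for neutral strains and
    intergenic insertions).  Counts are Poisson around abundances scaled
    to ``mean_depth_per_strain``; with ``overdispersion`` alpha > 0 they
    are gamma-Poisson (negative binomial) with variance mu + alpha*mu^2.

    Returns a barcode x sample count table whose columns are all time0 ids
    followed by all experiment ids.
    """
    if experiments.empty:
        raise ValueError("experiments table is empty")
    if mean_depth_per_strain <= 0:
        raise ValueError("mean_depth_per_strain must be > 0")
    rng = np.random.default_rng(seed)
    from auxofill.fitness import assign_genes  # shared gene-assignment logic

    pool = assign_genes(pool, genes)
    truth_idx = truth.set_index("gene_id")
    n = len(pool)

    # per-strain true effect per experiment; only role genes can be nonzero
    effects = np.zeros((n, len(experiments)))
    gene_ids = pool["gene_id"].fillna("").to_numpy()
    role_rows = truth_idx[(truth_idx["amino_acid"] != "") & (truth_idx["effect"] != 0)]
    for j, (_, exp) in enumerate(experiments.iterrows()):
        for g, row in role_rows.iterrows():
            f = true_effect(row, exp)
            if f != 0.0:
                effects[gene_ids == g, j] = f

    t0_ids = list(dict.fromkeys(experiments["time0_id"]))
    missing = set(experiments["time0_id"]) - set(t0_ids)
    assert not missing
    counts = pd.DataFrame(index=pool["barcode"], columns=t0_ids + list(experiments["exp_id"]),
                          dtype=float)

    def draw(mu: np.ndarray) -> np.ndarray:
        if overdispersion > 0:
            shape = 1.0 / overdispersion
            mu = rng.gamma(shape, mu / shape)
        return rng.poisson(mu)

    total = n * mean_depth_per_strain
    a0_by_t0: dict[str, np.ndarray] = {}
    for t0 in t0_ids:
        a0 = np.exp2(rng.normal(0.0, sigma_log2, size=n))
        a0_by_t0[t0] = a0
        counts[t0] = draw(a0 / a0.sum() * total)
    for j, (_, exp) in enumerate(experiments.iterrows()):
        a0 = a0_by_t0[exp["time0_id"]]
        a = a0 * np.exp2(exp["generations"] + effects[:, j])
        counts[exp["exp_id"]] = draw(a / a.sum() * total)
    return counts.astype(int)


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def simulate_annotations(
    truth: pd.DataFrame,
    pathway_db: PathwayDB,
    n_resources: int = 3,
    drop_spec: list[tuple[str, list[str]]] | None = None,
    baseline_resource: str = "baseline",
    seed: int = 0,
) -> pd.DataFrame:
    """Emit baseline + ``n_resources`` annotation tables from the truth.

    Every role gene is annotated with its reaction by the baseline and by
    each voting resource, except where ``drop_spec`` removes a reaction
    from specific resources: entries are ``(reaction_id, [resource, ...])``
    where ``"baseline"`` names the baseline resource.  Dropping a reaction
    from the baseline plants a gap; additionally dropping it from voting
    resources weakens or removes the clear candidate.  Neutral genes get
    no pathway annotations.
    """
    if n_resources < 3:
        raise ValueError("need n_resources >= 3")
    drop_spec = drop_spec or []
    for reaction, _ in drop_spec:
        if not pathway_db.has_reaction(reaction):
            raise ValueError(f"drop_spec names unknown reaction {reaction!r}")
    resources = [f"res{i + 1}" for i in range(n_resources)]
    dropped: dict[str, set[str]] = {}
    for reaction, missing_in in drop_spec:
        names = {baseline_resource if m == "baseline" else m for m in missing_in}
        unknown = names - set(resources) - {baseline_resource}
        if unknown:
            raise ValueError(f"drop_spec names unknown resources {sorted(unknown)}")
        dropped.setdefault(reaction, set()).update(names)
    rows = []
    role_genes = truth[truth["role"] != ""]
    for row in role_genes.itertuples():
        for res in [baseline_resource] + resources:
            if res in dropped.get(row.role, ()):  # planted miss
                continue
            rows.append({"gene_id": row.gene_id, "resource_id": res,
                         "reaction_id": row.role})
    return pd.DataFrame(rows, columns=["gene_id", "resource_id", "reaction_id"])


# ---------------------------------------------------------------------------
# whole worlds
# ---------------------------------------------------------------------------

@dataclass
class World:
    """A complete synthetic study: inputs plus planted ground truth."""

    genome: dict[str, str]
    genes: pd.DataFrame
    truth: pd.DataFrame
    pool: pd.DataFrame
    experiments: pd.DataFrame
    counts: pd.DataFrame
    annotations: pd.DataFrame
    pathway_db: PathwayDB
    baseline_resource: str = "baseline"
    resources: list[str] = field(default_factory=lambda: ["res1", "res2", "res3"])


def simulate_world(
    n_genes: int = 500,
    frac_essential: float = 0.1,
    auxotroph_spec: dict[str, int] | None = None,
    effect_size: float = -4.0,
    redundant_amino_acids: list[str] | None = None,
    target_strains: int = 10_000,
    gc_bias_slope: float = 0.0,
    mean_depth_per_strain: float = 50.0,
    drop_spec: list[tuple[str, list[str]]] | None = None,
    gc_range: tuple[float, float] = (0.4, 0.65),
    reps: int = 2,
    seed: int = 0,
    pathway_db: PathwayDB | None = None,
) -> World:
    """Build a default synthetic world, end to end.

    The defaults define the reference study conditions used throughout the
    test suite: 500 genes, 10% essential, three auxotrophy genes each for
    histidine, methionine and serine with a true defect of -4 in defined
    media, ~20 insertion strains per gene, 50 reads/strain of BarSeq
    depth, and a two-replicate compendium of defined, single-supplement
    and rich experiments.
    """
    if auxotroph_spec is None:
        auxotroph_spec = {"his": 3, "met": 3, "ser": 3}
    pathway_db = pathway_db or load_builtin_pathways()
    rng = np.random.default_rng(seed)
    s_genome, s_truth, s_pool, s_counts, s_exps = rng.integers(0, 2**31 - 1, size=5)
    genome, genes = simulate_genome(n_genes, gc_range=gc_range, seed=int(s_genome))
    truth = plant_truth(
        genes, pathway_db, frac_essential=frac_essential,
        auxotroph_spec=auxotroph_spec, effect_size=effect_size,
        redundant_amino_acids=redundant_amino_acids, cover_pathway=True,
        seed=int(s_truth))
    pool = simulate_pool(genome, genes, truth, target_strains=target_strains,
                         gc_bias_slope=gc_bias_slope, seed=int(s_pool))
    experiments = default_experiments(sorted(auxotroph_spec), reps=reps,
                                      seed=int(s_exps))
    counts = simulate_counts(pool, genes, truth, experiments,
                             mean_depth_per_strain=mean_depth_per_strain,
                             seed=int(s_counts))
    annotations = simulate_annotations(truth, pathway_db, drop_spec=drop_spec)
    return World(genome=genome, genes=genes, truth=truth, pool=pool,
                 experiments=experiments, counts=counts,
                 annotations=annotations, pathway_db=pathway_db)
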