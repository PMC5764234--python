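"""Gap classification from fitness and essentiality evidence.

Each enumerated gap ends up in exactly one category of a ledger:

==================  ======================  =============================
group               subgroup                meaning
==================  ======================  =============================
Clear candidate     multiple candidates     >= 2 clear candidates, none
                                            with a phenotype (possible
                                            genetic redundancy)
Clear candidate     auxotrophic             candidate important for
                                            fitness in most defined media
                                            and rescued by amino acids
Clear candidate     essential               candidate putatively
                                            essential in rich media
Clear candidate     no fitness data         insufficient mutant coverage
Clear candidate     other (redundant)       no phenotype; another gene is
                                            annotated to the reaction
Clear candidate     other                   no phenotype, unexplained
Gene model error                            curated sequencing/gene-call
                                            error
Transaminase                                promiscuous transaminase step
Known gap                                   filled in the literature but
                                            not the databases
Genuine gap         filled (this study)     rescue scan proposes a gene
Genuine gap         unfilled                no proposal
==================  ======================  =============================

Phenotype calls use the convention that gene fitness under -2 is a strong
growth defect and values within +-0.5 of zero are no phenotype; the
amino-acid rescue scan uses strict inequalities (mean fitness *under* -2
in minimal media and *above* -1 with the supplement).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources as _resources

import numpy as np
import pandas as pd

from auxofill import media
from auxofill.fitness import average_replicates
from auxofill.gaps import CLASSIFICATIONS, CLASS_CODES, GapRecord, PathwayDB

DEFAULT_T_DEFECT = -2.0
DEFAULT_T_NEUTRAL = -0.5
DEFAULT_FRAC_DEFINED = 0.5
DEFAULT_RESCUE_LOW = -2.0
DEFAULT_RESCUE_HIGH = -1.0

#: classification -> (group, subgroup) in the summary ledger
GROUP_SUBGROUP = {
    "clear_multiple": ("Clear candidate", "multiple candidates"),
    "clear_auxotrophic": ("Clear candidate", "auxotrophic"),
    "clear_essential": ("Clear candidate", "essential"),
    "clear_nodata": ("Clear candidate", "no fitness data"),
    "clear_redundant": ("Clear candidate", "other (redundant)"),
    "clear_other": ("Clear candidate", "other"),
    "gene_model_error": ("Gene model error", ""),
    "transaminase": ("Transaminase", ""),
    "known": ("Known gap", ""),
    "genuine_filled": ("Genuine gap", "filled (this study)"),
    "genuine_unfilled": ("Genuine gap", "unfilled"),
}
_CLASS_OF_GROUP = {v: k for k, v in GROUP_SUBGROUP.items()}


@dataclass
class PhenotypeCall:
    """Fitness-based phenotype of one gene."""

    gene_id: str
    label: str  # auxotrophic | essential | no_data | no_phenotype
    median_defined: float
    median_replete: float
    n_defined: int
    n_replete: int


def partition_experiments(experiments: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Split experiment ids into (defined-minimal, amino-acid-replete).

    Defined-minimal experiments have a defined medium and no amino-acid
    supplement of any kind; replete experiments are rich media or carry
    casamino acids / yeast extract.  Experiments supplemented with single
    amino acids belong to neither set (they feed the rescue scan).
    """
    defined = [e["exp_id"] for _, e in experiments.iterrows()
               if media.is_defined_minimal(e)]
    replete = [e["exp_id"] for _, e in experiments.iterrows() if media.is_replete(e)]
    return defined, replete


def phenotype_call(
    gene_id: str,
    fit: pd.DataFrame,
    experiments: pd.DataFrame,
    essentials: set[str],
    t_defect: float = DEFAULT_T_DEFECT,
    t_neutral: float = DEFAULT_T_NEUTRAL,
    frac_defined: float = DEFAULT_FRAC_DEFINED,
) -> PhenotypeCall:
    """Classify one gene as auxotrophic / essential / no_data / no_phenotype.

    Membership in the essential set takes precedence.  Otherwise the gene
    is ``no_data`` when it lacks fitness values in at least half of the
    defined-minimal experiments; ``auxotrophic`` when its fitness is at
    most ``t_defect`` in at least ``frac_defined`` of the defined-minimal
    experiments with data *and* its median amino-acid-replete fitness is
    at least ``t_neutral`` (no replete data counts as unopposed);
    ``no_phenotype`` otherwise.
    """
    defined_ids, replete_ids = partition_experiments(experiments)
    if not defined_ids:
        raise ValueError("no defined-minimal experiments in the metadata")
    if gene_id in fit.index:
        d = fit.loc[gene_id, defined_ids].astype(float)
        r = fit.loc[gene_id, replete_ids].astype(float) if replete_ids else pd.Series(dtype=float)
    else:
        d = pd.Series(np.nan, index=defined_ids)
        r = pd.Series(dtype=float)
    n_def, n_rep = int(d.notna().sum()), int(r.notna().sum())
    med_def = float(d.median()) if n_def else np.nan
    med_rep = float(r.median()) if n_rep else np.nan
    if gene_id in essentials:
        label = "essential"
    elif len(defined_ids) - n_def >= 0.5 * len(defined_ids):
        label = "no_data"
    else:
        strong = (d.dropna() <= t_defect).mean() >= frac_defined
        rescued = np.isnan(med_rep) or med_rep >= t_neutral
        label = "auxotrophic" if (strong and rescued) else "no_phenotype"
    return PhenotypeCall(gene_id, label, med_def, med_rep, n_def, n_rep)


def phenotype_calls(
    fit: pd.DataFrame,
    experiments: pd.DataFrame,
    essentials: set[str],
    **kwargs,
) -> dict[str, PhenotypeCall]:
    genes = list(dict.fromkeys(list(fit.index) + sorted(essentials)))
    return {g: phenotype_call(g, fit, experiments, essentials, **kwargs)
            for g in genes}


@dataclass
class RescueResult:
    """Fitness of one gene with and without one supplement."""

    gene_id: str
    compound: str
    fitness_minimal: float
    fitness_supplemented: float
    rescued: bool


def rescue_scan(
    fit: pd.DataFrame,
    experiments: pd.DataFrame,
    compound: str,
    f_low: float = DEFAULT_RESCUE_LOW,
    f_high: float = DEFAULT_RESCUE_HIGH,
) -> list[RescueResult]:
    """Genome-wide scan for genes whose mutants a supplement rescues.

    Fitness is first averaged within replicate groups; a gene is rescued
    iff its mean defined-minimal fitness is strictly under ``f_low`` and
    its mean fitness with the supplement is strictly above ``f_high``.
    Returns every gene with both means defined, strongest rescue
    (supplemented minus minimal fitness) first.
    """
    has_compound = [e["exp_id"] for _, e in experiments.iterrows()
                    if compound in media.parse_supplements(e.get("supplements", ""))]
    if not has_compound:
        raise ValueError(f"no experiment is supplemented with {compound!r}")
    defined_ids, _ = partition_experiments(experiments)
    if not defined_ids:
        raise ValueError("no defined-minimal experiments in the metadata")
    repfit = average_replicates(fit, experiments)
    groups = experiments.set_index("exp_id")["replicate_group"]
    minimal_groups = sorted(set(groups[defined_ids]))
    supp_groups = sorted(set(groups[has_compound]))
    f_min = repfit[minimal_groups].mean(axis=1)
    f_sup = repfit[supp_groups].mean(axis=1)
    out = []
    for g in fit.index:
        a, b = f_min.get(g, np.nan), f_sup.get(g, np.nan)
        if np.isnan(a) or np.isnan(b):
            continue
        out.append(RescueResult(g, compound, float(a), float(b),
                                bool(a < f_low and b > f_high)))
    out.sort(key=lambda r: (-(r.fitness_supplemented - r.fitness_minimal), r.gene_id))
    return out


def classify_gap(
    gap: GapRecord,
    calls: dict[str, PhenotypeCall],
    rescue_by_amino_acid: dict[str, list[RescueResult]],
    annotations: pd.DataFrame,
    pathway_db: PathwayDB,
) -> GapRecord:
    """Assign the final classification to one gap.

    Curated classes set by :func:`auxofill.gaps.flag_special` are kept.
    With clear candidates: two or more clear candidates none of which is
    auxotrophic or essential indicates possible redundancy among them
    (``clear_multiple``); otherwise the best candidate's phenotype decides
    (``clear_auxotrophic`` / ``clear_essential`` / ``clear_nodata``), and
    a candidate without phenotype is ``clear_redundant`` when another gene
    is also annotated with the gap's reaction, else ``clear_other``.
    Without a clear candidate the gap is genuine: ``genuine_filled`` by
    the strongest rescued gene for the gap's amino acid that is not
    already annotated to another step of that pathway, else
    ``genuine_unfilled``.
    """
    if gap.classification not in ("unclassified",):
        return gap
    clear = gap.clear_candidate_genes
    if clear:
        labels = {g: calls[g].label if g in calls else "no_data" for g in clear}
        with_phen = [g for g in clear if labels[g] in ("auxotrophic", "essential")]
        if len(clear) >= 2 and not with_phen:
            gap.classification = "clear_multiple"
            return gap
        best = with_phen[0] if with_phen else clear[0]
        label = labels[best]
        if label == "auxotrophic":
            gap.classification = "clear_auxotrophic"
        elif label == "essential":
            gap.classification = "clear_essential"
        elif label == "no_data":
            gap.classification = "clear_nodata"
        else:  # no_phenotype: redundant if someone else covers the reaction
            others = annotations[
                (annotations["reaction_id"] == gap.reaction_id)
                & (annotations["gene_id"] != best)
            ]
            gap.classification = ("clear_redundant" if len(others)
                                  else "clear_other")
        return gap
    # genuine gap: can the rescue scan fill it?
    pathway_steps = pathway_db.all_steps(gap.amino_acid) - {gap.reaction_id}
    assigned_elsewhere = set(
        annotations.loc[annotations["reaction_id"].isin(pathway_steps), "gene_id"])
    for res in rescue_by_amino_acid.get(gap.amino_acid, []):
        if res.rescued and res.gene_id not in assigned_elsewhere:
            gap.classification = "genuine_filled"
            gap.filled_by = res.gene_id
            return gap
    gap.classification = "genuine_unfilled"
    return gap


def classify_all(
    gap_list: list[GapRecord],
    calls: dict[str, PhenotypeCall],
    fit: pd.DataFrame,
    experiments: pd.DataFrame,
    annotations: pd.DataFrame,
    pathway_db: PathwayDB,
    f_low: float = DEFAULT_RESCUE_LOW,
    f_high: float = DEFAULT_RESCUE_HIGH,
) -> list[GapRecord]:
    """Classify every gap, running one rescue scan per gap amino acid."""
    rescue_by_aa: dict[str, list[RescueResult]] = {}
    for gap in gap_list:
        aa = gap.amino_acid
        if aa in rescue_by_aa or gap.clear_candidate_genes:
            continue
        try:
            rescue_by_aa[aa] = rescue_scan(fit, experiments, aa,
                                           f_low=f_low, f_high=f_high)
        except ValueError:  # amino acid never supplemented: cannot scan
            rescue_by_aa[aa] = []
    return [classify_gap(g, calls, rescue_by_aa, annotations, pathway_db)
            for g in gap_list]


# ---------------------------------------------------------------------------
# ledger summaries
# ---------------------------------------------------------------------------

def summarize_ledger(gap_list: list[GapRecord]) -> pd.DataFrame:
    """Tabulate classified gaps into (group, subgroup, cases) rows.

    Rows appear in canonical ledger order; zero-count categories are
    omitted.  Raises if any gap is unclassified, listing the offenders.
    """
    bad = [g for g in gap_list if g.classification == "unclassified"]
    if bad:
        names = ", ".join(f"{g.organism}/{g.amino_acid}/{g.reaction_id}" for g in bad)
        raise ValueError(f"unclassified gaps: {names}")
    counts: dict[str, int] = {}
    for g in gap_list:
        counts[g.classification] = counts.get(g.classification, 0) + 1
    rows = []
    for cls in CLASSIFICATIONS:
        if counts.get(cls):
            group, subgroup = GROUP_SUBGROUP[cls]
            rows.append({"group": group, "subgroup": subgroup,
                         "cases": counts[cls]})
    return pd.DataFrame(rows, columns=["group", "subgroup", "cases"])


def ledger_grid(
    gap_list: list[GapRecord],
    organisms: list[str] | None = None,
    amino_acids: list[str] | None = None,
) -> pd.DataFrame:
    """Compact organism x amino-acid grid of classification codes.

    Each cell concatenates one single-letter code per gap, with counts for
    repeats (two clear-candidate gaps render as ``c2``); amino acids with
    no gap render as an empty cell (prototroph).
    """
    organisms = organisms or sorted({g.organism for g in gap_list})
    amino_acids = amino_acids or media.AMINO_ACIDS
    grid = pd.DataFrame("", index=pd.Index(organisms, name="organism"),
                        columns=amino_acids)
    cell: dict[tuple[str, str], list[str]] = {}
    for g in gap_list:
        cell.setdefault((g.organism, g.amino_acid), []).append(g.code)
    for (org, aa), codes in cell.items():
        if aa not in grid.columns or org not in grid.index:
            continue
        parts = []
        for code in sorted(set(codes)):
            k = codes.count(code)
            parts.append(code if k == 1 else f"{code}{k}")
        grid.loc[org, aa] = "".join(parts)
    return grid


def load_reference_ledger() -> pd.DataFrame:
    """The packaged published gap-classification ledger.

    A transcription of the published survey of 173 amino-acid biosynthesis
    gaps across 10 heterotrophic bacteria, as (group, subgroup, cases).
    """
    path = _resources.files("auxofill") / "data" / "gap_ledger_10bacteria.tsv"
    df = pd.read_csv(str(path), sep="\t", keep_default_na=False)
    df["cases"] = df["cases"].astype(int)
    return df


def expand_summary(summary: pd.DataFrame) -> list[GapRecord]:
    """Inverse of :func:`summarize_ledger`: synthesize one classified gap
    record per counted case (placeholder organisms and reactions)."""
    out = []
    i = 0
    for row in summary.itertuples():
        cls = _CLASS_OF_GROUP[(row.group, row.subgroup)]
        for _ in range(int(row.cases)):
            i += 1
            out.append(GapRecord(organism="org", amino_acid="unk",
                                 reaction_id=f"R{i:04d}", variant_id="v1",
                                 classification=cls))
    return out
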