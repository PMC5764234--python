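"""Pathway gap enumeration and annotation-consensus candidate calling.

A *gap* is a reaction required for the biosynthesis of an amino acid for
which the baseline annotation resource assigns no gene.  Candidate genes
for a gap are drawn from independent annotation resources; a gene becomes
a *clear candidate* when at least two non-baseline resources annotate it
with the missing enzymatic capability.

Annotation tables are DataFrames with columns ``gene_id``, ``resource_id``,
``reaction_id``.  One designated *baseline* resource plays the role of the
automated prediction whose gaps are being audited; the remaining resources
vote on candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources as _resources

import pandas as pd

#: final classifications, in ledger order
CLASSIFICATIONS = [
    "clear_multiple", "clear_auxotrophic", "clear_essential", "clear_nodata",
    "clear_redundant", "clear_other", "gene_model_error", "transaminase",
    "known", "genuine_filled", "genuine_unfilled", "unclassified",
]

#: single-letter codes for compact per-organism grids
CLASS_CODES = {
    "clear_multiple": "c", "clear_auxotrophic": "c", "clear_essential": "c",
    "clear_nodata": "c", "clear_redundant": "c", "clear_other": "c",
    "gene_model_error": "g", "transaminase": "t", "known": "k",
    "genuine_filled": "f", "genuine_unfilled": "u", "unclassified": "?",
}


class PathwayDB:
    """Reaction requirements per amino acid, with pathway variants.

    Parameters
    ----------
    steps : DataFrame with columns amino_acid, variant_id, step_index,
        reaction_id; every (amino_acid, variant_id) needs >= 1 step.
    reactions : DataFrame with columns reaction_id, name, is_transaminase.
    """

    def __init__(self, steps: pd.DataFrame, reactions: pd.DataFrame):
        steps = steps.copy()
        steps["step_index"] = steps["step_index"].astype(int)
        reactions = reactions.copy()
        if reactions["is_transaminase"].dtype == object:
            reactions["is_transaminase"] = reactions["is_transaminase"].map(
                lambda v: str(v).strip().lower() in {"true", "1", "yes"})
        self.steps_df = steps
        self.reactions = reactions.set_index("reaction_id", drop=False)
        unknown = set(steps["reaction_id"]) - set(self.reactions.index)
        if unknown:
            raise ValueError(f"steps reference unknown reactions: {sorted(unknown)}")

    def amino_acids(self) -> list[str]:
        return sorted(self.steps_df["amino_acid"].unique())

    def variants(self, amino_acid: str) -> list[str]:
        sub = self.steps_df[self.steps_df["amino_acid"] == amino_acid]
        return sorted(sub["variant_id"].unique())

    def variant_steps(self, amino_acid: str, variant_id: str) -> list[str]:
        sub = self.steps_df[
            (self.steps_df["amino_acid"] == amino_acid)
            & (self.steps_df["variant_id"] == variant_id)
        ].sort_values("step_index")
        return list(sub["reaction_id"])

    def all_steps(self, amino_acid: str) -> set[str]:
        sub = self.steps_df[self.steps_df["amino_acid"] == amino_acid]
        return set(sub["reaction_id"])

    def is_transaminase(self, reaction_id: str) -> bool:
        return bool(self.reactions.loc[reaction_id, "is_transaminase"])

    def shared_with(self, reaction_id: str) -> list[str]:
        """Amino acids whose biosynthesis uses this reaction."""
        sub = self.steps_df[self.steps_df["reaction_id"] == reaction_id]
        return sorted(sub["amino_acid"].unique())

    def has_reaction(self, reaction_id: str) -> bool:
        return reaction_id in self.reactions.index


def load_builtin_pathways() -> PathwayDB:
    """Packaged pathway definitions for his, met, thr and ser.

    Histidine, methionine, threonine and serine are the amino acids whose
    biosynthesis most often hides behind annotation gaps in heterotrophic
    Proteobacteria; methionine carries two variants (the succinylated
    homoserine route and direct reductive sulfuration of aspartate
    semialdehyde).  A full 20-amino-acid curated database is user-supplied.
    """
    base = _resources.files("auxofill") / "data"
    steps = pd.read_csv(str(base / "pathways.tsv"), sep="\t", dtype=str)
    reactions = pd.read_csv(str(base / "reactions.tsv"), sep="\t", dtype=str)
    return PathwayDB(steps, reactions)


@dataclass
class GapRecord:
    """One putatively missing reaction in one organism's pathway."""

    organism: str
    amino_acid: str
    reaction_id: str
    variant_id: str
    candidates: list[tuple[str, int]] = field(default_factory=list)
    classification: str = "unclassified"
    filled_by: str | None = None

    @property
    def clear_candidate_genes(self) -> list[str]:
        return [g for g, s in self.candidates if s >= 2]

    @property
    def code(self) -> str:
        return CLASS_CODES[self.classification]


def predict_status(
    pathway_db: PathwayDB,
    annotations: pd.DataFrame,
    baseline_resource: str,
    organism: str = "org",
    amino_acids: list[str] | None = None,
    status_overrides: dict[str, str] | None = None,
) -> tuple[dict[str, str], list[GapRecord]]:
    """Predict prototrophy per amino acid from the baseline annotation.

    For each amino acid the pathway variant with the fewest missing steps
    is selected (ties broken by lexicographically smallest variant id);
    its missing steps become gaps.  An amino acid with zero gaps is called
    ``prototroph``, otherwise ``auxotroph_predicted``.  A reaction shared
    by several amino acids yields one :class:`GapRecord` per amino acid.

    ``status_overrides`` maps amino acid -> forced status string (e.g.
    ``"no_prediction"``) for baselines that decline to predict either way;
    overridden amino acids contribute no gaps.
    """
    base = annotations[annotations["resource_id"] == baseline_resource]
    covered = set(base["reaction_id"])
    status: dict[str, str] = {}
    gap_list: list[GapRecord] = []
    overrides = status_overrides or {}
    for aa in amino_acids or pathway_db.amino_acids():
        if aa in overrides:
            status[aa] = overrides[aa]
            continue
        variants = pathway_db.variants(aa)
        if not variants:
            status[aa] = "no_definition"
            continue
        best_variant, best_missing = None, None
        for var in variants:  # sorted -> lexicographic tie-break
            steps = pathway_db.variant_steps(aa, var)
            missing = [r for r in steps if r not in covered]
            if best_missing is None or len(missing) < len(best_missing):
                best_variant, best_missing = var, missing
        status[aa] = "prototroph" if not best_missing else "auxotroph_predicted"
        for reaction in best_missing:
            gap_list.append(GapRecord(organism, aa, reaction, best_variant))
    return status, gap_list


def clear_candidates(
    gap: GapRecord,
    annotations: pd.DataFrame,
    resources: list[str],
) -> GapRecord:
    """Attach candidate genes to a gap by annotation-resource consensus.

    Support is the number of non-baseline ``resources`` annotating a gene
    with the gap's reaction; support >= 2 makes a clear candidate.  All
    genes with support >= 1 are recorded, sorted by descending support
    then gene id.
    """
    if len(resources) < 3:
        raise ValueError("need >= 3 non-baseline annotation resources")
    sub = annotations[
        annotations["resource_id"].isin(resources)
        & (annotations["reaction_id"] == gap.reaction_id)
    ]
    support = sub.groupby("gene_id")["resource_id"].nunique()
    gap.candidates = sorted(
        ((g, int(s)) for g, s in support.items()),
        key=lambda gs: (-gs[1], gs[0]),
    )
    return gap


def flag_special(
    gap: GapRecord,
    curated_known: list[tuple[str, str]] | None = None,
    curated_gene_model_errors: list[tuple[str, str]] | None = None,
    pathway_db: PathwayDB | None = None,
) -> GapRecord:
    """Apply curated pre-classifications that preempt fitness evidence.

    Precedence: gene model error > transaminase > known.  Transaminase
    reactions are exempted because amino-acid transaminases are typically
    promiscuous, so their apparent absence is no evidence of auxotrophy.
    """
    key = (gap.organism, gap.reaction_id)
    if curated_gene_model_errors and key in set(curated_gene_model_errors):
        gap.classification = "gene_model_error"
    elif pathway_db is not None and pathway_db.is_transaminase(gap.reaction_id):
        gap.classification = "transaminase"
    elif curated_known and key in set(curated_known):
        gap.classification = "known"
    return gap


def write_gaps(gaps: list[GapRecord], path: str) -> None:
    rows = []
    for g in gaps:
        rows.append({
            "organism": g.organism,
            "amino_acid": g.amino_acid,
            "reaction_id": g.reaction_id,
            "variant_id": g.variant_id,
            "candidates": ",".join(f"{gene}:{s}" for gene, s in g.candidates),
            "classification": g.classification,
            "filled_by": g.filled_by or "",
        })
    pd.DataFrame(
        rows,
        columns=["organism", "amino_acid", "reaction_id", "variant_id",
                 "candidates", "classification", "filled_by"],
    ).to_csv(path, sep="\t", index=False)


def read_gaps(path: str) -> list[GapRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)
    out = []
    for row in df.itertuples():
        cands = []
        if row.candidates:
            for item in row.candidates.split(","):
                gene, s = item.rsplit(":", 1)
                cands.append((gene, int(s)))
        out.append(GapRecord(
            organism=row.organism,
            amino_acid=row.amino_acid,
            reaction_id=row.reaction_id,
            variant_id=row.variant_id,
            candidates=cands,
            classification=row.classification,
            filled_by=row.filled_by or None,
        ))
    return out
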