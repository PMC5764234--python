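"""Cofitness and phylogenetic-profile concordance.

Cofitness is the Pearson correlation of two genes' fitness profiles
across many experiments; genes acting in the same pathway tend to have
highly correlated profiles.  Missing values are handled pairwise-complete
(each pair's n is the number of experiments where both genes have
values), and correlations over fewer than ``min_experiments`` experiments
are treated as undefined because small-n correlations are noise.

A phylogenetic profile is the presence/absence pattern of a protein
family across a fixed, ordered list of genomes; near-identical profiles
of two families suggest a close functional relationship.  Manual
overrides (e.g. a protein known to be present as a split gene) are
applied before comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_MIN_EXPERIMENTS = 15


@dataclass
class CofitRecord:
    gene_a: str
    gene_b: str
    r: float
    n: int


def cofitness(
    fit: pd.DataFrame,
    gene_a: str,
    gene_b: str,
    min_experiments: int = DEFAULT_MIN_EXPERIMENTS,
) -> CofitRecord | None:
    """Pearson correlation of two genes' fitness profiles.

    Returns None when fewer than ``min_experiments`` experiments have
    values for both genes, or when either profile has zero variance.
    """
    for g in (gene_a, gene_b):
        if g not in fit.index:
            raise KeyError(f"unknown gene {g!r}")
    a = fit.loc[gene_a].astype(float)
    b = fit.loc[gene_b].astype(float)
    ok = a.notna() & b.notna()
    n = int(ok.sum())
    if n < min_experiments:
        return None
    x, y = a[ok].to_numpy(), b[ok].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    r = float(np.corrcoef(x, y)[0, 1])
    return CofitRecord(gene_a, gene_b, r, n)


def top_cofit(
    fit: pd.DataFrame,
    gene: str,
    k: int = 10,
    min_experiments: int = DEFAULT_MIN_EXPERIMENTS,
) -> list[CofitRecord]:
    """The k genes most cofit with ``gene`` (self excluded).

    Only defined records are returned (the list may be shorter than k);
    ties in r break by gene id.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    records = []
    for other in fit.index:
        if other == gene:
            continue
        rec = cofitness(fit, gene, other, min_experiments=min_experiments)
        if rec is not None:
            records.append(rec)
    records.sort(key=lambda r: (-r.r, r.gene_b))
    return records[:k]


def cofit_pairs(
    fit: pd.DataFrame,
    genes: list[str] | None = None,
    min_r: float | None = None,
    min_experiments: int = DEFAULT_MIN_EXPERIMENTS,
) -> pd.DataFrame:
    """All-pairs cofitness over a candidate gene list (or an |r| cutoff).

    To keep output linear in interest rather than quadratic in genes,
    either restrict to a ``genes`` list or supply ``min_r``.
    """
    if genes is None and min_r is None:
        raise ValueError("restrict the computation: pass genes or min_r")
    pool = list(genes) if genes is not None else list(fit.index)
    rows = []
    for i, a in enumerate(pool):
        for b in pool[i + 1:]:
            rec = cofitness(fit, a, b, min_experiments=min_experiments)
            if rec is None:
                continue
            if min_r is not None and abs(rec.r) < min_r:
                continue
            rows.append({"gene_a": a, "gene_b": b, "r": rec.r, "n": rec.n})
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "r", "n"])


@dataclass
class PresenceProfile:
    """Presence/absence of one protein family over an ordered genome list."""

    entity_id: str
    genomes: list[str]
    presence: list[bool]
    overrides: list[tuple[str, bool, str]] = field(default_factory=list)

    def resolved(self) -> list[bool]:
        """Presence vector with manual overrides applied."""
        values = dict(zip(self.genomes, self.presence))
        for genome, forced, _note in self.overrides:
            if genome not in values:
                raise KeyError(f"override names unknown genome {genome!r}")
            values[genome] = forced
        return [values[g] for g in self.genomes]


def profile_concordance(p: PresenceProfile, q: PresenceProfile) -> float:
    """Fraction of genomes on which two profiles agree, in [0, 1]."""
    if p.genomes != q.genomes:
        raise ValueError("profiles must share the same ordered genome list")
    a, b = p.resolved(), q.resolved()
    return sum(x == y for x, y in zip(a, b)) / len(a)


def read_presence(path: str) -> dict[str, PresenceProfile]:
    """Read profiles from a TSV of rows = entities, columns = genomes, 0/1."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    genomes = list(df.columns)
    return {
        entity: PresenceProfile(entity, genomes,
                                [bool(int(v)) for v in df.loc[entity]])
        for entity in df.index
    }
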