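"""Strain- and gene-level fitness from pool and BarSeq count tables.

Gene fitness in a condition is the log2 change in abundance of a gene's
mutants between the time0 sample and the sample after pooled growth.
Operationally, per strain

    raw = log2(cond + pseudocount) - log2(t0 + pseudocount)
          - log2(cond library size / t0 library size)

and gene fitness is a weighted mean of the raw values of the gene's
*central* strains (insertion in the central 10-90% of the gene), with
strain weight min(t0 reads, 20).  Columns are then centered so that
typical genes score ~0 (per-scaffold median zero).  Genes with too little
time0 coverage are left missing rather than estimated badly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from auxofill import media

DEFAULT_PSEUDOCOUNT = 1.0
DEFAULT_MIN_T0_STRAIN = 3
DEFAULT_MIN_T0_GENE = 30
WEIGHT_CAP = 20.0
CENTRAL_LO, CENTRAL_HI = 0.1, 0.9


def assign_genes(pool: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Map insertion strains to genes and central fractions.

    Adds ``gene_id`` (empty for intergenic insertions), ``fc`` (central
    fraction, (pos - begin + 0.5) / length) and ``central`` (0.1 <= fc <=
    0.9) columns.  Genes are assumed non-overlapping.
    """
    pool = pool.copy()
    pool["gene_id"] = ""
    pool["fc"] = np.nan
    for sid, sub in genes.groupby("scaffold_id"):
        sub = sub.sort_values("begin")
        mask = pool["scaffold_id"] == sid
        pos = pool.loc[mask, "position"].to_numpy()
        idx = np.searchsorted(sub["begin"].to_numpy(), pos, side="right") - 1
        ok = idx >= 0
        hit = ok & (pos <= sub["end"].to_numpy()[np.clip(idx, 0, None)])
        rows = pool.index[mask]
        begin = sub["begin"].to_numpy()[idx[hit]]
        end = sub["end"].to_numpy()[idx[hit]]
        pool.loc[rows[hit], "gene_id"] = sub["gene_id"].to_numpy()[idx[hit]]
        pool.loc[rows[hit], "fc"] = (pos[hit] - begin + 0.5) / (end - begin + 1)
    pool["central"] = (pool["fc"] >= CENTRAL_LO) & (pool["fc"] <= CENTRAL_HI)
    return pool


def validate_pool(pool: pd.DataFrame) -> None:
    """Check pool invariants: unique barcodes, mapping support >= 2 reads."""
    if pool["barcode"].duplicated().any():
        raise ValueError("pool contains duplicated barcodes")
    if (pool["n_reads"] < 2).any():
        raise ValueError("pool contains insertions supported by < 2 reads")


def strain_fitness(
    counts: pd.DataFrame,
    experiments: pd.DataFrame,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    min_t0_reads: int = DEFAULT_MIN_T0_STRAIN,
    library_size: str = "total",
) -> pd.DataFrame:
    """Raw per-strain fitness (log2) for every experiment.

    Strains with fewer than ``min_t0_reads`` time0 reads get NaN.  The
    library-size factor is the ratio of total counts (default) or the
    median of per-strain count ratios (``library_size="median"``).
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    out = pd.DataFrame(index=counts.index)
    for _, exp in experiments.iterrows():
        t0 = counts[exp["time0_id"]].astype(float)
        cond = counts[exp["exp_id"]].astype(float)
        if t0.sum() == 0:
            raise ValueError(f"time0 sample {exp['time0_id']} has zero total reads")
        if library_size == "median":
            ratio = ((cond + pseudocount) / (t0 + pseudocount)).median()
        else:
            ratio = cond.sum() / t0.sum()
        raw = np.log2(cond + pseudocount) - np.log2(t0 + pseudocount) - np.log2(ratio)
        raw[t0 < min_t0_reads] = np.nan
        out[exp["exp_id"]] = raw
    return out


def gene_fitness(
    pool: pd.DataFrame,
    counts: pd.DataFrame,
    experiments: pd.DataFrame,
    genes: pd.DataFrame | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    min_t0_reads_per_strain: int = DEFAULT_MIN_T0_STRAIN,
    min_t0_reads_per_gene: int = DEFAULT_MIN_T0_GENE,
    library_size: str = "total",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Unnormalized gene x experiment fitness and its per-entry support.

    Per gene and experiment, fitness is the weighted mean of raw strain
    fitness over the gene's central strains (weight min(t0 reads, 20)).
    The entry is missing when the qualifying central strains' summed time0
    reads fall below ``min_t0_reads_per_gene`` or no strain qualifies.

    Returns ``(fit, n_strains)``; both are genes x experiments.
    """
    if "central" not in pool.columns:
        if genes is None:
            raise ValueError("pool lacks gene assignment; pass the gene table")
        pool = assign_genes(pool, genes)
    pool = pool.set_index("barcode")
    # library sizes come from all pool barcodes, central or not
    all_shared = pool.index.intersection(counts.index)
    raw = strain_fitness(counts.loc[all_shared], experiments,
                         pseudocount=pseudocount,
                         min_t0_reads=min_t0_reads_per_strain,
                         library_size=library_size)
    pool = pool.loc[all_shared]
    pool = pool[pool["central"] & (pool["gene_id"] != "")]
    shared = pool.index
    raw = raw.loc[shared]
    gene_of = pool["gene_id"]
    all_genes = sorted(gene_of.unique()) if genes is None else list(genes["gene_id"])
    fit = pd.DataFrame(index=pd.Index(all_genes, name="gene_id"),
                       columns=list(experiments["exp_id"]), dtype=float)
    nstrains = fit.copy()
    for _, exp in experiments.iterrows():
        t0 = counts.loc[shared, exp["time0_id"]].astype(float)
        r = raw[exp["exp_id"]]
        ok = r.notna()
        w = np.minimum(t0[ok], WEIGHT_CAP)
        df = pd.DataFrame({"gene": gene_of[ok], "w": w, "wr": w * r[ok],
                           "t0": t0[ok]})
        agg = df.groupby("gene").sum()
        f = agg["wr"] / agg["w"]
        f[agg["t0"] < min_t0_reads_per_gene] = np.nan
        fit[exp["exp_id"]] = f.reindex(fit.index)
        nstrains[exp["exp_id"]] = df.groupby("gene").size().reindex(fit.index)
    return fit, nstrains


def normalize_matrix(
    fit: pd.DataFrame,
    genes: pd.DataFrame,
    min_genes_per_scaffold: int = 10,
) -> pd.DataFrame:
    """Center each experiment so typical genes score zero.

    Per experiment, the per-scaffold median over genes with values is
    subtracted; scaffolds with fewer than ``min_genes_per_scaffold``
    valued genes are centered on the genome-wide median instead.
    """
    scaff = genes.set_index("gene_id")["scaffold_id"].reindex(fit.index)
    out = fit.copy()
    for col in fit.columns:
        v = fit[col]
        global_med = v.median()
        for sid, idx in v.groupby(scaff).groups.items():
            vals = v.loc[idx]
            med = vals.median() if vals.notna().sum() >= min_genes_per_scaffold \
                else global_med
            if pd.notna(med):
                out.loc[idx, col] = vals - med
    return out


def fitness_pipeline(
    pool: pd.DataFrame,
    counts: pd.DataFrame,
    experiments: pd.DataFrame,
    genes: pd.DataFrame,
    **kwargs,
) -> pd.DataFrame:
    """Gene fitness, normalized: the standard pipeline entry point."""
    fit, _ = gene_fitness(pool, counts, experiments, genes=genes, **kwargs)
    return normalize_matrix(fit, genes)


def experiment_quality(
    pool: pd.DataFrame,
    counts: pd.DataFrame,
    experiments: pd.DataFrame,
    genes: pd.DataFrame,
    fit: pd.DataFrame | None = None,
    min_half_corr: float = 0.4,
    max_frac_strong: float = 0.25,
    **kwargs,
) -> pd.DataFrame:
    """Simplified internal-consistency quality metrics per experiment.

    Reports (a) the correlation between gene fitness computed from the
    strains in the first half versus the second half of each gene (split
    at central fraction 0.5), (b) the median |f| and (c) the fraction of
    genes with |f| > 1.  An experiment is flagged low quality when the
    half-gene correlation is below ``min_half_corr`` or the strong-effect
    fraction exceeds ``max_frac_strong``; flagged experiments should be
    excluded from downstream classification.
    """
    if "central" not in pool.columns:
        pool = assign_genes(pool, genes)
    first = pool[pool["fc"] < 0.5]
    second = pool[pool["fc"] >= 0.5]
    fit_first, _ = gene_fitness(first, counts, experiments, genes=genes, **kwargs)
    fit_second, _ = gene_fitness(second, counts, experiments, genes=genes, **kwargs)
    if fit is None:
        fit = fitness_pipeline(pool, counts, experiments, genes, **kwargs)
    rows = []
    for _, exp in experiments.iterrows():
        e = exp["exp_id"]
        pair = pd.concat([fit_first[e], fit_second[e]], axis=1).dropna()
        half_corr = pair.iloc[:, 0].corr(pair.iloc[:, 1]) if len(pair) >= 3 else np.nan
        f = fit[e].dropna()
        med_abs = f.abs().median() if len(f) else np.nan
        frac_strong = (f.abs() > 1).mean() if len(f) else np.nan
        low = bool((not np.isnan(half_corr) and half_corr < min_half_corr)
                   or (not np.isnan(frac_strong) and frac_strong > max_frac_strong))
        rows.append({"exp_id": e, "half_corr": half_corr, "median_abs_f": med_abs,
                     "frac_strong": frac_strong, "low_quality": low})
    return pd.DataFrame(rows)


def average_replicates(fit: pd.DataFrame, experiments: pd.DataFrame) -> pd.DataFrame:
    """Average fitness over replicate groups (column-wise)."""
    groups = experiments.set_index("exp_id")["replicate_group"]
    return fit.T.groupby(groups.reindex(fit.columns)).mean().T
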