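"""Essential-gene calling from transposon insertion statistics.

A protein-coding gene is called putatively essential when it is long
enough that the absence of insertions in its central 10-90% would be
surprising, and both its density of distinct central insertion locations
(normalized for GC-dependent insertion bias) and its central reads per
nucleotide are below 20% of the typical (median) gene's value.  Such
genes might not be strictly essential, but their mutants cannot grow
under the conditions in which the library was made.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from auxofill.fitness import CENTRAL_LO, CENTRAL_HI

DEFAULT_FRAC_CUTOFF = 0.2
_DENSITY_FLOOR_FRAC = 0.1  # floor predictions at 10% of the median density
_MIN_GC_SPREAD = 0.01


def gene_insertion_stats(
    pool: pd.DataFrame,
    genes: pd.DataFrame,
    genome: dict[str, str],
) -> pd.DataFrame:
    """Per-gene central-insertion statistics.

    Counts distinct central insertion *locations* — keyed by (scaffold,
    position, strand), so the two strands at one position are distinct —
    not barcodes; reads of barcodes sharing a location are summed.  GC is
    computed from the gene's genomic sequence.

    Returns a DataFrame indexed by gene_id with columns length, gc,
    n_central_sites, central_reads, density (sites per nt of the central
    80%), reads_per_nt.
    """
    for row in genes.itertuples():
        if row.scaffold_id not in genome or row.end > len(genome[row.scaffold_id]):
            raise ValueError(f"gene {row.gene_id} is off-scaffold")
    rows = []
    pool_by_sc = dict(tuple(pool.groupby("scaffold_id")))
    for row in genes.itertuples():
        seq = genome[row.scaffold_id][row.begin - 1:row.end]
        length = row.end - row.begin + 1
        gc = (seq.count("G") + seq.count("C")) / length
        sub = pool_by_sc.get(row.scaffold_id)
        n_sites, reads = 0, 0
        if sub is not None:
            pos = sub["position"]
            fc = (pos - row.begin + 0.5) / length
            central = sub[(fc >= CENTRAL_LO) & (fc <= CENTRAL_HI)]
            n_sites = central.groupby(["position", "strand"]).ngroups
            reads = int(central["n_reads"].sum())
        rows.append({
            "gene_id": row.gene_id, "length": length, "gc": gc,
            "n_central_sites": n_sites, "central_reads": reads,
            "density": n_sites / (0.8 * length),
            "reads_per_nt": reads / length,
        })
    return pd.DataFrame(rows).set_index("gene_id")


@dataclass
class GCDensityModel:
    """Expected central insertion density as a (floored) function of GC."""

    intercept: float
    slope: float
    slope_se: float
    floor: float
    is_constant: bool

    def predict(self, gc) -> np.ndarray:
        gc = np.asarray(gc, dtype=float)
        pred = self.intercept + self.slope * gc
        return np.maximum(pred, self.floor)


def fit_gc_density_model(
    stats: pd.DataFrame,
    min_length: int,
) -> GCDensityModel:
    """Fit an ordinary-least-squares line of insertion density on gene GC.

    Only genes of at least ``min_length`` nt enter the fit.  Predictions
    are floored at 10% of the genome-wide median density so normalized
    densities stay finite.  If the GC spread among fitted genes is
    degenerate (< 0.01), a constant model at the median density is used.
    """
    sub = stats[stats["length"] >= min_length]
    if len(sub) < 50:
        raise ValueError(f"need >= 50 genes of length >= {min_length} to fit "
                         f"the GC model (have {len(sub)})")
    med = float(sub["density"].median())
    floor = max(_DENSITY_FLOOR_FRAC * med, np.finfo(float).tiny)
    gc = sub["gc"].to_numpy()
    if gc.max() - gc.min() < _MIN_GC_SPREAD:
        return GCDensityModel(intercept=med, slope=0.0, slope_se=np.inf,
                              floor=floor, is_constant=True)
    X = sm.add_constant(gc)
    res = sm.OLS(sub["density"].to_numpy(), X).fit()
    return GCDensityModel(intercept=float(res.params[0]), slope=float(res.params[1]),
                          slope_se=float(res.bse[1]), floor=floor, is_constant=False)


def auto_min_length(
    stats: pd.DataFrame,
    genome: dict[str, str],
    pool: pd.DataFrame,
    expected_sites: float = 4.0,
) -> int:
    """Smallest gene length at which zero central insertions is surprising.

    Uses the genome-wide distinct-site density d and returns the smallest
    L with 0.8 * L * d >= ``expected_sites`` (default 4, i.e. P(no site)
    < ~2% under Poisson coverage).
    """
    genome_len = sum(len(s) for s in genome.values())
    n_sites = pool.groupby(["scaffold_id", "position", "strand"]).ngroups
    density = n_sites / genome_len
    if density <= 0:
        raise ValueError("pool has no insertions")
    return int(np.ceil(expected_sites / (0.8 * density)))


def call_essential(
    stats: pd.DataFrame,
    min_length: int | None = None,
    frac_cutoff: float = DEFAULT_FRAC_CUTOFF,
    gc_normalize: bool = True,
    genome: dict[str, str] | None = None,
    pool: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Call putatively essential genes.

    A gene is called essential iff its length is at least ``min_length``
    (computed by :func:`auto_min_length` when None), its GC-normalized
    insertion density is below ``frac_cutoff`` times the median normalized
    density, and its central reads per nt are below ``frac_cutoff`` times
    the median reads per nt — medians over genes of qualifying length.

    Returns the stats table with added expected_density, norm_density and
    ``called`` columns.  The call set is ``out.index[out['called']]``.
    """
    if min_length is None:
        if genome is None or pool is None:
            raise ValueError("min_length=None requires genome and pool for "
                             "automatic calibration")
        min_length = auto_min_length(stats, genome, pool)
    out = stats.copy()
    if gc_normalize:
        model = fit_gc_density_model(stats, min_length)
        out["expected_density"] = model.predict(out["gc"])
    else:
        long = out[out["length"] >= min_length]
        out["expected_density"] = float(long["density"].median())
    out["norm_density"] = out["density"] / out["expected_density"]
    long = out[out["length"] >= min_length]
    d_cut = frac_cutoff * float(long["norm_density"].median())
    r_cut = frac_cutoff * float(long["reads_per_nt"].median())
    out["called"] = ((out["length"] >= min_length)
                     & (out["norm_density"] < d_cut)
                     & (out["reads_per_nt"] < r_cut))
    out.attrs["min_length"] = int(min_length)
    return out
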