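"""Readers and writers for the flat-file dialects used by the pipeline.

All tables are tab-separated UTF-8 with a header row and no quoting; genome
coordinates are 1-based inclusive.  Fitness matrices store missing values
as empty strings.
"""

from __future__ import annotations

import os

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GENE_COLUMNS = ["gene_id", "scaffold_id", "begin", "end", "strand", "desc"]
POOL_COLUMNS = ["barcode", "scaffold_id", "position", "strand", "n_reads"]


def write_genome(genome: dict[str, str], path: str) -> None:
    records = [SeqRecord(Seq(seq), id=sid, description="") for sid, seq in genome.items()]
    SeqIO.write(records, path, "fasta")


def read_genome(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_genes_tsv(genes: pd.DataFrame, path: str) -> None:
    cols = [c for c in GENE_COLUMNS if c in genes.columns]
    extra = [c for c in genes.columns if c not in cols]
    genes[cols + extra].to_csv(path, sep="\t", index=False)


def read_genes_tsv(path: str) -> pd.DataFrame:
    genes = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "scaffold_id": str})
    genes["begin"] = genes["begin"].astype(int)
    genes["end"] = genes["end"].astype(int)
    return genes


def write_genes_gff3(genes: pd.DataFrame, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples():
            attrs = f"ID={row.gene_id}"
            desc = getattr(row, "desc", "")
            if isinstance(desc, str) and desc:
                attrs += f";Note={desc}"
            fh.write(
                f"{row.scaffold_id}\tauxofill\tgene\t{row.begin}\t{row.end}"
                f"\t.\t{row.strand}\t.\t{attrs}\n"
            )


def write_pool(pool: pd.DataFrame, path: str) -> None:
    cols = [c for c in POOL_COLUMNS if c in pool.columns]
    pool[cols].to_csv(path, sep="\t", index=False)


def read_pool(path: str) -> pd.DataFrame:
    pool = pd.read_csv(path, sep="\t", dtype={"barcode": str, "scaffold_id": str})
    pool["position"] = pool["position"].astype(int)
    pool["n_reads"] = pool["n_reads"].astype(int)
    return pool


def write_counts(counts: pd.DataFrame, path: str) -> None:
    counts.to_csv(path, sep="\t", index=True, index_label="barcode")


def read_counts(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="barcode")


def write_experiments(exps: pd.DataFrame, path: str) -> None:
    exps.to_csv(path, sep="\t", index=False)


def read_experiments(path: str) -> pd.DataFrame:
    exps = pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)
    exps["generations"] = exps["generations"].astype(float)
    return exps


def write_truth(truth: pd.DataFrame, path: str) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path: str) -> pd.DataFrame:
    truth = pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)
    truth["essential"] = truth["essential"].map({"True": True, "False": False})
    truth["effect"] = truth["effect"].astype(float)
    return truth


def write_annotations(annot: pd.DataFrame, path: str) -> None:
    annot.to_csv(path, sep="\t", index=False)


def read_annotations(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def write_fitness(fit: pd.DataFrame, path: str) -> None:
    fit.to_csv(path, sep="\t", index=True, index_label="gene_id", na_rep="")


def read_fitness(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
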