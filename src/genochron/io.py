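"""File-format helpers: FASTA, BED, hit tables, ALG maps, rates tables."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .rates import HIT_COLUMNS, LineageRate
from .synteny import GeneLocus

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "write_hit_table",
    "read_alg_map",
    "write_alg_map",
    "read_rates",
    "write_rates",
]

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_fasta(path) -> dict[str, str]:
    """FASTA file -> ordered {id: sequence}."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    """Write sequences as FASTA wrapped at 60 columns."""
    records = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_bed(path) -> dict[str, GeneLocus]:
    """6-column BED (0-based half-open) -> {gene id: GeneLocus}."""
    df = pd.read_csv(path, sep="\t", header=None, names=BED_COLUMNS)
    return {
        row.name: GeneLocus(
            gene_id=row.name, chrom=row.chrom, start=int(row.start),
            end=int(row.end), strand=row.strand,
        )
        for row in df.itertuples(index=False)
    }


def write_bed(loci: pd.DataFrame, path) -> None:
    """Write a (chrom, start, end, name, score, strand) frame as BED."""
    loci[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def write_hit_table(hits: pd.DataFrame, path) -> None:
    """Write a 12-column tabular homology-hit table (no header)."""
    hits[HIT_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_alg_map(path) -> dict[str, str]:
    """TSV (gene_id, ALG) with header -> {gene_id: ALG}."""
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_alg_map(alg_map: pd.DataFrame, path) -> None:
    alg_map.to_csv(path, sep="\t", index=False)


def write_rates(rates: dict[str, LineageRate], path) -> None:
    """Write per-species rates as TSV (species, r, sd, n)."""
    rows = [
        dict(species=lr.species, r=lr.r, sd=lr.dispersion, n=lr.n_orthologs)
        for lr in rates.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_rates(path) -> dict[str, LineageRate]:
    df = pd.read_csv(path, sep="\t")
    return {
        row.species: LineageRate(
            species=row.species, r=float(row.r), dispersion=float(row.sd),
            n_orthologs=int(row.n),
        )
        for row in df.itertuples(index=False)
    }
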