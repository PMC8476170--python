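"""Macrosynteny against ancestral bilaterian linkage groups (ALGs).

Mutual-best-hit orthologs between a focal species and a reference species
whose genes carry ALG labels let every focal gene inherit an ALG.  The
chromosome x ALG contingency table is then tested cell-by-cell for
enrichment (one-sided hypergeometric, Benjamini-Hochberg corrected), and
the significant associations drive rearrangement event calls (fusion,
fission, translocation), a scalar conservation index, and dot-plot
coordinates.

The conservation index used here is the fraction of assigned orthologs
lying on their chromosome's dominant ALG: CI = sum_c max_g n[c,g] / N.
This definition is local to this package (recorded in output metadata);
CI = 1 for a perfectly conserved karyotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneLocus",
    "KaryotypeTable",
    "RearrangementCall",
    "assign_genes_to_algs",
    "chromosome_alg_contingency",
    "call_rearrangement_events",
    "conservation_index",
    "dotplot_coordinates",
]

CI_DEFINITION = "dominant-ALG fraction (non-canonical, package-local)"


@dataclass(frozen=True)
class GeneLocus:
    """A gene's location: 0-based half-open coordinates on a chromosome."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"{self.gene_id}: require start < end, got "
                f"[{self.start}, {self.end})"
            )


@dataclass
class KaryotypeTable:
    """Chromosome x ALG ortholog counts with per-cell enrichment calls."""

    counts: pd.DataFrame  # chromosomes x ALGs
    pvalues: pd.DataFrame
    qvalues: pd.DataFrame
    significant: pd.DataFrame  # bool: q < alpha and count >= min_genes
    n_assigned: int
    n_unassigned: int = 0
    alpha: float = 0.05
    min_genes: int = 5
    ci_definition: str = CI_DEFINITION


@dataclass(frozen=True)
class RearrangementCall:
    """One called interchromosomal event."""

    type: str  # "fusion" | "fission" | "translocation"
    chromosomes: tuple[str, ...]
    algs: tuple[str, ...]
    supporting_genes: tuple[int, ...]


def assign_genes_to_algs(
    ortholog_pairs: list[tuple[str, str]],
    reference_alg_map: dict[str, str] | pd.DataFrame,
) -> tuple[dict[str, str], int]:
    """Focal gene -> ALG via mutual-best reference partners.

    ``ortholog_pairs`` are (focal, reference) pairs from
    :func:`genochron.rates.reciprocal_best_hits`; each focal gene inherits
    the ALG of its partner.  Pairs whose partner is absent from the map are
    unassigned and counted.  Duplicate focal genes are rejected (reciprocal
    best hits guarantee uniqueness).

    Returns ``(assignments, n_unassigned)``.
    """
    if isinstance(reference_alg_map, pd.DataFrame):
        reference_alg_map = dict(
            zip(reference_alg_map.iloc[:, 0], reference_alg_map.iloc[:, 1])
        )
    assignments: dict[str, str] = {}
    unassigned = 0
    for focal, ref in ortholog_pairs:
        if focal in assignments:
            raise ValueError(f"duplicate focal gene in ortholog pairs: {focal}")
        alg = reference_alg_map.get(ref)
        if alg is None:
            unassigned += 1
        else:
            assignments[focal] = alg
    return assignments, unassigned


def chromosome_alg_contingency(
    assignments: dict[str, str],
    loci: dict[str, GeneLocus],
    alpha: float = 0.05,
    min_genes: int = 5,
) -> KaryotypeTable:
    """Tabulate assigned orthologs by chromosome x ALG and test enrichment.

    Each cell gets a one-sided hypergeometric enrichment p-value
    (P[X >= n_cg] drawing the chromosome's genes from the assigned total),
    Benjamini-Hochberg corrected across all cells; a cell is significant
    when q < ``alpha`` and it holds at least ``min_genes`` genes.

    Raises ``ValueError`` on an empty assignment or on assigned genes
    without a locus (all offenders listed).
    """
    if not assignments:
        raise ValueError("no assigned genes")
    missing = sorted(g for g in assignments if g not in loci)
    if missing:
        raise ValueError(
            f"{len(missing)} assigned gene(s) lack a locus: "
            + ", ".join(missing[:10])
        )
    rows = [
        dict(gene=g, chrom=loci[g].chrom, alg=a) for g, a in assignments.items()
    ]
    df = pd.DataFrame(rows)
    counts = (
        df.pivot_table(index="chrom", columns="alg", values="gene",
                       aggfunc="count", fill_value=0)
        .sort_index(axis=0)
        .sort_index(axis=1)
    )
    counts.index.name = "chrom"
    counts.columns.name = "alg"

    mat = counts.to_numpy()
    total = int(mat.sum())
    row_sums = mat.sum(axis=1, keepdims=True)
    col_sums = mat.sum(axis=0, keepdims=True)
    # P[X >= n] for X ~ Hypergeom(N=total, K=col_sum, n=row_sum)
    pvals = hypergeom.sf(mat - 1, total, col_sums, row_sums)
    flat_q = multipletests(pvals.ravel(), method="fdr_bh")[1]
    qvals = flat_q.reshape(pvals.shape)
    signif = (qvals < alpha) & (mat >= min_genes)

    return KaryotypeTable(
        counts=counts,
        pvalues=pd.DataFrame(pvals, index=counts.index, columns=counts.columns),
        qvalues=pd.DataFrame(qvals, index=counts.index, columns=counts.columns),
        significant=pd.DataFrame(
            signif, index=counts.index, columns=counts.columns
        ),
        n_assigned=total,
        alpha=alpha,
        min_genes=min_genes,
    )


def call_rearrangement_events(
    table: KaryotypeTable,
    support_frac: float = 0.20,
    transloc_band: tuple[float, float] = (0.05, 0.20),
) -> list[RearrangementCall]:
    """Call fusion / fission / translocation events from the contingency.

    * fusion: one chromosome significantly associated with >= 2 ALGs, each
      contributing at least ``support_frac`` of the chromosome's genes;
    * fission: one ALG significant on >= 2 chromosomes, each holding at
      least ``support_frac`` of the ALG's genes;
    * translocation: a significant minority cell holding a fraction of its
      ALG's genes inside ``transloc_band``, off the ALG's majority
      chromosome.
    """
    counts = table.counts
    signif = table.significant
    calls: list[RearrangementCall] = []

    for chrom in counts.index:
        row = counts.loc[chrom]
        sig_algs = [
            g for g in counts.columns
            if signif.loc[chrom, g] and row[g] >= support_frac * row.sum()
        ]
        if len(sig_algs) >= 2:
            calls.append(
                RearrangementCall(
                    type="fusion",
                    chromosomes=(chrom,),
                    algs=tuple(sig_algs),
                    supporting_genes=tuple(int(row[g]) for g in sig_algs),
                )
            )

    for alg in counts.columns:
        col = counts[alg]
        alg_total = col.sum()
        if alg_total == 0:
            continue
        majority_chrom = col.idxmax()
        sig_chroms = [
            c for c in counts.index
            if signif.loc[c, alg] and col[c] >= support_frac * alg_total
        ]
        if len(sig_chroms) >= 2:
            calls.append(
                RearrangementCall(
                    type="fission",
                    chromosomes=tuple(sig_chroms),
                    algs=(alg,),
                    supporting_genes=tuple(int(col[c]) for c in sig_chroms),
                )
            )
        lo, hi = transloc_band
        for c in counts.index:
            if c == majority_chrom:
                continue
            # minority cells are a targeted per-ALG test: gate on the raw
            # hypergeometric p and the minimum gene count (the BH-corrected
            # q over all cells has no power against small translocations)
            if not (
                table.pvalues.loc[c, alg] < table.alpha
                and col[c] >= table.min_genes
            ):
                continue
            frac = col[c] / alg_total
            if lo <= frac < hi:
                calls.append(
                    RearrangementCall(
                        type="translocation",
                        chromosomes=(c,),
                        algs=(alg,),
                        supporting_genes=(int(col[c]),),
                    )
                )
    return calls


def conservation_index(table: KaryotypeTable) -> float:
    """Fraction of assigned orthologs on their chromosome's dominant ALG."""
    mat = table.counts.to_numpy()
    total = mat.sum()
    if total == 0:
        raise ValueError("no assigned genes")
    return float(mat.max(axis=1).sum() / total)


def dotplot_coordinates(
    ortholog_pairs: list[tuple[str, str]],
    loci_focal: dict[str, GeneLocus],
    loci_ref: dict[str, GeneLocus],
) -> pd.DataFrame:
    """Rank coordinates of mutual-best orthologs for a macrosynteny dot plot.

    Genes are ranked by (chromosome, start) on each side; one point per
    pair with both loci present (pairs missing a locus are dropped and
    counted in the ``n_dropped`` attribute of the returned frame).
    """

    def ranks(loci: dict[str, GeneLocus]) -> dict[str, int]:
        ordered = sorted(loci.values(), key=lambda l: (l.chrom, l.start, l.gene_id))
        return {l.gene_id: i for i, l in enumerate(ordered)}

    rank_f = ranks(loci_focal)
    rank_r = ranks(loci_ref)
    rows = []
    dropped = 0
    for focal, ref in ortholog_pairs:
        if focal not in rank_f or ref not in rank_r:
            dropped += 1
            continue
        rows.append(
            dict(
                x_rank=rank_f[focal],
                y_rank=rank_r[ref],
                chrom_focal=loci_focal[focal].chrom,
                chrom_ref=loci_ref[ref].chrom,
                focal=focal,
                ref=ref,
            )
        )
    df = pd.DataFrame(
        rows,
        columns=["x_rank", "y_rank", "chrom_focal", "chrom_ref", "focal", "ref"],
    )
    df.attrs["n_dropped"] = dropped
    return df
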