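"""Paralog-family duplication dating via codon-threaded alignments and NG86.

A protein alignment of the family (produced by any aligner) is threaded back
onto the coding sequences codon-by-codon; Nei-Gojobori dN is computed for
every pair, and each pairwise duplication age is T = dN/(2r) — divergence
accrues on both copies after the duplication.  Events are ordered by
single-linkage clustering on the age matrix, youngest first.  dS-based
dating uses the same plumbing behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .divergence import GENETIC_CODE, STOP_CODONS, ng86_pair
from .rates import LineageRate

__all__ = [
    "CodonAlignment",
    "DuplicationReport",
    "translate",
    "thread_codon_alignment",
    "date_paralog_family",
]


def translate(cds: str) -> str:
    """Translate an ungapped CDS with the standard code ('*' for stops)."""
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    return "".join(
        GENETIC_CODE.get(cds[i:i + 3].upper(), "X")
        for i in range(0, len(cds), 3)
    )


@dataclass
class CodonAlignment:
    """In-frame gapped CDS alignment derived from a protein alignment."""

    sequences: dict[str, str]  # id -> gapped CDS, all equal length
    dropped_codons: int = 0

    @property
    def ids(self) -> list[str]:
        return list(self.sequences)

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))


@dataclass
class DuplicationReport:
    """Pairwise dN and age matrices for a paralog family.

    Matrices are symmetric with zero diagonal, indexed by sequence id;
    saturated pairs carry ``nan`` ages.  ``event_order`` lists merge events
    from single-linkage clustering on the age matrix, youngest first, each
    as (age_myr, members_left, members_right).
    """

    ids: list[str]
    dn: pd.DataFrame
    ages: pd.DataFrame
    saturated: pd.DataFrame
    event_order: list[tuple[float, tuple[str, ...], tuple[str, ...]]]
    rate: float
    metric: str = "dN"


def thread_codon_alignment(
    protein_alignment: dict[str, str], cds_by_id: dict[str, str]
) -> CodonAlignment:
    """Expand a gapped protein alignment to its source codons.

    Each amino-acid column becomes the corresponding codon of that
    sequence's CDS; protein gaps become triple gaps.  A trailing stop codon
    on a CDS is stripped.  Every CDS must translate exactly to its ungapped
    protein row; mismatches are rejected with the sequence id and codon
    position, as are internal stops.
    """
    if not protein_alignment:
        raise ValueError("empty protein alignment")
    lengths = {len(s) for s in protein_alignment.values()}
    if len(lengths) != 1:
        raise ValueError("protein alignment rows differ in length")
    out: dict[str, str] = {}
    for sid, prot_row in protein_alignment.items():
        if sid not in cds_by_id:
            raise ValueError(f"no CDS provided for {sid!r}")
        cds = cds_by_id[sid].upper().replace("U", "T")
        if len(cds) % 3:
            raise ValueError(f"{sid}: CDS length {len(cds)} not a multiple of 3")
        codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
        if codons and codons[-1] in STOP_CODONS:
            codons = codons[:-1]
        aa_seq = prot_row.replace("-", "").upper()
        if len(codons) != len(aa_seq):
            raise ValueError(
                f"{sid}: CDS has {len(codons)} codons but protein row has "
                f"{len(aa_seq)} residues"
            )
        for i, (codon, aa) in enumerate(zip(codons, aa_seq)):
            trans = GENETIC_CODE.get(codon, "X")
            if trans == "*":
                raise ValueError(f"{sid}: internal stop at codon {i + 1}")
            if trans != aa:
                raise ValueError(
                    f"{sid}: translation mismatch at codon {i + 1} "
                    f"({codon} -> {trans}, protein has {aa})"
                )
        it = iter(codons)
        out[sid] = "".join(
            "---" if aa == "-" else next(it) for aa in prot_row.upper()
        )
    return CodonAlignment(sequences=out)


def date_paralog_family(
    alignment: CodonAlignment,
    rate: LineageRate | float,
    use_ds: bool = False,
) -> DuplicationReport:
    """Pairwise duplication ages of a paralog family.

    For every sequence pair, NG86 gives dN (or dS with ``use_ds``); the
    pair's duplication age is T = d/(2r) Myr.  Saturated pairs get ``nan``
    ages; if every pair is saturated the family cannot be dated and a
    ``ValueError`` is raised.  Event order comes from single-linkage
    clustering on the age matrix (saturated ages imputed at just above the
    oldest finite age for clustering only).
    """
    r = rate.r if isinstance(rate, LineageRate) else float(rate)
    if r <= 0:
        raise ValueError("substitution rate must be positive")
    ids = alignment.ids
    if len(ids) < 2:
        raise ValueError("need at least two sequences to date duplications")
    n = len(ids)
    dn = np.zeros((n, n))
    ages = np.zeros((n, n))
    sat = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            cd = ng86_pair(alignment.sequences[ids[i]], alignment.sequences[ids[j]])
            d = cd.dS if use_ds else cd.dN
            dn[i, j] = dn[j, i] = d
            if math.isnan(d):
                sat[i, j] = sat[j, i] = True
                ages[i, j] = ages[j, i] = math.nan
            else:
                t = d / (2.0 * r)
                ages[i, j] = ages[j, i] = t
    finite = ages[np.triu_indices(n, 1)]
    finite = finite[~np.isnan(finite)]
    if finite.size == 0:
        raise ValueError("all pairs saturated: family cannot be dated")

    # single-linkage ordering of duplication events, youngest first
    cluster_ages = ages.copy()
    if sat.any():
        cluster_ages[np.isnan(cluster_ages)] = finite.max() * 1.01 + 1.0
    z = linkage(squareform(cluster_ages, checks=False), method="single")
    clusters: dict[int, tuple[str, ...]] = {i: (ids[i],) for i in range(n)}
    events = []
    for k, (left, right, height, _) in enumerate(z):
        li, ri = int(left), int(right)
        events.append((float(height), clusters[li], clusters[ri]))
        clusters[n + k] = clusters[li] + clusters[ri]
    events.sort(key=lambda e: e[0])

    idx = pd.Index(ids, name="id")
    return DuplicationReport(
        ids=ids,
        dn=pd.DataFrame(dn, index=idx, columns=idx),
        ages=pd.DataFrame(ages, index=idx, columns=idx),
        saturated=pd.DataFrame(sat, index=idx, columns=idx),
        event_order=events,
        rate=r,
        metric="dS" if use_ds else "dN",
    )
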