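"""Core divergence formulas for molecular dating.

This module implements the arithmetic shared by the TE-insertion and
gene-duplication dating pipelines:

* raw (observed) divergence between two aligned sequences,
* the Jukes-Cantor multiple-hit correction on the percent scale,
  ``K = -(300/4) * ln(1 - D*4/300)``,
* Nei-Gojobori (1986) synonymous / nonsynonymous site and substitution
  counting with JC correction of the resulting proportions,
* the dating equation ``T = K / (2 r)``, which converts a corrected
  divergence ``K`` (substitutions/site) accumulated along two lineages,
  each evolving at rate ``r`` (substitutions/site/Myr), into an age in Myr.

D and K are percentages at the interfaces of :func:`raw_divergence` and
:func:`jc_correct` (the printed constant 300 = 4 x 75 fixes the percent
scale); :func:`date_event` takes K as a fraction per site.
"""

from __future__ import annotations

import functools
import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable

__all__ = [
    "SATURATION_PERCENT",
    "DivergenceEstimate",
    "CodonDivergence",
    "DatedEvent",
    "raw_divergence",
    "jc_correct",
    "divergence_estimate",
    "ng86_site_counts",
    "ng86_codon_pair_differences",
    "ng86_pair",
    "jc_correct_proportion",
    "date_event",
]

#: Divergence (percent of sites) at and beyond which the JC correction
#: is undefined: 75% is the expected divergence after infinite time.
SATURATION_PERCENT = 75.0

_NUCS = "ACGT"
_NUCSET = frozenset(_NUCS)

# Standard genetic code, DNA alphabet. "*" marks stops.
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")


class SaturatedDivergenceError(ValueError):
    """Raised when a correction is requested outside its domain."""


@dataclass(frozen=True)
class DivergenceEstimate:
    """Observed and JC-corrected divergence for one aligned pair.

    ``D`` and ``K`` are percentages of compared sites.  When the raw
    divergence reaches 75% the correction diverges; the estimate is then
    flagged ``saturated`` and ``K`` is ``nan`` (saturated records are
    excluded downstream, never clamped).
    """

    D: float
    K: float
    sites_compared: int
    saturated: bool


@dataclass(frozen=True)
class CodonDivergence:
    """Nei-Gojobori quantities for one coding-sequence pair.

    ``S``/``N`` are mean synonymous/nonsynonymous site counts over the two
    sequences (S + N = 3 x codons compared); ``Sd``/``Nd`` the difference
    counts; ``pS``/``pN`` the proportions; ``dS``/``dN`` the JC-corrected
    rates per site (``nan`` where the proportion reaches 3/4).
    """

    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float
    dN: float
    codons_compared: int
    codons_dropped: int = 0

    @property
    def saturated(self) -> bool:
        """True if either proportion is outside the JC correction domain."""
        return math.isnan(self.dS) or math.isnan(self.dN)


@dataclass(frozen=True)
class DatedEvent:
    """A dated TE insertion or gene duplication: T = K/(2r), K per site."""

    kind: str  # "TE_insertion" | "duplication"
    entity_id: str
    K: float  # corrected divergence, substitutions per site (fraction)
    r: float  # substitutions/site/Myr
    T: float  # age, Myr

    def __post_init__(self) -> None:
        if self.kind not in ("TE_insertion", "duplication"):
            raise ValueError(f"unknown event kind: {self.kind!r}")


def raw_divergence(a: str, b: str) -> tuple[float, int]:
    """Percent mismatch between two equal-length (possibly gapped) sequences.

    Columns containing a gap (``-``) or any non-ACGT ambiguity character in
    either sequence are excluded from the comparison.

    Returns ``(D, sites_compared)`` with D in percent of compared columns.

    Raises ``ValueError`` on length mismatch or when no column is comparable.
    """
    if len(a) != len(b):
        raise ValueError(
            f"aligned sequences differ in length: {len(a)} vs {len(b)}"
        )
    a = a.upper()
    b = b.upper()
    compared = 0
    mismatches = 0
    for ca, cb in zip(a, b):
        if ca not in _NUCSET or cb not in _NUCSET:
            continue
        compared += 1
        if ca != cb:
            mismatches += 1
    if compared == 0:
        raise ValueError("no comparable (gap- and ambiguity-free) columns")
    return 100.0 * mismatches / compared, compared


def jc_correct(D: float) -> float:
    """Jukes-Cantor multiple-hit correction on the percent scale.

    ``K = -(300/4) * ln(1 - D*4/300) = -75 ln(1 - D/75)``, with D and K in
    percent of sites.  Returns ``nan`` for ``D >= 75`` (saturated: the
    observed divergence is at or beyond its infinite-time expectation).

    Raises ``ValueError`` for negative D.
    """
    if D < 0:
        raise ValueError(f"divergence must be non-negative, got {D}")
    if D >= SATURATION_PERCENT:
        return math.nan
    return -SATURATION_PERCENT * math.log1p(-D / SATURATION_PERCENT)


def divergence_estimate(a: str, b: str) -> DivergenceEstimate:
    """Raw + corrected divergence for one aligned pair, with saturation flag."""
    D, sites = raw_divergence(a, b)
    K = jc_correct(D)
    return DivergenceEstimate(
        D=D, K=K, sites_compared=sites, saturated=math.isnan(K)
    )


def jc_correct_proportion(p: float) -> float:
    """JC correction on the fraction scale: d = -(3/4) ln(1 - 4p/3).

    Returns ``nan`` for p >= 3/4.
    """
    if p < 0:
        raise ValueError(f"proportion must be non-negative, got {p}")
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-p / 0.75)


def _check_codon(codon: str) -> str:
    codon = codon.upper()
    if len(codon) != 3 or any(c not in _NUCSET for c in codon):
        raise ValueError(f"not an unambiguous codon: {codon!r}")
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon not allowed: {codon}")
    return codon


@functools.lru_cache(maxsize=None)
def ng86_site_counts(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts of one codon (NG86).

    Each codon position contributes (synonymous single-base changes) /
    (counted single-base changes), where changes creating a stop codon are
    excluded from both numerator and denominator; the position's
    nonsynonymous share is the complement, so s + n = 3 per codon.

    Raises ``ValueError`` for stop codons or ambiguous characters.
    """
    codon = _check_codon(codon)
    aa = GENETIC_CODE[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        counted = 0
        for alt in _NUCS:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1:]
            if mutant in STOP_CODONS:
                continue
            counted += 1
            if GENETIC_CODE[mutant] == aa:
                syn += 1
        # counted >= 1 for every non-stop codon position under the
        # standard code, so the ratio is always defined
        s += syn / counted
    return s, 3.0 - s


@functools.lru_cache(maxsize=None)
def ng86_codon_pair_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous difference counts between two codons (NG86).

    Multi-position differences are averaged over all orderings of single-base
    steps; pathways passing through a stop codon are excluded and the weights
    of the remaining pathways renormalised.  If every pathway passes through a
    stop (cannot happen for 1-step differences), all pathways are used.
    """
    codon_a = _check_codon(codon_a)
    codon_b = _check_codon(codon_b)
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return 0.0, 0.0

    pathways: list[tuple[int, int]] = []  # (syn steps, nonsyn steps)
    fallback: list[tuple[int, int]] = []
    for order in itertools.permutations(diff_positions):
        current = codon_a
        syn = nsyn = 0
        valid = True
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
            if nxt in STOP_CODONS:
                valid = False
            elif GENETIC_CODE[nxt] == GENETIC_CODE[current]:
                syn += 1
            else:
                nsyn += 1
            current = nxt
        if valid:
            pathways.append((syn, nsyn))
        fallback.append((syn, nsyn))
    chosen = pathways if pathways else fallback
    sd = sum(p[0] for p in chosen) / len(chosen)
    nd = sum(p[1] for p in chosen) / len(chosen)
    # steps through stops in fallback pathways were not classified; pad as
    # nonsynonymous so sd+nd equals the number of differing positions
    total = len(diff_positions)
    nd += total - (sd + nd)
    return sd, nd


def _iter_codon_pairs(
    cds_a: str, cds_b: str
) -> Iterable[tuple[int, str, str]]:
    for i in range(0, len(cds_a), 3):
        yield i // 3, cds_a[i:i + 3], cds_b[i:i + 3]


def ng86_pair(cds_a: str, cds_b: str) -> CodonDivergence:
    """Nei-Gojobori (1986) dN/dS quantities for an aligned CDS pair.

    Sequences must be equal length and a multiple of 3; codons containing a
    gap or ambiguity character in either sequence are dropped pairwise.
    Internal stop codons are rejected.  Site counts are averaged over the
    two sequences; proportions are JC-corrected to per-site rates
    (``nan`` + saturated flag where p >= 3/4).
    """
    if len(cds_a) != len(cds_b):
        raise ValueError(
            f"aligned CDS differ in length: {len(cds_a)} vs {len(cds_b)}"
        )
    if len(cds_a) % 3:
        raise ValueError(f"alignment length {len(cds_a)} is not a multiple of 3")
    cds_a = cds_a.upper()
    cds_b = cds_b.upper()

    s_a = s_b = 0.0
    sd = nd = 0.0
    compared = 0
    dropped = 0
    for idx, ca, cb in _iter_codon_pairs(cds_a, cds_b):
        if any(ch not in _NUCSET for ch in ca + cb):
            dropped += 1
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            raise ValueError(f"internal stop codon at codon index {idx}")
        compared += 1
        s_a += ng86_site_counts(ca)[0]
        s_b += ng86_site_counts(cb)[0]
        d = ng86_codon_pair_differences(ca, cb)
        sd += d[0]
        nd += d[1]
    if compared == 0:
        raise ValueError("no comparable codons in alignment")

    S = (s_a + s_b) / 2.0
    N = 3.0 * compared - S
    pS = sd / S if S > 0 else 0.0
    pN = nd / N if N > 0 else 0.0
    dS = jc_correct_proportion(pS)
    dN = jc_correct_proportion(pN)
    return CodonDivergence(
        S=S, N=N, Sd=sd, Nd=nd, pS=pS, pN=pN, dS=dS, dN=dN,
        codons_compared=compared, codons_dropped=dropped,
    )


def date_event(K: float, r: float) -> float:
    """Age in Myr of a divergence event: ``T = K / (2 r)``.

    ``K`` is the corrected divergence in substitutions per site (a fraction;
    percent inputs are divided by 100 upstream) and ``r`` the per-lineage
    substitution rate in substitutions/site/Myr.
    """
    if r <= 0:
        raise ValueError(f"substitution rate must be positive, got {r}")
    if K < 0:
        raise ValueError(f"corrected divergence must be non-negative, got {K}")
    return K / (2.0 * r)
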