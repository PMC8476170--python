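"""Per-lineage substitution-rate calibration from three-species orthologs.

Single-copy orthologs are selected as reciprocal best hits from all-by-all
homology searches; pairwise JC-corrected distances between the three
aligned sequences are decomposed additively onto the three branches of the
unrooted triplet, and each branch length is divided by its calibration time
(the ingroup divergence for the two ingroup branches, the outgroup
divergence for the outgroup branch) to give a per-lineage rate in
substitutions/site/Myr.  Species rates are alignment-length-weighted means
over ortholog triplets with a bootstrap dispersion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .divergence import jc_correct, raw_divergence

__all__ = [
    "HIT_COLUMNS",
    "OrthologTriplet",
    "BranchLengths",
    "LineageRate",
    "CalibrationConfig",
    "read_hit_table",
    "reciprocal_best_hits",
    "triplet_branch_lengths",
    "triplet_from_alignment",
    "estimate_lineage_rates",
]

#: Column names of the 12-column tabular homology-hit format.
HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass(frozen=True)
class OrthologTriplet:
    """Pairwise JC distances (substitutions/site) for one ortholog triplet."""

    id_a: str
    id_b: str
    id_c: str
    d_ab: float
    d_ac: float
    d_bc: float
    length: int


@dataclass(frozen=True)
class BranchLengths:
    """Additive branch lengths of the unrooted 3-taxon tree.

    ``clamped`` flags any branch whose raw decomposition was negative
    (triangle-inequality violation from noise) and was set to 0.
    """

    a: float
    b: float
    c: float
    clamped: tuple[bool, bool, bool] = (False, False, False)


@dataclass(frozen=True)
class LineageRate:
    """A per-species substitution rate with its calibration provenance."""

    species: str
    r: float  # substitutions/site/Myr
    n_orthologs: int
    dispersion: float  # bootstrap SD
    calibration: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError(f"rate must be positive, got {self.r}")
        if self.n_orthologs < 1:
            raise ValueError("n_orthologs must be >= 1")


@dataclass(frozen=True)
class CalibrationConfig:
    """Externally supplied divergence times (Myr) for the 3-taxon tree."""

    ingroup_time: float  # A-B split
    outgroup_time: float  # (A,B)-C split

    def __post_init__(self) -> None:
        if not self.outgroup_time > self.ingroup_time > 0:
            raise ValueError(
                "require outgroup_time > ingroup_time > 0, got "
                f"{self.outgroup_time} / {self.ingroup_time}"
            )


def read_hit_table(path) -> pd.DataFrame:
    """Read a 12-column tabular homology-hit file.

    Raises ``ValueError`` naming the first malformed line.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", dtype=str,
        skip_blank_lines=True,
    )
    if df.shape[1] != len(HIT_COLUMNS):
        raise ValueError(
            f"{path}: expected {len(HIT_COLUMNS)} columns, found {df.shape[1]}"
        )
    df.columns = HIT_COLUMNS
    for col in ("pident", "evalue", "bitscore"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("length", "mismatch", "gapopen", "qstart", "qend",
                "sstart", "send"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df.isna().any(axis=1)
    if bad.any():
        line = int(np.nonzero(bad.to_numpy())[0][0]) + 1
        raise ValueError(f"{path}: malformed row at line {line}")
    return df


def _best_hits(hits: pd.DataFrame) -> pd.Series:
    """Top hit per query: highest bitscore, ties broken by lower e-value,
    longer alignment, then lexicographic subject id (deterministic)."""
    ordered = hits.sort_values(
        by=["bitscore", "evalue", "length", "sseqid"],
        ascending=[False, True, False, True],
        kind="mergesort",
    )
    return ordered.groupby("qseqid", sort=True)["sseqid"].first()


def reciprocal_best_hits(
    hits_ab: pd.DataFrame, hits_ba: pd.DataFrame
) -> list[tuple[str, str]]:
    """Reciprocal-best-hit ortholog pairs from two directed hit tables.

    ``(x, y)`` is retained iff y is x's top hit in ``hits_ab`` and x is y's
    top hit in ``hits_ba``.  Output sorted by the first id.
    """
    best_ab = _best_hits(hits_ab)
    best_ba = _best_hits(hits_ba)
    pairs = []
    for x, y in best_ab.items():
        if best_ba.get(y) == x:
            pairs.append((x, y))
    return pairs


def triplet_branch_lengths(
    d_ab: float, d_ac: float, d_bc: float
) -> BranchLengths:
    """Additive decomposition of three pairwise distances onto branches.

    ``a = (d_AB + d_AC - d_BC)/2`` and cyclically; any negative branch is
    clamped to 0 and flagged.
    """
    for name, d in (("d_ab", d_ab), ("d_ac", d_ac), ("d_bc", d_bc)):
        if not np.isfinite(d) or d < 0:
            raise ValueError(f"{name} must be finite and non-negative, got {d}")
    a = (d_ab + d_ac - d_bc) / 2.0
    b = (d_ab + d_bc - d_ac) / 2.0
    c = (d_ac + d_bc - d_ab) / 2.0
    clamped = tuple(x < 0 for x in (a, b, c))
    return BranchLengths(
        a=max(a, 0.0), b=max(b, 0.0), c=max(c, 0.0), clamped=clamped
    )


def triplet_from_alignment(
    seq_a: str, seq_b: str, seq_c: str,
    id_a: str = "A", id_b: str = "B", id_c: str = "C",
) -> OrthologTriplet:
    """Pairwise JC-corrected distances (fractions/site) from one alignment."""
    d = {}
    lengths = []
    for key, (x, y) in {
        "d_ab": (seq_a, seq_b), "d_ac": (seq_a, seq_c), "d_bc": (seq_b, seq_c)
    }.items():
        D, sites = raw_divergence(x, y)
        K = jc_correct(D)
        if np.isnan(K):
            raise ValueError(f"saturated pairwise distance for {key}")
        d[key] = K / 100.0
        lengths.append(sites)
    return OrthologTriplet(
        id_a=id_a, id_b=id_b, id_c=id_c, length=min(lengths), **d
    )


def estimate_lineage_rates(
    triplets: list[OrthologTriplet],
    cal: CalibrationConfig,
    species: tuple[str, str, str] = ("A", "B", "C"),
    n_bootstrap: int = 200,
    seed: int = 0,
) -> dict[str, LineageRate]:
    """Per-species substitution rates from ortholog triplets.

    Each triplet's ingroup branches are divided by the ingroup divergence
    time and its outgroup branch by the outgroup divergence time; the
    species rate is the alignment-length-weighted mean over triplets.
    Dispersion is the SD over ``n_bootstrap`` seeded resamples of triplets.

    Raises ``ValueError`` on an empty triplet list or if a species'
    weighted-mean rate is zero (degenerate input).
    """
    if not triplets:
        raise ValueError("no ortholog triplets supplied")
    if len(triplets) < 10:
        warnings.warn(
            f"only {len(triplets)} triplets: rate estimates will be noisy",
            stacklevel=2,
        )
    per_rates = np.empty((len(triplets), 3))
    weights = np.empty(len(triplets))
    for i, t in enumerate(triplets):
        bl = triplet_branch_lengths(t.d_ab, t.d_ac, t.d_bc)
        per_rates[i] = (
            bl.a / cal.ingroup_time,
            bl.b / cal.ingroup_time,
            bl.c / cal.outgroup_time,
        )
        weights[i] = t.length
    means = np.average(per_rates, axis=0, weights=weights)
    if np.any(means <= 0):
        raise ValueError("degenerate input: a lineage rate estimate is zero")

    rng = np.random.default_rng(seed)
    boots = np.empty((n_bootstrap, 3))
    for b in range(n_bootstrap):
        idx = rng.integers(0, len(triplets), size=len(triplets))
        boots[b] = np.average(per_rates[idx], axis=0, weights=weights[idx])
    sds = boots.std(axis=0, ddof=1)

    calibration = (
        ("ingroup", cal.ingroup_time), ("outgroup", cal.outgroup_time)
    )
    return {
        sp: LineageRate(
            species=sp, r=float(means[k]), n_orthologs=len(triplets),
            dispersion=float(sds[k]), calibration=calibration,
        )
        for k, sp in enumerate(species)
    }
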