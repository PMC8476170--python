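"""TE insertion-time landscapes from repeat-annotation tables.

Parses the 15-column RepeatMasker-style ``.out`` dialect, merges fragmented
hits of one element by their copy id, classifies families into the four TE
classes (SINE, LINE, LTR, DNA), converts each copy's consensus divergence D
into an age T = K/(2r) via the percent-scale JC correction, bins the ages
into per-class landscapes (bp-weighted by default), and detects burst peaks
by smoothed local-maximum search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .divergence import jc_correct
from .rates import LineageRate

__all__ = [
    "RepeatHit",
    "Landscape",
    "parse_repeat_annotation",
    "classify_te_family",
    "build_insertion_landscape",
    "detect_bursts",
]

TE_CLASSES = ("SINE", "LINE", "LTR", "DNA")


@dataclass
class RepeatHit:
    """One aligned repeat copy (fragments merged by copy id)."""

    score: int
    divergence: float  # percent mismatch to the family consensus
    perc_del: float
    perc_ins: float
    query: str
    qbegin: int  # 1-based inclusive
    qend: int
    strand: str  # '+' or '-'
    family: str
    class_family: str
    copy_id: str | None = None

    @property
    def length(self) -> int:
        return self.qend - self.qbegin + 1


@dataclass
class Landscape:
    """Binned insertion-time histogram for one TE class.

    ``bin_edges`` has len(bp)+1 entries in Myr; ``bp`` and ``copies`` are
    per-bin totals.  Saturated copies (D >= 75%) are excluded and counted.
    """

    te_class: str
    bin_edges: np.ndarray
    bp: np.ndarray
    copies: np.ndarray
    rate: float
    excluded_copies: int = 0
    excluded_bp: int = 0

    @property
    def bin_midpoints(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0


def _parse_row(fields: list[str], lineno: int) -> RepeatHit:
    strand = fields[8]
    if strand == "C":
        strand = "-"
    elif strand not in ("+", "-"):
        raise ValueError(f"line {lineno}: unknown strand symbol {strand!r}")
    return RepeatHit(
        score=int(fields[0]),
        divergence=float(fields[1]),
        perc_del=float(fields[2]),
        perc_ins=float(fields[3]),
        query=fields[4],
        qbegin=int(fields[5]),
        qend=int(fields[6]),
        strand=strand,
        family=fields[9],
        class_family=fields[10],
        copy_id=fields[14] if len(fields) > 14 else None,
    )


def parse_repeat_annotation(path) -> list[RepeatHit]:
    """Parse a 15-column repeat-annotation (.out dialect) file.

    The first three lines are headers.  Fragments sharing a copy id are
    merged into a single hit spanning their extremes, with length-weighted
    mean divergence.  Hits without a copy id are kept as singletons.
    Strand 'C' is normalised to '-'.

    Raises ``ValueError`` with the line number for rows that do not have
    15 whitespace-separated columns (the '(left)' parenthesised fields
    count as single columns).
    """
    hits: list[RepeatHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno <= 3 or not line.strip():
                continue
            fields = line.split()
            # an optional trailing '*' (overlapping-hit mark) is tolerated
            if fields and fields[-1] == "*":
                fields = fields[:-1]
            if len(fields) != 15:
                raise ValueError(
                    f"line {lineno}: expected 15 columns, found {len(fields)}"
                )
            hits.append(_parse_row(fields, lineno))

    merged: dict[str, RepeatHit] = {}
    order: list[RepeatHit] = []
    for hit in hits:
        if hit.copy_id is None:
            order.append(hit)
            continue
        prev = merged.get(hit.copy_id)
        if prev is None:
            merged[hit.copy_id] = hit
            order.append(hit)
        else:
            w_prev, w_new = prev.length, hit.length
            prev.divergence = (
                prev.divergence * w_prev + hit.divergence * w_new
            ) / (w_prev + w_new)
            prev.qbegin = min(prev.qbegin, hit.qbegin)
            prev.qend = max(prev.qend, hit.qend)
            prev.score = max(prev.score, hit.score)
    return order


def classify_te_family(class_family: str) -> str:
    """Map a class/family annotation string to SINE/LINE/LTR/DNA/other.

    Prefix match on the class token before '/', case-insensitive;
    RC (rolling-circle, Helitron) elements count as DNA transposons.
    """
    token = class_family.split("/", 1)[0].strip().upper()
    for cls in TE_CLASSES:
        if token.startswith(cls):
            return cls
    if token.startswith("RC") or token.startswith("HELITRON"):
        return "DNA"
    return "other"


def build_insertion_landscape(
    hits: list[RepeatHit],
    rate: LineageRate | float,
    bin_width: float = 1.0,
    correct: bool = True,
) -> dict[str, Landscape]:
    """Per-class insertion-time landscapes from merged repeat hits.

    For each hit, K = jc_correct(D) (skipped with ``correct=False`` when the
    annotation's divergence column is already corrected) and
    T = (K/100)/(2r) Myr.  Saturated hits (D >= 75%) are excluded and
    counted.  Returns one bp- and copy-weighted histogram per TE class
    present (``other`` families are ignored).
    """
    r = rate.r if isinstance(rate, LineageRate) else float(rate)
    if r <= 0:
        raise ValueError("substitution rate must be positive")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")

    ages: dict[str, list[tuple[float, int]]] = {}
    excluded: dict[str, list[int]] = {}
    for hit in hits:
        cls = classify_te_family(hit.class_family)
        if cls == "other":
            continue
        K = jc_correct(hit.divergence) if correct else hit.divergence
        if math.isnan(K):
            excluded.setdefault(cls, []).append(hit.length)
            continue
        T = (K / 100.0) / (2.0 * r)
        ages.setdefault(cls, []).append((T, hit.length))

    landscapes: dict[str, Landscape] = {}
    for cls in sorted(set(ages) | set(excluded)):
        pairs = ages.get(cls, [])
        ts = np.array([t for t, _ in pairs])
        lens = np.array([l for _, l in pairs])
        t_max = ts.max() if ts.size else 0.0
        n_bins = max(1, int(np.ceil((t_max + 1e-12) / bin_width)))
        edges = np.arange(n_bins + 1) * bin_width
        if ts.size:
            idx = np.minimum((ts // bin_width).astype(int), n_bins - 1)
            bp = np.bincount(idx, weights=lens, minlength=n_bins)
            copies = np.bincount(idx, minlength=n_bins).astype(float)
        else:
            bp = np.zeros(n_bins)
            copies = np.zeros(n_bins)
        landscapes[cls] = Landscape(
            te_class=cls,
            bin_edges=edges,
            bp=bp,
            copies=copies,
            rate=r,
            excluded_copies=len(excluded.get(cls, [])),
            excluded_bp=int(sum(excluded.get(cls, []))),
        )
    return landscapes


def detect_bursts(
    landscape: Landscape,
    smooth_window: int = 3,
    weight: str = "bp",
) -> list[float]:
    """Peak insertion times (Myr) of a landscape.

    The per-bin series (``bp`` by default, ``copies`` optionally) is
    smoothed with a centred moving average of ``smooth_window`` bins; peaks
    are bins strictly above both existing neighbours (edge bins compare
    against their single neighbour), ranked by smoothed height, ties broken
    younger-first.  Peak time is the bin midpoint.

    Raises ``ValueError`` if the landscape is empty.
    """
    series = landscape.bp if weight == "bp" else landscape.copies
    if series.sum() <= 0:
        raise ValueError("landscape has no occupied bins")
    if len(series) == 1:
        return [float(landscape.bin_midpoints[0])]
    w = max(1, int(smooth_window))
    kernel = np.ones(w)
    # edge-corrected moving average: divide by actual window coverage so a
    # flat series stays flat at the boundaries
    smooth = np.convolve(series, kernel, mode="same") / np.convolve(
        np.ones_like(series), kernel, mode="same"
    )
    mids = landscape.bin_midpoints

    # runs of equal smoothed value; a run is a peak when strictly above
    # both flanking values (an edge run needs only its inner flank); a run
    # spanning the whole series (uniform landscape) is never a peak
    peaks = []
    n = len(smooth)
    l = 0
    while l < n:
        r = l
        while r + 1 < n and smooth[r + 1] == smooth[l]:
            r += 1
        v = smooth[l]
        left_ok = l == 0 or smooth[l - 1] < v
        right_ok = r == n - 1 or smooth[r + 1] < v
        if left_ok and right_ok and v > 0 and not (l == 0 and r == n - 1):
            # report the plateau bin with the largest raw value, tie -> younger
            best = min(range(l, r + 1), key=lambda i: (-series[i], mids[i]))
            peaks.append((float(v), float(mids[best])))
        l = r + 1
    peaks.sort(key=lambda p: (-p[0], p[1]))
    return [t for _, t in peaks]
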