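"""Brute-force Nei-Gojobori oracle, independent of the implementation.

Sites and difference pathways are enumerated directly, with codon
translation delegated to Biopython (a second, independent source of the
standard genetic code).  Used only to cross-check
``genochron.divergence.ng86_pair``.
"""

from itertools import permutations

from Bio.Seq import Seq


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def _is_stop(codon: str) -> bool:
    return _aa(codon) == "*"


def syn_sites(codon: str) -> float:
    s = 0.0
    for pos in range(3):
        syn = counted = 0
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            mut = codon[:pos] + alt + codon[pos + 1:]
            if _is_stop(mut):
                continue
            counted += 1
            if _aa(mut) == _aa(codon):
                syn += 1
        s += syn / counted
    return s


def pair_differences(a: str, b: str) -> tuple[float, float]:
    diffs = [i for i in range(3) if a[i] != b[i]]
    if not diffs:
        return 0.0, 0.0
    valid, all_paths = [], []
    for order in permutations(diffs):
        cur, sd, nd, ok = a, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if _is_stop(nxt):
                ok = False
            elif _aa(nxt) == _aa(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            valid.append((sd, nd))
        all_paths.append((sd, nd))
    paths = valid if valid else all_paths
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    nd += len(diffs) - (sd + nd)  # unclassified stop steps -> nonsynonymous
    return sd, nd


def ng86_reference(cds_a: str, cds_b: str):
    """(S, N, Sd, Nd) by direct enumeration over all codon pairs."""
    s_a = s_b = sd = nd = 0.0
    n_codons = 0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i:i + 3], cds_b[i:i + 3]
        if any(ch not in "ACGT" for ch in ca + cb):
            continue
        n_codons += 1
        s_a += syn_sites(ca)
        s_b += syn_sites(cb)
        d = pair_differences(ca, cb)
        sd += d[0]
        nd += d[1]
    S = (s_a + s_b) / 2
    N = 3 * n_codons - S
    return S, N, sd, nd
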