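"""Synthetic molecular-evolution generator with known ground truth.

Every input class the dating and macrosynteny pipelines consume can be
generated here with its truth recorded: neutrally evolving sequences under
Jukes-Cantor, TE copy families with known burst ages, paralog families with
known duplication ages, three-species ortholog triplets with known
per-lineage rates, and rearranged karyotypes with known fusion / fission /
translocation events.  All outputs are deterministic given the config seed.

Divergence conventions
----------------------
The dating equation ``T = K/(2r)`` interprets a divergence ``K`` as having
accumulated along *two* lineages, each at rate ``r``.  The generators follow
that convention: a TE copy of age ``t`` is evolved from its consensus with
effective branch length ``2 r t`` (copy and ancestral-consensus lineages
both drift), and a paralog pair that split ``t`` Myr ago evolves each copy
independently for ``t``, so the pair diverges by ``2 r t``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .divergence import GENETIC_CODE, STOP_CODONS, raw_divergence

__all__ = [
    "SimConfig",
    "TEHistory",
    "ParalogFamily",
    "OrthologTripletSet",
    "KaryotypeSim",
    "evolve_sequence_jc",
    "random_sequence",
    "random_cds",
    "simulate_te_history",
    "simulate_paralog_family",
    "simulate_ortholog_triplets",
    "simulate_karyotype_evolution",
]

_NUCS = np.frombuffer(b"ACGT", dtype="S1")
TE_CLASSES = ("SINE", "LINE", "LTR", "DNA")
N_ALGS_DEFAULT = 17


@dataclass
class SimConfig:
    """Parameters of the synthetic-evolution scenarios.

    Rates are substitutions/site/Myr per lineage; times and ages are Myr.
    ``seed`` fixes every output bit-for-bit.
    """

    seed: int = 0
    rate_r: float = 0.005
    burst_times: Sequence[float] = (10.0,)
    copies_per_burst: int = 300
    copy_length: int = 1000
    age_jitter_sd: float = 0.0
    dup_times: Sequence[float] = (20.0,)
    codon_count: int = 500
    syn_rate: float | None = None  # defaults to rate_r
    # ortholog triplets
    rate_a: float = 0.002
    rate_b: float = 0.004
    rate_c: float = 0.002
    ingroup_time: float = 62.7
    outgroup_time: float = 200.0
    n_triplets: int = 200
    alignment_length: int = 1500
    # karyotype
    karyotype_spec: Sequence[str] = ()
    n_algs: int = N_ALGS_DEFAULT
    genes_per_alg: int = 100
    noise_frac: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.noise_frac < 1.0:
            raise ValueError("noise_frac must be in [0, 1)")
        for name in ("rate_r", "rate_a", "rate_b", "rate_c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def random_sequence(length: int, rng: np.random.Generator) -> str:
    """Uniform random nucleotide sequence of the given length."""
    return rng.choice(_NUCS, size=length).tobytes().decode()


_SENSE_CODONS = sorted(c for c in GENETIC_CODE if c not in STOP_CODONS)


def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """Random CDS of ``n_codons`` sense codons (no stops)."""
    idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons)
    return "".join(_SENSE_CODONS[i] for i in idx)


def jc_substitution_probability(r: float, t: float) -> float:
    """Per-site substitution probability after time t at rate r under JC."""
    return 0.75 * (1.0 - np.exp(-4.0 * r * t / 3.0))


def evolve_sequence_jc(
    seq: str, r: float, t: float, seed: int | np.random.Generator
) -> str:
    """Evolve a nucleotide sequence under Jukes-Cantor for time ``t``.

    Each site is independently substituted with probability
    ``p = (3/4)(1 - exp(-4rt/3))``; the substituted base is uniform over the
    three alternatives.  Deterministic given the seed (an int, or an already
    seeded :class:`numpy.random.Generator` for streaming use).

    Raises ``ValueError`` on an empty sequence, a non-ACGT character (with
    its 1-based position), or negative ``r``/``t``.
    """
    if not seq:
        raise ValueError("sequence must be non-empty")
    if r < 0 or t < 0:
        raise ValueError("rate and time must be non-negative")
    arr = np.frombuffer(seq.upper().encode(), dtype="S1")
    bad = ~np.isin(arr, _NUCS)
    if bad.any():
        pos = int(np.nonzero(bad)[0][0]) + 1
        raise ValueError(f"non-ACGT character {seq[pos - 1]!r} at position {pos}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = jc_substitution_probability(r, t)
    hit = rng.random(arr.size) < p
    if hit.any():
        # map each hit base to one of its 3 alternatives, uniformly
        codes = np.searchsorted(np.sort(_NUCS), arr[hit])  # ACGT -> 0..3
        offset = rng.integers(1, 4, size=hit.sum())
        arr = arr.copy()
        arr[hit] = np.sort(_NUCS)[(codes + offset) % 4]
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# TE copy families


@dataclass
class TEHistory:
    """Simulated TE copies with known insertion ages.

    ``copies`` maps copy id -> sequence; ``consensi`` maps family -> consensus.
    ``annotation`` is the 15-column repeat-annotation table (one row per
    copy, D = exact percent mismatch to the consensus).  ``truth`` has one
    row per copy: id, family, te_class, true_age_myr, true_D.
    """

    copies: dict[str, str]
    consensi: dict[str, str]
    annotation: pd.DataFrame
    truth: pd.DataFrame

    def annotation_text(self) -> str:
        """Render the annotation as a RepeatMasker-style .out file."""
        buf = io.StringIO()
        buf.write(
            "   SW   perc perc perc  query      position in query    "
            "         matching repeat       position in repeat\n"
            "score   div. del. ins.  sequence   begin end    (left)   "
            "repeat            class/family  begin  end (left)   ID\n"
            "\n"
        )
        for row in self.annotation.itertuples(index=False):
            buf.write(
                f"{row.score:5d} {row.perc_div:6.2f} {row.perc_del:4.1f} "
                f"{row.perc_ins:4.1f} {row.query} {row.qbegin} {row.qend} "
                f"({row.qleft}) {row.strand} {row.family} {row.class_family} "
                f"{row.rbegin} {row.rend} ({row.rleft}) {row.copy_id}\n"
            )
        return buf.getvalue()


def simulate_te_history(cfg: SimConfig) -> TEHistory:
    """Simulate TE bursts: copies diverged from a family consensus.

    Each burst time ``t_b`` produces one family (class cycling over
    SINE/LINE/LTR/DNA) of ``copies_per_burst`` copies, each evolved from the
    family consensus for age ``t_b + Normal(0, age_jitter_sd)`` truncated at
    0 by resampling, with effective branch length ``2 r age`` (two-lineage
    divergence convention, see module docstring).  The annotation table
    reports D as the exact aligned percent mismatch to the consensus.
    """
    if len(cfg.burst_times) < 1:
        raise ValueError("at least one burst time is required")
    if any(t < 0 for t in cfg.burst_times):
        raise ValueError("burst times must be non-negative")
    if cfg.copy_length < 50:
        raise ValueError(
            "copy_length below 50 bp: divergence estimate too noisy"
        )
    rng = np.random.default_rng(cfg.seed)
    copies: dict[str, str] = {}
    consensi: dict[str, str] = {}
    ann_rows = []
    truth_rows = []
    for b, t_b in enumerate(cfg.burst_times):
        te_class = TE_CLASSES[b % len(TE_CLASSES)]
        family = f"FAM{b}"
        consensus = random_sequence(cfg.copy_length, rng)
        consensi[family] = consensus
        for i in range(cfg.copies_per_burst):
            age = t_b
            if cfg.age_jitter_sd > 0:
                age = -1.0
                while age < 0:
                    age = t_b + rng.normal(0.0, cfg.age_jitter_sd)
            copy_id = f"{family}_copy{i}"
            seq = evolve_sequence_jc(consensus, 2.0 * cfg.rate_r, age, rng)
            copies[copy_id] = seq
            D, _ = raw_divergence(seq, consensus)
            qbegin = 1 + i * (cfg.copy_length + 10)
            ann_rows.append(
                dict(
                    score=1000,
                    perc_div=round(D, 2),
                    perc_del=0.0,
                    perc_ins=0.0,
                    query=f"chr{(b % 5) + 1}",
                    qbegin=qbegin,
                    qend=qbegin + cfg.copy_length - 1,
                    qleft=0,
                    strand="+" if i % 2 == 0 else "C",
                    family=family,
                    class_family=f"{te_class}/{family}",
                    rbegin=1,
                    rend=cfg.copy_length,
                    rleft=0,
                    copy_id=len(ann_rows) + 1,
                )
            )
            truth_rows.append(
                dict(
                    copy_id=copy_id,
                    family=family,
                    te_class=te_class,
                    true_age_myr=age,
                    true_D=D,
                )
            )
    return TEHistory(
        copies=copies,
        consensi=consensi,
        annotation=pd.DataFrame(ann_rows),
        truth=pd.DataFrame(truth_rows),
    )


# ---------------------------------------------------------------------------
# Paralog families


@dataclass
class ParalogFamily:
    """Serially duplicated CDS family with known pairwise split ages.

    ``cds`` maps gene id -> unaligned (equal-length, gapless) CDS;
    ``truth`` has one row per unordered pair: id_a, id_b, true_age_myr.
    """

    cds: dict[str, str]
    truth: pd.DataFrame


def _evolve_cds(
    cds: str, syn_rate: float, nonsyn_rate: float, t: float,
    rng: np.random.Generator,
) -> str:
    """Evolve a CDS for time t with separate syn / nonsyn site-class rates.

    Per codon, a continuous-time chain over single-base neighbours: each
    synonymous change has rate syn_rate/3, each nonsynonymous change
    nonsyn_rate/3, changes to stops rate 0 (stop-creating mutations are
    never emitted).
    """
    out = []
    for i in range(0, len(cds), 3):
        codon = cds[i:i + 3]
        time_left = t
        while True:
            neigh = []
            rates = []
            for pos in range(3):
                for alt in "ACGT":
                    if alt == codon[pos]:
                        continue
                    mutant = codon[:pos] + alt + codon[pos + 1:]
                    if mutant in STOP_CODONS:
                        continue
                    neigh.append(mutant)
                    syn = GENETIC_CODE[mutant] == GENETIC_CODE[codon]
                    rates.append((syn_rate if syn else nonsyn_rate) / 3.0)
            total = sum(rates)
            if total <= 0:
                break
            wait = rng.exponential(1.0 / total)
            if wait >= time_left:
                break
            time_left -= wait
            probs = np.asarray(rates) / total
            codon = neigh[rng.choice(len(neigh), p=probs)]
        out.append(codon)
    return "".join(out)


def simulate_paralog_family(cfg: SimConfig) -> ParalogFamily:
    """Simulate serial tandem duplication of a CDS at the given ages.

    ``cfg.dup_times`` are duplication ages in Myr, sorted ascending.  Events
    are applied from the oldest forward in time; at each event the most
    recently created copy duplicates, after which all copies evolve
    independently (nonsynonymous sites at ``rate_r``, synonymous sites at
    ``syn_rate``, default equal).  The truth table records each pair's
    divergence age (the age of their most recent common duplication).
    """
    times = list(cfg.dup_times)
    if times != sorted(times):
        raise ValueError("dup_times must be sorted ascending")
    if cfg.codon_count < 100:
        raise ValueError("codon_count must be at least 100")
    rng = np.random.default_rng(cfg.seed)
    syn_rate = cfg.rate_r if cfg.syn_rate is None else cfg.syn_rate
    root = random_cds(cfg.codon_count, rng)

    # lineages: list of (sequence, id); split_age[(i,j)] = age of the
    # duplication separating lineages i and j
    seqs = [root]
    split_age: dict[tuple[int, int], float] = {}
    prev_age = None
    for age in sorted(times, reverse=True):  # oldest event first
        # evolve all current lineages from the previous event down to `age`
        if prev_age is not None and prev_age > age:
            dt = prev_age - age
            seqs = [
                _evolve_cds(s, syn_rate, cfg.rate_r, dt, rng) for s in seqs
            ]
        new_idx = len(seqs)
        src_idx = len(seqs) - 1  # most recently created copy duplicates
        seqs.append(seqs[src_idx])
        for i in range(new_idx):
            split_age[(i, new_idx)] = (
                age if i == src_idx else split_age[tuple(sorted((i, src_idx)))]
            )
        prev_age = age
    # evolve everyone from the last event to the present
    if prev_age is not None and prev_age > 0:
        seqs = [_evolve_cds(s, syn_rate, cfg.rate_r, prev_age, rng) for s in seqs]

    ids = [f"par{i}" for i in range(len(seqs))]
    truth_rows = [
        dict(id_a=ids[i], id_b=ids[j], true_age_myr=split_age[(i, j)])
        for (i, j) in sorted(split_age)
    ]
    return ParalogFamily(
        cds=dict(zip(ids, seqs)), truth=pd.DataFrame(truth_rows)
    )


# ---------------------------------------------------------------------------
# Ortholog triplets


@dataclass
class OrthologTripletSet:
    """Three-species ortholog alignments with known per-branch truth.

    ``alignments`` is a list of dicts ``{"A": seq, "B": seq, "C": seq}``
    (gapless, equal length).  ``hits`` maps ('A','B')-style directed species
    pairs to 12-column hit tables.  ``truth`` records the configured rates
    and times plus the true ortholog pairing per species pair.
    """

    alignments: list[dict[str, str]]
    hits: dict[tuple[str, str], pd.DataFrame]
    truth: pd.DataFrame
    rates: dict[str, float]
    ingroup_time: float
    outgroup_time: float


def _hit_row(q: str, s: str, length: int, bitscore: float, evalue: float):
    return dict(
        qseqid=q, sseqid=s, pident=95.0, length=length, mismatch=0,
        gapopen=0, qstart=1, qend=length, sstart=1, send=length,
        evalue=evalue, bitscore=bitscore,
    )


def simulate_ortholog_triplets(cfg: SimConfig) -> OrthologTripletSet:
    """Simulate single-copy ortholog triplets on a fixed 3-taxon tree.

    Species A and B split ``ingroup_time`` Myr ago; their ancestor split
    from outgroup C ``outgroup_time`` Myr ago.  Each lineage evolves at its
    configured rate (the internal root-to-AB-ancestor branch at ``rate_c``).
    Directed pairwise hit tables are emitted whose mutual best hits equal the
    true ortholog pairs; with ``noise_frac > 0`` that fraction of hits is
    cyclically misassigned, so the corresponding mutual-best-hit pairs
    disagree with truth.
    """
    if cfg.outgroup_time <= cfg.ingroup_time:
        raise ValueError("outgroup divergence must predate ingroup divergence")
    rng = np.random.default_rng(cfg.seed)
    alignments = []
    for _ in range(cfg.n_triplets):
        root = random_sequence(cfg.alignment_length, rng)
        anc_ab = evolve_sequence_jc(
            root, cfg.rate_c, cfg.outgroup_time - cfg.ingroup_time, rng
        )
        alignments.append(
            {
                "A": evolve_sequence_jc(anc_ab, cfg.rate_a, cfg.ingroup_time, rng),
                "B": evolve_sequence_jc(anc_ab, cfg.rate_b, cfg.ingroup_time, rng),
                "C": evolve_sequence_jc(root, cfg.rate_c, cfg.outgroup_time, rng),
            }
        )

    n = cfg.n_triplets
    n_noisy = int(round(cfg.noise_frac * n))
    noisy = rng.choice(n, size=n_noisy, replace=False) if n_noisy else np.array([], int)

    hits: dict[tuple[str, str], pd.DataFrame] = {}
    truth_rows = []
    for sp_q, sp_s in [("A", "B"), ("B", "A"), ("A", "C"), ("C", "A"),
                       ("B", "C"), ("C", "B")]:
        partner = np.arange(n)
        if n_noisy >= 2:
            # cyclic shift among the noisy subset, applied identically in
            # both directions so the wrong pairs remain reciprocal
            partner[noisy] = np.roll(noisy, 1)
        rows = []
        for q in range(n):
            p = partner[q] if sp_q < sp_s else int(np.nonzero(partner == q)[0][0])
            qid = f"{sp_q}_g{q}"
            best = f"{sp_s}_g{p}"
            rows.append(_hit_row(qid, best, cfg.alignment_length, 900.0, 1e-180))
            decoy = (q + 1) % n
            rows.append(
                _hit_row(qid, f"{sp_s}_g{decoy}", cfg.alignment_length // 2,
                         200.0, 1e-30)
            )
        hits[(sp_q, sp_s)] = pd.DataFrame(rows)
    for q in range(n):
        truth_rows.append(
            dict(triplet=q, id_a=f"A_g{q}", id_b=f"B_g{q}", id_c=f"C_g{q}")
        )
    return OrthologTripletSet(
        alignments=alignments,
        hits=hits,
        truth=pd.DataFrame(truth_rows),
        rates={"A": cfg.rate_a, "B": cfg.rate_b, "C": cfg.rate_c},
        ingroup_time=cfg.ingroup_time,
        outgroup_time=cfg.outgroup_time,
    )


# ---------------------------------------------------------------------------
# Karyotype evolution


@dataclass
class KaryotypeSim:
    """Two species' gene coordinates with known rearrangement history.

    Species A retains the 1 ALG = 1 chromosome identity karyotype and doubles
    as the ALG reference; species B applies the rearrangement directives.
    ``loci_a``/``loci_b`` are 6-column BED-style tables; ``hits`` the two
    directed hit tables; ``alg_map`` the reference gene -> ALG table;
    ``truth`` per-gene true ALG and B-chromosome plus the event list.
    """

    loci_a: pd.DataFrame
    loci_b: pd.DataFrame
    hits: dict[tuple[str, str], pd.DataFrame]
    alg_map: pd.DataFrame
    truth_genes: pd.DataFrame
    truth_events: pd.DataFrame


def _parse_directive(directive: str) -> tuple[str, list[str], list[str]]:
    """Parse 'fuse(ALG3,ALG10)->C7' / 'fission(ALG4)->C8,C9' /
    'translocate(0.3,ALG2)->C2'."""
    directive = directive.strip().replace("→", "->")
    head, _, target = directive.partition("->")
    head = head.strip()
    targets = [t.strip() for t in target.split(",")] if target else []
    op, _, args = head.partition("(")
    args = [a.strip() for a in args.rstrip(")").split(",")]
    op = op.strip().lower()
    if op not in ("fuse", "fission", "translocate"):
        raise ValueError(f"unknown karyotype directive: {directive!r}")
    return op, args, targets


def simulate_karyotype_evolution(cfg: SimConfig) -> KaryotypeSim:
    """Simulate karyotype rearrangement against an ALG-identity ancestor.

    Starts from ``n_algs`` ancestral linkage groups with ``genes_per_alg``
    genes each.  Species B applies the ``karyotype_spec`` directives in
    order; ``noise_frac`` then reassigns that fraction of B genes to a
    uniformly random chromosome (emulating homology-mapping error).  Gene
    orders within chromosomes are shuffled.  The hit tables link true
    orthologs as mutual best hits.
    """
    rng = np.random.default_rng(cfg.seed)
    algs = [f"ALG{i + 1}" for i in range(cfg.n_algs)]
    genes = {
        alg: [f"{alg}_g{j}" for j in range(cfg.genes_per_alg)] for alg in algs
    }

    # species B chromosome assignment starts as identity: ALGi -> Bi
    chrom_of: dict[str, str] = {}
    for i, alg in enumerate(algs):
        for g in genes[alg]:
            chrom_of[g] = f"B{i + 1}"
    live = {f"B{i + 1}" for i in range(cfg.n_algs)}
    alg_to_chrom = {alg: f"B{i + 1}" for i, alg in enumerate(algs)}

    events = []
    for directive in cfg.karyotype_spec:
        op, args, targets = _parse_directive(directive)
        for a in args:
            if op in ("fuse", "fission") and a not in algs:
                raise ValueError(f"directive references unknown group: {a}")
        if op == "fuse":
            new_c = targets[0] if targets else f"B_{'_'.join(args)}"
            sources = []
            for alg in args:
                src = alg_to_chrom[alg]
                if src not in live:
                    raise ValueError(
                        f"directive references consumed chromosome: {src}"
                    )
                sources.append(src)
                live.discard(src)
            live.add(new_c)
            for g, c in chrom_of.items():
                if c in sources:
                    chrom_of[g] = new_c
            for alg in args:
                alg_to_chrom[alg] = new_c
            events.append(dict(type="fusion", algs=";".join(args), chrom=new_c))
        elif op == "fission":
            alg = args[0]
            src = alg_to_chrom[alg]
            if src not in live:
                raise ValueError(f"directive references consumed chromosome: {src}")
            c1, c2 = (targets + [f"{src}a", f"{src}b"])[:2]
            members = [g for g, c in chrom_of.items() if c == src]
            half = rng.permutation(len(members))
            for k, g in enumerate(members):
                chrom_of[g] = c1 if half[k] < len(members) / 2 else c2
            live.discard(src)
            live.update((c1, c2))
            alg_to_chrom[alg] = c1
            events.append(dict(type="fission", algs=alg, chrom=f"{c1};{c2}"))
        else:  # translocate
            frac = float(args[0])
            alg = args[1]
            src = alg_to_chrom[alg]
            if src not in live:
                raise ValueError(f"directive references consumed chromosome: {src}")
            dest = targets[0] if targets else sorted(live - {src})[0]
            members = [g for g in genes[alg] if chrom_of[g] == src]
            n_move = int(round(frac * len(members)))
            moved = rng.choice(len(members), size=n_move, replace=False)
            for k in moved:
                chrom_of[members[k]] = dest
            live.add(dest)
            events.append(
                dict(type="translocation", algs=alg, chrom=f"{src}->{dest}")
            )

    all_genes = [g for alg in algs for g in genes[alg]]
    alg_of = {g: alg for alg in algs for g in genes[alg]}

    # mapping noise: reassign a random fraction of B genes to random chromosomes
    chrom_list = sorted(live)
    n_noisy = int(round(cfg.noise_frac * len(all_genes)))
    if n_noisy:
        noisy_idx = rng.choice(len(all_genes), size=n_noisy, replace=False)
        for k in noisy_idx:
            chrom_of[all_genes[k]] = chrom_list[rng.integers(len(chrom_list))]

    gene_len = 1000
    rows_a = []
    for i, alg in enumerate(algs):
        order = rng.permutation(cfg.genes_per_alg)
        for rank, j in enumerate(order):
            start = rank * (gene_len + 500)
            rows_a.append(
                dict(chrom=f"A{i + 1}", start=start, end=start + gene_len,
                     name=f"refA_{genes[alg][j]}", score=0, strand="+")
            )
    by_chrom: dict[str, list[str]] = {}
    for g in all_genes:
        by_chrom.setdefault(chrom_of[g], []).append(g)
    rows_b = []
    for c in sorted(by_chrom):
        members = by_chrom[c]
        order = rng.permutation(len(members))
        for rank, j in enumerate(order):
            start = rank * (gene_len + 500)
            rows_b.append(
                dict(chrom=c, start=start, end=start + gene_len,
                     name=f"focB_{members[j]}", score=0, strand="+")
            )

    hits_ab = pd.DataFrame(
        [_hit_row(f"focB_{g}", f"refA_{g}", gene_len, 800.0, 1e-150)
         for g in all_genes]
    )
    hits_ba = pd.DataFrame(
        [_hit_row(f"refA_{g}", f"focB_{g}", gene_len, 800.0, 1e-150)
         for g in all_genes]
    )
    alg_map = pd.DataFrame(
        [dict(gene_id=f"refA_{g}", alg=alg_of[g]) for g in all_genes]
    )
    truth_genes = pd.DataFrame(
        [dict(gene_id=f"focB_{g}", alg=alg_of[g], chrom=chrom_of[g])
         for g in all_genes]
    )
    return KaryotypeSim(
        loci_a=pd.DataFrame(rows_a),
        loci_b=pd.DataFrame(rows_b),
        hits={("B", "A"): hits_ab, ("A", "B"): hits_ba},
        alg_map=alg_map,
        truth_genes=truth_genes,
        truth_events=pd.DataFrame(
            events, columns=["type", "algs", "chrom"]
        ),
    )
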