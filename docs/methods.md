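# Methods

## Model and dating equation

All dating in this package rests on a single substitution model:
Jukes–Cantor (JC), i.e. all four bases equally frequent and all
substitutions equally likely. Observed divergence *D* (percent of compared
sites) is corrected for multiple hits as K = −75·ln(1 − D/75); the percent
scale matches the constant 300 = 4×75 in the correction as usually printed.
The correction is undefined at D ≥ 75% (the infinite-time expectation);
such records are flagged *saturated* and **excluded** from landscapes and
reports rather than clamped — clamping would fabricate arbitrarily old ages.

An event's age is T = K/(2r): the corrected divergence *K* (substitutions
per site) is assumed to have accumulated along **two** lineages since the
event, each evolving at rate *r* (substitutions/site/Myr). For a paralog
pair this is the natural reading — both copies drift after the duplication.
For a TE copy versus its family consensus the same convention is applied:
the copy and the (reconstructed ancestral) consensus lineage are treated as
two diverging lines. The synthetic generator follows the identical
convention — a copy of age *t* is evolved with effective branch length
2·r·t — so simulation and analysis share one model and parameter recovery
is a meaningful check of the code, not of the convention itself.

## Nei–Gojobori counting

dN/dS uses the unweighted NG86 scheme. Site counts: each codon position
contributes (synonymous single-base changes)/(counted single-base changes),
where changes creating a stop codon are excluded from numerator and
denominator; the position's nonsynonymous share is the complement, so
s + n = 3 per codon exactly (the per-position renormalised convention).
Differences: multi-position codon differences are averaged over all
orderings of single-base steps; pathways passing through a stop are
excluded and the remaining pathway weights renormalised (if no stop-free
pathway exists — not attainable for 1- and 2-step differences under the
standard code — all pathways are used and unclassified stop steps count as
nonsynonymous). Proportions pS = Sd/S and pN = Nd/N are JC-corrected as
d = −(3/4)·ln(1 − 4p/3), saturating at p ≥ 3/4. Codons containing a gap or
ambiguity in either sequence are dropped pairwise. The implementation is
verified exactly, site-by-site and pathway-by-pathway, against an
independent brute-force enumerator in the test suite.

Duplication ages use **dN** by default. dN is a conservative clock (it
saturates slowly but runs at the nonsynonymous rate, so the calibrating
rate must be a nonsynonymous rate for absolute ages to be meaningful); a
dS mode with identical plumbing is available behind `use_ds=True` /
`--use-ds` for families young enough that synonymous sites are not
saturated.

## Rate calibration

The three-taxon additive decomposition replaces a maximum-likelihood
free-ratio fit: for three taxa the pairwise distances carry exactly the
information of the three branch lengths, so
a = (d_AB + d_AC − d_BC)/2 (and cyclically) is the complete solution, and
it is testable against simulation truth at desk scale. Negative branches
(noise-induced triangle violations) are clamped to 0 and flagged.

Each ingroup branch is divided by the ingroup divergence time and the
outgroup branch by the outgroup divergence time; species rates are
alignment-length-weighted means over triplets, with dispersion from 200
seeded bootstrap resamples. The outgroup normalisation is a deliberate
simplification: the outgroup branch of the unrooted triplet actually spans
2·t_out − t_in of lineage time, so the reported outgroup rate is inflated
by roughly (2 − t_in/t_out) and should be read as a relative quantity
only. The two ingroup rates — the quantities the dating pipeline consumes —
are unbiased, and simulation recovery confirms them within 10% at 200
triplets × 1.5 kb.

Pairwise distances for triplets come from gap-aware raw divergence plus the
JC correction. JC nucleotide distances saturate near p = 0.75; the default
simulated outgroup split (200 Ma at r ≈ 0.002) keeps the deepest pairwise
divergence comfortably inside the correction's domain. For much older
outgroups a distance measure with a deeper working range would be needed;
that is outside this package's scope.

## TE landscapes and burst detection

The repeat-annotation parser reads the 15-column `.out` dialect (three
header lines, optional trailing `*`), merges fragments sharing a copy id
into one element with length-weighted mean divergence, and normalises
strand `C` to `-`. The divergence column is treated as **raw** percent
mismatch and JC-corrected here; if the table was produced with an internal
(e.g. Kimura) correction, pass `correct=False` / `--no-correct` to avoid
double-correcting.

Landscapes are per-class (SINE/LINE/LTR/DNA; rolling-circle elements count
as DNA transposons; everything else is ignored) histograms of T, weighted
by base pairs (standard repeat-landscape practice; copy counts are also
recorded). Defaults: 1-Myr bins, 3-bin moving-average smoothing — both
configurable; neither is canonical.

Peak detection uses an **edge-corrected** moving average (window sums
divided by actual coverage, so a flat series stays flat at the
boundaries), then finds runs of equal smoothed value strictly above both
flanking values; an edge run needs only its inner flank, and a run
spanning the whole series (uniform landscape) is never a peak. Since
smoothing turns an isolated spike into a plateau, a peak run reports the
bin with the largest raw value (tie → youngest). Peaks are ranked by
smoothed height, ties younger-first.

## Macrosynteny

ALG assignment is by inheritance: a focal gene takes the ALG of its
reciprocal-best reference partner (ties in the best-hit choice broken by
bitscore, then e-value, alignment length, and subject id, so results are
deterministic). Enrichment of each chromosome×ALG cell is a one-sided
hypergeometric tail test against the assigned-gene background,
BH-corrected across all cells; a cell is *significant* at q < 0.05 with at
least 5 genes. These thresholds, and the event-call thresholds below, are
package choices made to match common macrosynteny practice — they are not
canonical values.

Event calls: fusion = one chromosome significant for ≥2 ALGs each holding
≥20% of the chromosome's genes; fission = one ALG significant on ≥2
chromosomes each holding ≥20% of the ALG's genes; translocation = a
minority cell holding 5–20% of its ALG's genes off the majority
chromosome. Translocation cells are gated on the **raw** per-cell
hypergeometric p < 0.05 plus the 5-gene minimum rather than the
BH-corrected q: the BH correction across hundreds of mostly-empty cells
has essentially no power against a genuine 10–15% minority cell at
desk-scale gene counts, while the min-count gate already suppresses
mapping noise. A transferred block larger than the 20% band is, by
construction, reported as a fusion-like split (receiving chromosome gains
a second significant ALG; the donor ALG may additionally be called
fissioned) — the thresholds partition one continuum of block sizes.

The conservation index CI = Σ_c max_g n[c,g] / N is the fraction of
assigned orthologs lying on their chromosome's dominant ALG. No canonical
published formula could be confirmed for this statistic, so this
definition is **local to the package** and recorded in output metadata;
CI = 1 for perfect conservation, and under uniform random reassignment of
a fraction f of genes among m chromosomes the expectation is
1 − f + f/m (the closed form the tests check).

## Synthetic generator

The generator emulates exactly the model the analyses assume, no more:

* **Sequence evolution** is site-independent JC — each site substitutes
  with p = (3/4)(1 − e^(−4rt/3)), uniformly among the three alternatives.
  No indels, no rate heterogeneity, no base-composition bias.
* **TE families**: one family per burst (class cycling through the four TE
  classes), copies evolved from a random consensus at effective branch
  length 2·r·(burst age + optional truncated-normal jitter, default 0 —
  whether real bursts carry within-burst age dispersion is unknowable from
  the data this emulates). The annotation reports the exact aligned percent
  mismatch.
* **Paralog families** duplicate serially (the most recent copy duplicates
  at each event age, oldest event first); codons evolve by a continuous-time
  chain over single-base neighbours with synonymous changes at `syn_rate`
  and nonsynonymous at `rate_r` (each neighbour at rate/3), stop-creating
  changes at rate 0 — so no internal stop is ever emitted and NG86-dN
  recovery has a known target of 2·r·t per pair.
* **Ortholog triplets** evolve on the fixed ((A,B),C) tree with per-lineage
  rates; the internal branch uses the outgroup's rate. Emitted hit tables
  make true orthologs mutual best hits; `noise_frac` cyclically misassigns
  that fraction of partners (reciprocally, so the wrong pairs survive RBH —
  emulating paralog confusion).
* **Karyotypes** start from 17 identity ALGs; directives
  `fuse(ALGi,ALGj)->C`, `fission(ALGi)->C1,C2`,
  `translocate(frac,ALGi)->C` are applied in order, then `noise_frac`
  reassigns genes to uniformly random chromosomes (emulating
  homology-mapping error, including back onto the correct chromosome —
  hence the 1 − f + f/m CI expectation).

Because the generator realises the analysis model, passing recovery tests
demonstrates correctness of the implementation under that model — not
robustness to the ways real genomes violate it (indels and alignment
error, rate variation across sites and families, TE nesting and deletion
bias, incomplete lineage sorting, paralogy in "single-copy" sets). Those
violations would mostly bias ages through the rate parameter, which is why
the rate's provenance is carried on `LineageRate` records.

Determinism: every operation takes a seed (or an explicitly passed
generator); one global RNG stream per operation. Identical config + seed
reproduces all outputs byte-for-byte, which the test suite and the
acceptance script both verify on the full pipeline.

## Default study conditions and problem sizes

The validation scenarios fix: TE bursts of 300 copies × 1 kb at 10 Ma with
r = 0.005/site/Myr; 200 ortholog triplets × 1.5 kb with r_A = 0.002,
r_B = 0.004, splits at 62.7 and 200 Ma; paralog duplications at 20 Ma
(500 codons, r = 0.002) and serial 5/40 Ma; karyotypes of 17 ALGs × 100
genes with 2 fusions + 1 fission at 2% mapping noise, and CI calibration at
10% noise. Replicate counts (20–50 seeds) give binomial error bars small
enough to distinguish the recovery targets (10–15% relative tolerances)
from failure while keeping the full suite under a minute of CPU.

## Numerical choices and degenerate inputs

* Saturation boundaries are closed (D ≥ 75, p ≥ 3/4 → `nan` + flag).
* `raw_divergence` rejects zero comparable columns rather than returning 0.
* Branch clamping at 0 is flagged, never silent.
* Age-jitter truncation at 0 is by resampling (no probability mass piles
  up at exactly 0).
* RBH and best-hit ties are broken deterministically (bitscore, e-value,
  length, lexicographic id).
* Single-linkage event ordering imputes saturated pairwise ages just above
  the oldest finite age — for ordering only; reported age matrices keep
  `nan`.
* The pipeline validates every referenced input file before any stage runs
  (no partial writes on config errors); a stage failure leaves completed
  stage outputs and a manifest naming the failed stage.

## Known limitations

* JC-only distances: no transition/transversion weighting anywhere
  (deliberate — the unweighted NG86 and the percent-scale JC correction
  are the methods being implemented).
* The outgroup lineage rate is a flagged, biased convenience quantity.
* Translocations below ~10 genes or ~5% of an ALG are undetectable at
  default thresholds; blocks above 20% surface as fusion-like splits.
* The CI definition is package-local; comparisons to CI values computed
  under other definitions are not meaningful.
* TE ages inherit every bias of the annotation's divergence column; the
  `--no-correct` escape hatch only handles the double-correction case.
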