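# Methods

## The killer–protector viability model

An allele is a named set of functional components; a locus is one
indivisible linkage unit (the three native *S1* genes are tightly
linked and form a single allele's component set; transgene insertions
are separate, independently assorting loci). A diploid genotype assigns
an unordered allele pair to every locus.

The model has two rules with deliberately different scopes:

- **Arming (sporophytic).** The killer arms iff the union of components
  over *both allele copies at all loci* of the parent plant contains
  the killer set (default {A4, TPR, A6}). The union is taken across
  loci because unlinked transgenes complement each other in trans: a
  plant hemizygous for an A4–A6 insertion and a TPR insertion arms the
  killer exactly as the native linked block does.
- **Protection (gametophytic).** When the killer is armed, a haploid
  gamete survives with probability 1 if its own component union
  contains the protector set (default {TPR}), and with probability
  1 − *k* otherwise, where *k* is the sex-specific abortion
  probability. Only the gamete's own contents count; S1TP is an inert
  component and confers nothing.

Gametes are enumerated by independent assortment (1/2 per allele per
locus, identical classes merged by exact allele-name equality), weights
are renormalised after selection, and the surviving mass is recorded as
the viable fraction. Fertility per sex equals that fraction; spikelet
fertility is taken to be the female fraction, with pollen assumed in
excess (observed pollen and spikelet semi-sterility co-occur, and no
pollen-limitation mechanism is modelled). Progeny distributions are the
outer product of the maternal (female) and paternal (male)
post-selection pools; genotype classes are canonical sorted pairs with
the null allele ("-") ordered last, giving the conventional labels
`gs`, `T-`, `--`.

With the default *k* = 1 this reproduces the idealised expectations:
50% fertility for an *S1* heterozygote, 75% with one unlinked
hemizygous protector copy, 100% with a homozygous protector; 4:4:1 for
both loci in the protected-heterozygote self; 1:2:1 at *S1* with a
fixed transgene in the killer-knockout design. *k* < 1 models
incomplete penetrance; the surviving driver-gamete fraction from a
heterozygote is 1/(2 − *k*).

### Parameters

| parameter | meaning | default |
|---|---|---|
| `killer_components` | sporophytic arming requirement | {A4, TPR, A6} |
| `protector_components` | gametophytic survival requirement | {TPR} |
| `abort_prob_male` / `abort_prob_female` | P(unprotected gamete aborts), per sex | 1.0 |

Male and female abortion probabilities are separate parameters with
equal defaults; nothing in the modelled observations distinguishes
them, and matching pollen/spikelet fertilities suggest they are
similar. The ~95% ceiling of "fully fertile" field plants is background
sterility, outside the model: fertility 1.0 means "no model-induced
abortion".

## Segregation analysis

Observed genotype-class counts are tested with a Pearson χ²
goodness-of-fit (statistic Σ(O−E)²/E over classes with E > 0, upper
tail of the χ² distribution, df = classes − 1, no continuity or
multiple-testing correction — single planned tests). Classes with
expected probability 0 and observed count 0 are dropped before df;
an observed count in a zero-probability class raises a
model-contradiction error instead of an infinite statistic, since the
*k* = 1 model genuinely assigns zero mass to classes real data may
contain — the remedy is to fit *k* < 1. Transmission ratios use the
Wilson interval (small-count stability, never outside [0, 1]).

The abortion probability is estimated by maximising the multinomial
likelihood of the class counts over *k* ∈ [0, 1] (bounded Brent,
tolerance 1e-8; the two boundary values are evaluated explicitly so a
boundary maximum is exact), with a profile-likelihood 95% interval
(log-likelihood drop of χ²₁,₀.₉₅/2, bounds by Brent root-finding).
`CrossDesign.with_pooling` lets observed categories lump model classes
together, for scoring schemes that cannot resolve every genotype —
e.g. a dominant marker (carrier vs non-carrier), or a report giving
only the homozygote fraction. With fully resolved classes and only the
homozygote fraction 0.758 observed, the pooled fit solves
(1/(2 − k))² = 0.758 giving k ≈ 0.851. A design whose class
probabilities do not vary with *k* raises a non-identifiability error.
A separate one-line inverter recovers *k* from an observed fertility,
using the monotone non-increasing fertility–*k* relationship.

On synthetic F2 data (multinomial, n = 500, 200 replicates per true
*k* ∈ {0.2, 0.5, 0.85, 1.0}) the estimator's mean error is < 0.02 and
profile-interval coverage sits in the nominal band for interior *k*;
at the boundary *k* = 1 the interval always contains the truth
(coverage 1 by construction), the expected behaviour of a profile
interval at a parameter-space boundary.

## Drive dynamics

Genotype-class frequencies at the focal locus (plus any unlinked loci)
are propagated by one application of the viability model per
generation. Under **selfing** (default — the modelled F2s are selfed
F1s) each genotype unites its own surviving gamete pools; under
**random mating** all genotypes shed survivors into pooled male and
female gamete clouds that unite at random. In both systems a
genotype's offspring contribution is weighted by frequency × viable
gamete fraction (a semi-sterile plant sets proportionally fewer seeds);
this choice matters only for mixed populations, not for the
single-genotype founders used in the headline predictions. One selfed
generation from a heterozygote at *k* = 0.95 gives driver frequency
0.952 ≈ 0.95. Under selfing the driver plateaus just short of fixation:
fully fertile non-driver homozygotes escape killing entirely and breed
true, an equilibrium the deterministic recursion exposes.

The stochastic mode resamples N individuals multinomially from the
deterministic expectation each generation (a Wright–Fisher scheme with
fertility selection). Replicate r uses a generator seeded seed + r,
so runs are reproducible and replicates independent. Fixation is not
special-cased. With *k* = 0 the driver frequency is a martingale; this
is verified over 2000 replicates.

## Haplotype typing

Presence/absence of *S1A4*/*S1A6* uses breadth of coverage: the
fraction of interval positions at per-base depth ≥ 2 must reach 0.8
(both thresholds exposed as flags; breadth is robust to uneven
coverage, and the calls are monotone in depth). Depth input is 3-column
chrom/pos/depth text; positions missing from the file count as depth 0,
which makes the `samtools depth` default and `-a` dialects equivalent.
Gene intervals come from BED (0-based half-open) and are converted to
1-based inclusive coordinates internally; the conversion is tested
explicitly. SNP states are read from VCF — only the seven panel sites
are consulted; missing or heterozygous genotypes yield "N" (accessions
are inbred lines; a het call is treated as missing, not guessed). The
TPR/TP call is the site-7 stop-gain state; anything but the two
panel-defined nucleotides makes the accession untypable, reported as
such. Panel states are defined on the forward strand of the reference
layout; no reverse-complement handling. The named-allele catalog
(pattern → allele class) ships as an editable YAML of clearly marked
synthetic placeholder entries — it is configuration, not code; unknown
patterns classify as "novel".

## Synthetic data

All generators are pure functions of (configuration, seed), and the
defaults are the study-like conditions used throughout the tests:
progeny counts are multinomial draws from the model's class
probabilities; depth profiles are independent Poissons (mean 30 for
present genes; mean 30 × 0.01 contamination for absent genes —
cross-mapping noise, no GC or mappability bias); accession panels pair
an African-rice-like lineage (three-gene A4-TPR-A6 structure,
all-reference SNP pattern) with an Asian-rice-like lineage (one-gene
TP structure, derived states at sites 1, 3, 4, 6 and the stop-gain
site), written one VCF per accession plus a depth TSV, a gene BED and
a ground-truth table under a run directory named by seed.

These generators emulate the sampling noise of genotyped families and
the coverage signal of mapped short reads, not real sequencing:
no read-level errors, no mapping bias, no linkage disequilibrium
beyond the modelled loci, no population structure within lineages.
Passing tests therefore demonstrate correctness of the inference
machinery under the model's own assumptions, not robustness to
artefacts of real resequencing panels.

## Numerical choices and problem sizes

Probability bookkeeping is double precision with sums checked to
1e-12. Optimisation tolerances are 1e-8 (ML and root-finding).
Monte-Carlo checks use 10,000 multinomial resamples (χ² p-values,
compared within 0.01 at df ≤ 4 on count configurations large enough
that lattice discreteness is below that tolerance), 200 replicates ×
n = 500 for estimator calibration, 2000 replicates at N = 50 for the
martingale check, and N = 100,000 for the law-of-large-numbers check
of the stochastic mode. The default test suite and the acceptance
script each run in well under a minute on one CPU.

## Known limitations

No recombination within or between loci (each locus is an indivisible
unit; the native three-gene block never recombines). No mutation,
migration, or fitness effects beyond gamete viability. No molecular
mechanism (protein complexes, pathways) — the model is purely
combinatorial over component sets. Killing penetrance is a free
parameter: the observed 75.8% transgene homozygote excess in real
plants reflects an unknown efficiency and is treated as something to
estimate, not to reproduce.
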