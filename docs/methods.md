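# Methods

`amphase` reconstructs the two allele sequences of amplicon-sequenced genes
in a heterozygous diploid F1 (double pseudo-testcross) family and tests
alleles for association with a flowering-time phenotype. This note records
the models, the parameter choices, and the limits of what the synthetic
validation shows.

## Population and nomenclature model

The design is a cross of two heterozygous parents: a maternal line
contributing alleles E1/E2 ("early") and a paternal line contributing L1/L2
("late") at every locus. Barring recombination, each offspring inherits
exactly one maternal and one paternal allele per gene, and linked genes in
one region share the same transmitted pair. Parental alleles may coincide
in sequence; the identity pattern of {E1, E2, L1, L2} is one of the 15 set
partitions of four labeled items, collapsed to 14 codes because the two
single-cross-pair partitions (E1=L2 alone, E2=L1 alone) share the code `N`.
The all-identical situation has no conventional printed symbol; this
package uses `N0` for it, and `NN` for the double-cross partition
(E1=L2 and E2=L1), the only consistent completion of the 14-code set.
Sequence identity is exact string equality over the compared interval by
default; a tolerance flag exists but near-identical alleles (one mismatch)
are deliberately distinct, since the nomenclature is defined on identity.

## Phasing: minimum error correction

Fragments (read pairs) observing at least two heterozygous sites are the
phasing evidence; a fragment covering one site carries no linkage
information and is discarded. Because every phased site is heterozygous,
the haplotype pair is a single binary vector per connected component of the
fragment-site graph, and the objective is the minimum error correction
(MEC) score: the number of fragment calls that must be flipped so each
fragment is consistent with one haplotype.

Two solvers share this objective:

* `phase_exact` enumerates all `2^(k-1)` candidate vectors per component
  (first site fixed, breaking the global-swap symmetry), with mismatch
  counts computed by matrix products; components are capped at 20 sites.
  It is the oracle.
* `phase_heuristic` runs greedy single-site flips from a deterministic
  start, restarting from seeded random vectors on plateaus, within an
  iteration budget (default 600 sweeps). Accepted moves never increase
  MEC; output is deterministic given the seed. On random instances of up
  to 12 sites and 60 fragments at 10% call error it reaches the exhaustive
  optimum in 500/500 trials (re-measured by the test suite and the
  acceptance script).

Ties are broken by the lexicographically smallest binary haplotype. MEC is
unweighted; per-call qualities are carried but not used as weights, since
the choice of weighting is not forced by anything and unweighted MEC is
the common baseline. Fragment calls observing neither of an individual's
two genotype alleles are dropped and counted — a diploid cannot carry a
third allele at a site, so such calls signal error or contamination.

## Filtering, phaseable intervals, sequence reconstruction

Sites with depth or genotype quality below 20 (strict: DP 19 fails, DP 20
passes) are removed per individual before phasing. The interval over which
a phase block's reconstruction is claimed extends from just after the
nearest heterozygous site *not* in the block (or the amplicon edge) on each
side. Filtered or missing-genotype sites are additional barriers the
interval may not cross: their true genotype is unknowable, so any interval
containing them would claim sequence that was never assessed. When a
barrier falls strictly inside a block's span, the interval is restricted
to the barrier-free segment containing the most phased sites, and the
block is trimmed to match. This extension rule is this package's own
definition; other reasonable rules (e.g. half-way extension) exist.

Allele sequences are rebuilt by substituting each haplotype's alleles into
the reference, applying variants right-to-left so indel length changes
cannot shift the coordinates of edits still pending; homozygous-alternative
calls inside the interval are applied to both strings. All coordinates are
1-based inclusive throughout the package.

## Pedigree validation and allele dropout

Offspring haplotypes are labeled by comparing them (edit distance, via
edlib) against the four parental alleles over the identical interval; the
one-maternal-plus-one-paternal pairing minimizing total mismatches wins.
`max_mismatch` defaults to 0 — amplicon consensus should be near-exact —
and is tunable to absorb residual sequencing error. Identical parental
alleles produce label *sets* (ambiguity is preserved, never guessed away);
a haplotype matching no parental allele is a violation, reported with a
single-breakpoint diagnostic rather than auto-resolved, because F1
recombinants are expected to be rare, not absent.

Allele dropout — one allele failing to amplify — makes a locus look
homozygous. It is flagged when the offspring is homozygous at essentially
all informative sites (het fraction ≤ 0.1) yet no maternal×paternal allele
pair explains the calls at fewer than 2 sites. The observed haplotype is
then matched against the parental alleles; if it matches alleles of one
parent only, the other parent's contribution is the missing one. The
missing allele's sequence is reported as unknown — it was never sampled,
so reconstructing it would be invention. The two-site minimum and the 10%
het tolerance are this package's calibration of an otherwise qualitative
rule; at ≥100× depth and 0.2% call error they yield 100% recall of
injected dropouts with 0 false flags in the bundled evaluation.

## Marker segregation coding

STS product sizes are clustered by single linkage at a size tolerance
(default 0 for sizes predicted from phased sequences, 2 bp for capillary
instrument data, whose accuracy is 1–2 bp), then coded by parental
heterozygosity and cluster count: `abxcd` (4 alleles, both parents het),
`efxeg` (3, both het), `hkxhk` (2, both het), `lmxll` (mother het only),
`nnxnp` (father het only). The bundled expected-vs-observed comparison
table keeps one published expected code (`bbxcd`) that falls outside this
legend; it is reported as legend-undefined rather than silently recoded,
and counts as non-matching.

## Phenotype normalization and association

Full-bloom days (days after January 1st) are normalized within each year's
population flowering window: day rank within the window divided by window
length, giving values in (0, 1]; an individual's statistic is the median
over its available years. Days outside the window are clamped to the
nearer bound with a logged warning (treated as data-entry slips, not
rejected). Missing years are skipped, never imputed; an individual with no
usable year is excluded.

Association between allele presence and the phenotype is the two-sided
Wilcoxon rank-sum test, midranks for ties, significance at p ≤ 0.05, with
no multiple-testing correction by default (raw per-gene p-values are the
convention this mirrors; Benjamini–Hochberg is available behind a flag).
The exact null distribution of W is enumerated over all C(n, n_a) group
assignments when the pooled sample is small (≤ 20 without ties, ≤ 12 with
ties); otherwise a normal approximation with tie-corrected variance and
continuity correction is used. The exact path is cross-checked against
scipy's independent implementation in the tests, never replaced by it.

A subtlety: with n=8+8 the exact two-sided p-value takes only 33 values
with gaps up to 0.08, so its raw distribution under the null cannot pass a
Kolmogorov–Smirnov uniformity test at realistic sample sizes — by
discreteness, not error. Calibration therefore uses the randomized
("fuzzy") p-value `P(T > t) + U·P(T = t)`, which is exactly Uniform(0,1)
if and only if the enumerated null distribution is correct.

Flowering classes 1–6 (very early … very late) are sextiles of the median
statistic — the class boundaries are not externally fixed, so equal-count
quantiles are this package's choice — with ties broken toward the lower
class by (median, id) order for determinism; classes merge pairwise to a
3-class view.

## Synthetic data generator

The generator emulates the study conditions the pipeline is built for:
151 offspring of which 35 are sequenced; amplicons up to 8 kb; variant
density 1.3 per 100 bp (observed range 1.02–1.63), 90% SNPs and 10% indels
of ≤ 6 bp at Poisson-placed, collision-free positions; 2×250 bp read pairs
with 500 ± 60 bp inserts; per-individual-per-amplicon depth drawn from
Normal(286, 276) truncated at 20; per-base call error 0.002; per-amplicon
recombination probability 0.01; per-amplicon-per-individual dropout
probability 0.05 (modeled as complete single-haplotype amplification
failure; partial dropout is out of scope). Each of the four parental
haplotypes carries each placed variant with probability 1/2. One
transmitted label pair is drawn per offspring and shared across amplicons,
modeling a set of tightly linked genes in one QTL region — which is why,
absent recombination, labels agree across loci. The 35 sequenced
individuals are chosen as early/intermediate/late thirds by latent genetic
score, mirroring a phenotype-stratified selection whose exact proportions
are unknown; equal thirds are a choice.

Genotype evidence is rebuilt from the sampled fragments: DP is the number
of covering fragments, the genotype is the maximum-likelihood diploid call
under a symmetric error model, and GQ is the phred-scaled likelihood ratio
to the runner-up call (capped at 99). The fragment-count per amplicon is
calibrated so the *interior* per-base depth matches the target; coverage
tapers mechanically within one insert length of the amplicon ends, which
is where most filtered sites (and hence interval truncations) arise —
deliberately, since edge dropout is a real failure mode of fragmented
amplicon libraries.

Phenotypes come from an additive latent score (sum of carried allele
effects plus Normal(0, 3) days of noise; 3 days is a realistic
within-population environmental spread against windows of 10–17 days),
mapped per year into the recorded flowering window by blending the score's
scaled rank 50/50 with per-individual uniform jitter and rounding into
`[start, end]`. When every latent score is identical the mapping
degenerates to the window's first day for everyone. This generative model
is invented — the source material gives windows and days, not a mechanism
— so power results transfer to real data only insofar as a −5 day allele
effect against ~3 days of noise is representative.

What the synthetic validation does *not* show: robustness to mismapping,
PCR chimeras, primer-site polymorphism dropout, index hopping between
pooled libraries, or indel realignment artifacts — none of which the
generator models. Fragments are placed in reference coordinates and report
alleles at variant anchor positions, so indel-induced coordinate shifts
within reads are not exercised at the alignment level.

## Problem sizes in the shipped checks

The test suite and acceptance script run the simulation studies at
desk-scale sizes chosen to exercise every code path with tight statistical
bounds: recovery on 12 sequenced offspring over 2 kb amplicons at 120×
depth across several seeds (the full-scale defaults remain 151/35/8 kb/286×
and are exercised structurally); MEC oracle agreement on 200–500 random
instances; dropout detection on 35×6 individual×amplicon grids; association
power at the full n=151 over 100 replicates and type-I error over 1000
replicates (phenotype-level simulation, which is exact for this question
since genotype evidence does not enter the test).

## Known limitations

* Diploid genotypes are assumed per individual throughout.
* Sites with more than two observed alleles in one individual are excluded
  from that individual's phasing and logged, not modeled.
* Dropout detection names the missing parent, not the missing allele
  within that parent, when the parent's two alleles agree at the observed
  sites.
* The interval-extension rule and the dropout decision thresholds are
  package definitions; alternative formalizations would shift interval
  lengths and flag counts without changing the phasing itself.
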