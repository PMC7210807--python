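# Methods

## Scope and data model

The package models a forensic STR parentage panel: a set of named
tetra/pentanucleotide microsatellite loci, each with a registry of alleles
named by repeat count under the ISFG convention (`13`, and microvariants
`13.1`/`13.2`/`13.3` for lengths that are not whole multiples of the motif;
pentanucleotide loci additionally admit `.4`). Genotypes are unordered allele
pairs; populations are cohorts of diploid individuals with possibly partial
genotype tables, and every per-locus estimate uses that locus's own
typed-individual denominator, since hair-derived samples routinely drop loci.

The packaged reference fixture describes a population of 31 unrelated captive
tigers typed at 15 autosomal loci. The published frequency table is rounded
to 4 decimals, but every frequency is consistent with an integer chromosome
count out of 62 (`round(p × 62)` yields counts summing to exactly 62 at every
locus), so the fixture stores those counts and rebuilds exact frequencies
from them. All published per-locus statistics are reproduced to the printed
4 decimals from the count-backed tables; the rounded frequencies alone leave
several values one unit off in the fourth decimal. One published frequency
(DE1S613 allele 19.1, 0.2741) differs from its count's rounding (17/62 =
0.2742) and is carried as printed alongside count 17.

## Forensic statistics

Per locus, with allele frequencies `p_i` and genotype frequencies `g_i`:

* expected heterozygosity `He = 1 − Σ p_i²`;
* probability of exclusion
  `PE = Σ p_i (1−p_i)² − ½ Σ_{i<j} p_i² p_j² (4 − 3p_i − 3p_j)`;
* discrimination power `DP = 1 − Σ g_i²`, the probability that two random
  individuals differ in genotype (DP needs observed genotype frequencies and
  cannot be derived from allele frequencies without an equilibrium
  assumption, so frequency-only reports leave it blank);
* panel cumulants `CPE = 1 − Π(1 − PE_k)` and `TDP = 1 − Π(1 − DP_k)`,
  accumulated in the panel's declared locus order; the final values are
  order-invariant.

**Which exclusion scenario PE models.** The PE convention above (with the ½
factor on the unordered-pair sum) is the one used in published multiplex-panel
characterizations of this kind, and it reproduces the reference panel's
printed PE column and CPE = 0.999999472 exactly. It does not, however, equal
the exclusion probability of any of the three classical parentage scenarios.
The variant *without* the ½ factor — the Jamieson-style formula, exposed as
`exclusion_probability_mother_known` — exactly equals the probability that a
random unrelated male is Mendelian-incompatible with a mother–child pair
drawn under Hardy–Weinberg; the package verifies this both by exhaustive
enumeration over small allele alphabets and by Monte-Carlo trio simulation
(200,000 trials, agreement within 3 binomial standard errors). The panel
convention is therefore slightly larger than the known-mother exclusion
probability at every locus. Both functions are provided; all panel reports
and cumulants use the panel convention, since reproducing the published
characterization is the package's reference behaviour.

Report formatting follows the published table style: per-locus values at 4
decimals; cumulative columns at adaptive precision (two digits beyond the
leading nines, minimum 4, maximum 15 decimals), so the final CPE prints as
`0.999999472` and the TDP of the published DP column as
`0.999999999999995`.

Means over loci are unweighted arithmetic means. All computation is at full
double precision; rounding happens only at report time.

## Hardy–Weinberg exact test

The test conditions on observed allele counts. Under random mating the
probability of a genotype array `{n_ij}` given allele counts `c_i`
(`Σ c_i = 2n`) is Levene's conditional distribution
`P = n! 2^h Π c_i! / (Π n_ij! (2n)!)` with `h` heterozygous individuals. The
p-value is the total probability of arrays no more probable than the observed
one ("probability test" ordering, the classic exact-test default). Arrays are
compared in log space with a relative tolerance of 1e-9 so ties are counted
as at-or-below.

Small array spaces (≤ 10⁶ configurations by default) are fully enumerated by
recursion over heterozygote pair counts, with log-sum-exp normalization.
Larger spaces fall back to Monte Carlo: random pairings of the 2n allele
copies, which samples arrays exactly from the conditional null; the p-value
is the plain fraction of sampled arrays at or below the observed probability.
The Monte-Carlo path refuses to run without an explicit seed, and a panel run
derives one sub-seed per locus from a single master seed, so results are
bit-reproducible. Default 100,000 replicates.

Calibration: under Hardy–Weinberg simulation (100 individuals per replicate,
1,000 replicates, 2,000 Monte-Carlo replicates per test) the rejection rate
at α = 0.05 falls within [0.03, 0.07] for the 5-allele reference locus
models — slightly conservative, as expected for a discrete exact test.
Flags follow the published table's convention: `D` (departure) iff p < 0.05,
`NS` otherwise, `NA` for monomorphic or empty loci. No multiple-testing
correction is applied across panel loci, matching the per-locus flag
convention of the reference characterization.

## Parentage

Mendelian logic: a duo (single putative parent) is compatible iff parent and
child share at least one allele; a trio iff one child allele can be assigned
to the mother and the other to the father. The trio rule is validated
exhaustively against a brute-force enumeration of the four gamete
combinations over a 4-allele alphabet. Untyped loci are uninformative, never
exclusions.

Candidate evaluation ranks all mother×father pairs (or duos when one side is
empty) by exclusions ascending, then informative loci descending. The default
exclusion threshold is 0 — one incompatible locus excludes — because the
reference analyses assume mutation-free transmission; a threshold ≥ 1
tolerates mutation/drop-out at a documented cost in discriminating power.
Pedigree reconstruction is conservative: an offspring is assigned only when
exactly one candidate pair is consistent; zero or multiple consistent pairs
leave it unassigned with a reason code (`no_consistent_pair`, `ambiguous`,
`untyped`). Shared parents across families are permitted. Studbook
correction demands never guessing among ambiguous pairs.

Sex calling uses the amelogenin length polymorphism: the Y-linked copy
carries a deletion, so defaults are X = 109 bp, Y = 87 bp with a ±2 bp
electrophoretic tolerance. XY iff both lengths are present, XX iff only X;
anything else — including a lone Y-length fragment, which is biologically
implausible and more likely an artefact — is `unknown`. Both lengths are
independent parameters rather than one being derived from the other, because
the published fragment pair (87/109) differs by 22 bp while the underlying
deletion is 20 bp (primer placement accounts for the difference).

## Marker screening

Candidates are retained iff (1) the motif is a tetra- or pentanucleotide,
(2) the reference genome carries 10–20 repeat units — both bounds inclusive,
fractional repeat-finder copy numbers compared numerically — and (3) the
multi-sample calls show 3–6 distinct alleles. Rejections carry the first
failed criterion in that order. Annotation positions are 1-based.

Fragment-size → allele-name conversion anchors a ladder at one sequenced
allele of known size; each step is one motif length, and residual bases
(from compound/complex repeat structure) become microvariant names, i.e. the
general tetrameric-structure naming convention for complex loci. Fragments
outside the ladder window or off the 1-bp grid by more than the tolerance
raise an off-ladder error rather than being force-called.

## Synthetic data

Generators emulate the study conditions each stage expects: Hardy–Weinberg
populations drawn from a frequency table (default n = 31, the reference
cohort size; loci unlinked; optional per-locus dropout), Mendelian families
(default mutation rate 0, matching the assumption of mutation-free
transmission; optional stepwise ±1-repeat mutation, the standard STR mutation
model), and screening fixtures with planted class composition realized by
largest-remainder apportionment. All generators require a seed and are
bit-reproducible. They do not emulate peak heights, stutter, allelic
drop-in, linkage, or genotyping error, so passing pipeline tests demonstrate
correctness of the statistical logic, not robustness to raw
electrophoretic artefacts.

Validation experiment sizes (chosen to make sampling error negligible
relative to the tested tolerances): parameter recovery at n = 10,000
individuals over 3 seeds (max |Δp| averaged < 0.02); false-inclusion
screening of 100,000 random unrelated couples against simulated offspring
across the 15-locus panel (expected inclusions ≈ panel-level
1 − CPE-couple ≪ 1, observed 0); mother-known exclusion-rate agreement at
200,000 trials.

## Known limitations

* PE/CPE carry no θ-correction for population substructure, and no
  likelihood-based (paternity-index/LOD) statistics are computed — exclusion
  counting only.
* The HWE test's published per-locus D/NS flags for the reference cohort are
  not reproducible here because they require the cohort's raw genotypes,
  which are not part of the packaged frequency fixture.
* Genome-wide screening totals depend on a reference-genome scan that is out
  of scope; the filters operate on annotation/call tables.
* Allele codes in GenePop exports are `repeats × 10 + microvariant`, which
  requires repeat counts below 100 (always true for panel-grade STRs).
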