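# Methods

## Data model

A *haplogroup defining-SNP profile* is an ordered set of
(locus, normal allele, mutant allele) triples in 1-based rCRS coordinates,
tied to one haplogroup and one study class. Eight class tables are packaged
(AD, PD, T2D, T2D with angiopathy, centenarians, semi-supercentenarians,
non-obese and obese healthy young males). Profiles are flat: no phylogeny is
modelled, and the same haplogroup name may appear in several class tables
with different entry sets — the class label is part of a profile's identity.
A locus may appear twice in one profile with different mutant alleles
(the centenarian D4b2a profile lists both T>A and T>C at 9824); both entries
count toward the profile size, which is the denominator of the match ratio.

A person is a *variant set*: a haploid consensus mapping locus → observed
nucleotide for every position where they differ from the reference.
Heteroplasmy, indels, and structural variation are out of scope.

## Match-ratio screening

For profile P with |P| entries, a person v scores

    ratio(v, P) = |{(locus, mutant) ∈ P : v[locus] = mutant}| / |P|

held as an exact `Fraction`. By default an entry counts only on an exact
mutant-allele match (`require_allele_match=True`); the lax mode accepts any
non-reference call at the locus. Mutations outside P never change the ratio.
A person is flagged for a class when some ratio strictly exceeds the
decision threshold, default 0.8. Three numerical choices matter:

- **Strict inequality.** A ratio of exactly 4/5 does not flag. The threshold
  is configurable for users who want ≥.
- **Exact threshold comparison.** The float threshold is normalised through
  `Fraction(str(t))`, so 0.8 means the decimal 4/5, not the nearest binary
  float; `ratio > threshold` is exact rational arithmetic.
- **Rendering.** Ratios render at three decimals (two on request),
  round-half-away-from-zero: 11/13 → 0.846, 10/12 → 0.833, 13/15 → 0.867.
  The stored value is always the exact fraction.

The 0.8 cutoff is a convention carried by the method, not a validated
clinical threshold; the output is a qualitative flag, never a disease
probability.

With all eight tables loaded, the best-ranked entry for a person need not be
the one of primary interest: profiles of the same haplogroup recur across
class tables with different sizes, and a smaller sibling profile can yield a
larger fraction from the same mutations (e.g. 11/12 against a 12-entry G2a
profile outranking 11/13 against the 13-entry one). Reports therefore list
every (class, haplogroup) entry, sorted by ratio, rather than a single call.

## RBF network

Genotypes are encoded A, G, C, T → 1, 2, 3, 4 with 0 for missing, and the
network computes the weighted basis sum f(x) given in the README over
Euclidean distance on those integer codes. The encoding imposes a spurious
ordinal structure — A (1) is numerically closer to G (2) than to T (4) —
which is a documented property of the method as defined, kept deliberately;
a one-hot encoding would change the geometry and is out of scope.

Fitting, where the method's description leaves freedom, follows the standard
RBF-network recipe:

- **Centers**: k-means (scikit-learn, seeded, `n_init=10`) on the training
  rows; `m` is either fixed or chosen from the grid (2, 4, 8, 16, 32) by
  validation accuracy, ties to the smaller m. Cohorts whose rows are all
  identical fall back to a single center.
- **Widths**: σᵢ = distance from center i to its nearest other center
  (m = 1: mean distance of the training rows to the center). Non-positive
  widths from duplicate centers are replaced by the mean positive width,
  or 1.0 if none exists.
- **Readout**: ridge-regularised least squares (normal equations,
  λ = 1e-6 by default) on the Gaussian activations plus a bias column,
  against targets 1 (positive class) / 0 (rest).

Raw f(x) is unbounded; reported probabilities are clipped to [0, 1], but
*ranking always uses the raw scores* — clipping collapses everything above 1
into a tie and would let the tie-break rule, not the model, choose the top
individuals.

Cohorts are split per class into 2/3 training, 1/3 validation, the training
count being round(2n/3): 96 → 64/32, 112 → 75/37, 3 → 2/1. The split is a
seeded shuffle within each class, deterministic given the seed. Under the
eight-class design (seven classes of 96 plus one of 112) the training pool
totals 64·7 + 75 = 523 vectors.

## Selection and association

The *modified cluster* is the top of the score ranking: either the N
highest-scoring individuals (ties broken by ascending sample id, for
reproducibility) or all individuals with score strictly above a probability
threshold. The cluster report assigns every individual to its nearest
center and lists clusters in descending mean clipped probability (as a
percentage). The per-cluster figure is the mean predicted probability of
its members; an alternative reading — fraction of true-class members per
cluster — is not implemented.

Haplogroup association assigns each subset member to the profile maximising
its match fraction (ties: larger profile, then name order), counts members
whose best fraction reaches `min_fraction` (default 0.5 — deliberately
looser than the 0.8 screening threshold, since cohort association tolerates
partial profiles), and reports whole-percent shares rounded half away from
zero (8/15 → 53%, 3/15 → 20%). This best-match rule is a flat
reconstruction; it does not place individuals on a phylogeny.

Position summaries count, at each locus where any member is mutated, Y =
carriers of the mutant allele and X = carriers of the normal allele,
rendered `locus N>M (Y/X)`. Members without a call at the locus count as
reference (variant sets are defined relative to the reference). If a third
allele occurs, each mutant allele gets its own summary line and carriers of
the other mutant alleles are reported in a separate `other` count, keeping
Y + X + other equal to the subset size.

## Synthetic cohorts

`simulate_cohort` emulates the case-control design the classifier targets:
per class, a stated share of individuals is sourced from one or more
haplogroup profiles (largest-remainder allocation of counts, e.g. 53% of
96 → 51 carriers), the rest are background. Defaults mirror the study
conditions: 96 individuals per class (112 for the semi-supercentenarian
analogue), carrier completeness 0.9, noise rate 3.

- A carrier inherits each profile entry independently with probability
  `carrier_completeness`; when both alleles of a two-entry locus are drawn,
  one is kept at random (a person carries one allele per locus).
- Noise adds Poisson(`noise_rate`) mutations at loci uniformly drawn outside
  the individual's own profile, each with a random non-reference allele.
- The genotype matrix covers the union of all profile loci plus the noise
  loci actually used; unmutated positions carry the reference base.

The generator is a pure function of (spec, seed). It plants separable
structure and does **not** model phylogenetic linkage between haplogroups,
realistic site-frequency spectra, mutation-rate heterogeneity, heteroplasmy,
or sequencing error. Passing recovery tests therefore demonstrates that the
pipeline recovers planted dominant structure under moderate incompleteness
and noise — not that it would resolve the subtler structure of real cohorts.

`pipeline_recovery_check` runs simulate → train → select top-15 → associate
and reports whether the planted dominant haplogroup returns as the modal
assignment. Its contract assumes one dominant haplogroup (proportion ≥ 0.5)
in the positive class and disjoint haplogroups in the negative classes; with
two planted positive haplogroups the top-15 may legitimately concentrate on
the minor one, which is a property of the design, not a failure of
recovery.

## Reference sequence

The package never needs the real rCRS for profile matching (tables are
self-contained). For simulation and consistency checks it builds a
*synthetic* reference: length 16,569, the tables' normal alleles at every
profile locus, seeded arbitrary bases elsewhere. Real-genome analyses
should load the true rCRS via `read_fasta`.

## Problem sizes in the test suite

The suite exercises the documented study-scale conditions directly: ratio
oracle equivalence on 1,000 random variant sets, a binomial-mean check on
10,000 simulated carriers, and 2 × 20 seeded end-to-end recovery runs on
96-per-class cohorts (completeness 0.95 / noise 2, and the noise-free
limit). The full suite runs in well under a minute on one CPU.

## Known limitations

- The integer encoding's ordinal artifact (above).
- Flat profile matching cannot distinguish nested haplogroups sharing most
  defining mutations; sibling profiles across class tables produce correlated
  ratios by construction.
- The 0.8 threshold and the top-15 selection size are conventions of the
  method, exposed as parameters but not validated here.
- Variant input assumes consensus single-nucleotide calls; VCF support is a
  minimal SNV-only subset (FILTER must be PASS/'.', indels skipped and
  counted).
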