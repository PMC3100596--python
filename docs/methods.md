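# Methods

This note documents the models behind `hylaxy`, the defaults and why they
were chosen, what the synthetic-data generators do and do not emulate, and
the numerical and design choices a maintainer should know about.

## Scientific setting

In many ectotherms the X and Y (or Z and W) chromosomes are homomorphic:
cytogenetically and genetically undifferentiated despite millions of years
of male heterogamety.  Two explanations compete.  Under the *high-turnover*
hypothesis, master sex-determining genes are replaced often enough that
non-recombining regions never have time to decay; under the
*fountain-of-youth* hypothesis, an old XY pair is maintained by occasional
X-Y recombination, for instance in sex-reversed XY females (recombination
patterns follow phenotypic sex in many vertebrates, so an XY female
recombines like any female).  The hypotheses leave different footprints:

* both predict sex linkage of the same markers across related species if
  the chromosome pair is ancestral;
* with ongoing (even rare) X-Y exchange, gene genealogies of sex-linked
  loci cluster **by species**; with exchange frozen since before species
  divergence, they cluster **by gametolog** (all Y alleles together, all X
  alleles together);
* a recent turnover of the Y from the ancestral X produces gametolog
  clustering restricted to the sister group of the species that underwent
  the turnover.

The pipeline quantifies each footprint: sex-specific recombination from
sibships, Y-haplotype structure, X-Y similarity statistics, and
genealogy-clustering classification.

## Two-point linkage likelihood

For a family and a locus pair, the likelihood of the offspring genotypes
given the parents is

L(θ_m, θ_f) = Σ_phases (½)^(#double-het parents) Π_offspring P(g_o | phases, θ_m, θ_f),

where each fully typed parent contributes four ordered two-locus gametes —
parental with probability (1−θ)/2 and recombinant with θ/2 under a given
phase — and P(g_o | ·) sums the gamete combinations compatible with the
offspring's unphased genotype.  The phase of each double-heterozygous
parent is unknown but constant across the sibship (prior ½ per phase).
Because only the class (parental/recombinant) of a gamete matters, each
offspring reduces to a 2×2 integer matrix of compatible combinations and
the family likelihood to a product of bilinear forms; surfaces over θ grids
are therefore cheap.

Conventions for imperfect data:

* **Missing** calls are marginalized (compatible with everything).
* A **null allele** (non-amplifying, written `*`) is a real, inheritable
  allele.  When a parent's genotype records one, transmissions include it
  and an offspring's apparent homozygote `A/A` also matches the true pair
  `{A, NULL}`.  A parent *not* recorded as a null carrier is taken at face
  value; an offspring incompatible with every parental transmission
  (suspected dropout or scoring error) is treated as missing at that locus
  pair rather than zeroing the family — conservative, since the source
  data's null calls are themselves inferences.
* A parent not fully typed at both loci contributes no transmission
  information; the family then informs only the other parent's fraction.

**Estimation.**  (θ̂_m, θ̂_f) maximize the summed family log-likelihood on
[0, 0.5]²: a 0.01-step coarse grid locates the optimum and a 0.001-step
local grid pins it down (verified against an exhaustive 0.001 grid in the
tests).  The boundary value 0 is on the grid, so complete linkage is
reported exactly.  A sex with zero informative meioses (no double-
heterozygous, fully typed parent with typed offspring) is reported as NA.
LOD_s compares the joint MLE with the same likelihood at θ_s = 0.5, the
other sex's fraction held at its MLE; it is non-negative by construction.

**Phase-unknown information loss.**  With unknown phase the likelihood at
θ = 0.5 contains both phase terms, which costs ln 2 relative to a
phase-known binomial per double-heterozygous parent, and Fisher information
vanishes as θ → 0.5.  Practically: the MLE's sampling spread near 0.5 is
about 0.03 (one-sided, clipped at the boundary) even with ~60 families of
20 offspring, so recovery experiments should place true fractions in the
interior of [0, 0.5].  The acceptance protocol uses interval truths
0.30–0.45 for exactly this reason.

**Morton's M-test.**  Heterogeneity of θ across k datasets, per sex:
Λ = 2[Σᵢ max ln Lᵢ − max over a common θ for the tested sex], the other
sex's fraction free per group in both terms; df = k−1.  All maxima are
taken on a shared 0.005-step grid, which makes Λ ≥ 0 structural and the
statistic reproducible.  Boundary MLEs (θ̂ = 0, θ̂ = 0.5) make the χ²
reference conservative, so a permutation reference (families reallocated
among groups with group sizes kept, ≥1,000 permutations recommended) is
available; both p-values are reported in the CLI.  Calibration at interior
θ with 3 × 15 families × 10 offspring gives a Type-I rate near the nominal
5% (the acceptance study asserts [0.03, 0.07]).

**Maps.**  Orders are searched exhaustively (≤10 loci, identified up to
reversal), minimizing the summed adjacent-interval female Haldane length
d = −50 ln(1−2θ) cM; ties break lexicographically.  An adjacent θ̂_f ≥ 0.5
is capped at 0.49 and flagged.  Order recovery is reliable when interval
fractions are moderate (≈0.25: ≥95% at 100 families in tests) and degrades
as intervals approach 0.5, where Haldane lengths diverge and their sampling
noise dominates — the qualitative structure (synteny, zero male length),
not per-cM values, is the robust output in the high-recombination regime.
Male positions use θ̂_m per adjacent interval (NA contributes no length);
with complete male linkage the male map length is exactly 0 cM.

## Sex linkage and Y haplotypes

* **G-test**: G = 2 Σ O ln(O/E) on the allele-count × sex table of typed
  adults.  The null permutes *individual* sex labels so both alleles of an
  individual travel together — within-individual allele dependence is
  respected, in the spirit of permutation tests in standard
  population-genetics software.  p = (1 + #{G* ≥ G}) / (1 + n_perm) never
  reports zero.
* **Sibship Y inference** assumes complete male linkage (callers assert
  θ_m = 0, which the linkage stage establishes).  Per locus, each
  offspring's received paternal allele is resolved through the mother's
  genotype where possible; the allele received by every unambiguous son
  and no daughter is the Y call.  A homozygous father is uninformative
  (flagged); a son-daughter conflict marks the locus `inconsistent` —
  the expected signature of a sex-reversal ancestor, a rare X-Y
  recombination event, or a scoring error — and the call ambiguous.
* **Population assignment** intersects each male's genotype with candidate
  Y-allele sets (from sibships and/or male-biased alleles); exactly one
  match is a call, zero or two are ambiguous, and a homozygote for a
  candidate is called but flagged since the same allele may sit on his X.
  Distinct multilocus haplotypes are counted wildcard-tolerantly (two
  haplotypes differ only if they conflict at a locus called in both) by
  deterministic greedy agglomeration, most-informative males first.  The
  greedy count is an upper-bound heuristic for the minimum compatible
  number; with few ambiguous calls it is exact, matching the
  "minimum number of Y haplotypes" reading used for sparse tables.

## Permutation tests of X-Y similarity

* **Size-difference test.**  Observed statistic: mean |a₁ − a₂| over every
  male genotype with two amplified alleles at the sex-linked loci
  (homozygotes contribute 0; genotypes containing null or missing alleles
  are excluded, since a null's size is unknown).  Null replicates refill
  each genotype slot at locus ℓ with two alleles drawn from the pooled
  typed adults (both sexes) at ℓ, constrained to come from different
  species, preserving per-locus slot counts.  One-tailed:
  small observed = conspecific X and Y more similar than allospecific
  alleles, i.e. recent X-Y coalescence.  A locus typed in a single species
  has no cross-species null and is excluded (reported).  An alternative
  null preserving each slot's own species composition would condition more
  finely; the pooled-draw null is the one implemented and tested.
* **Cross-amplification test.**  For a binary locus × species × gametolog
  success matrix, the statistic is the number of (locus, species) pairs
  with discordant X/Y entries.  Null: the observed number of failures is
  scattered uniformly over all cells ("random permutations of the
  matrix"); left tail, +1-corrected.  The exact tail is closed-form: with
  P pairs and z zeros, P(a pairs fully zero, b half zero) =
  C(P,a)·C(P−a,b)·2^b / C(2P,z) with 2a + b = z, summed over b ≤ d_obs.
  For the reference 9 × 3 × 2 configuration (three whole-locus failures in
  each of the two sister species, two gametolog-specific failures in the
  reference species: z = 14, d_obs = 2) the exact tail is 7.7 × 10⁻⁵,
  below the 2 × 10⁻⁴ bound the simulated test must reproduce.

## Synthetic data

**Pedigrees.**  Founder haplotypes are drawn locus-wise from X-pool and
Y-pool allele-frequency spectra (linkage equilibrium within a pool);
fathers carry one X and one Y haplotype, mothers two X.  A paternal gamete
starts on the Y background for sons and the X background for daughters
(the sex-determining region rides with the first locus) and switches
background between adjacent loci with probability θ_m per interval;
maternal gametes start on a random haplotype and use θ_f.  Stepwise
mutation moves an allele by ±1 repeat unit with the per-meiosis rate; null
alleles are assigned to founder haplotypes and inherited, and genotypes
record them explicitly, emulating a curated table (an optional masking of
nulls as apparent homozygotes was considered and left out: the analyses'
null-handling is exercised through the explicit convention).  Defaults —
20 families per species, truncated-Poisson(20) offspring, six dinucleotide
loci with six founder alleles on overlapping X/Y spectra, θ_m = 0 and
θ_f = 0.4 — reproduce the study regime of ~20-offspring sibships with
complete male linkage and high female recombination.  Not emulated:
genotyping error, allelic dropout beyond heritable nulls, recombination
interference, family-size/paternity structure.  Passing tests therefore
show correctness of the inference under the stated model, not robustness
to scoring artifacts.

**Genealogies.**  A backwards-time structured coalescent on the species
tree ((Hi, Hm), Ha): within a species, lineages in the same pool (X or Y)
coalesce at rate k(k−1)/2N_pool per generation; each lineage switches pool
at the exchange rate r (per lineage per generation), the footprint of X-Y
recombination in XY females; at a split time the daughter species' same-
class pools merge.  Defaults: split times from divergence estimates of
5.4 My (sister pair) and 7.1 My (root) with a 2-year generation time
(2.7 × 10⁶ and 3.55 × 10⁶ generations); N_X : N_Y = 3000 : 1000, the
standard 3:1 effective-size ratio; r presets 0 ("frozen"), 10/N_Y
("occasional"), configurable.  The `frozen_ancestral` preset needs
coalescence above the root, so an ancestral exchange rate r_anc = 1/N_Y
applies there — the freeze postdates an exchanging ancestor by
construction.  `turnover_from_X` moves the reference species' Y lineages
into its X pool at a user-supplied recent t_turn (required, since no
turnover age is implied by the scenario itself).  Sequences evolve by
Jukes-Cantor along the genealogy (uniform root, per-site change
probability (3/4)(1 − e^(−4μt/3))); defaults μ = 10⁻⁸ per site per
generation and L = 1000 give comfortably resolvable X-Y divergence under
the frozen scenario.  Not emulated: demography beyond the species tree,
rate heterogeneity, gene conversion tracts (the turnover preset's
relabeling is the only stand-in), recombination within the simulated
fragment.

## Genealogy classification

Distances use pairwise deletion; JC entries are flagged infinite at
p ≥ 0.75 and neighbor-joining refuses saturated matrices.  NJ follows the
Saitou-Nei Q criterion with ties broken by the lexicographically smallest
cluster-label pair (clusters labelled by their smallest tip), so output is
independent of input order; negative branch lengths are clamped to zero
and flagged.  Bootstrap supports are percentages of column-resampled
replicates containing each original bipartition.

`classify_clustering` works on unrooted bipartitions: a tip set is
"monophyletic" iff some edge splits exactly it from the rest.  Verdict
rule: `species_clustered` iff every species' pooled X∪Y tips form such a
split; otherwise `gametolog_clustered` iff the pooled Y tips of the
designated sister group form a split (excluding their conspecific X tips
by definition of a split); otherwise `mixed`.  The reference species
defaults to the lexicographically smallest name and the sister group to
all others; both are parameters.  When both patterns hold, the species
verdict wins (monophyly of every species is the stronger statement).
Fitch parsimony change counts for the species and gametolog characters
accompany the verdict as continuous scores so users can apply their own
decision rules; on multifurcating nodes children are folded sequentially.

## Problem sizes and determinism

The test suite and the acceptance script run everything at desk scale:
100,000 replicates for the matrix test, 3 × 20 families × 20 offspring for
the linkage regime with 100 replicate M-test studies, 1,000 calibration
simulations, 100 families for Y recovery, and 100 replicates per genealogy
scenario — a few minutes in total on one CPU.  All randomness flows
through explicit integer seeds (`numpy.random.default_rng`); the
acceptance script derives every stage's seed from its `--seed` argument.

## Known limitations

* Multipoint likelihoods are out of scope; ordering is two-point based and,
  as noted, noisy when interval fractions approach 0.5.  A multipoint
  order that differs from the two-point one (as can happen for real data)
  is not reproducible here.
* Values that require the original study's raw genotypes or sequences —
  the observed mean X-Y size difference and its null (6.26 / 9.24 bp
  scale), the 93.8 cM female consensus distance, per-order map
  log-likelihoods, divergence-time estimates, and bootstrap values on the
  published trees — are not recomputed; the corresponding machinery is
  validated on synthetic data with known truth instead.  Molecular dating
  and ML tree search are likewise out of scope; externally inferred trees
  can be classified via the Newick reader.
* The structured coalescent treats the locus as non-recombining internally
  and the exchange process as memoryless; bursts of recombination after a
  single sex-reversal event are not modelled.
* The greedy wildcard haplotype count can overestimate the true minimum in
  adversarial ambiguity patterns.
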