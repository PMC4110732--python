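# Methods

`mitotreescan` tests whether mitochondrial haplotype clades are associated
with a continuous phenotype — relative mtDNA copy number — in a cohort whose
members are related through a known pedigree.  This note records the model,
the algorithmic and numerical choices, what the synthetic-data generator does
and does not emulate, and the package's known limitations.

## Pipeline overview

1. **Variant extraction** (`mtvar`).  Input is a pre-computed multiple
   alignment of full mitochondrial genomes including the 16,569-bp reference
   row.  Each sample row is diffed against the reference: maximal runs of
   sample gaps over reference bases become one deletion, maximal runs of
   reference-gap columns carrying sample bases become one insertion, `N` is
   missing and never yields a variant.  Variants are named `m.263A>G`,
   `m.del8281-8289`, `m.303insC` (1-based reference coordinates, closed
   intervals; the circular genome is treated as linear for naming, and no
   origin-spanning feature is represented).  Indels are left-aligned within
   homopolymer runs so that a haplotype's identity — its set of called
   variants — does not depend on where the upstream aligner placed a gap.
   Unsequenced individuals are imputed onto their matrilineal
   representative's haplotype, which is exact under strict maternal
   inheritance and no de novo mutation.

2. **Haplotype network** (`hapnet`).  Nodes are observed haplotypes; each
   edge segment is one mutational step, so an edge of Hamming length *d*
   carries *d − 1* latent degree-2 placeholder nodes.  The network is the
   union of all minimum spanning trees of the complete Hamming-distance
   graph.  Where the MST is unique this is a tree; ties appear as
   reticulation loops.  All loop resolutions (= all MSTs) are enumerated by
   the weight-class decomposition of MSTs: within each weight class the
   retained edges form tie-clusters over the components assembled from
   lighter edges, the number of spanning trees per cluster is counted by the
   matrix-tree theorem before any enumeration (so an over-ambiguous network
   fails fast, reporting the count against the `max_resolutions` cap,
   default 64), and resolutions are the Cartesian product of per-cluster
   spanning trees.  No median (inferred) haplotypes are created.  Branches
   are observed-node-to-observed-node edges; each is numbered
   deterministically (root at the most frequent haplotype, ties broken
   lexicographically; breadth-first edge order) and induces a bipartition of
   haplotypes into two allelic classes, the side away from the root being
   the clade it defines.

3. **Kinship and the familial adjustment score** (`kinship`).  Kinship
   f(i,j) is computed by the standard recursion over a parents-first
   ordering; unknown parents are unique non-inbred founders.  The familial
   adjustment score of individual *i* is

       FAS_i = Σ_{j≠i} y_j · f(i,j) / (N · y_i)

   with y the copy numbers and N the number of phenotyped individuals.  The
   sum excludes the self term (an `include_self` switch restores it);
   individuals with missing phenotype contribute nothing and receive no
   score.  The score is dimensionless and is used as a regression covariate
   intended to absorb phenotype variance attributable to relatedness, both
   maternal and paternal.

4. **TreeScanning** (`treescan`).  For each testable branch the statistic is
   the partial F (1 numerator df) for adding the branch's 0/1 allele
   indicator to the linear model with intercept, age, sex and FAS.  A branch
   is testable when both allelic classes contain at least `min_class = 5`
   individuals with complete data (listwise over phenotype, age, sex and
   the score).  Nominal p-values use the add-one convention
   (1 + #{T* ≥ T}) / (n_perm + 1), so p ∈ [1/(n_perm+1), 1].  Significance
   means multiplicity-corrected p < 0.05; corrected p is never below nominal
   p and is monotone down the step-down ranking.  If loops exist, the scan
   runs once per resolution on a shared permutation schedule and the summary
   reports, per bipartition, the maximum corrected p across resolutions
   (conservative); a clade is called significant only if significant in
   every resolution in which it appears.

## Permutation inference: why it is not plain Freedman–Lane

The natural scheme — fit the covariate model once, permute its residuals,
add back fitted values (Freedman–Lane) — is used for the outcome-independent
covariates (age, sex, conditioning indicators).  Two measured failure modes
forced refinements; both were diagnosed on the synthetic generator where the
truth is known.

**The familial adjustment score is outcome-derived.**  FAS contains the
focal individual's own phenotype in its denominator and the relatives'
phenotypes in its numerator.  Holding the observed-data score fixed while
permuting residuals couples the residuals of relatives (measured
related-pair residual correlation 0.27 after conditioning on the score,
versus 0.02 without it) and the family-wise error rate of the naive scheme
was 0.52 under the generator's null.  The scan therefore treats the score
as part of the statistic: for every permuted response the score is
recomputed from that response before the partial F is evaluated, so the
null distribution carries exactly the coupling the observed statistic
carries.  (The permuted response's denominator is floored at 0.05 copy-number
units for numerical safety; copy number is a positive ratio.)

**Kinship-structured phenotype variance breaks exchangeability.**  Residuals
of relatives are positively correlated (variance component σ²_g on 2·K),
and the tested clades coincide with families, so exchangeable permutation
understates clade-contrast variance.  Residuals are whitened by the
Cholesky factor of Σ̂ = 2σ̂²_g·K + σ̂²_e·I, permuted, and re-coloured.  The
variance components come from a method-of-moments fit of the residual
cross-products to 2K, pooled per family cluster (connected component of the
kinship graph) with one-step rejection of grossly outlying clusters
(deviations beyond 6 robust SDs).  The rejection step matters: a genuine
clade effect is a mean shift concentrated in a few families and otherwise
inflates σ̂²_g (measured 0.11 versus a true 0.045 under the alternative),
over-disperses the permutation null, and costs power against exactly the
effects the scan exists to find.

**Step-down correction is studentized maxT.**  Because the outcome-derived
score inflates the null distributions of family-aligned branches 2–3× while
leaving family-poor branches near χ²(1), a common raw-scale maxT threshold
hands the entire family-wise budget to the most inflated branches.  Each
branch's observed and null statistics are standardized by that branch's own
permutation null moments, and the step-down maximum is taken over the
standardized statistics.  Null columns are standardized by leave-one-out
moments: a null draw must not enter its own reference moments, otherwise
extreme null columns shrink themselves and the correction turns liberal
(measured family-wise error 0.082 with self-inclusive moments versus 0.054
with leave-one-out, at the nominal 0.05).  The studentized procedure is the
member of the minP/maxT family usable at a few hundred permutations; pure
minP would need n_perm ≫ n_branches / α.

**Known trade-off.**  With a valid null, conditioning on the familial
adjustment score costs real power: on identical replicates (800
individuals, a 14-member clade shifted by ~1.2 residual SD), detection is
0.81 without the score in the model and 0.69 with it, because the score is
family-structured noise that inflates the sampling variance of
family-aligned contrasts.  The score is retained — it is the method's
relatedness adjustment — and the cost is documented rather than hidden by
an anti-conservative null.

## Conditioning and the second round

After round 1, each significant branch's indicator is added to the fixed
covariates and the scan re-run ("round 1-cond"); the conditioned branch's
own indicator becomes collinear, its partial F is exactly 0 and its nominal
p exactly 1, and any other branch that stays significant represents a
statistically separate effect.  Round 2 looks for phenotypic heterogeneity
inside a significant branch's allelic classes: every branch strictly nested
within one class splits it into two sub-alleles (a three-allele system with
the other class held constant); permutations shuffle residuals only within
each class (block permutation; with whitening, the within-block shuffle is
applied to the whitened residuals before re-colouring, an approximation),
the parent indicator stays in the model, and step-down correction is applied
within the round-2 family.  Sub-classes below `min_class` are reported
untestable.

## Synthetic-data generator

The generator emulates a population-based elderly cohort with
matrilineage-based sequencing and imputation.  Defaults (the configured
study scale): 1007 individuals over 274 matrilineages; matrilineage sizes
geometric with the cohort mean (long-tailed, largest groups tens of
members); a random growing genealogy over matrilineages in which each new
matrilineage descends from a uniformly chosen existing one with
Poisson(3.15) fresh mutations per branch plus a Poisson(8) offset between
the cohort ancestor and the reference; infinite sites (unique positions, no
recurrence), ~5% of mutations indels of 1–9 bp with a one-base guard band
so left-normalization cannot merge features.  This yields ≈ 250–265 unique
haplotypes, ≈ 870 segregating variants and ≈ 25 variants per person.
Because ancestral haplotypes remain sampled — as in a densely sampled
population where common haplotypes are ancestors of rare ones — and the
sites are infinite, Hamming distance equals tree path length and the
minimum spanning network is loop-free; reticulation handling is exercised
by constructed fixtures instead.  An earlier design that sampled only the
leaves of a bifurcating genealogy made every unobserved ancestor a
parsimony tie-cluster and produced astronomically many loop resolutions,
which no real cohort of this kind shows.

Pedigree: members of a matrilineage coalesce backwards through unobserved
ancestral females in random sibships of 2–3 per generation; each sibship
shares one unobserved founder father, so kinship is confined to
matrilineages.  Ages are uniform on [65, 95] (the cohort design enrols 65+;
this makes the mean age ≈ 80, higher than a real ageing cohort's ≈ 76, a
known simplification), sex is male with probability 0.44.

Phenotype: y_i = μ + β_age·age + β_sex·sex + γ·1[clade] + g_i + ε_i with
g ~ N(0, 2σ²_g·K), ε ~ N(0, σ²_e); defaults μ = 3.53 (so the background
mean is ≈ 2.69 at the age/sex defaults), β_age = −0.01 per year,
β_sex = −0.10, γ = 1.1 (clade mean ≈ 3.8, ≈ 1.25 residual SD), σ²_g = 0.045,
σ²_e = 0.72, 19% missing at random; values below 0.2 are resampled (copy
number is a positive ratio).  The target clade is the genealogy node with
≥ 1 defining mutation whose membership count falls in the configured range
(default 10–17, closest to the midpoint).  Everything is deterministic from
(config, seed); emitted files are byte-identical across runs.

What the generator does **not** emulate: recurrent and back mutation,
mutational hotspots and heteroplasmy; haplogroup structure; realistic
missingness mechanisms; cross-matrilineage paternal kinship; non-normal
phenotype tails.  Passing tests on this generator therefore show the
pipeline's statistical machinery is correct under its stated model, not
that real buccal-swab copy-number data meet those assumptions.

## Numerical choices and degenerate inputs

* Coordinates 1-based closed for variants; alignment columns 0-based.
* QR-based residualization; rank deficiency raises rather than silently
  dropping a covariate.
* Alleles numerically in the covariate span (residual squared norm ≤ 1e−12)
  get F = 0; constant responses (total residual SS ≤ 1e−20) get F = 0.
* Permutation schedules are drawn once per scan from the seed and shared by
  all resolutions and conditioning re-scans; round 2 draws its own.
* Haplotype ids are assigned by descending membership then variant labels;
  branch ids by BFS from the deterministic root — reruns are bit-identical.
* Fewer than two haplotypes, a single-class allele, or zero permutations
  raise typed errors (`DegenerateInputError`, `ParameterError`).

## Problem sizes

The shipped test suite and the acceptance script run, per invocation: one
study-scale cohort (1007 individuals, 10,000 permutations), 200–500 null
cohorts of 400 individuals at 200 permutations for the family-wise error
estimate, and 100–200 cohorts of 800 individuals at 1000 permutations for
the power estimate — sizes chosen so a full run completes in minutes on one
CPU while keeping Monte-Carlo error well inside the asserted margins.

## Limitations

* The loop-resolution enumerator is exact but capped; data sets with
  pathological tie structure (many equal-weight alternatives) are rejected
  with the resolution count rather than analysed approximately.
* The familial variance model is a single additive component on 2K;
  dominance, inbreeding depression and shared environment are not modelled.
* Round-2 block permutation combined with whitening mixes a small amount of
  information across blocks (the colouring matrix is not block-diagonal).
* The score-based relatedness adjustment is kept for fidelity to the
  method; a mixed-model (GLS) association test would likely dominate it in
  both error control and power and is a natural extension.
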