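# Methods

This note records the models and conventions behind pedstruct's
computations, the defaults of the synthetic pedigree generator and what
they do (and do not) emulate, and the numerical choices a maintainer would
want to know about.

## Pedigree model

A pedigree is a set of animal records (id, sire, dam, sex, birth year,
breed, alive flag) stored in topological order (parents before offspring),
validated for duplicate ids, parent-link cycles and sex consistency.
Unknown parents are a first-class concept: `"", 0, NA, UNKNOWN` on input
all normalize to "unknown", and dangling parent ids (used as a parent but
never recorded — common in real registries) become phantom founder records
with a logged warning.  The topological sort is Kahn's algorithm with a
min-heap on input position, so repeated reads of one file give identical
orderings.  Birth dates may be ISO dates or bare years; bare years are
placed at July 1 so age arithmetic in decimal years (365.25 d) is unbiased.

Population subsets keep the selected animals as the *focal* set and retain
their ancestors as computational context only; "current" selects living
animals, a breed label selects that breed, "historical" keeps everything.

## Relationship machinery

* **Inbreeding** uses the Meuwissen–Luo traversal of the `L D L'`
  decomposition of the numerator relationship matrix: per animal, its
  ancestor set is expanded once (largest topological index first) and
  `A_ii = sum_j L_ij^2 D_j`; memory stays linear.  The within-family
  segregation variance is `D_i = 0.5 - 0.25 (F_s + F_d)` with an unknown
  parent entering as `F = -1`.
* **Exact means** of coancestry (population, within- and between-breed)
  use Colleau's indirect method: `A v = T (D (T' v))` via one backward and
  one forward sweep, `O(n)` per product.  Mean coancestry over a reference
  includes self-pairs `f_xx = (1+F_x)/2`; this is the convention under
  which `fg = 1/(2C)` equals `n` for `n` unrelated founders.
* The dense tabular matrix is available for small pedigrees (tests,
  pairwise work below ~4000 animals) but no population mean depends on it.

## Rates, effective sizes, alpha

Per-generation rates normalize by pedigree depth `t` (equivalent
generations, `sum (1/2)^g` over known ancestors): `dF = 1-(1-F)^(1/(t-1))`;
for `t <= 1` the rate is defined as `F` itself (one observed generation).
The pairwise rate `dC = 1-(1-f_ab)^(2/(t_a+t_b))` is averaged over distinct
pairs of the reference — self-pairs are not matings, whereas the mean
coancestry used for `alpha` and `fg` does include them.  For references
larger than 2000 animals the pairwise mean switches to a seeded random
sample of pairs (2,000,000 by default) computed with memoized recursive
kinship; below that it is exact.  Realized effective sizes are
`Ne = 1/(2 x rate)`; their ratio `S = NeC/NeF` measures equivalent
subpopulations (>1 substructure, <1 mixing).

`alpha = 1 - (1-mean F)/(1-mean C)` may be negative (coancestry-avoiding
mating).  The per-individual analogue used as a CDA feature is
`1 - (1-F_i)/(1-C_breed)` with `C_breed` the animal's own breed mean —
the population-level quantity has no per-animal definition, so this is the
natural individual decomposition (it averages back to ~alpha).

## Gene origin

Gene *origins* are the base-population animals: every unknown-parent slot
is a point of origin credited to the animal carrying it, so an animal with
one unknown parent is a half founder (the convention printed in studbook
analyses) and origin probabilities `q_k` sum to exactly 1.  `fe = 1/sum
q_k^2`.  Strict founders (both parents unknown), the base population
(>= 1 unknown parent) and the actual base (half-founder weighted) are all
reported separately.

`fa` uses greedy marginal selection: each round picks the candidate with
the largest contribution to the reference through paths not intercepted by
already-selected ancestors, times the fraction of its own genome not
already explained by them; candidates are strict ancestors of the
reference plus founders; ties break lexicographically by id (fa can differ
in the third decimal under ties).  Selection stops below a residual of
1e-8.

**A caveat worth knowing:** `fa <= fe` is an empirical regularity of
studbook-like pedigrees (many founders, right-skewed parent usage), not a
theorem.  The greedy decomposition can split one origin's contribution
across a nodal descendant and the origin itself, yielding a marginally
flatter partition than the origin distribution; with small founder pools
and near-equal contributions `fa` can exceed `fe` at the second decimal
(origins `q = (0.6, 0.4)` with a nodal ancestor carrying 0.31 from each is
a minimal counterexample).  `fg <= fa` and `fg <= fe` are structural.  The
test suite asserts the ordering accordingly: strictly for `fg`, over
replicates for `fa <= fe`.

`fg` is analytic (`1/(2C)`) or estimated by gene dropping: two labeled
alleles per founder (and per unknown-parent slot), random transmission,
`fg` from the mean simulated identity probability across replicates, with
a delta-method standard error; fewer than 100 replicates is rejected as
unstable.  The inbreeding partition uses `F_i = 0.5 sum_j T_{s_i j}
T_{d_i j} D_j`: one gene-flow sweep per contributing common ancestor, with
the contributions summing to the reference's mean F (checked to 1e-8).

## Structure

Fixation indices use coancestry-based definitions from three means — self
inbreeding `F`, within-subpopulation coancestry `fw`, metapopulation
coancestry `fT` — so `(1-FIT) = (1-FIS)(1-FST)` holds identically.
Subpopulations are weighted by census size (within: linear weights;
metapopulation: the full census-weighted pair mean).  Nei's minimum
distance is the coancestry analogue `D_ij = (f_ii + f_jj)/2 - f_ij`.  The
UPGMA dendrogram delegates agglomeration to scipy's average-linkage and
serializes Newick with branch lengths as merge-height differences; on
ultrametric inputs the cophenetic matrix round-trips exactly.

## Canonical discriminant analysis

Features per individual: F(%), AR(%), alpha contribution, GCI, maximum /
complete / equivalent generations, offspring count; breed is the grouping
factor.  The VIF screen (`1/(1-R^2)`, iterative removal of the largest
offender, default threshold 4 — the stricter of the two conventional
cutoffs, configurable) is expected to drop F and equivalent generations on
strongly inbred data, since both are near-functions of the retained
variables.  The PCA screen (correlation-matrix loadings over
Kaiser-retained components, threshold |0.5|) is report-only by default.
Forward stepwise selection minimizes overall Wilks' Lambda with partial-F
entry (default 3.84, the chi-square(1)/F convention; no entry criterion is
standard in the source software).

The canonical solution solves `B v = lambda W v` by a symmetric
generalized eigendecomposition; axes are scaled to unit pooled
within-group score variance and signed so the dominant loading is
positive.  Identities maintained to 1e-12: `Rc^2 = lambda/(1+lambda)`,
`Lambda = prod 1/(1+lambda)`.  Wilks' Lambda is tested with Bartlett's
chi-square `-(n-1-(p+g)/2) ln Lambda` on `(p-r+1)(g-r)` df for the set of
functions from `r`; Pillai's trace `V = sum Rc^2` gets the standard F
approximation.  Functions with `Rc >= 0.30` are flagged meaningful.
Classification is linear (pooled covariance) with priors from group sizes
by default; LOOCV removes each case by exact rank-one downdates of the
pooled scatter and group mean (identical to a per-case refit, which is
also implemented and cross-checked).  Press' Q `(N-nK)^2/(N(K-1))` is
compared against the chi-square critical value 6.63 (1 df, 0.01).
Unstandardized coefficients are deliberately not exposed: they are
scale-dependent and not comparable across variables.

## Synthetic generator: what it emulates, and what not

Defaults (chosen once, on field realism): 40 founders per breed and 5
generations (tests size this down or up per scenario); sire usage
right-skewed via a dominant-sire categorical with maximum share 0.3 per
generation (real registries show single ancestors explaining 15-30% of a
gene pool; share 0.3 reproduces ~10-20% top marginal contributions);
dams drawn uniformly; sex ratio 0.5; generation step 8 years (between the
~10-13 y intervals of long-lived horse registries and the discrete-cohort
idealization of the simulator); mortality 0.3 per non-terminal animal with
the terminal cohort always alive, so "current" subsets are never empty.
The default composite scheme has five stages — F1 (50:50), backcross to A
(75:25), backcross to B (25:75), the 25x75 cross that re-fixes 50:50, and
50x50 inter se — approximating a staged historical breeding program whose
published ratios are qualitative only.  Blood fractions are simulator
truth labels for tests; no analysis reads them.

The generator does **not** emulate: selection on phenotypes, genotypes or
markers, non-random mate choice within a cohort, fertility or lifespan
variation, open-studbook immigration, or time-varying census sizes.
Consequently, passing tests demonstrate the correctness of the estimators
and the qualitative recovery of structure (Ne near census in an idealized
population, random mating giving alpha ~ 0, a majority-ancestry composite
sorting closer to its majority ancestor) — not calibrated agreement with
any particular real registry.

The Wright-Fisher-like `ideal_population` (constant census, equal sex
ratio, uniform parent draws, non-overlapping generations) is the oracle
for effective-size recovery: over 20 replicates of n=50, 10 generations,
the mean `NeF` lands in [35, 70] (the sampling band of the estimator at
that problem size).

## Problem sizes and numerical choices

Test and acceptance runs use pedigrees of ~200-600 animals, 20-replicate
seed loops, 10,000 gene-drop replicates, and CDA problems of n <= 500,
p <= 8 — sizes at which every exact oracle (dense tabular A, explicit
scatter eigenproblem, per-case LOOCV refit) is feasible, and the whole
suite runs in seconds.  Degenerate inputs are errors, not silent NaNs:
empty references, single-sex generations, unproducible blood fractions,
non-positive rates ("population not losing diversity"), singular
within-group scatter (reported with the offending column), LOOCV folds
that would empty a group.  All simulation randomness flows from one
`numpy.random.Generator` per call; a fixed seed gives byte-identical
pedigrees and pipeline artifacts.

## Known limitations

* Large-pedigree (>10^5) performance was not a goal; the per-animal
  Meuwissen-Luo loop is pure Python and the gene-origin sweeps are O(n)
  per selected ancestor.
* The pairwise-dC sampling scheme for very large references is a
  documented approximation (the source analyses do not state theirs).
* PCI aggregates the first five generations by simple mean; harmonic
  variants exist and give different absolute levels.
* Mahalanobis distances and the CDA assume a pooled within-group
  covariance; no regularized or quadratic variant is provided.
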