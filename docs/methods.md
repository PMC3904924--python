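# Methods

## Model and criteria

The package works on a two-group cohort: m patients, n features, labels
yⱼ ∈ {+1, −1} for the high-CRP set G⁺ and the low-CRP set G⁻. A linear
classifier is a hyperplane H(**w**, θ) with the deterministic decision rule
"predict G⁺ iff w·x − θ > 0"; a score of exactly zero goes to G⁻, and this
tie policy is applied identically everywhere (apparent error, leave-one-out,
the diagnostic map).

The perceptron criterion is

    φⱼ(w, θ) = max(0, δ − yⱼ(w·xⱼ − θ)),    Φ(w, θ) = Σⱼ αⱼ φⱼ(w, θ),

and the modified (feature-selection) criterion is

    Ψ_λ(w, θ) = Φ(w, θ) + λ Σᵢ γᵢ |wᵢ|.

The margin and weighting conventions vary across the CPL literature; the
ones used here are the standard choices, made explicit because results
depend on them:

* **δ = 1** for every patient. Any δ > 0 merely rescales the optimal
  weights, so unit margin loses no generality.
* **αⱼ = 1/(2m⁺) on G⁺ and 1/(2m⁻) on G⁻** (class-balanced, each class
  summing to 1/2). This makes the criterion insensitive to class imbalance
  and gives the λ → ∞ limit a clean closed form: with w forced to 0, every
  hinge equals δ, so the optimum is exactly 1. Configurable per object.
* **γᵢ = 1** for every feature; configurable for cost-sensitive variants.
* **θ is never penalized.**

## Exact minimization

Both criteria are convex piecewise-linear, so the global minimum is a linear
program: minimize Σⱼ αⱼ ξⱼ + λ Σᵢ γᵢ(uᵢ + vᵢ) subject to
ξⱼ ≥ δ − yⱼ((u − v)·xⱼ − θ), ξ, u, v ≥ 0, θ free, with w = u − v. The LP is
solved with HiGHS through `scipy.optimize.linprog`. Vertex solutions give
exact zero weights; the reported zero set uses an absolute tolerance
`zero_tol = 1e−8` (on standardized features) and separability is declared
when the λ = 0 optimum is below `sep_tol = 1e−7`. The tests verify the
optimum against an independently constructed epigraph-form LP (different
variables and constraints, interior-point solver) to 1e−6 on hundreds of
random programs, and verify separability decisions against a plain LP
feasibility oracle.

Continuous (phenotypic) features are z-scored once, before any fitting, so
that unit feature costs act on comparable scales; binary genetic indicators
are left untouched. The fitted location/scale are stored so new patients can
be projected in the training coordinate frame. Statistics are deliberately
*not* recomputed inside cross-validation folds (a single preprocessing pass,
matching the single-pass protocol the package replicates); the small
optimistic leakage this induces is documented rather than corrected.

## The selection path

`run_rls` walks a geometric λ grid (λ₀ = 1e−4, ratio 1.2, λ_max = 1e3 by
default), minimizes Ψ_λ on the currently retained feature set, and drops the
features whose optimal weights are exactly zero. Removal is permanent —
once eliminated a feature never re-enters — which is what makes the recorded
sequence strictly nested. Whenever the retained set changes, the new
subspace is recorded together with a λ = 0 refit, its apparent error,
separability flag, and (optionally) its leave-one-out CVE. When one grid
step would eliminate more than `max_drop` features, the interval is
geometrically bisected until steps are small enough (default `max_drop = 1`,
yielding a near-unit-step dimension ladder) or the interval is relatively
tighter than 1e−3. For large cohorts the path can be run with `max_drop`
unbounded, recording subspaces at the grid's natural granularity; selection
quality is unchanged, only the resolution of the AE/CVE-versus-dimension
curve. The large property-based runs in the tests and the acceptance script
use this coarser recording, with cohorts of up to 200 patients × 50
features; these sizes were chosen as the smallest at which the recovery and
synergy properties are comfortably identified.

`select_optimal_subspace` returns the record with minimal CVE, breaking ties
toward the smaller dimension. CVE is computed with the subspace *fixed*
(selection is not re-run inside folds), replicating the usual evaluation
protocol; the optimistic bias of that choice is inherent to the protocol and
documented, not corrected. No randomness enters anywhere in the pipeline, so
identical inputs give bit-identical paths.

## Preprocessing

* **Median split:** label +1 iff CRP strictly above the sample median;
  values exactly at the median go to the low class (a deterministic rule is
  required; "above/below" alone does not define one).
* **Missingness filter:** first drop patients observed on less than a
  minimum fraction of features, then features observed on less than a
  minimum fraction of the *surviving* patients. Defaults 0.75/0.75,
  configurable.
* **Genotype encoding:** one binary indicator per *observed* genotype
  category per site — usually three (e.g. AA/AG/GG), fewer when
  polymorphism is reduced, five for a tri-allelic site with five observed
  genotypes. A missing call blanks all of the site's indicators; a
  single-category site yields one constant column flagged degenerate rather
  than dropped, keeping column counts faithful to the coding convention.
* **Imputation:** each missing cell is filled from the nearest same-class
  patient that has the cell observed — Euclidean distance over mutually
  observed phenotypic columns (z-scored on full-cohort statistics so scale
  cannot dominate the distance), Hamming
  distance over mutually observed genetic indicators. Ties and empty
  overlaps resolve to the lowest patient index. Observed cells are never
  altered. Imputation runs once on the full cohort before any
  cross-validation, mirroring a single-pass preprocessing protocol; the
  leakage implication is noted, not fixed.

## Diagnostic map

For a classifier on the combined space, each patient maps to
(Σ phenotypic wᵢxᵢ, Σ genetic wᵢxᵢ). Since the two fractions sum to the full
decision score plus θ, classifying by the line phen + gen = θ reproduces the
classifier's predictions exactly (verified as an exact, not approximate,
property). New patients are placed on the map with the stored
standardization and classified by majority vote among their K nearest mapped
neighbours; K must be odd (strict majority) and defaults to 5, the
conventional KNN setting; distance ties break by patient order.

## Synthetic cohorts

The generator emulates the structure of a mixed clinical-genetics cohort:
defaults of 112 + 113 patients, 57 continuous phenotypic features, and 76
polymorphic sites that one-hot encode to 228 indicators (285 features
total) when every site shows all three genotypes — with a base allele
frequency of 0.5 and >200 patients, a missing genotype category is
vanishingly rare, so the default geometry is stable across seeds. Raw CRP
values are drawn class-consistently (low class uniform on 1–5 mg/L, high on
5–9 mg/L) so the strict-above-median split reproduces the planted labels.

* **Marginal mode:** informative phenotypic features are mean-shifted
  between classes by an effect size in SD units; informative sites get a
  class allele-frequency difference, expanded to genotype frequencies under
  Hardy–Weinberg equilibrium. Defaults (effect 1.0 SD on 5 features, allele
  shift 0.2 on 10 sites) give moderately separable cohorts comparable to a
  real exploratory study; sampling genotypes per patient from class allele
  frequencies is the simplest two-parameter control of indicator
  informativeness.
* **Complementary mode:** the genetic score s_g is the centered
  allele-count total over the informative sites, sampled with
  class-*independent* frequencies; the first informative phenotypic feature
  is then set to c·y − s_g with c = 0.8·sd(s_g). The combined space is
  exactly separable with margin c (weights: 1 on that feature, the
  allele-count weights 0/1/2 on the site indicators), while the phenotypic
  block alone has class overlap d′ = 2c/sd(s_g) = 1.6 and the genetic block
  alone carries no class signal — so neither block separates alone but the
  union does, the qualitative signature of complementary phenotypic and
  genetic information.
* **Missingness injection** masks cells i.i.d. at a given rate (≤ 0.5, past
  which class-wise donor pools degenerate), reproducibly from a seed.

All randomness flows from one seeded generator; no global state.

What the generator does *not* emulate: linkage disequilibrium between
sites, realistic phenotype covariance, non-Gaussian measurement
distributions, or informative (non-random) missingness. Passing tests on
these cohorts therefore demonstrate the correctness and the qualitative
behaviour of the method — exact minimization, nested paths, recovery of
planted signal, the synergy effect — not its error rates on real clinical
data.

## Numerical and degenerate-input choices

* LP failures (infeasible/unbounded) cannot occur for λ ≥ 0, γ > 0 and are
  treated as internal errors.
* All-constant feature sets yield no separating direction; the path records
  the full space with positive apparent error and terminates.
* If the cost term zeroes every weight at some λ, the path stops without
  recording an empty subspace.
* A λ = 0 refit reports separability as objective ≤ 1e−7; apparent error is
  0 exactly where that flag is true (checked as an invariant).
* Leave-one-out requires at least two patients per class so no training
  fold is one-class.

## Known limitations

* **CVE plateaus.** When several informative features carry partially
  redundant signal, the CVE curve is nearly flat across a range of
  dimensions: removing one of five equal-shift features at a 4-SD total
  Mahalanobis margin changes the ideal error by only ~1.4 percentage
  points, below the leave-one-out resolution √(p(1−p)/m) ≈ 1.2 points at
  m = 200. The minimal-CVE record can then sit one dimension below the full
  informative set. This is a property of the CVE stop criterion itself, not
  of the minimizer (the minimum of a flat-bottomed curve is noise-driven);
  on real data the same behaviour shows up as a CVE minimum that is broad
  rather than sharp, and near-optimal subspaces deserve inspection
  alongside the arg-min.
* CVE is evaluated on subspaces chosen on the same cohort (no nested
  double cross-validation), so reported CVE is optimistic as a generalization
  estimate; this replicates the protocol the package implements and is
  flagged as future work.
* Monotone (no re-entry) elimination is assumed from the nested-sequence
  description of the method; a feature dropped at small λ is never
  reconsidered.
* Leave-one-out refits one LP per patient per recorded subspace; for
  cohorts much beyond a few hundred patients × hundreds of features the
  path with unit-step recording becomes expensive (the LP itself scales
  well; the fold count dominates).
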