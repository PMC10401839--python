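# Methods

`segmint` reimplements, as a reusable and tested pipeline, a quantitative
segmentation analysis of older public-assistance recipients: soft
clustering of categorical administrative records, selection of the number
of clusters, affiliation-based cluster characterization, descriptive
tabulation, and the classification of mixed-methods concordance between
cluster profiles and caseworker recall.  Because the source roster is
restricted municipal data, the package ships a synthetic generator whose
marginals are calibrated to the published population table; every claim
the test suite makes about recovery is a claim about that synthetic
population, not about the real one.

## The model

Each individual *i* carries one level of each of 13 categorical variables
(age group, nationality, living arrangement, disability/disease,
hospitalization history, long-term-care certification, working status,
previous assistance use, reason for starting assistance, facility
admission, housing type, and median-split bands of working income and
pension — 40 levels in total).  One-hot encoding yields a binary
co-occurrence matrix n(i, v) over individuals × variable-levels in which
every row sums to 13.  The aspect model (probabilistic latent semantic
analysis) represents the joint distribution as a mixture over K latent
clusters z:

    P(i, v) = Σ_k P(z_k) P(i|z_k) P(v|z_k)

fitted by EM on the observed cells only (zero cells contribute nothing to
the log-likelihood; restricting the E-step to the support makes an
iteration O(nnz·K)).  Both individuals and variable-levels belong to
clusters softly, through the posteriors

    A(z|v) ∝ P(v|z) P(z),    A(z|i) ∝ P(i|z) P(z),

each summing to 1 across clusters.  Analyses are stratified by sex: two
independent models, male and female, with sex never entering the matrix.

Assumptions worth keeping in mind: the model treats the 13 variables
symmetrically as exchangeable "tokens" of an individual; it has no notion
of variable identity beyond the one-hot block structure, and the
per-individual parameters P(i|z) make the joint parameterization grow
with the sample (consequences below).

## EM details and numerics

* **Initialization.** Each restart draws the columns of P(i|z) and P(v|z)
  from a flat Dirichlet and sets P(z) uniform.  Exactly symmetric starts
  are EM fixed points that collapse all clusters onto the independence
  solution (a unit test demonstrates this), which is why random restarts
  are required.  Restart r uses seed `root_seed + r`; the winning
  restart's seed is recorded in the model for exact refitting.
* **Convergence.** Relative log-likelihood change below `tol = 1e-8` or
  `max_iter = 500` iterations (defaults, config-exposed).  Non-convergence
  returns the model with `converged=False` and a warning — at large K on
  well-separated data the tail of the EM trajectory is extremely flat and
  truncating it does not move any selection decision we test.
* **Probability floor.** M-step accumulators that are exactly zero are
  replaced by 1e-12 before renormalization.  Zeros cannot occur for
  parameters touching observed cells under positive initialization, so
  the floor only guards degenerate inputs; applied this narrowly it does
  not perturb the EM ascent property (monotonicity holds to 1e-10).
* **Guard rails.** A zero modeled probability on an observed cell raises
  an error rather than returning -inf; the saturated bound
  Σ n·ln(n/R) is exposed for upper-bound checks.
* Tempered EM is not implemented; the fitting recipe is plain EM with
  restarts.

## Choosing the number of clusters

The sweep fits K = 2..10 with 5 restarts each and records, per K, two
families of penalized criteria:

* **Joint-likelihood AIC/BIC** with the full symmetric parameter count
  d = (K−1) + K(I−1) + K(V−1), and BIC sample size R = 13·I (the total
  co-occurrence count; R = I available via `r_convention`).  These
  columns document the raw fit, but they cannot locate a finite optimum:
  the K(I−1) membership parameters are *incidental* — their number grows
  with the sample — so joint BIC is monotone increasing in K (the
  penalty swamps any attainable gain), while the same criterion without
  the membership count is monotone decreasing (the joint likelihood keeps
  absorbing individual-level variance).  Both behaviours are measured on
  the preset and are structural, not tuning artifacts.
* **Folded class-marginal AIC/BIC** (`aic_class`, `bic_class`), the
  default selection basis.  The per-individual parameters are profiled
  out: starting from the fitted posteriors A(z|i), EM on the folded
  latent-class model (cluster weights π_k plus per-variable level
  distributions θ_k only) converges to the folded MLE, and the criterion
  penalizes −2·Σ_i ln Σ_k π_k Π_j θ_k(x_ij) with
  d = (K−1) + K·Σ_j(L_j−1) parameters and sample size I.  This is the
  classical latent-class BIC, consistent for the number of classes under
  exactly the generative structure the synthetic data implement.

Selection takes the smallest-K argmin of the chosen criterion among rows
whose smallest hard-assigned cluster (argmax A(z|i)) meets a size floor
(default 10 individuals); ties within `tie_tolerance` resolve toward
parsimony.  "Interpretability" is deliberately left to humans: the tool
emits the ranked table and candidate profiles (`top_candidates`) rather
than deciding on semantic grounds.

## Cluster characterization

A cluster's profile is the set of variable-levels with A(z|v) ≥ τ,
reported with their affiliation values and sorted descending; the working
threshold is τ = 0.55, inclusive.  The threshold sits strictly above 0.5
because at 0.50 a level could characterize one cluster while the
remaining 0.50 of its affiliation sits in another; a unit test exhibits
this double-membership case at τ = 0.5.  Raising τ can only shrink
profiles (anti-monotonicity is property-tested).  A cluster may have no
level reaching τ; it is reported empty with a warning.

Descriptive tables report per-sex counts and percentages for every level,
with percentages rounded half-away-from-zero to one decimal (bankers'
rounding disagrees with the published table on .x5 boundaries).  Income
and pension banding computes the per-sex median over strictly positive
amounts, codes zero amounts "none", and sends at-median values below —
the rule that reproduces the published below-by-one splits (35 vs 34 men;
31 vs 30, 417 vs 416 women).

## The synthetic population

The generator draws each individual's segment from a per-sex mixing
vector π and then each variable independently from the segment's level
distribution θ — exactly the conditional-independence structure the
clustering model assumes, so parameter recovery is well posed.  Ground
truth is a hard segment label per individual; mixed membership is not
simulated.  One root seed drives everything, with the female stratum on
a fixed-offset stream (seed + 1,000,003) so either block is reproducible
alone.

The `table1` preset has five segments per sex with mixing
(0.28, 0.23, 0.20, 0.14, 0.15) and a near-block structure: on each of
eight informative variables every segment is assigned one dominant level
(target within-segment probability 0.9), and iterative proportional
fitting reconciles that pattern with the published per-sex level
frequencies, which the mixture marginals then match to < 1e-9.
Variables whose levels are all rare (nationality, hospitalization,
facility admission, working income) are left uninformative — every
segment follows the marginal — because no subgroup of plausible size can
dominate a 1–6% level.  Each segment ends up with at least three levels
at probability ≥ 0.8 that other segments do not share (property-tested),
and the separation between the closest pair of segments was sized, when
the assignment tables were designed, to sit well above the BIC penalty
increment at the printed sample sizes.  The five profiles loosely echo the published
cluster themes (younger renters on decreased income; older recipients
with physical disease; care-need recipients in public housing; for
women, the over-85 facility-resident group), but only the marginals are
calibrated; the preset is not a reconstruction of the real clusters.

What the preset does **not** emulate: dependence between variables within
a segment, mixed membership, household structure, and any municipality
effect.  Passing recovery tests therefore show that the pipeline works
when the model's assumptions hold at realistic sizes and separations —
they say nothing about model fit on the real roster.

## Parameter recovery and label switching

Mixture likelihoods are invariant to cluster relabeling, so fitted
clusters are aligned to generating segments by the permutation minimizing
the mean total-variation distance between level distributions, averaged
over the 13 variables and K clusters (exhaustive search for K ≤ 8,
Hungarian assignment above).  The fitted side of the comparison uses the
folded class-conditional estimates, not the raw P(v|z) columns: the
per-individual parameters sharpen P(v|z) toward the hard-assigned
empirical distributions — several times farther from the generating
distributions than sampling noise alone — whereas the folded MLE is the
consistent estimator.  The acceptance suite checks, at the printed
sample sizes, that the preset recovers all five segments per sex with
mean TV ≤ 0.05 and that the class-BIC argmin lands at K = 5 for both
sexes.

## Mixed-methods integration

Interview responses are supplied by the analyst after the qualitative
phase (the tool does not automate it) as one boolean per (cluster,
interviewee).  The verdict per cluster is: concordance if every
interviewee could recall recipients matching the profile, discordance if
none could, partial concordance otherwise; all interviewees are weighted
equally.  The joint display carries one row per (sex, cluster) with the
profile summary, tallies, and verdict.

## Problem sizes and runtime

The shipped test suite and acceptance script run the full-size preset
(1,483 + 1,682 individuals, K = 2..10, 5 restarts) once per sex — about
two minutes on one core; unit and property tests use down-scaled
populations (60–600 individuals, K ≤ 6) chosen so that sampling noise
stays well inside each asserted tolerance.

## Known limitations

* The folded class criterion is the package's resolution of an
  ill-posedness in penalizing the joint PLSA likelihood; other software
  may report AIC/BIC curves on other conventions, and their absolute
  levels are not comparable.
* EM with 5 restarts can miss the global optimum at large K; the table
  flags decreasing best log-likelihoods across K with a warning rather
  than failing.
* The exhaustive-enumeration guarantee for cluster matching holds only
  through K = 8 (Hungarian assignment above is still exact for the
  separable TV objective).
* Empty profiles at τ = 0.55 are possible and legitimate; downstream
  naming of clusters is a human task and out of scope.
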