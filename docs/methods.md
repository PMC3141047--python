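# Methods

This note documents the models and algorithms implemented in `gsppr`,
their assumptions, the tunable parameters and defaults, the synthetic
data the test suite relies on, and the numerical choices that matter.

## The modelling problem

Given a table of n compounds × p numeric molecular descriptors and an
activity vector y (pIC50 = −log₁₀ IC50, IC50 in nM), build a regression
model that predicts activity for new compounds, using a training subset
and reporting honest statistics on a held-out test subset.  The regime of
interest is p ≳ n with heavy collinearity among descriptors, so variable
selection and overfitting control are the central concerns.

## Descriptor pruning

Constant descriptors (sample variance ≤ `var_eps`, default 1e-12) are
removed first.  Then pairs are scanned in column order; when a pair has
|Pearson r| ≥ `corr_threshold` (default 0.99) the member with the larger
mean absolute correlation to all other survivors is dropped (ties drop
the later column) and the scan restarts.  The tie-break keeps the feature
that is more independent of the rest of the table; the procedure is
deterministic and idempotent, and every removal is logged with its
reason.

## BMLR — best multi-linear regression

A beam-search approximation to best-subset OLS:

1. rank all single descriptors by R²;
2. fit all descriptor pairs whose mutual |r| < `pair_corr_max`
   (default 0.8), keep the `beam_width` (default 400) best by Fisher F;
3. extend every retained model by each descriptor whose |r| with every
   member passes the same filter; keep the `beam_width` best; repeat.

Within a fixed size, ranking by F is equivalent to ranking by R², so with
a beam at least as wide as the number of admissible pairs the search
provably reproduces the exhaustive all-subsets optimum up to size 3 (this
is an acceptance test).  Growth stops at `max_size` or when the best R²
improves by less than `breakpoint` (default 0.02) from one size to the
next; the selected model is the last size before the breakpoint fired.
If the breakpoint never fires the `max_size` model is returned with a
warning.  Regression is on raw descriptor scales; coefficients are
therefore scale-dependent, as is conventional for reported QSAR
equations.

Each model carries R² (squared Pearson correlation of fitted vs
observed), the leave-one-out R²cv computed in closed form from the
hat-matrix diagonal (eᵢ/(1−hᵢᵢ), no refits), s² = RSS/(n−p−1) and the
F statistic.  Both R² and F are computed at every stage; F is used for
beam retention, R² for the per-size champion and the breakpoint.

## PPR — projection pursuit regression

The model is ŷ(x) = ȳ + Σᵢ₌₁..nterms βᵢ gᵢ(αᵢ·x̃), with x̃ the
descriptors standardised by training mean and SD, ‖αᵢ‖₂ = 1, and gᵢ a
one-dimensional smoother.  Assumptions: additivity of a small number of
ridge effects, smoothness of each gᵢ, and (for the standardisation to be
meaningful) non-constant descriptors.

**Smoother.** Each gᵢ is a natural cubic smoothing spline fitted by the
Reinsch scheme: with sorted distinct projections as knots, the penalised
criterion Σwⱼ(rⱼ−fⱼ)² + λ∫f″² is solved through the banded system
(R + λQᵀW⁻¹Q)γ = Qᵀr.  The smoothness control exposed to the user is not
λ but the *equivalent degrees of freedom*: λ is calibrated by bisection
until trace S(λ) matches the requested `df` (within 0.02 for final fits;
an acceptance test requires 0.05).  df = 2 is a straight line; df → n
approaches interpolation.  Outside the training projection range the
smoother continues linearly with the boundary slope, and predictions made
there are flagged per row.  Duplicated or near-coincident projections
(gap < 1e-7 of the range) are merged by weighted averaging before
fitting — tiny gaps add no resolvable structure but destroy the numerical
definiteness of the system.

**Forward pass.** Terms are added greedily on the current residuals up to
`max_terms`.  One term is fitted by alternating (a) smoothing the
residuals against the projection and (b) a Gauss–Newton update of the
direction: with slope sⱼ = β g′(tⱼ), the weighted least-squares target
zⱼ = tⱼ + (rⱼ − β g(tⱼ))/sⱼ with weights sⱼ² gives the new direction,
which is renormalised.  A proposed update is accepted only if it lowers
the residual sum of squares, with up to four step-halvings on the unit
sphere; iteration stops when the relative RSS change drops below `tol`
(default 1e-4) or after `max_iter` (default 50) iterations.  Because
every accepted step decreases RSS and each new term enters with its own
least-squares scale, the training RSS is non-increasing across the
forward pass by construction.

**Direction initialisation.** Three deterministic-plus-seeded sources:
the OLS coefficient direction of the residuals; the leading eigenvector
of the residual-weighted second moment Σⱼ rⱼ xⱼxⱼᵀ; and seeded random
unit vectors up to `n_restarts` (default 4) candidates in total.  The
second-moment init exists because the OLS direction vanishes identically
for even ridge shapes (for y = (a·x)² with centred Gaussian descriptors,
E[x y] = 0), which would leave a gradient method with no usable starting
point; for exactly that shape the second moment is I + 2aaᵀ (up to
scale), whose leading eigenvector is the true direction.  The best
converged candidate by RSS is kept, making fits reproducible given
(data, hyperparameters, seed).

**Backward pass.** After growing to `max_terms`, terms are pruned one at
a time — lowest share of explained variance first — down to `nterms`.
`optlevel` sets what is refitted after each drop: 0 nothing; 1 a cyclic
backfit of the ridge functions and scales with directions frozen; 2 a
backfit that also re-runs the Gauss–Newton direction update per term;
3 is an alias of 2 (the distinction in the original formulation concerns
multi-response balancing, which does not arise with a single response).
Backfit updates are accepted only when they lower the training RSS, so
more refitting can never degrade the training fit — a property the suite
asserts.  Final scales βᵢ (and an intercept correction absorbed into the
response centre) are always least squares on the term outputs, which
makes the training residuals orthogonal to every term's output.

**Term importance** is the share of Σᵢ‖βᵢ(gᵢ−ḡᵢ)‖² attributable to each
term.  With correlated term outputs this attribution is approximate, but
it is only used to order the pruning and to report shares.

Models serialise to versioned JSON (directions, knots, values, scales,
standardisation, hyperparameters); the spline is reconstructed exactly
from its knots and values because a natural cubic smoothing spline is the
unique natural cubic interpolant of its own fitted values.

## Evaluation and the grid search

RMSE is √(mean squared error); R² is the squared Pearson correlation
between experimental and predicted activities.  k-fold CV (default k=5)
uses seeded, size-balanced folds on the training rows only; out-of-fold
predictions are pooled into one vector before computing R²cv/RMSEcv
(per-fold values are also reported, since conventions differ).  k = n
reduces exactly to leave-one-out, which the suite cross-checks against
the closed-form hat-matrix PRESS.

The grid search evaluates every admissible cell of
nterms × max.terms × df × optlevel (cells with nterms > max.terms are
skipped) with a *shared* fold assignment, and selects the minimal mean CV
RMSE, breaking ties toward parsimony (smaller nterms, then max.terms,
then df).  Training-set statistics per cell are exported alongside for
optimisation-surface plots, but selection never sees the test set: tuning
against held-out data would leak the very information the test set is
meant to measure.

The PCA diagnostic eigendecomposes the correlation matrix (not the
covariance — descriptors live on heterogeneous scales) of a descriptor
subset and returns percent explained variance and the first two score
columns with train/test labels, to check that a random split covers the
descriptor space evenly.

## Molecular descriptors

* **LP1** — largest eigenvalue of the 0/1 adjacency matrix of the
  molecular graph; an index of branching (chains lowest, stars highest at
  fixed atom count — asserted for n = 4…8).  Hydrogens are excluded by
  default (`heavy-only`), the common convention for topological indices;
  `explicit` keeps them.
* **SIC1** — atoms are partitioned into classes by (own element, multiset
  of neighbour elements); the value is the Shannon entropy of class sizes
  normalised by log₂(n), hence in [0, 1].  Bond orders are ignored; exact
  parity with any commercial implementation is not claimed.
* **Principal moments of inertia** — coordinates are translated to the
  centre of mass and the 3×3 inertia tensor diagonalised; moments are
  reported sorted (IA ≤ IB ≤ IC, amu·Å²) and PMIC = IC, following the
  spectroscopic convention for the C axis.  All atoms present contribute
  regardless of hydrogen policy.

A minimal whitespace-delimited connection-table format (`atoms` block of
`index element [x y z]`, `bonds` block of `i j`) feeds the calculators
from files; masses come from a built-in standard atomic-weight table.

## Synthetic data

The generator emulates the *shape* of a real descriptor study — by
default 128 compounds (split 103/25 downstream), a few informative
standard-normal descriptors, one near-duplicate collinear copy per
informative column (copy noise SD 0.1, giving |r| ≈ 0.995), a block of
pure-noise columns, and an activity offset of 7 putting values on a
realistic pIC50 scale with Gaussian noise (default SD 0.3, a plausible
assay-scale error).  The activity is either a linear form or a sum of
planted ridge functions (square, sine, or sigmoid shapes of unit
directions over the informative block); the ground truth (names,
directions, noiseless activity) is returned and serialised alongside, so
selection and recovery can be verified exactly.

What it does **not** emulate: heterogeneous descriptor marginals,
scaffold clustering, activity cliffs, or assay censoring.  Passing tests
therefore demonstrate correctness of the algorithms under controlled
conditions, not predictive performance on real chemistry.

The default test and acceptance problem sizes (40–100 noise columns, a
handful of grid cells, 10 seeds for the stochastic recovery checks) were
chosen so the whole suite runs in minutes on one CPU while keeping every
planted-structure check well-powered; the same code runs unchanged at
~10³ descriptors.

## Numerical choices and edge cases

* λ-calibration brackets log₁₀λ in [−16, 16] with a warm start carried
  across Gauss–Newton iterations (loose tolerance 0.1 inside the
  alternation, tight 0.02 for the final smoother of each term).
* Requested df is clipped to the feasible (2, n_knots) range; two distinct
  knots degrade gracefully to the weighted least-squares line.
* A relative jitter (1e-10 of the diagonal) restores positive
  definiteness of the penalised system if rounding breaks it.
* Rank-deficient OLS designs raise an error naming the collinear columns
  (pivoted-QR diagnostics); leverages of 1 make LOO undefined and raise.
* Grid cells that fail to fit are logged and skipped; the search errors
  only if every cell fails.
* The model-order experiments in the acceptance suite use optlevel 2 and
  df 7: identifying the true number of ridge terms by CV requires the
  pruned model to be refitted thoroughly (otherwise a third term
  legitimately mops up the bias left by frozen directions and wins the
  CV), and the natural-spline boundary condition (zero curvature at the
  ends) needs df headroom to track a quadratic ridge near the data edge.

## Known limitations

* The smoother family is the df-calibrated smoothing spline; the
  variable-span "supersmoother" used by some PPR implementations is not
  provided, so bit-exact parity with other PPR software is neither
  expected nor claimed (differential behaviour is tested instead).
* BMLR stage 2 fits all admissible pairs; for p ≫ 10³ descriptors this
  is O(p²) model fits and becomes the dominant cost.
* Importance shares attribute correlated term outputs approximately.
* The descriptor calculators cover only LP1, SIC1 and inertia moments;
  leverage-matrix (GETAWAY), dipole-weighted edge-adjacency and
  quantum-chemical descriptors require electronic-structure inputs that
  are out of scope.
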