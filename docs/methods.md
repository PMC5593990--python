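# Methods

This note records the models implemented in `macroqg`, their assumptions,
the numerical choices made where the method description left the design
open, and what the synthetic-data calibration does and does not establish.

## Drift null and the two neutrality tests

Both tests assume that the pooled within-species phenotypic covariance
**W** is proportional to the additive-genetic covariance **G** and that this
structure was approximately stable over the clade's diversification. Under
those assumptions, drift makes the between-species covariance of mean
phenotypes proportional to **W**: `B = W (t/Ne)`.

**Regression test.** Species means are projected on the unit eigenvectors
of the node's **W** (sign convention: the largest-magnitude loading is
positive). The between-group variance of each PC, `B_i`, is the variance of
the phylogenetic independent contrasts of the scores on the node's subtree,
with divisor equal to the number of contrasts and no mean-centering
(contrasts have expectation zero under Brownian motion; the same convention
is used for the full B-matrix estimator `contrast_covariance`). The slope
of `ln B_i` on `ln W_i` is estimated by OLS over the retained PCs —
`min(p, n_taxa - 1)`, minus PCs with eigenvalues below `1e-12 * lambda_1`
or with zero between-group variance — with a t-based 95% confidence
interval (degrees of freedom = number of PCs − 2). The test runs only at
nodes with more than `min_taxa` (default 5) terminal taxa.

*Sensitivity.* The slope test detects selection regimes that tilt the whole
variance spectrum (e.g. between-group variance growing like a power of the
within-group eigenvalues); the test suite verifies power > 0.8 against a
`B_i ∝ W_i^1.5` regime at 30 tips. It is, by construction, insensitive to
inflation of a *single* PC: one outlying point in a 10-point regression
inflates the residual variance against which its own leverage is judged,
and the expected t-statistic is bounded below the critical value for any
inflation factor. The suite documents this insensitivity explicitly; the
correlation test and the branch-wise gradients are the instruments for
isolated-axis selection.

**Correlation test.** For every pair among the first `min(n_taxa - 1,
retained)` PCs, the Pearson correlation of the score contrasts is computed
through the origin (contrasts are mean-zero with arbitrary sign; a centered
mode is available as a switch) and tested two-sided with df = number of
contrasts − 1. Pairs are *listed* at raw p < 0.01 (descriptive convention);
the drift *rejection decision* uses the Bonferroni criterion at family
level 0.05. Both thresholds are configurable; the two conventions are
reported side by side because descriptive pair lists and family-wise
decisions serve different purposes.

## Covariance estimation

* Replicated digitizations are averaged per specimen before any estimation;
  per-trait repeatability is the one-way ANOVA intraclass correlation with
  the standard unbalanced-design correction for the effective replicate
  count, clipped to [0, 1].
* P-matrices are MANOVA-controlled: each candidate term (factor main
  effects, pairwise interactions) is screened with Wilks' lambda (Rao's F
  approximation) as a Type II marginal test at alpha = 0.05; the retained
  linear model keeps significant terms only (an interaction only when both
  mains are retained), and P is the residual cross-product matrix divided
  by n − rank(design). With no significant term P is the plain sample
  covariance (divisor n − 1). When n ≤ p + 1 the screening is skipped and
  the raw covariance returned with a warning — Wilks' lambda needs a
  non-singular error matrix.
* Node W-matrices pool the clade's P-matrices with weights (n_k − 1), the
  df-correct pooled-covariance weighting. Species with fewer than 35
  specimens (configurable) do not contribute their own P: their slot is
  filled by the W of their immediate ancestral node. This is implemented in
  two passes — first pooling adequately sampled species at every node (with
  a top-down fill for clades containing none), then re-pooling with the
  small species represented by their parent's first-pass matrix — which
  avoids the circularity a literal single top-down pass would have (a
  node's W would need descendant Ws computed later).

## Eigenvalue extension

Inverting **W** for selection gradients is dominated by its smallest, most
noise-contaminated eigenvalues. The extension step scans the descending
eigenvalue scree with its second differences `d_j = λ_{j+1} − 2λ_j +
λ_{j−1}` and sets the cutoff rank j* to the smallest j ≥ 3 for which the
variance of the `w = 4` second differences *following* j falls below
`tol · λ_1²` (default tol = 1e-4): the scree has stabilized beyond j.
Eigenvalues past j* are raised to `λ_{j*}` and the matrix rebuilt with its
original eigenvectors. The window is placed after the candidate cutoff
because a window that includes the transition into the noise floor sees the
transition's own curvature and pushes the cutoff too deep to be useful.
`tol`, the window width, and a manual rank override are exposed. Matrices
with p < 5 are returned unchanged (scree too short to diagnose).

Guaranteed invariants (tested): eigenvectors preserved (W and W_ext
commute), leading eigenvalues identical up to j*, output PSD, minimum
eigenvalue never decreases, condition number never increases.

## Ancestral states and selection gradients

**Linear parsimony** minimizes total absolute change per trait, ignoring
branch lengths, via a continuous Sankoff dynamic program over convex
piecewise-linear cost functions (the min-plus convolution with |x−y| clips
slopes to ±1). An upward and a downward pass give, per node and trait, the
full interval of values attainable in some globally optimal reconstruction;
the point estimate is the interval midpoint and the interval is retained in
the output. Midpoints are chosen independently per node, so the vector of
point estimates need not itself realize the minimum cost when optima are
non-unique — the reported cost always comes from the exact optimum.

**ML-Brownian** states are the GLS estimates under Brownian motion,
computed by two-pass belief propagation; this realizes the re-rooting
identity (each node's estimate is the PIC root value of the tree re-rooted
there) in linear time, and the root estimate coincides with the PIC
recursion's root value to machine precision. Zero-length branches receive
an epsilon of 1e-8 × tree depth, as in the contrast recursion.

Parsimony is the headline method (branch lengths on published supertrees
are often the least reliable layer); ML-Brownian is always available and
the pipeline reports the correlation between the two reconstructions.

**Gradients.** `beta` solves `W_ext beta = dz` through the
eigendecomposition (no explicit inverse). The matrix inverted on a branch
is the *parent* node's pooled W — the ancestral population's covariance is
what shaped the response — with a child-side convention available as a
switch. Mean-standardization multiplies `beta_i` by the parent-node
ancestral mean of trait i, making the magnitude `‖beta_μ‖` dimensionless
and invariant to unit changes (scaling all traits by c scales beta by 1/c
and the means by c). The paper trail for ambiguity is kept: with a hard
rank cutoff instead of extension, the component of `dz` outside the
retained subspace would be unexplained response; extension (the default)
fixes conditioning, not rank, so `dz` is used as-is.

## Mk diet models

Diet is coded into eight categories (insectivory, strict insectivory,
hematophagy, omnivory, carnivory, nectarivory, frugivory, obligate
frugivory). ER/SYM/ARD rate matrices are fitted by L-BFGS-B on log rates
from multiple jittered starts (seeded), likelihoods by Felsenstein pruning
with per-node scaling; transition matrices come from the eigendecomposition
of Q with an `expm` fallback for ill-conditioned cases. The root prior is
uniform by default. AIC uses k = 1, s(s−1)/2 and s(s−1) free rates
respectively. Ancestral diets are summarized by exact marginal posteriors
(downward partials combined with upward messages) and branches are flagged
as dietary transitions where the maximum-a-posteriori state changes —  a
deterministic summary of the quantity stochastic character maps sample,
chosen because sampled histories add stochastic surface without analytical
content here.

## Synthetic data: what it emulates, what it does not

The generator reproduces the statistical structure the analysis assumes:
a pure-birth tree scaled to a 30-Myr clade age; a shared within-species
covariance whose leading eigenvector is an all-positive allometric size
axis (~45% of variance) over a geometrically decaying spectrum with a
floor; Brownian trait evolution with rate `sigma2_drift · Σ` (default 0.01
per Myr — neutral divergence modest relative to within-species variation);
optional deterministic selection pulses `Σ β*` on chosen branches (default
intensity 8 within-species SD along PC1, the scale of a quantum-evolution
dietary transition); an optional co-selection regime adding shared random
branch shifts along two PCs at 1.5 within-species SD per unit branch
length; specimen sampling with per-species n uniform on [10, 90] (so the
< 35 pooling fallback is exercised), sexual size dimorphism of 0.3 SD,
locality shifts of 0.2 SD, and duplicate digitization with 0.15 SD error
(repeatability ≈ 0.98). Everything is reproducible from a single seed.

It does *not* emulate: skull geometry or landmark-level measurement
structure, allometric curvature (trait relations are linear), heterogeneity
of **P** across species (all species share Σ exactly — real matrices only
approximate proportionality), diversification-rate shifts, or
diet-dependent trait evolution (diet and traits evolve independently unless
pulses are placed by hand). Passing calibration therefore shows the
estimators are correct and well-calibrated *under the model's own
assumptions*; it does not validate the proportionality of **P** and **G**
or the stability of **W** on any real clade.

## Problem sizes and numerical conventions

Calibration experiments run at 30 tips and 10 traits (500 replicates for
null calibration, 200 for power and pulse recovery), sizes at which the
sampling distributions are already well resolved; exhaustive oracles cover
all tree shapes to 7 tips (parsimony, against full grid enumeration) and 6
tips / 3 states (Mk, against sum-over-histories). Mk model-recovery
simulations use 3 diet categories at 57 tips: with 8 categories an ARD
model has 56 free rates and is not identifiable from 57 tips, so the
recovery experiment would measure optimizer failure rather than model
selection. Ties in eigenvalue ordering are broken by the descending sort;
eigenvector signs follow the largest-loading-positive rule; polytomies are
resolved ladder-wise with zero-length branches replaced by
1e-8 × tree depth inside the recursions that require positive lengths.
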