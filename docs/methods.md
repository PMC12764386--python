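# Methods

## Model

Observations are triples (s_i, x_i, y_i): a planar spatial location
s_i ∈ S ⊂ ℝ², covariates x_i ∈ ℝᵖ, and a scalar response y_i. The spatial
domain is partitioned into L regions S_1, …, S_L, and each region carries
its own response function:

    y_i = Σ_j 1(l_i = j) · f_j(x_i) + ε_i,     ε_i ~ N(0, τ²),

where l_i = j ⇔ s_i ∈ S_j. The cluster labels l_i, the partition, and the
functions f_j are all unobserved; the goal is to recover the labels. This
is *spatial clustering in the functional sense*: two regions belong to
different clusters not because their covariates differ marginally but
because the covariate–response relationship differs.

Each f_j is approximated by a zero-mean Gaussian process with the
squared-exponential kernel

    K(x, x′) = σ² · exp( −‖x − x′‖² / (2b) ),

with signal variance σ², length scale b (note the convention: b divides the
squared distance directly; the common exp(−d²/(2ℓ²)) parameterization is
recovered by b = ℓ², so the two conventions describe the same model family
and no switch is needed). A nugget τ² ≥ 10⁻⁸σ² is always present on the
Gram diagonal: it carries the observation-noise variance, keeps the
factorization stable, and keeps in-sample residuals informative (exact
interpolation would zero every within-cluster error and freeze the label
updates). Hyperparameters θ = (σ², b, τ²) are estimated by maximizing the
log marginal likelihood log N(Y | 0, K + τ²I) over a bounded box, with
L-BFGS-B on log-parameters and analytic gradients. Responses are centered
per cluster before fitting and the offset restored at prediction; features
are z-scored once with whole-dataset statistics, so a single isotropic
length scale across heterogeneous columns is meaningful. Prediction is the
BLUP / kriging mean ŷ(x*) = K(x*, X)(K(X, X) + τ²I)⁻¹Y.

## The clustering iteration

Given current labels, one iteration (a) fits one GP per cluster on its
members, (b) recomputes each cluster's spatial center C_j (coordinate-wise
mean of standardized s), and (c) reassigns every observation to

    l̂_i = argmin_j ( f̂_j(x_i) − y_i )² + λ · ‖s_i − C_j‖ ,

ties to the lowest index. λ ≥ 0 (default 0) trades prediction error against
spatial contiguity; because coordinates are standardized, λ is data-scale
free in space but carries the squared units of y — a useful mental model is
"λ · (1 standardized spatial unit) should be comparable to the squared-error
difference you are willing to override". The loop stops when the label
vector repeats, with a cap of T total iterations.

By default the GP design contains the covariates only, matching the model
equation above. The algorithm listing's variant — concatenating s into the
design — is available as `feature_mode="space+covariates"`, but is not the
default: the response is a deterministic function of (s, x) away from
region boundaries, so with coordinates in the design a flexible GP can
near-interpolate an arbitrarily mislabeled cluster, zeroing its residuals
and freezing the iteration. Injecting spatial structure through λ avoids
that failure mode.

## Optimization schedule

From a random initialization every cluster is a mixture of regimes, and the
plain iteration is prone to two local traps: *interpolation freezing*
(above) and *patchwork optima*, where each GP fits different regimes in
different parts of covariate space and no coherent reassignment flow
exists. Two devices address this; both reduce to the plain bounded
iteration in their final phase.

**Annealed bounds.** Early iterations impose floors on b and τ², and a cap
on σ² (a few times var(y)) — without the cap the fitted signal variance
inflates to buy back the flexibility the floors remove. Rigid, heavily
regularized fits approximate each cluster's *mixture-weighted mean
function*, whose prediction errors order the clusters coherently for every
observation of a given regime, so reassignment flows all points of one
regime toward the cluster that is already richest in it. The floors are
relaxed geometrically (default factor 0.25 per level, 5 levels, starting at
b₀ = 20, τ₀² = 0.5·var(y), σ² ≤ 4·var(y)), iterating to label-stability at
each level, and the final level runs at the configured bounds (defaults
b ∈ [10⁻², 10³], σ² ∈ [10⁻³, 10³]·var(y), τ² ∈ [10⁻⁸, 1]·var(y)).
An initialization supplied as explicit labels skips the schedule entirely
and is refined directly at the configured bounds: a correct partition is
then a fixed point of the reassignment (the absorbing-state property), which
the schedule must not perturb.

**Restart selection.** Random initialization is restarted n_init times
(default 3) and the final state with the largest summed per-cluster log
marginal likelihood is kept. A correct partition explains each cluster as a
smooth function plus small noise; merged or patchwork states need either a
large nugget or a short length scale, and their marginal likelihood is
lower by a wide margin (thousands of nats at n ≈ 800 in the packaged
studies), so the selection is sharp.

Hyperparameters are warm-started across iterations within a level
(`restarts` fresh multi-starts at each level change). Empty clusters are
reseeded with the observation carrying the largest current assignment cost,
provided the donor cluster stays at least `min_cluster_size`.

## Synthetic studies

Three generators draw s and x independently and uniformly on [0, 1]²,
partition the spatial domain geometrically, and generate y from per-region
functions plus N(0, noise_var) noise. They emulate the qualitative designs
of the motivating simulation studies; all constants are overridable.

* `linear_ball` — disc of radius 0.25 at the center vs background;
  f₁ = 3x₁ + 2x₂, f₂ = −3x₁ − 2x₂. No single marginal (s, x, or y)
  separates the clusters; the structure lives only in the x–y relation.
* `nonlinear_ring` — annulus with radii 0.25/0.4 vs background;
  f₁ = 5sin(2πx₁) + 5cos(2πx₂), f₂ = 5(x₁² + x₂²). The surfaces intersect
  on curves, so separation is functional, not an offset.
* `sun_moon` — discs of radius 0.15 at (0.3, 0.5) ("sun") and (0.7, 0.5)
  ("moon"; optionally a crescent) vs background;
  f₁ = 20sin(2πx₁) + 20cos(2πx₂) − 80, f₂ = 20(x₁² + x₂²),
  f₃ = 40x₁x₂ + 80. The three surfaces are pairwise separated by at least
  40 response units everywhere on the covariate box — four noise standard
  deviations at the reference noise variance of 100. This is deliberate:
  recovery under heavy noise is only possible when the separation between
  regime functions dominates the noise scale (the same condition the
  method's theory requires), and an assignment oracle knowing the true
  functions confirms near-perfect recoverability at this separation and
  near-chance recovery without it.

What the generators do *not* emulate: covariate dependence on location
(s and x are independent), non-uniform sampling density, irregular region
boundaries (tract polygons), heteroscedastic or non-Gaussian noise, and
discrete responses. Passing recovery tests on these designs therefore
demonstrates the mechanism — functional separation drives label recovery —
not robustness to real-survey messiness.

## Study-scale choices

The packaged end-to-end checks run the ball and ring studies at n = 800 and
the sun/moon study at n = 900 with noise variance 100, five seeds each,
median ARI reported; the over-specification check requests L = 5 from the
three-regime design. For the noisy compact-region study the spatial penalty
is set to λ = 50: squared-error differences between the low-offset regimes
are of order the noise variance (100), so a penalty of ~0.5·var(noise) per
standardized spatial unit breaks near-ties in favor of contiguity without
overriding clear functional evidence. λ = 2 (a token positive value) leaves
the penalty inert at this noise scale.

## Numerical notes

* Gram factorizations are Cholesky-based; on failure the diagonal jitter is
  escalated ×10 up to 10⁻⁴σ² before a numerical error is raised.
* `fit_gp_mle` is deterministic given its seed; restarts draw log-uniform
  starting points inside the bound box. The heuristic first start uses
  σ² = var(y), b = median squared inter-point distance, τ² = 0.1·var(y).
* Reassignment uses in-sample predictions, as in the algorithm listing; the
  nugget keeps them informative. Leave-one-out residuals were considered
  and rejected for cost; the annealed τ² floor covers the pathological
  regime where in-sample residuals vanish.
* Tie-breaks (argmin over clusters) go to the lowest index, making runs
  bitwise reproducible under fixed seeds.
* Degenerate inputs: constant y gives σ² at its floor; clusters of size 1
  fit a pure-nugget GP; empty clusters at initialization are re-drawn
  (random init) or reseeded (mid-run).

## Known limitations

* Model selection for L is out of scope; over-specified L is tolerated
  (surplus clusters drain or split the background) but under-specified L
  merges regimes silently.
* Planar Euclidean geometry throughout; longitude/latitude inputs at
  continental scale should be projected first.
* Exact GP fitting is O(n³) per cluster per iteration; the packaged studies
  (n ≤ 900) run in minutes on one core, but the method as implemented is
  not suitable for n ≫ 10⁴ without sparse approximations.
* With heavy noise and very small regimes (a few % of n), recovery is
  restart-limited: individual descents can merge a small regime into the
  background, and reliability comes from n_init plus the likelihood-based
  selection rather than from any single descent.
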