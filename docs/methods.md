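# Methods

## Model

Given n instances x₁…x_n ∈ ℝᵈ of which l are labeled with classes coded
as one-hot vectors c₁…c_M (c_mm = 1) and u = n − l are unlabeled, the
classifier learns a vector-valued decision function in an RKHS,
f(x) = Σᵢ αᵢ K(xᵢ, x) with αᵢ ∈ ℝᴹ, together with a possibilistic
label-membership function w(x) ∈ (0, 1]ᴹ. Three ideas shape the
objective:

1. **Clustering promotion through local weighted means.** Each instance
   is tied to its LWM, x̂ᵢ = Σ_{j∈Ne(xᵢ)} W_ij xⱼ / Σ W_ij with
   W_ij = exp(−γ‖xᵢ−xⱼ‖²) over its k nearest neighbors (self excluded),
   by penalizing the distance of f(x̂ᵢ) to the same target as f(xᵢ) with
   weight λ_s. In kernel space the LWM is the same convex combination of
   mapped neighbors, so the Gram matrix against LWMs is K̄ = K·N with N
   the column-normalized neighbor weights — no explicit feature map is
   needed and the construction works for any Mercer kernel.
2. **Possibilistic memberships.** Unlabeled instances enter the loss
   through per-class weights w_m(xⱼ)² without a sum-to-one constraint;
   labeled instances are pinned one-hot.
3. **Fuzzy-entropy regularization.** The term
   C Σ (w² ln w² − w²) prevents the trivial all-zero membership solution
   and sets how sharply memberships decay with distance; the membership
   exponent is fixed at 2 (exponent 1 collapses to hard clustering,
   exponent → ∞ to uniform memberships).

Both block updates are exact minimizers, so the objective is
non-increasing along the alternation and, being bounded below (the
entropy term is bounded by −C per element; every other term is
nonnegative), the trace converges. Note the objective can be negative —
boundedness below, not nonnegativity, is what convergence uses.

### Decision update

For fixed memberships the objective decouples across the M output
coordinates. Collecting per-instance weights d (1 for labeled, Σ_m w_m²
for unlabeled) and targets T (one-hot for labeled, column w_m² for
unlabeled), the stationarity condition is one symmetric n×n system
shared by all M coordinates:

    α (K D K + λ_s K̄ D K̄ᵀ + λ K) = T K + λ_s T K̄ᵀ.

This scalar-level derivation is used deliberately: it is unambiguous,
verified in the tests against generic numeric minimization (objective
gap ≤ 1e−4 relative) and a vanishing-gradient condition
(‖∇‖ ≤ 1e−6·(1+‖α‖)).

### Membership update

For fixed f the per-element problem
min_{0≤w≤1} w²d₁ + λ_s w²d₂ + C(w² ln w² − w²), with d₁ = ‖f(x)−c_m‖²
and d₂ = ‖f(x̂)−c_m‖², has the closed-form global minimum
w = exp(−(d₁ + λ_s d₂)/(2C)). The λ_s factor on the LWM distance is kept
in the solution because it is the exact stationary point of the
objective actually minimized (the simplified form without it is the
special case λ_s = 1). Exponent underflow clamps to 0.

### Hard variant

The ablation replaces graded memberships by a single one-hot assignment
per unlabeled instance, yⱼ = argmin_m d₁ + λ_s d₂ (ties to the lowest
class code), drops the entropy term, and otherwise shares the decision
solve and stopping rule. It is the baseline against which the
possibilistic variant's outlier robustness is measured.

### Consistency diagnostics

Predictions can be read from f (argmax) or from w (argmax). With
λ_s = 0, argmax w = argmax f identically (the membership is a monotone
transform of ‖f − c_m‖², and for one-hot codes argmin_m ‖f − c_m‖² =
argmax_m f_m), so the prediction-consistency rate is exactly 1. With
λ_s > 0, argmax w = argmax_m [f_m(x) + λ_s f_m(x̂)], and instances
trichotomize: *intrinsic* (x and x̂ share the f-argmax),
*fake-consistent* (they do not, but the margin inequality
f_j(x̂) − f_m(x̂) < (f_m(x) − f_j(x))/λ_s holds for every competitor j, so
the two predictors still agree), and *inconsistent* (boundary instances
whose predictions are unreliable). The ground-truth consistency rate is
the intrinsic fraction.

## Parameters

| parameter | default | meaning |
|---|---|---|
| λ | 0.1 | RKHS ridge weight; `Hyperparams.preset("deap")` sets 1.0 |
| λ_s | 0.1 | LWM-consistency weight (0 disables the LWM coupling) |
| C | "auto" | entropy weight; auto = mean distance to the centroid, Σ‖xⱼ−x̄‖/n (rejected if 0, i.e. all points identical) |
| k | 5 | neighbor count of the LWM graph |
| γ | "auto" | graph Gaussian width; auto = 1/(2σ̄²), σ̄ = mean pairwise distance |
| ε | 1e−3 | relative objective-change stopping threshold |
| max_iter | 50 | cap on alternations; 0 returns the labeled-only initialization |

Kernels: linear, rbf (exp(−γ‖·‖²)), laplacian (exp(−σ‖·‖)),
inverse_square_distance (1/(1+σ‖·‖²)), inverse_distance (1/(1+σ‖·‖)),
precomputed, and multi (sum of component Grams — the Gram of the
orthogonally concatenated feature map; a stacked-blocks view of the
combination is notational only, since only the sum yields a valid n×n
Gram for the decision solve). "auto" widths all derive from the mean
pairwise distance σ̄, mapped dimension-appropriately: γ = 1/(2σ̄²) for
rbf, σ = 1/σ̄ for the first-power distance kernels, σ = 1/σ̄² for the
squared-distance kernel.

## Numerical choices

* Unlabeled memberships initialize at zero, so the first decision solve
  fits the labeled data alone; a uniform-random initialization is
  available (`init="random"`) but zeros is the default and makes the
  first iterate deterministic.
* The system matrix inherits K's rank deficiencies; on an
  ill-conditioned direct solve a jitter of 1e−10·tr(K)/n is added, and a
  least-squares solve is the final fallback (both logged as warnings).
* Stopping uses |F_t − F_{t−1}| < ε|F_{t−1}| with an absolute floor
  |F| < 1e−12 treated as converged; the entropy convention 0·ln 0 = 0
  keeps the all-zero initialization finite. The entropy sum ranges over
  unlabeled instances only (labeled memberships are constants).
* Ties everywhere (neighbor distances, argmax predictions, hard
  assignments) break to the lowest index/code, making runs
  bit-reproducible; `solve_decision` returns C-contiguous coefficients
  so serialized models reproduce predictions bit-for-bit.
* Out-of-sample points take their LWM over the k nearest *training*
  instances with the training γ; training points evaluated through this
  path reproduce their training LWM exactly (zero-distance training
  points are excluded, mirroring self-exclusion). For precomputed
  kernels the graph is built from feature-space distances
  ‖φᵢ−φⱼ‖² = Kᵢᵢ+Kⱼⱼ−2Kᵢⱼ and LWM-based prediction is transductive
  (training set only).

## Synthetic data

`SyntheticSpec`/`make_problem` emulate the method's intended setting:
M Gaussian classes at the vertices of a regular simplex whose edge is
`separation` within-class standard deviations (default 8 — essentially
non-overlapping), few stratified labels (default 10 total, spread as
evenly as possible), and optionally a fraction of outliers drawn
uniformly on a shell at `outlier_scale` (default 5) times the inlier
radius, appended unlabeled. A single seeded generator drives all draws
in a documented order, so fixtures are stable. What this generator does
*not* emulate: real EEG feature structure (band-power correlations,
non-Gaussian class shapes, session drift, label noise) — passing tests
demonstrate the optimization and the possibilistic mechanics, not
field performance on EEG.

Problem sizes used by the test suite were chosen to keep the full run
in the order of minutes: random oracle instances use n ≤ 30, the
monotonicity sweep uses 100 fits of n ≈ 30–150, and the recovery and
robustness checks use the canonical n = 300 problem over 20 seeds.

## Known limitations

* **Scale coupling of the entropy weight.** The membership exponent
  compares distances between decision values and one-hot codes — an
  O(1), scale-free quantity — while the auto heuristic for C scales
  with the data (mean distance to centroid). On data whose scale is
  large relative to 1 (e.g. the canonical separation-8, unit-noise blob
  problem, C ≈ 4.7), memberships saturate toward 1 in every class, the
  unlabeled targets pull f toward the code centroid, and label-recovery
  accuracy degrades to ~0.92 on average even on cleanly separated
  clusters, whereas the labeled-only initialization and the hard variant
  recover 100%. On unit-scale data (C ≲ 1) memberships are
  well-contrasted and recovery is essentially perfect. Users should
  standardize features to O(1) scale, or set C explicitly, when sharp
  memberships are wanted.
* The stopping rule compares relative changes of an objective dominated
  by the (large, nearly constant) entropy term, so it can fire while the
  loss terms are still moving; lower ε forces further iterations.
* Dense n×n solves limit practical n to a few thousand instances; no
  approximate nearest-neighbor or low-rank paths are provided.
* Kernel combination uses unit weights (concatenation); combination
  weights are not learned.
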