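# Methods

This note documents the models, numerical choices and known limitations of
`pwasoft`. Notation follows the README: y(k) is the target output, u(k) ∈ R⁶
the auxiliary inputs, X(k) the lagged regression vector of dimension
n = n_y + n_u·r, z(k) = [X(k)ᵀ, y(k)]ᵀ the modeling vector, S the number of
local affine models.

## Data model and preprocessing

A batch is a uniformly sampled record with an observation mask on the
outputs: off-line assays exist only on a slow grid (hourly by default), and
piecewise-linear interpolation (cubic optional) fills the fast 5-minute grid
before modeling. Extrapolation beyond the first/last assay is refused unless
explicitly requested — fabricating unobserved tails silently would bias the
training set. Normalization is per-channel min–max onto [−1, 1], fitted on
the training collection; channels with zero range map to 0 and are flagged
(the min–max formula is undefined there). Test-time values outside the
training range keep the same affine map and may leave [−1, 1]; they are
logged, never clipped, because clipping would distort one-step dynamics.
Regression vectors are built per batch with the first max(n_y, p + n_u)
samples trimmed; lag windows never span two batches, since consecutive
batches are independent realizations and a window across the joint would
fabricate dynamics no batch exhibits. The pure delay p is not identifiable
from the data design here and defaults to 0 (configurable).

## Order selection

Choosing (n_y, n_u) is treated as an embedding-dimension problem over a
nested schedule of lag structures, output lag first: (1,1), (2,1), (2,2),
(3,2), … Two diagnostics are computed per step with L∞ distances:

* **FNN fraction** — the nearest neighbor at step s is re-measured after the
  next step's coordinates are appended; it is false when the relative growth
  |d⁽ˢ⁺¹⁾ − d⁽ˢ⁾| / d⁽ˢ⁾ reaches the threshold R_T (default 10, the low end
  of the conventional 10–50 range). A variant that divides by d⁽ˢ⁺¹⁾ instead
  is kept behind `printed_variant=True`; under coordinate nesting that ratio
  is bounded below 1, so it can never fire at R_T ≥ 10 — it exists for
  comparison only.
* **Cao statistics** — α(p,s) = d⁽ˢ⁺¹⁾(p)/d⁽ˢ⁾(p), E(s) = mean over p,
  E0(s) = E(s+1)/E(s). Pairs with zero step-s distance are excluded from the
  mean and counted (duplicated trajectory points would otherwise divide by
  zero).

For input/output data E0 is a blunt instrument: appending an input lag adds
coordinates that carry exogenous innovations no embedding can predict, so E0
oscillates with the append type instead of settling. The selector therefore
treats the first step where the FNN fraction drops below δ₀ = 0.02, and the
E0-stability rule |E0 − 1| < tol (tol = 0.05, with the usual n+1 convention),
as co-equal proposals; the earlier one fixes a total-lag budget L. All splits
with n_y + n_u ≤ L + 1 are then ranked by one-step least-squares ARX residual
on a trailing held-out slice (30%), and the smallest split within 5% of the
best residual wins — more output lags break ties at equal size. On noiseless
linear benchmarks this reproduces the true (n_y, n_u) reliably; on noisy data
the parsimony rule guards against the residual ranking's bias toward larger
models.

Randomness detection uses Cao's companion statistic: E*(s) is the mean
distance of the *appended* coordinates between each point and its step-s
neighbor, and E2(s) = E*(s+1)/E*(s). For an i.i.d. series the appended
coordinate is independent of the neighbor choice, so E2 ≈ 1 at every step —
that flatness (within tol) raises the `random_like` flag. E0 itself does
*not* go to 1 for noise at small dimensions: nearest-neighbor distances for
i.i.d. data scale as N^(−1/d), so E0(d) ≈ N^(−1/(d(d+1))), far below 1 at
small d — which is exactly why the randomness test must be E2, not E0.

## Compression-factor particle swarm

The velocity update is v ← μ(G)·(w·v + c₁r₁(p_b − p) + c₂r₂(p_g − p)) with
μ(G) = δ·σ^{G/(N+G−1)}. With the recommended δ = 24, σ = 0.01, N = 300 the
raw schedule runs from ≈23.6 down to ≈2.4 — useful as a decay *shape* but not
as a multiplier between 1 and 0. The default mode therefore normalizes by
μ(1), so the schedule starts at exactly 1 and decays to ≈0.10 at G = 300,
fast early (escaping local optima) and smoothly late (fine search); the raw
("printed") schedule, the classic Clerc constriction factor
φ = 2/|2 − ρ − √(ρ² − 4ρ)| (ρ = c₁ + c₂ > 4) and plain PSO are selectable.
Defaults w = 0.729, c₁ = c₂ = 1.49 are standard constriction-equivalent
values. Positions initialize uniformly in the search box, velocities at
zero; positions leaving the box are clipped with the violated velocity
component zeroed. Non-finite fitness values become +∞ with a warning. A
`plot_factor_regimes` utility draws μ(G) for representative (δ, σ) pairs in
both admissible regimes (δ∈(0,1) with σ>1, and δ>1 with σ∈(0,1)).

## Joint identification of S and θ

Each particle encodes all S local models: [θ₁, Z₁, …, θ_S, Z_S], with θᵢ and
the cluster center Zᵢ both of dimension n + 1. Fitness is
J₁ = Σₖ (y(k) − [X(k)ᵀ, 1]θ_{label(k)})², labels by nearest center in
z-space (Euclidean, ties to the lowest index). Design choices where the
procedure is underdetermined:

* **Threshold Y_ts.** When unset, Y_ts defaults to 1% of the total output
  variance — a pragmatic "fits to within 1%" rule. For fixtures with a known
  noise floor the caller should set Y_ts near that floor (the synthetic
  fixtures export a per-pair threshold at 2.5–3× the noise variance);
  one-step prediction of smooth trajectories is easy, so a variance-relative
  default can be satisfied by a single global model.
* **Center initialization** by greedy farthest-point sampling of data
  z-vectors (random first pick per particle): keeps initial centers inside
  the data cloud with good coverage.
* **Empty clusters** are penalized (J₁ × (1 + 10·#empty)) and repaired
  before the next evaluation by teleporting each empty center onto the
  currently worst-fit point.
* **θ bounds** [−10, 10] per coordinate (data are normalized); center bounds
  are the z bounding box padded by 5%.
* **Refine mode** (`refine=True`, off by default): a memetic polish that
  replaces each particle's θ block with the per-cluster ordinary
  least-squares solution for its current labels, both inside the iteration
  (reducing the effective search to the centers) and on the final result.
  For fixed labels the polish can only lower J₁, so the incremental-S
  threshold test remains conservative. Without it, the swarm must co-adapt
  θ and centers in up to 2S(n+1) dimensions — feasible but far less
  reliable per seed; the polished mode is what the end-to-end benchmarks
  use, and `refine_local_parameters` doubles as the recovery oracle in
  tests. Restarts (`n_restarts`) re-run the swarm with a derived substream
  and keep the best result; the threshold short-circuits them.

The outer loop runs S = 1, 2, …, S_max and stops at the smallest S with
J₁ ≤ Y_ts — the lexicographic reading of the two-objective problem
(min S subject to fit). If the cap is reached the best S is returned with a
`s_cap_reached` flag rather than an exception.

## Dividing surfaces

Adjacency between clusters uses the nearest-other-center rule (ties at equal
distance are all adjacent), which is why a 3-region model can have two
surfaces rather than three. Each adjacent pair trains a two-class LS-SVM on
its regression vectors (lower-indexed region = +1) by solving the
(N+1)×(N+1) KKT system [[0, yᵀ], [y, Ω + I/γ]]·[b; α] = [0; 1] directly;
γ defaults to 10, the condition number is checked, and the solution is
verified against the assembled system (relative residual < 1e−8) and the
constraint Σαₖyₖ = 0. Hyperplane parameters exist only for the linear
kernel (w = Σαₖyₖxₖ); the offset is averaged over all training points,
v = mean(yₖ − wᵀxₖ), the numerically stable form of reading it off one
support vector. An RBF kernel (width 0.2 by default) remains available for
the sign classifier but cannot emit a hyperplane, and the extraction
function refuses it explicitly.

Region assignment checks each region's sign constraints in index order and
returns the first fully satisfied one; a value of exactly 0 satisfies both
sides (closed polyhedra), so boundary points land in the lower-indexed
region. Pairwise-trained surfaces can produce inconsistent sign patterns;
such points fall back to the nearest center in X-space, and the count is
logged. The map is total and deterministic.

## Prediction and metrics

Prediction is series-parallel (one-step-ahead) from measured lags; free-run
simulation is deliberately not part of the evaluation contract. MAPE is
reported as a fraction of mean |(y − ŷ)/y| with samples below an |y| floor
(1e−8) excluded and counted; RMSE uses all samples. Metrics are computed on
the normalized scale and, when the model carries its scaling transform, on
the physical scale too — on the normalized scale the [−1, 1] map sends
mid-range values near zero and inflates relative errors, so for strictly
positive quantities like concentrations the physical-scale MAPE is the
meaningful figure. An RMSE-vs-cumulative-test-size table (20-sample steps)
accompanies every evaluation.

## Synthetic data

`gen_pwarx_dataset` simulates exact switched-affine systems (regions by
thresholds on a regressor coordinate or by nearest X-space center), with a
divergence guard naming the offending θ. The two standard fixtures:

* **Two-regime benchmark** (r = 1, d_θ = 3): the regime follows the sign of
  u(k−1), where the input holds a level near ±0.8 with small jitter and
  flips with probability 0.06 per step. This guarantees balanced regime
  occupancy for every seed and two well-separated z-clouds — the benchmark
  is meant to test recovery under favorable geometry, not robustness to
  overlap. Y_ts is exported at 3× the per-pair noise floor (floor 0.01²
  when noiseless).
* **Three-phase fixture** (r = 6, d_θ = 8): a growth-like trajectory through
  lag / exponential / stationary phases split by thresholds on y(k−1) at
  0.30 and 0.65, with per-phase dynamics (y-coefficients 0.97 / 1.04 / 0.70)
  and strongly contrasting input-coefficient patterns. The six input
  channels drift linearly over a batch (as real fermentation variables do);
  the coefficient patterns are projected orthogonal to the drift direction
  so the drift separates the phase clusters in z-space without perturbing
  the trajectory. Defaults: 10 batches × 96 samples, output noise sd 0.002,
  exported Y_ts at 2.5× the noise floor — calibrated so that the attainable
  J₁ of any one- or two-regime partition of this system lies above the
  threshold while the true three-regime structure lies below it.

`gen_fermentation_batches` is a mechanistic surrogate, not a physiological
model of *Pichia pastoris*: logistic biomass growth dX/dt = μ_max·g(T)·g(pH)·
g(DO)·X·(1 − X/X_max) with Gaussian-bell modulation around the setpoints
(28 °C, pH 7.3, DO 40%, flow 1100 L/h, 250 rpm, 0.04 MPa), Luedeking–Piret
product formation dP/dt = a·dX/dt + b·X (a = 0.3, b = 0.005 h⁻¹), Euler
integration on the 5-minute grid, AR(1) input perturbations (coefficient
0.9, stationary sd 2% of setpoint). Outputs are observed hourly, linearly
interpolated to the fast grid, thinned by stride 10 to 96 samples per batch
(the full 80 h at 5 min would give 960 per batch; the retained design keeps
960 *total* across 10 batches), split 576/204/180 by global sample index in
batch order, and min–max normalized. Defaults (μ_max = 0.12 h⁻¹,
X₀/X_max = 0.02) make the three phases each span a substantial share of the
80 h window. What the surrogate does *not* emulate: sensor faults and
outliers, methanol-induction phases, batch-to-batch kinetic variability
beyond inoculum jitter, measurement noise on the assays. Passing tests on
this surrogate therefore demonstrate pipeline correctness, not predictive
performance on a real fermentor.

## Problem sizes and determinism

The benchmarks run at desk scale by choice: swarm 30–40 particles × 60–100
iterations (schedule horizon N = 300 regardless, so the μ decay shape is
unchanged), 300–960-sample datasets, 10–20 seeds per statistical check.
Every stochastic component draws from a `numpy` generator seeded from the
user-facing seed (outer-loop substreams derive by fixed offsets), so models,
labels and reports are bit-reproducible; model JSON is written with sorted
keys and round-trips losslessly.

## Known limitations

* The incremental-S loop returns the smallest S meeting Y_ts; a poorly
  chosen threshold yields S = 1 on smooth data (too loose) or S_max (too
  tight). The per-S best-J₁ trace is exported so users can inspect the
  elbow.
* Nearest-center clustering in z-space cannot represent regime boundaries
  that are not Voronoi-like in z; strongly overlapping regimes degrade label
  accuracy near boundaries and hence polished-θ accuracy.
* Pairwise LS-SVM surfaces do not guarantee a consistent global partition;
  the nearest-center fallback keeps the region map total but can disagree
  with the training labels in thin wedges.
* Order selection assumes a reasonably persistent, smooth input; white-noise
  inputs weaken the FNN signal at the true dimension (the ARX ranking then
  carries the decision).
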