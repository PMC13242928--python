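# Methods

## Model and estimation

`cellgrn` treats each cell's expression vector as one observation from a
Gaussian copula graphical model (GCGM): X = f(Z) entrywise for unknown
monotone f, Z ~ N(0, Θ⁻¹). The network of interest is the support of the
latent precision matrix Θ, and because the copula is invariant to monotone
marginal transforms, estimation reduces to (i) estimating the latent
correlation matrix rank-based and (ii) a penalized Gaussian likelihood
solve.

A single cell cannot identify its own Θ. The working assumption is that
networks change smoothly along the cell manifold (trajectory) or the
spatial landscape, so each cell's likelihood is a kernel-weighted sum over
its neighborhood:

    Θ̂ᵢ = argmin_{Θ≻0} (|Nᵢ|/2) Σ_{j∈Nᵢ} K_ij [−log det Θ + tr(Σ̂ⱼΘ)]
                        + λ‖Θ‖₁,off + β‖Mᵢ⊙Θ‖²_F

Internally the data term is normalized: with Wᵢ = Σⱼ K_ij and
S̄ᵢ = Σⱼ K_ij Σ̂ⱼ / Wᵢ, the solve minimizes −log det Θ + tr(S̄ᵢΘ) plus
penalties. For a fixed cell this has the same argmin as the raw weighted
sum with penalties rescaled by 2/(|Nᵢ|·Wᵢ); the normalized form is the
default because it gives λ and β the same meaning in every cell regardless
of neighborhood mass (`SolverConfig(scale_penalties=False)` restores the
raw scaling).

The ℓ1 penalty covers off-diagonal entries only — the standard
graphical-lasso convention. This keeps the precision diagonal unbiased and
makes the solver directly comparable to reference graphical-lasso
implementations; the diagonal is additionally protected from the mask term
by construction (prior diagonals are fixed to 1, so masks have zero
diagonal — penalizing the diagonal would fight positive definiteness).

### Kernel weights

1. Center genes; project cells to `n_pcs` principal components (default 20,
   capped at min(n, g) − 1). Spatial mode uses raw coordinates instead.
2. Pairwise Euclidean distances; symmetric ("union") k-NN graph, default
   k = 5. A union graph preserves connectivity better than mutual k-NN and
   keeps distances symmetric.
3. If the graph is disconnected, components are bridged by the single
   shortest inter-component Euclidean edge, repeatedly, with a log message
   — a minimal intervention consistent with the connected-manifold
   assumption the geodesic approximation rests on. Zero-length edges
   (coincident cells) are legitimate graph edges and are preserved.
4. Geodesic distances D by Dijkstra on the graph;
   K = exp(−D²/(2σ²)), unit diagonal.

Bandwidth σ controls how fast networks are allowed to change: small σ =
fast change, little borrowing. Default is the heuristic σ = median(D)/2,
which puts the median cell pair at weight e⁻² ≈ 0.14 — neighbors well
inside the median dominate. Neighborhood sizes default to
max(15, ⌈0.1·n⌉) for both the objective neighborhood Nᵢ and the covariance
neighborhood Nⱼ; the two are exposed independently (nothing forces them to
coincide). Neighbor selection sorts by geodesic distance with self forced
first and ties broken by ascending cell index, making runs deterministic.

### Nonparanormal covariance

For each cell j, over ordered pairs k ≠ k′ of cells in Nⱼ:

    τⱼ(m,n) = Σ w_kk′^{mn} sign((X_km−X_k′m)(X_kn−X_k′n)) / (|Nⱼ|(|Nⱼ|−1))
    w_kk′^{mn} = b_km b_k′m b_kn b_k′n K_kk′,   b_km = [X_km ≠ 0]

The zero indicators b drop any comparison involving a dropout zero; tied
nonzero values contribute sign 0 (no tie correction). The denominator is
the *unweighted* ordered-pair count, so weights and zeros shrink τ toward
0 in low-weight or zero-rich neighborhoods — a deliberate conservative
bias. `normalize_by_weight=True` switches to a Σw denominator for users
who prefer an unbiased-at-the-price-of-variance estimate; it is off by
default.

Σ̂ⱼ = sin(π/2·τⱼ) off-diagonal, 1 on the diagonal (Greiner's identity maps
Kendall's τ of a Gaussian copula to its latent Pearson correlation; the
calibration is verified in the tests at ρ = 0.6, 2000 samples, error
≤ 0.05). Σ̂ⱼ is then projected to the positive-definite cone by replacing
eigenvalues ≤ 0 with ε = 10⁻³; projection happens once per cell at
construction, before any weighted averaging. The projection is idempotent
and leaves already-PD inputs untouched.

### ADMM

Split Θ = Z; augmented Lagrangian penalty ρ (default 1.0, optional
residual-balancing adaptation by factor 2 within [10⁻³, 10³], off by
default — the fixed value converges on all test instances).

* Θ-update: eigendecompose ρ(Z − U) − S̄ = QΛQᵀ; the minimizer maps each
  eigenvalue through (λ_r + √(λ_r² + 4ρ))/(2ρ), which is strictly
  positive — every Θ-iterate is PD for any PD start.
* Z-update (exact prox of the combined penalty at V = Θ + U):
  soft-threshold(V, λ/ρ) off-diagonal, V on the diagonal; masked entries
  additionally shrink by ρ/(ρ + 2β).
* U ← U + Θ − Z.

Initialization Θ⁰ = Z⁰ = I, U⁰ = 0 (an `inverse_sigma` start is
available). Stopping: ‖Θ−Z‖_F ≤ tol·g and ρ‖Z−Z_prev‖_F ≤ tol·g with
tol = 10⁻⁵, max 1000 iterations; non-converged cells are flagged with a
warning, never an exception. The returned estimate is the symmetrized
(Θ+Z)/2, which is PD at convergence (the strictly-PD Θ iterate is used in
the rare non-PD corner); the soft-thresholded Z, whose zeros are exact, is
exposed on `SolveResult.z` for support queries. At the default tolerances
the two agree to ~10⁻⁵, so edge rankings are unaffected by the choice.

With β = 0 this is exactly the graphical lasso: the implementation is
checked against an independent least-angle-regression-based solver to
10⁻⁴ Frobenius, and against the closed-form inverse at λ = 0.

### Priors and masks

ATAC mode: region ↔ target-gene links use the strand-aware upstream window
[TSS − w, TSS] (+ strand; mirrored for − strand), w = 50 kb by default,
any-base overlap in half-open coordinates. "Upstream" is read
biologically, i.e. relative to strand; the window is not symmetric around
the TSS. Region ↔ TF links come from the motif-hit table. An (f, t) edge
is allowed in cell i iff some region accessible in cell i links both —
so all prior edges route through a TF motif and target–target edges are
never created in ATAC mode. TF mode forbids exactly the target–target
pairs and is shared across cells. BED intervals are 0-based half-open; TSS
tables are 1-based and converted internally.

### Partial correlations and dynamics

G(m,n) = −Θ(m,n)/√(Θ(m,m)Θ(n,n)); the diagonal is reported as 0 rather
than the literal −1 — a self-partial-correlation is not an edge. G is
invariant to diagonal rescaling of Θ and bounded by 1 in absolute value
for PD Θ (both property-tested).

Dynamics summaries use absolute edge weights ("regulation strength"), so a
sign flip counts as activity, and population variances (denominator n —
every cell is observed, nothing is sampled). The target-count threshold
defaults to the 90th percentile of |G| over the whole tensor when not
given. All rankings break ties lexicographically by gene name.

## Synthetic data generator

The generator produces the three artifacts a multi-omic simulator would:
ground-truth per-cell networks, expression, and per-cell prior graphs. It
emulates the statistical structure only — there is no kinetic model and no
region-count simulation.

* **Networks**: a random symmetric support at the requested density
  (default 0.1 of unordered pairs) anchors the sequence; at each of
  `n_rewire_events` (default 2) evenly spaced anchors, `rewire_fraction`
  (default 0.3) of the edges toggle on/off, and weights (uniform magnitude
  0.2–1, random sign) interpolate linearly between anchors. The 0.3
  fraction makes roughly two-thirds of the edge set turn over across the
  whole trajectory: substantial rewiring — the phenomenon cell-specific
  inference exists to detect — while consecutive cells still differ
  infinitesimally. Positive definiteness comes from strict diagonal
  dominance (diagonal = off-diagonal absolute row sum + 0.1), which
  preserves the designed support exactly, unlike nearest-PD projection.
* **Expression**: one latent Gaussian draw per cell from Θᵢ⁻¹,
  standardized, pushed through a monotone marginal quantile (log-normal by
  default, exponential available; an identity-Gaussian marginal exists for
  calibration tests only), then independent Bernoulli dropout (default
  rate 0.2) — exactly the excess-zero mechanism the τ estimator's zero
  indicators handle.
* **Priors**: the true support (plus unit diagonal) with each off-diagonal
  entry flipped symmetrically with probability `noise_level`; the
  benchmark uses 0.01 and 0.1, the two cross-modality noise rates of
  interest.

What the generator does **not** emulate: count noise and library-size
variation (expression is continuous), batch effects, region-level
accessibility (priors are corrupted at the gene-pair level, not through a
region model), or abrupt network switches. Passing benchmarks therefore
demonstrate correctness of the estimator under its own model class plus
dropout and prior noise — not robustness to every artifact of real
single-cell data.

## Benchmark

Default conditions: g = 20, n = 200, density 0.1, 2 rewire events, dropout
0.2, noise ∈ {0.01, 0.1}, three seeds. Inference uses n_pcs = 20, k = 5,
the σ heuristic, neighborhoods of 20, λ = 0.01, β = 10, max 500 ADMM
iterations. These problem sizes keep a full benchmark run to a few seconds
per seed while leaving enough cells per neighborhood (20) for stable rank
correlations. Reported references: the prevalence baseline (AUPRC of any
constant ranking = true edge density) and a population-level single fit
(uniform weights, all cells, no mask) applied unchanged to every cell.
Typical results: pipeline AUPRC ≈ 0.88 at noise 0.01, ≈ 0.72 at noise 0.1,
population fit ≈ 0.82, prevalence ≈ 0.14 — cell-specific inference beats
both references, and noisier priors hurt, as expected.

## Numerical choices and degenerate inputs

* Covariance PD floor ε = 10⁻³; ADMM tolerances 10⁻⁵·g; oracle-agreement
  tests at 10⁻⁴ Frobenius.
* τ requires |Nⱼ| ≥ 2 (pairs); n = 1 datasets are rejected with a
  parameter error.
* An all-zero gene in a neighborhood annihilates its τ rows/columns to 0;
  the Σ̂ diagonal pin and PD floor keep the solve well-posed.
* Coincident cells: distance-0 edges are kept in the k-NN graph; self is
  forced first in every neighborhood; ties break by cell index.
* Empty TF lists are rejected (the prior would forbid everything);
  unknown TF names and motif hits naming unknown TFs are dropped with
  logged warnings.
* Constant-score evaluation inputs are handled by tie-grouping in the PR
  curve (AUPRC = prevalence).

## Known limitations

Graphs are undirected; TF–TF edge direction is unidentifiable here. The
smooth-changing assumption breaks across abrupt transitions, and the
kernel cannot model discontinuities. Per-cell solves are embarrassingly
parallel but currently run sequentially without warm starts — correctness
first; batching is a future optimization. Hyperparameters (σ, λ, β,
neighborhood sizes) materially affect results; the defaults documented
here are sensible starting points, not universal choices.
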