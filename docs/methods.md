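# Methods

## Model

The network consists of `N` binary (McCulloch–Pitts) excitatory units with
non-negative recurrent weights (zero diagonal) and one aggregated linear
inhibitory unit.  Synchronous updates apply a strict threshold,
`s_i' = Θ(v_i − θ)` with `Θ(0) = 0`; boundary equalities therefore never
activate a unit or trigger plasticity, which keeps ties deterministic.
The neuronal threshold is parametrized as `θ = (N−1) ψ`.

**Inhibition.**  `I(x, s) = H0 + H1 (Σ x_i)/(f N X) + λ (Σ s_i − f N)`.
The slope λ equals the mean initial weight and is frozen during learning
(the mean weight stays within a few percent of its initial value in the
regimes we simulate; see Limitations for the near-capacity exception).  The
basal term

    H0 = (N−1)(f·w̄ − ψ) + H⁻¹(f) √((N−1) f) σ_w,   H(x) = erfc(x/√2)/2

centres the Gaussian bulk of the local fields so that a fraction `f` of
units exceeds θ; `H1 = f γ √(N−1)` is the inhibitory reaction to the
external drive.  At `f = 0.5` the quantile term vanishes and `H0` is
independent of the weight spread; at sparser coding `σ_w` drifts during
learning, so `H0` is re-derived from the current weight spread after each
full sweep of pattern presentations.  The quantile term uses the field
spread `σ_w √((N−1) f)`; the exact Bernoulli variance carries an extra
`(1−f)` factor, so the spontaneous activity at `f = 0.2` settles at
≈ 0.17–0.18 rather than 0.20 — within the 0.05 band the self-stabilization
tests enforce, and immaterial at `f = 0.5`.

**Patterns.**  Entries are independent Bernoulli(`f`); we accept the
binomial fluctuation of per-pattern activity rather than fixing exactly
`fN` active units.  Category-correlated sets draw `L` independent
prototypes and copy each prototype entry with probability `c` (resampling
Bernoulli(`f`) otherwise), which makes the pattern–prototype Pearson
correlation exactly `c` and within-category pattern correlations `c²` at
any coding level.  A master seed spawns one child stream per pattern, so
extending a set never changes earlier patterns.

**Initial weights.**  Normal(1, 1) rectified at zero, diagonal cleared.
Closed-form moments: mean `Φ(1)+φ(1) ≈ 1.0833`, standard deviation
`√(2Φ(1)+φ(1) − mean²) ≈ 0.8667`.  About `H(1) ≈ 15.9%` of synapses start
exactly silent.

## Learning protocol

Each presentation clamps the network with `x = X ξ` (`X = γ√N`), performs
one synchronous update (for `γ ≳ 6` at `f = 0.5` this pins the state to the
pattern), and applies the three-threshold update from the clamped fields.
Weights are clipped at zero elementwise after every update — the model
requires excitatory synapses, and clipping matches the sign-constrained
perceptron setting; silent synapses are therefore exact zeros.

**Threshold placement.**  The inhibition-corrected stimulus shifts the OFF
population by `−f γ √N` and the ON population by `+(1−f) γ √N`.  Requiring
that the in-presentation comparisons against `θ0`/`θ1` be equivalent to the
free-field robustness tests against `θ ∓ f ε √N` fixes

    θ0 = θ − (γ+ε) f √N,       θ1 = θ + ((1−f) γ + f ε) √N.

At `f = 0.5` these are symmetric about θ with half-gap `(γ+ε) f √N` — the
familiar dense-regime form.  At sparser coding the symmetric form would
park every ON-unit field above `θ1` and disable potentiation entirely (we
verified the resulting collapse numerically), so the potentiation threshold
must track the larger ON-population shift; this is the package's reading of
the protocol at `f ≠ 0.5` and is what makes the sparse-regime experiments
work.

**Stopping.**  Training stops when (i) every pattern satisfies the robust
fixed-point condition — free field above `θ + f ε √N` for ON units and
below `θ − f ε √N` for OFF units (`converged = True`), (ii) a full sweep
causes no weight change (`quiescent = True`), or (iii) `max_sweeps` is
reached.  Condition (i) is the margin the learning rule targets, but at
finite `N` it is generally unattainable in full: learned fields pile within
one learning kick (`η f N`) of the no-plasticity boundaries, while the
per-pattern activity fluctuation `Δ^μ = Σξ^μ − fN` shifts the free-field
criterion by `≈ γ Δ^μ/√N` relative to the clamped-field windows (plus a
`√N` vs `√(N−1)` rounding between `X` and `H1`).  Fields just outside the
windows receive no further plasticity, so a thin residue of margin
violations — of order one learning kick — persists.  The residue scales
like `γ √(f(1−f)) / (f ε √N)` relative to the margin and vanishes at large
`N`.  Success of storage is therefore always measured by retrieval, not by
the margin count.

**Defaults** (dense regime): `ψ = 0.35`, `γ = 6`, `η = 0.01` with at most
1000 sweeps; when `ε = 0` the granularity of the updates matters and the
defaults switch to `η = 0.001` with 10000 sweeps.  Sparse regime as above
with `γ = 12` at full scale; scaled-down sparse runs in the tests use
`γ = 8` so that the `γΔ/√N` finite-size noise stays below the `ε = 3`
margin at `N = 400`.

**Perceptron baseline (PLR).**  Identical protocol and random numbers; only
the Step-2 branch differs: the desired output is read from the pattern, and
weights change when the clamped field fails the margin test
(`ξ_i = 0` and `v_i > θ0` → depression; `ξ_i = 1` and `v_i < θ1` →
potentiation).  The error test includes the ε margin so both rules target
the same constraint set.  Under strong drive (`γ = 12`, `f = 0.5`) the two
rules produce bit-identical weight matrices; at `γ = 6` rare field
excursions across θ during presentations make the 3TLR mislabel the desired
output, and weight discrepancies appear as the load approaches the 3TLR
capacity.

**Hopfield baseline.**  `w_ij = (1/N) Σ_μ (2ξ_i−1)(2ξ_j−1)`, symmetric,
zero diagonal, paired with its own ±1 synchronous dynamics at threshold 0
(`sign(0) = +1` for determinism).  No inhibition module is involved.

## Measurement protocols

**Basin of attraction.**  A perturbed start resamples a uniformly chosen
fraction `b` of units as Bernoulli(`f`) — at `f = 0.5` this is a starting
distance `b/2`.  A pattern set is stored at basin size `b` if every pattern
is recovered to within 1% normalized Hamming distance, in at most 30 free
synchronous steps, in at least 90% of 50 trials.  The 90% criterion is
applied per pattern.  `basin_size` scans an ascending `b` grid (default
resolution 0.05) and reports the largest passing `b`; trials abort early
once a pattern can no longer reach the 90% rate.

**Capacity.**  `storage_success` composes training with the basin
criterion at a fixed `b`; success probabilities are Monte-Carlo estimates
over independent seeds (default 10) and capacities are the 0.5 crossings of
the success curve, linearly interpolated on the α grid.  Experiment cells
can be cached on disk keyed by a hash of their full configuration, making
sweeps resumable.  The Hopfield breakdown load is measured by starting the
±1 dynamics at each stored pattern and locating the load where the mean
final overlap crosses 0.95 (grid step 0.005); at `N = 500–800` this lands
at ≈ 0.138 ± 0.005.

**Connectivity statistics.**  Silent fraction counts exact zeros by default
(`tol` exposed); the symmetry degree is the Pearson correlation of
`(w_ij, w_ji)` over unordered pairs.

## Replica-symmetric theory

Each unit's storage problem is a perceptron with box-constrained rescaled
weights `W_j = w_j/w̄ − 1 ∈ [−1, ∞)`, margin `f K √N` (`K = ε/w̄`), and a
threshold offset `T √Q` with `T = H⁻¹(f) √f` inherited from the sparse-
regime inhibition.  With outputs σ = ±1 occurring with probabilities
`(f, 1−f)` and order parameters `Q` (self-overlap), `q` (mutual overlap),
`M` (scaled mean), the RS quenched entropy yields six saddle equations; at
the critical load `ΔQ = Q − q → 0` and the conjugates diverge as
`q̂ = C/ΔQ²`, `ΔQ̂ = A/ΔQ`, `M̂ = B√C/ΔQ`, leaving the closed system

    Q = (C − B√C)/A
    A = H(x),  x = B − A/√C
    0 = (√C/A)(G(x) − BA) − (1−A)
    C = α_c Q ⟨(1+τ_σ²) H(τ_σ) − τ_σ G(τ_σ)⟩_σ
    A = α_c ⟨H(τ_σ)⟩_σ
    0 = ⟨σ (G(τ_σ) − τ_σ H(τ_σ))⟩_σ

with `τ_σ = [σ(fM − T√Q) − fK] / √(f(1−f)Q)` and
`⟨φ⟩_σ = f φ(+1) + (1−f) φ(−1)`.  The placement of the `f` factors follows
our own derivation of the quenched average (margin `fK`, mean-shift `fM`,
variance `f(1−f)Q`); it is validated three ways: the `K = 0` bound, an
independent finite-`N` linear-programming feasibility oracle (at `f = 0.5`,
`K = 0.3`, `N = 200–400` the LP transition brackets the predicted
`α_c = 1.126`), and the agreement of the two solvers below.

**Numerics.**  The three W-side equations are a one-parameter family in
`x`: `A = H(x)`, `√C = A/(G(x) − xA)`, `B = x + G(x) − xA`,
`Q = √C(√C − B)/A`.  The solver therefore nests three scalar root-finders
(brentq): the output-balance equation for `M` (its left side is strictly
monotone, so the root is unique and bracketed adaptively), the `A`-equation
for `α`, and the `C`-equation for `x`; the outer bracket comes from a sign
scan over `x ∈ [−30, 8]`.  This needs no continuation or damping and
converges for any `(f, K)` we probed; all six residuals are checked to
`1e-8` and non-convergence raises an explicit error with the last residual.
At `K = 0` the system has a degenerate `Q → 0` branch — the constraints
become scale-free and the box never binds — on which the capacity equals
the unbounded-weight value (`α_c = 2` at `f = 0.5`, rising as coding moves
away from `f = 0.5`); this branch reduces to a single scalar equation and
is solved directly.

The general finite-`ΔQ` system (`entropy_saddle`) is solved with a hybrid
Newton method on `(Q, M, q̂, ΔQ̂, M̂, α)` at fixed `ΔQ`, seeded from the
critical solution's divergence ansatz; Gaussian integrals use a 240-node
probabilists' Gauss–Hermite rule, `ln H` via `log_ndtr`, and the Mills-type
ratio `𝒢 = G/H` via the scaled complementary error function `erfcx`, which
is accurate for arbitrarily large arguments in both directions.  The
solved load `α(ΔQ)` extrapolated quadratically from
`ΔQ ∈ {0.02, 0.01, 0.005}` to `ΔQ = 0` agrees with the critical solver to
better than `1e-3` — the two solvers share no code path beyond the special
functions, so this is the package's internal consistency oracle.
`theory_curve` maps `ε → K = ε/w̄` with `w̄ = 1.0833` (the rectified-
Gaussian initial mean) by default.  For comparison with unconstrained
weights, `gardner_unconstrained(κ)` evaluates the classical spherical
capacity `[(1+κ²)Φ(κ) + κφ(κ)]⁻¹`; matched at the constrained solution's
self-overlap (`κ = K/√Q` at `f = 0.5`), the constrained capacity always
lies below it.

## What the synthetic generator does and does not emulate

All inputs are generated internally: Bernoulli pattern sets, correlated
category sets, rectified-Gaussian initial weights.  The generator matches
the study conditions (coding levels 0.5 and 0.2, category count 5,
correlations up to 0.75, the parameter table above) but does not emulate
spatially or temporally structured memories, graded activity, dilution, or
neuronal noise; passing tests therefore speak to the storage-capacity
claims under the stated statistical ensemble, not to robustness under
biological variability beyond it.

## Scaled-down test sizes

The always-run suite uses `N = 200–500` (training), `N = 500–600`
(Hopfield transition), `N = 1001` only for cheap one-shot checks
(self-stabilization, clamping, initial-weight statistics).  The
rule-equivalence experiment runs at `N = 250`, `ε = 3` (where the
theoretical ceiling `α_c ≈ 0.22` keeps pattern counts small), and the
capacity-ratio experiment at `N = 300`, basin `b = 0.2`, with ε chosen
from {1.5, 2.0, 2.5}.  The full-scale `N = 1001` experiments (zero-basin
capacity ≈ 1.6 at `ε = 0`, the external-drive collapse near `γ ≈ 2.4`, the
sparse-regime fraction of theory, the ≥11× Hopfield ratio at zero basin)
are registered with their expected outcomes in
`threetlr.FULL_SCALE_PRESETS` and are meant for overnight runs through the
CLI; they are not executed in the test suite.

## Known limitations

* The strict robust-margin count almost never reaches zero at finite `N`
  (see Stopping above); `converged` is reported honestly and capacity is
  defined through retrieval.
* Near capacity at small `N` the mean weight can drift upward while `H0`
  (dense regime) stays fixed, producing a heavy-tailed weight distribution;
  the coarse shape checks account for this.
* Asynchronous updates, palimpsest forgetting, replica-symmetry-breaking
  corrections and finite-size extrapolations are out of scope.
* The sparse regime at desk scale is sensitive to the finite-size
  inhibitory-reaction noise `γΔ/√N`; conclusions at `f = 0.2` below
  `N ≈ 1000` should use margins `ε ≳ 3` or moderate drive.
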