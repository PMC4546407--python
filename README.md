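# threetlr

Attractor neural networks trained with a **three-threshold learning rule
(3TLR)**: an online, error-signal-free synaptic plasticity rule for recurrent
networks of binary excitatory neurons that stores random memory patterns
close to the maximal (Gardner) storage capacity.  The package bundles the
network simulator, the learning rules (3TLR, supervised perceptron baseline,
Hopfield/Hebb baseline), the measurement protocols (basin of attraction,
storage capacity, external-drive dependence, correlated patterns,
connectivity statistics), and the matching replica-symmetric capacity
theory.

## The model

A fully connected network of `N` binary neurons `s_i ∈ {0,1}` with
non-negative recurrent weights `w_ij ≥ 0` (`w_ii = 0`, Dale's principle) is
stabilized at activity level `f` by a global linear inhibitory feedback.
The local field of unit `i` is

    v_i = Σ_j w_ij s_j + x_i − I(x, s)
    I(x, s) = H0 + H1 (Σ_i x_i)/(f N X) + λ (Σ_i s_i − f N)

and units update synchronously, `s_i' = Θ(v_i − θ)`.  Memories
`ξ ∈ {0,1}^N` (coding level `f`) are presented as strong external fields
`x = X ξ`, `X = γ √N`, which clamps the state to the pattern.  Learning then
depends only on the local field relative to three thresholds
`θ0 < θ < θ1`:

    θ0 < v_i < θ   →  w_ij ← max(0, w_ij − η s_j)   (depression)
    θ  < v_i < θ1  →  w_ij ← w_ij + η s_j            (potentiation)
    otherwise      →  no change

With `θ0 = θ − (γ+ε) f √N` and `θ1` placed at the ON-population stimulus
shift, this reproduces the supervised perceptron rule with robustness margin
`ε` — without any explicit error signal.  The margin enlarges the basins of
attraction at the cost of capacity: the storage load is `α = p/N`, and the
critical load `α_c(f, ε)` is computed by the replica-symmetric saddle-point
theory of the corresponding sign-constrained perceptron problem
(`α_c = 2` at `f = 0.5`, `ε = 0`; the Hopfield/Hebb baseline manages
`α_c ≈ 0.138`).

## Worked example

```python
import numpy as np
import threetlr as t

N, alpha, eps = 300, 0.15, 1.2
patterns = t.generate_patterns(N, int(alpha * N), coding_level=0.5, seed=101)
W0 = t.initialize_weights(N, seed=102)
params = t.NetworkParams.standard(N, f=0.5, gamma=6.0,
                                  mean_w=W0.mean_w, std_w=W0.std_w)
config = t.LearningConfig.for_params(params, eps=eps)
result = t.train_3tlr(W0, patterns, params, config, seed=103)
print(f"trained in {result.sweeps_used} sweeps; plasticity quiescent: {result.quiescent}")

basin = t.basin_size(result.weights, patterns, result.params,
                     b_grid=np.arange(0, 0.45, 0.05), seed=104)
print(f"basin size b = {basin.basin_fraction:.2f} "
      f"(all {patterns.n_patterns} patterns retrieved >= 90%)")
print(f"silent synapses: {t.silent_fraction(result.weights):.3f}, "
      f"symmetry r = {t.symmetry_degree(result.weights):.3f}")

sol = t.critical_capacity(0.5, eps / t.INIT_WEIGHT_MEAN)
print(f"replica theory: alpha_c(f=0.5, eps={eps}) = {sol.alpha_c:.3f}")
```

prints

```
trained in 102 sweeps; plasticity quiescent: True
basin size b = 0.15 (all 45 patterns retrieved >= 90%)
silent synapses: 0.086, symmetry r = 0.408
replica theory: alpha_c(f=0.5, eps=1.2) = 0.523
```

Reading: 45 patterns (`α = 0.15`) were stored with robustness `ε = 1.2` in
102 presentation sweeps; every pattern is recovered in at least 90% of
trials after randomizing 15% of the units (basin size `b = 0.15`); 8.6% of
synapses ended exactly silent and reciprocal weights are substantially
correlated (`r ≈ 0.41`).  The theoretical ceiling at this robustness is
`α_c ≈ 0.52`, so the run sits comfortably below capacity.

A command-line front end mirrors the experiments
(`threetlr theory`, `capacity`, `basin`, `gamma-sweep`, `eps-opt`,
`compare-rules`, `hopfield-baseline`, `stats`); every output table embeds
the package version and a hash of the configuration, and reruns are
bit-identical.

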