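"""Training rules: the three-threshold learning rule (3TLR), the supervised
perceptron learning rule (PLR) baseline, and the Hopfield/Hebb baseline.

The 3TLR protocol presents each memory pattern as a strong external field
(x = X * xi, X = gamma * sqrt(N)).  Step 1: a single synchronous update,
which clamps the network state to the pattern when gamma is large.  Step 2:
each synapse w_ij onto a unit whose local field v_i falls inside one of two
plasticity windows is changed by -eta*s_j (depression, theta0 < v_i < theta)
or +eta*s_j (potentiation, theta < v_i < theta1); outside (theta0, theta1)
no plasticity occurs.  The auxiliary thresholds

    theta0 = theta - (gamma + eps) * f * sqrt(N)
    theta1 = theta + (gamma + eps) * f * sqrt(N)

are placed so that, during a presentation, the field of a unit relative to
theta0 (or theta1) equals its free field relative to theta -/+ f*eps*sqrt(N)
— the robust stability margin.  Under strong drive this makes the 3TLR
equivalent to a perceptron rule with margin eps, without an explicit error
signal.

Weights are clipped at zero after each update (excitatory synapses; Dale's
principle), and the diagonal stays zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import NetworkParams, WeightMatrix, derive_inhibition
from .patterns import PatternSet

__all__ = [
    "LearningConfig",
    "TrainingResult",
    "learning_thresholds",
    "three_threshold_update",
    "present_and_learn",
    "robust_violations",
    "train_3tlr",
    "train_plr",
    "train_hopfield",
    "hopfield_dynamics",
]


def learning_thresholds(params: NetworkParams, eps: float, gamma: float | None = None) -> tuple[float, float]:
    """Auxiliary learning thresholds (theta0, theta1).

    During a presentation the inhibition-corrected stimulus shifts the OFF
    population by -f*gamma*sqrt(N) and the ON population by
    +(1-f)*gamma*sqrt(N), so the thresholds that make the in-presentation
    field tests equivalent to the free-field margin tests are

        theta0 = theta - (gamma + eps) * f * sqrt(N)
        theta1 = theta + ((1-f) * gamma + f * eps) * sqrt(N)

    At f = 0.5 these are symmetric about theta with half-gap
    (gamma + eps) * f * sqrt(N); at sparser coding the potentiation
    threshold must track the larger ON-population shift or potentiation
    never occurs."""
    if eps < 0:
        raise ValueError("eps must be >= 0")
    g = params.gamma if gamma is None else gamma
    f = params.f
    rootN = np.sqrt(params.N)
    theta0 = params.theta - (g + eps) * f * rootN
    theta1 = params.theta + ((1.0 - f) * g + f * eps) * rootN
    return theta0, theta1


@dataclass(frozen=True)
class LearningConfig:
    """Learning-rule configuration.

    Defaults follow the dense-regime simulation table: eta = 0.01 with at
    most 1000 sweeps, switching to eta = 0.001 with 10000 sweeps when
    eps = 0 (the margin-free limit needs finer steps).
    """

    eta: float
    eps: float
    gamma: float
    theta0: float
    theta1: float
    max_sweeps: int = 1000
    recalibrate_H0: bool = True

    def __post_init__(self) -> None:
        if self.eta < 0:
            raise ValueError("eta must be >= 0")
        if self.eps < 0:
            raise ValueError("eps must be >= 0")
        if not self.theta0 <= self.theta1:
            raise ValueError("theta0 must not exceed theta1")

    @classmethod
    def for_params(
        cls,
        params: NetworkParams,
        eps: float,
        eta: float | None = None,
        max_sweeps: int | None = None,
        recalibrate_H0: bool = True,
    ) -> "LearningConfig":
        th0, th1 = learning_thresholds(params, eps)
        if eta is None:
            eta = 0.001 if eps == 0 else 0.01
        if max_sweeps is None:
            max_sweeps = 10000 if eps == 0 else 1000
        return cls(
            eta=eta,
            eps=eps,
            gamma=params.gamma,
            theta0=th0,
            theta1=th1,
            max_sweeps=max_sweeps,
            recalibrate_H0=recalibrate_H0,
        )


@dataclass
class TrainingResult:
    """Outcome of a training run.

    ``converged`` means every pattern satisfied the robust fixed-point
    margins (free field above theta + f*eps*sqrt(N) for active units, below
    theta - f*eps*sqrt(N) for inactive ones) at the start of some sweep.
    ``quiescent`` means a full sweep produced no weight change — the rule's
    own fixed point — which at finite N can be reached while a thin residue
    of margin violations remains (fields pile within one learning kick of
    the no-plasticity boundaries).
    """

    weights: WeightMatrix
    sweeps_used: int
    converged: bool
    errors_per_sweep: list[int] = field(default_factory=list)
    quiescent: bool = False
    params: NetworkParams | None = None
    config: LearningConfig | None = None
    seed: int | None = None


def three_threshold_update(
    W: np.ndarray,
    presyn_state: np.ndarray,
    fields: np.ndarray,
    config: LearningConfig,
    theta: float,
) -> np.ndarray:
    """Apply one 3TLR weight update in place and return W.

    Rows (postsynaptic units) with theta0 < v_i < theta are depressed by
    eta * s_j; rows with theta < v_i < theta1 are potentiated; all other
    rows are untouched.  Boundary equalities produce no change.  Weights are
    clipped at zero and the diagonal is restored.
    """
    dep = (fields > config.theta0) & (fields < theta)
    pot = (fields > theta) & (fields < config.theta1)
    return _apply_update(W, presyn_state, dep, pot, config.eta)


def _apply_update(W, presyn_state, dep, pot, eta):
    changed = False
    if dep.any():
        W[dep] -= eta * presyn_state
        changed = True
    if pot.any():
        W[pot] += eta * presyn_state
        changed = True
    if changed:
        np.maximum(W, 0.0, out=W)
        np.fill_diagonal(W, 0.0)
    return W


def _presentation_fields(Warr, s, xi, params):
    # fields with the external pattern applied, at the current state
    X = params.X
    ext_sum = X * xi.sum()
    inh = params.H0 + params.lam * (s.sum() - params.f * params.N)
    if X > 0:
        inh += params.H1 * ext_sum / (params.f * params.N * X)
    return Warr @ s + X * xi - inh


def present_and_learn(
    W: WeightMatrix | np.ndarray,
    pattern: np.ndarray,
    params: NetworkParams,
    config: LearningConfig,
    state: np.ndarray | None = None,
    rule: str = "3tlr",
) -> tuple[np.ndarray, np.ndarray]:
    """One pattern presentation: clamp (Step 1) then learn (Step 2).

    Returns ``(W, state)`` with the post-presentation network state; the
    weight array is modified in place when a bare ndarray is passed.
    """
    Warr = W.W if isinstance(W, WeightMatrix) else W
    xi = np.asarray(pattern, dtype=np.float64)
    s = xi.copy() if state is None else np.asarray(state, dtype=np.float64)
    # Step 1: one synchronous update under the external field
    v = _presentation_fields(Warr, s, xi, params)
    s = (v - params.theta > 0).astype(np.float64)
    # Step 2: plasticity from the fields at the (normally clamped) state
    v = _presentation_fields(Warr, s, xi, params)
    if rule == "3tlr":
        dep = (v > config.theta0) & (v < params.theta)
        pot = (v > params.theta) & (v < config.theta1)
    elif rule == "plr":
        # supervised variant: desired output read from the pattern itself,
        # error test against the same margins the 3TLR windows encode
        on = xi > 0.5
        dep = ~on & (v > config.theta0)
        pot = on & (v < config.theta1)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    _apply_update(Warr, s, dep, pot, config.eta)
    return Warr, s


def robust_violations(
    W: WeightMatrix | np.ndarray,
    patterns: PatternSet | np.ndarray,
    params: NetworkParams,
    eps: float,
) -> int:
    """Count (unit, pattern) pairs violating the robust fixed-point margins
    under zero external field."""
    Warr = W.W if isinstance(W, WeightMatrix) else np.asarray(W)
    pats = patterns.patterns if isinstance(patterns, PatternSet) else np.asarray(patterns)
    if pats.size == 0:
        return 0
    Xi = pats.T.astype(np.float64)  # N x p
    fN = params.f * params.N
    V = Warr @ Xi - (params.H0 + params.lam * (Xi.sum(axis=0) - fN))[None, :]
    margin = params.f * eps * np.sqrt(params.N)
    on = Xi > 0.5
    ok = np.where(on, V - params.theta > margin, V - params.theta < -margin)
    return int((~ok).sum())


def _train(W, patterns, params, config, seed, rule):
    Warr = (W.W if isinstance(W, WeightMatrix) else np.asarray(W, dtype=np.float64)).copy()
    pats = patterns.patterns if isinstance(patterns, PatternSet) else np.asarray(patterns)
    pats = pats.astype(np.float64)
    p = pats.shape[0]
    rng = np.random.default_rng(seed)
    s = (rng.random(params.N) < params.f).astype(np.float64)
    errors = []
    converged = quiescent = False
    sweeps = 0
    for sweep in range(config.max_sweeps):
        nerr = robust_violations(Warr, pats.astype(np.uint8), params, config.eps)
        errors.append(nerr)
        if nerr == 0:
            converged = True
            break
        W_before = Warr.copy()
        for mu in rng.permutation(p):
            Warr, s = present_and_learn(Warr, pats[mu], params, config, state=s, rule=rule)
        sweeps = sweep + 1
        if config.recalibrate_H0 and params.f != 0.5:
            # sigma_w drifts during learning at f != 0.5; re-derive the basal
            # inhibition after each full presentation of the pattern set
            wm = WeightMatrix(np.maximum(Warr, 0.0))
            H0, _ = derive_inhibition(
                params.N, params.f, params.theta, params.psi, params.gamma,
                params.lam, wm.std_w,
            )
            params = params.with_H0(H0)
        if np.array_equal(Warr, W_before):
            quiescent = True
            nerr = robust_violations(Warr, pats.astype(np.uint8), params, config.eps)
            errors.append(nerr)
            converged = nerr == 0
            break
    else:
        nerr = robust_violations(Warr, pats.astype(np.uint8), params, config.eps)
        errors.append(nerr)
        converged = nerr == 0
    if p == 0:
        converged = True
    return TrainingResult(
        weights=WeightMatrix(Warr),
        sweeps_used=sweeps,
        converged=converged,
        errors_per_sweep=errors,
        quiescent=quiescent,
        params=params,
        config=config,
        seed=seed,
    ), params


def train_3tlr(
    W: WeightMatrix | np.ndarray,
    patterns: PatternSet | np.ndarray,
    params: NetworkParams,
    config: LearningConfig,
    seed: int,
) -> TrainingResult:
    """Train with the three-threshold rule.

    Patterns are presented sequentially in a fresh random permutation each
    sweep.  Training stops when every pattern satisfies the robust margins,
    when a full sweep causes no weight change, or after ``max_sweeps``.
    When ``recalibrate_H0`` is set and f != 0.5, the basal inhibition is
    re-derived from the current weight spread after each sweep.
    """
    result, _ = _train(W, patterns, params, config, seed, "3tlr")
    return result


def train_plr(
    W: WeightMatrix | np.ndarray,
    patterns: PatternSet | np.ndarray,
    params: NetworkParams,
    config: LearningConfig,
    seed: int,
) -> TrainingResult:
    """Train with the supervised perceptron rule under the identical
    protocol (same presentations, same random numbers); only the Step-2
    branch differs.  At large gamma the two rules produce bit-identical
    weight matrices."""
    result, _ = _train(W, patterns, params, config, seed, "plr")
    return result


# ----------------------------------------------------------------------
# Hopfield baseline (Hebbian rule, +/-1 units, threshold 0, no inhibition)
# ----------------------------------------------------------------------

def train_hopfield(patterns: PatternSet | np.ndarray) -> np.ndarray:
    """Hebbian weight matrix w_ij = (1/N) sum_mu (2 xi_i - 1)(2 xi_j - 1),
    symmetric with zero diagonal.  Signed weights; paired with its own
    +/-1 dynamics (:func:`hopfield_dynamics`)."""
    pats = patterns.patterns if isinstance(patterns, PatternSet) else np.asarray(patterns)
    S = 2.0 * pats.astype(np.float64) - 1.0
    N = S.shape[1]
    W = (S.T @ S) / N
    np.fill_diagonal(W, 0.0)
    return W


def hopfield_dynamics(W: np.ndarray, S: np.ndarray, max_steps: int = 30) -> np.ndarray:
    """Synchronous +/-1 dynamics S' = sign(W S) (sign(0) = +1), batched over
    the columns of S."""
    S = S.astype(np.float64, copy=True)
    single = S.ndim == 1
    if single:
        S = S[:, None]
    for _ in range(max_steps):
        S_new = np.where(W @ S >= 0, 1.0, -1.0)
        if np.array_equal(S_new, S):
            break
        S = S_new
    return S[:, 0] if single else S
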