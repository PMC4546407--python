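"""Recurrent network of binary excitatory neurons with global inhibitory
feedback.

The network has ``N`` McCulloch-Pitts units s_i in {0,1}, fully connected by
non-negative weights w_ij (w_ii = 0, Dale's principle), plus a single
aggregated inhibitory unit modelled as a linear function of the overall
excitatory activity.  The local field of unit i is

    v_i = sum_j w_ij s_j + x_i - I(x, s)
    I(x, s) = H0 + H1 * (sum_i x_i) / (f N X) + lam * (sum_i s_i - f N)

where x_i in {0, X} is a strong binary external field (X = gamma sqrt(N)),
H0 is the basal inhibition, H1 the inhibitory reaction to external input and
lam the inhibitory feedback slope.  Updates are synchronous and strict:
s_i' = 1 iff v_i - theta > 0.

H0 and H1 are derived so that, with random initial weights, the free network
self-stabilizes at activity level f: H0 centres the Gaussian bulk of the
local fields such that a fraction f exceeds the neuronal threshold theta.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import special

__all__ = [
    "NetworkParams",
    "WeightMatrix",
    "FieldVector",
    "initialize_weights",
    "derive_inhibition",
    "local_fields",
    "step",
    "run_dynamics",
    "INIT_WEIGHT_MEAN",
    "INIT_WEIGHT_STD",
]

# closed-form moments of max(0, Normal(1,1)): mean = Phi(1)+phi(1),
# E[X^2] = 2*Phi(1)+phi(1)
_PHI1 = float(special.ndtr(1.0))
_phi1 = float(np.exp(-0.5) / np.sqrt(2 * np.pi))
INIT_WEIGHT_MEAN = _PHI1 + _phi1                      # ~ 1.0833 (Table-value ~1.08)
INIT_WEIGHT_STD = float(np.sqrt(2 * _PHI1 + _phi1 - INIT_WEIGHT_MEAN**2))  # ~ 0.8667


def gauss_tail(x):
    """H(x) = P(Z > x) = erfc(x / sqrt(2)) / 2 for a standard normal Z."""
    return 0.5 * special.erfc(np.asarray(x, dtype=float) / np.sqrt(2.0))


def gauss_tail_inv(p):
    """Inverse of :func:`gauss_tail`; H^-1(0.5) = 0."""
    return -special.ndtri(p)


@dataclass(frozen=True)
class NetworkParams:
    """Scalar network parameters.

    ``theta = (N-1) * psi`` is enforced; ``X = gamma * sqrt(N)`` is the
    strength of the binary external fields.
    """

    N: int
    f: float
    theta: float
    psi: float
    lam: float
    gamma: float
    H0: float
    H1: float

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if not 0.0 < self.f < 1.0:
            raise ValueError(f"f must lie in (0,1), got {self.f}")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if abs(self.theta - (self.N - 1) * self.psi) > 1e-9 * max(1.0, abs(self.theta)):
            raise ValueError("theta must equal (N-1)*psi")

    @property
    def X(self) -> float:
        return self.gamma * np.sqrt(self.N)

    @classmethod
    def standard(
        cls,
        N: int,
        f: float = 0.5,
        psi: float = 0.35,
        gamma: float = 6.0,
        mean_w: float = INIT_WEIGHT_MEAN,
        std_w: float = INIT_WEIGHT_STD,
    ) -> "NetworkParams":
        """Dense-regime parameters with inhibition derived from the given
        weight statistics (lam is set to the mean weight)."""
        theta = (N - 1) * psi
        H0, H1 = derive_inhibition(N, f, theta, psi, gamma, mean_w, std_w)
        return cls(N=N, f=f, theta=theta, psi=psi, lam=mean_w, gamma=gamma, H0=H0, H1=H1)

    def with_H0(self, H0: float) -> "NetworkParams":
        return replace(self, H0=H0)


@dataclass
class WeightMatrix:
    """Non-negative recurrent weight matrix with zero diagonal."""

    W: np.ndarray
    seed: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=np.float64)
        N = self.W.shape[0]
        if self.W.ndim != 2 or self.W.shape[1] != N:
            raise ValueError("W must be square")
        if (self.W < 0).any():
            raise ValueError("weights must be non-negative")
        if np.diagonal(self.W).any():
            raise ValueError("diagonal must be zero")

    @property
    def N(self) -> int:
        return self.W.shape[0]

    def _offdiag(self) -> np.ndarray:
        return self.W[~np.eye(self.N, dtype=bool)]

    @property
    def mean_w(self) -> float:
        return float(self._offdiag().mean())

    @property
    def std_w(self) -> float:
        return float(self._offdiag().std())

    def save(self, path: str | Path, params: NetworkParams | None = None) -> None:
        meta = {}
        if params is not None:
            meta = {
                f"param_{k}": np.float64(getattr(params, k))
                for k in ("N", "f", "theta", "psi", "lam", "gamma", "H0", "H1")
            }
        np.savez_compressed(path, W=self.W, seed=np.int64(-1 if self.seed is None else self.seed), **meta)

    @classmethod
    def load(cls, path: str | Path) -> "WeightMatrix":
        with np.load(path) as z:
            seed = int(z["seed"])
            return cls(z["W"], seed=None if seed < 0 else seed)


@dataclass
class FieldVector:
    """Local fields v_i and the external input that produced them."""

    v: np.ndarray
    external: np.ndarray


def initialize_weights(N: int, seed: int) -> WeightMatrix:
    """Random initial weights: Normal(1,1) rectified at zero, zero diagonal.

    The rectification gives off-diagonal mean ~1.083 and std ~0.867.
    """
    rng = np.random.default_rng(seed)
    W = rng.normal(1.0, 1.0, (N, N))
    np.maximum(W, 0.0, out=W)
    np.fill_diagonal(W, 0.0)
    return WeightMatrix(W, seed=seed)


def derive_inhibition(
    N: int,
    f: float,
    theta: float,
    psi: float,
    gamma: float,
    mean_w: float,
    std_w: float,
) -> tuple[float, float]:
    """Basal inhibition H0 and inhibitory reaction H1 for a self-stabilizing
    network at activity level f.

        H0 = (N-1)(f w_bar - psi) + H^-1(f) sqrt((N-1) f) sigma_w
        H1 = f gamma sqrt(N-1)

    At f = 0.5 the quantile term vanishes (H^-1(0.5) = 0), so H0 does not
    depend on the weight spread; at sparser f it does, and must be re-derived
    as sigma_w changes during learning.
    """
    if not 0.0 < f < 1.0:
        raise ValueError(f"f must lie in (0,1), got {f}")
    if std_w < 0:
        raise ValueError("std_w must be >= 0")
    H0 = (N - 1) * (f * mean_w - psi) + float(gauss_tail_inv(f)) * np.sqrt((N - 1) * f) * std_w
    H1 = f * gamma * np.sqrt(N - 1)
    return float(H0), float(H1)


def _inhibition(params: NetworkParams, state: np.ndarray, external: np.ndarray | None) -> float:
    I = params.H0 + params.lam * (state.sum() - params.f * params.N)
    if external is not None and params.X > 0:
        I += params.H1 * external.sum() / (params.f * params.N * params.X)
    return I


def local_fields(
    W: WeightMatrix | np.ndarray,
    state: np.ndarray,
    external: np.ndarray | None,
    params: NetworkParams,
) -> FieldVector:
    """Total input v_i = sum_j w_ij s_j + x_i - I(x, s) for every unit."""
    Warr = W.W if isinstance(W, WeightMatrix) else np.asarray(W)
    state = np.asarray(state, dtype=np.float64)
    if Warr.shape[0] != state.shape[0]:
        raise ValueError("state length must match weight matrix size")
    if external is not None:
        external = np.asarray(external, dtype=np.float64)
        if external.shape != state.shape:
            raise ValueError("external length must match state length")
        if not np.isin(external, (0.0, params.X)).all():
            raise ValueError("external entries must be 0 or X")
    v = Warr @ state - _inhibition(params, state, external)
    if external is not None:
        v = v + external
    ext = np.zeros_like(state) if external is None else external
    return FieldVector(v=v, external=ext)


def step(
    W: WeightMatrix | np.ndarray,
    state: np.ndarray,
    external: np.ndarray | None,
    params: NetworkParams,
) -> np.ndarray:
    """One synchronous update: s_i' = Theta(v_i - theta), with Theta(0) = 0."""
    v = local_fields(W, state, external, params).v
    return (v - params.theta > 0).astype(np.float64)


def run_dynamics(
    W: WeightMatrix | np.ndarray,
    initial_state: np.ndarray,
    params: NetworkParams,
    max_steps: int = 30,
) -> tuple[np.ndarray, int, bool]:
    """Iterate free (zero-external-field) synchronous dynamics to a fixed
    point.

    Returns ``(final_state, n_steps, converged)``.  A state that repeats its
    immediate predecessor is a fixed point; a 2-cycle is reported as not
    converged.
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    Warr = W.W if isinstance(W, WeightMatrix) else np.asarray(W)
    s = np.asarray(initial_state, dtype=np.float64)
    for t in range(max_steps):
        s_new = step(Warr, s, None, params)
        if np.array_equal(s_new, s):
            return s_new, t + 1, True
        s = s_new
    return s, max_steps, False


def run_dynamics_batch(
    Warr: np.ndarray,
    S: np.ndarray,
    params: NetworkParams,
    max_steps: int = 30,
) -> np.ndarray:
    """Free dynamics on a batch of states (columns of the N x m array S).

    Used by the retrieval measurements; each column evolves independently
    under the shared weight matrix.  Columns that reach a fixed point stop
    changing on their own, so a single dense iteration is exact.
    """
    S = S.astype(np.float64, copy=True)
    fN = params.f * params.N
    for _ in range(max_steps):
        V = Warr @ S - (params.H0 + params.lam * (S.sum(axis=0) - fN))[None, :]
        S_new = (V - params.theta > 0).astype(np.float64)
        if np.array_equal(S_new, S):
            break
        S = S_new
    return S
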