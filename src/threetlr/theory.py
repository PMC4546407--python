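"""Replica-symmetric storage-capacity theory for the sign-constrained
recurrent perceptron problem solved by the 3TLR network.

Each unit must satisfy, for every stored pattern, the margin condition

    sigma^mu ( sum_j W_j xi_j^mu - T sqrt(Q) sqrt(N) ) > f K sqrt(N)

over rescaled weights W_j = w_j / w_bar - 1 in [-1, inf), where
sigma^mu = 2 xi^mu - 1 is the desired output, K = eps / w_bar the rescaled
robustness, T = H^-1(f) sqrt(f) the sparse-regime threshold offset, and
Q = (1/N) sum_j W_j^2 the self-overlap.  The quenched entropy of the
solution volume is evaluated with the replica-symmetric ansatz; at the
critical load the solution space shrinks to a point (mutual overlap q -> Q).

Two independent solvers are provided:

* :func:`critical_capacity` solves the six-equation critical system
  directly (order parameters alpha_c, Q, A, B, C, M).  The W-side equations
  reduce to a one-parameter family — with x = B - A/sqrt(C):

      A = H(x),  sqrt(C) = A / (G(x) - x A),  B = x + G(x) - x A,
      Q = sqrt(C) (sqrt(C) - B) / A

  — so the full system collapses to nested scalar root-finding (inner:
  the output-balance equation for M; outer: the C-equation for x), which is
  globally robust and needs no continuation.  At K = 0 the system has a
  degenerate Q -> 0 branch on which the capacity equals that of unbounded
  weights (alpha_c = 2 at f = 0.5): the constraints become scale-free, so
  the optimal volume hugs W = 0 where the box plays no role.

* :func:`entropy_saddle` solves the general finite-DeltaQ saddle system
  (DeltaQ = Q - q) and serves as an internal consistency oracle: the load
  alpha(DeltaQ) solved at fixed small DeltaQ extrapolates, as DeltaQ -> 0,
  to the critical solver's alpha_c.

All Gaussian integrals use probabilists' Gauss-Hermite quadrature; the
Mills-ratio-type function calG(x) = G(x)/H(x) is evaluated through the
scaled complementary error function, stable for any argument.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special

from .network import INIT_WEIGHT_MEAN

__all__ = [
    "gaussian_funcs",
    "SaddleSolution",
    "EntropySolution",
    "ConvergenceError",
    "critical_capacity",
    "entropy_saddle",
    "entropy_saddle_fixed_dq",
    "theory_curve",
    "gardner_unconstrained",
]

_SQRT2 = np.sqrt(2.0)
_SQRT2PI = np.sqrt(2.0 * np.pi)

# probabilists' Gauss-Hermite rule (weight e^{-u^2/2}/sqrt(2 pi))
_GH_NODES, _GH_W = np.polynomial.hermite_e.hermegauss(240)
_GH_W = _GH_W / _SQRT2PI


class ConvergenceError(RuntimeError):
    """A saddle-point solve failed; carries the last residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(f"{message} (residual {residual:.3e})")
        self.residual = residual


def _G(x):
    return np.exp(-0.5 * np.square(x)) / _SQRT2PI


def _H(x):
    return 0.5 * special.erfc(np.asarray(x, dtype=float) / _SQRT2)


def _calG(x):
    # G/H = sqrt(2/pi) / erfcx(x/sqrt(2)); erfcx is stable for all x
    return np.sqrt(2.0 / np.pi) / special.erfcx(np.asarray(x, dtype=float) / _SQRT2)


def _Hinv(p):
    return -special.ndtri(p)


def _lnH(x):
    return special.log_ndtr(-np.asarray(x, dtype=float))


def gaussian_funcs(x):
    """Gaussian density G, upper-tail H and their ratio calG = G/H.

    ``H(x) = erfc(x/sqrt(2))/2``; calG is computed via the scaled
    complementary error function and is accurate for arguments far beyond
    +/-40 (calG(x) ~ x for large positive x)."""
    x = np.asarray(x, dtype=float)
    return _G(x), _H(x), _calG(x)


@dataclass
class SaddleSolution:
    """Critical-capacity order parameters at a point (f, K)."""

    f: float
    K: float
    T: float
    alpha_c: float
    Q: float
    A: float
    B: float
    C: float
    M: float
    residual: float


@dataclass
class EntropySolution:
    """General (finite DeltaQ) saddle solution."""

    f: float
    K: float
    alpha: float
    Q: float
    q: float
    M: float
    q_hat: float
    dq_hat: float
    m_hat: float
    entropy: float
    residual: float

    @property
    def delta_q(self) -> float:
        return self.Q - self.q


def _avg(phi_plus, phi_minus, f):
    # average over the desired output sigma: +1 w.p. f, -1 w.p. 1-f
    return f * phi_plus + (1.0 - f) * phi_minus


def _tau(sigma, M, Q, f, K, T):
    return (sigma * (f * M - T * np.sqrt(Q)) - f * K) / np.sqrt(f * (1.0 - f) * Q)


def _wside(x):
    """W-side order parameters as functions of x = B - A/sqrt(C)."""
    A = float(_H(x))
    g = float(_G(x)) - x * A          # G(x) - x H(x) > 0 for all x
    sqrtC = A / g
    B = x + g
    Q = sqrtC * (sqrtC - B) / A
    return A, B, sqrtC, Q


def _solve_M(Q, f, K, T):
    """Output-balance equation <sigma (G(tau) - tau H(tau))> = 0 in M.

    The left side is strictly decreasing in M, so the root is unique."""

    def bal(M):
        tp = _tau(1.0, M, Q, f, K, T)
        tm = _tau(-1.0, M, Q, f, K, T)
        return f * (_G(tp) - tp * _H(tp)) - (1.0 - f) * (_G(tm) - tm * _H(tm))

    lo, hi = -1.0, 1.0
    while bal(lo) < 0 and lo > -1e9:
        lo *= 2.0
    while bal(hi) > 0 and hi < 1e9:
        hi *= 2.0
    return optimize.brentq(bal, lo, hi, xtol=1e-14, rtol=8.9e-16)


def _degenerate_branch(f: float) -> SaddleSolution:
    # K = 0: Q -> 0, A -> 1; one scalar unknown t = tau_+ remains and the
    # capacity coincides with the unbounded-weight value
    def bal(t):
        return (2.0 * f - 1.0) * _G(t) + t * _avg(_H(-t), _H(t), f)

    t = optimize.brentq(bal, -40.0, 40.0, xtol=1e-14, rtol=8.9e-16)
    denom = _avg(_H(-t), _H(t), f)
    alpha = 1.0 / denom
    T = float(_Hinv(f)) * np.sqrt(f)
    return SaddleSolution(
        f=f, K=0.0, T=T, alpha_c=float(alpha), Q=0.0, A=1.0, B=0.0, C=0.0,
        M=0.0, residual=abs(bal(t)),
    )


def critical_capacity(f: float, K: float) -> SaddleSolution:
    """Critical storage load alpha_c of the sign-constrained problem.

    Parameters
    ----------
    f
        Coding level in (0, 1).
    K
        Rescaled robustness eps / w_bar, >= 0.

    Raises
    ------
    ConvergenceError
        If the outer equation has no bracketed root or the assembled
        solution's residual exceeds 1e-8.
    """
    if not 0.0 < f < 1.0:
        raise ValueError(f"f must lie in (0,1), got {f}")
    if K < 0:
        raise ValueError("K must be >= 0")
    if K == 0.0:
        return _degenerate_branch(f)
    T = float(_Hinv(f)) * np.sqrt(f)

    def pattern_side(Q):
        M = _solve_M(Q, f, K, T)
        tp = _tau(1.0, M, Q, f, K, T)
        tm = _tau(-1.0, M, Q, f, K, T)
        avgH = _avg(_H(tp), _H(tm), f)
        return M, tp, tm, avgH

    def resid(x):
        A, B, sqrtC, Q = _wside(x)
        M, tp, tm, avgH = pattern_side(Q)
        alpha = A / avgH
        c4 = _avg(
            (1.0 + tp**2) * _H(tp) - tp * _G(tp),
            (1.0 + tm**2) * _H(tm) - tm * _G(tm),
            f,
        )
        return sqrtC**2 - alpha * Q * c4

    xs = np.linspace(-30.0, 8.0, 600)
    rs = np.array([resid(x) for x in xs])
    sign_flip = np.where(np.diff(np.sign(rs)) != 0)[0]
    if len(sign_flip) == 0:
        raise ConvergenceError(
            f"no root bracket for critical system at f={f}, K={K}",
            float(np.nanmin(np.abs(rs))),
        )
    i = sign_flip[0]
    x = optimize.brentq(resid, xs[i], xs[i + 1], xtol=1e-13, rtol=8.9e-16)
    A, B, sqrtC, Q = _wside(x)
    M, tp, tm, avgH = pattern_side(Q)
    alpha = A / avgH

    # residuals of all six equations of the critical system
    C = sqrtC**2
    eq = np.array([
        Q - (C - B * sqrtC) / A,
        A - _H(x),
        (sqrtC / A) * (_G(x) - B * A) - (1.0 - A),
        C - alpha * Q * _avg(
            (1.0 + tp**2) * _H(tp) - tp * _G(tp),
            (1.0 + tm**2) * _H(tm) - tm * _G(tm), f),
        A - alpha * avgH,
        _avg(_G(tp) - tp * _H(tp), -(_G(tm) - tm * _H(tm)), f),
    ])
    residual = float(np.max(np.abs(eq)))
    if residual > 1e-8:
        raise ConvergenceError(f"critical system residual too large at f={f}, K={K}", residual)
    return SaddleSolution(
        f=f, K=K, T=T, alpha_c=float(alpha), Q=float(Q), A=A, B=B,
        C=float(C), M=float(M), residual=residual,
    )


# ----------------------------------------------------------------------
# general saddle system at finite DeltaQ (validation oracle)
# ----------------------------------------------------------------------

def _general_residuals(z, f, K, dq):
    """Residuals of the six saddle equations at fixed DeltaQ;
    ``z = (Q, M, q_hat, dq_hat, m_hat, alpha)``."""
    Q, M, qh, dqh, mh, alpha = z
    T = float(_Hinv(f)) * np.sqrt(f)
    q = Q - dq
    if Q <= 0 or q <= 0 or qh <= 0 or dqh <= 0:
        return np.full(6, 1e6)
    u = _GH_NODES
    den = np.sqrt(f * (1.0 - f) * dq)
    shift = f * M - T * np.sqrt(Q)
    spread = np.sqrt(f * (1.0 - f) * q)
    tp = (f * K - shift + u * spread) / den
    tm = (f * K + shift + u * spread) / den
    gp, gm = _calG(tp), _calG(tm)
    e1 = dqh - (alpha / np.sqrt(q * dq)) * np.sum(_GH_W * u * _avg(gp, gm, f))
    e2 = qh - (alpha / dq) * np.sum(_GH_W * _avg(gp * tp, gm * tm, f)) - dqh
    e3 = np.sum(_GH_W * _avg(gp, -gm, f))
    beta = -(u * np.sqrt(qh) - mh + dqh) / np.sqrt(dqh)
    gb = _calG(beta)
    e4 = Q - ((qh + mh**2) / dqh**2 + 1.0 / dqh
              + dqh**-1.5 * np.sum(_GH_W * (u * np.sqrt(qh) - mh - dqh) * gb))
    e5 = dq - (1.0 / dqh + np.sum(_GH_W * u * gb) / np.sqrt(dqh * qh))
    e6 = -mh / dqh + np.sum(_GH_W * gb) / np.sqrt(dqh)
    return np.array([e1, e2, e3, e4, e5, e6])


def _entropy_value(Q, M, qh, dqh, mh, alpha, f, K, dq):
    T = float(_Hinv(f)) * np.sqrt(f)
    q = Q - dq
    u = _GH_NODES
    den = np.sqrt(f * (1.0 - f) * dq)
    shift = f * M - T * np.sqrt(Q)
    spread = np.sqrt(f * (1.0 - f) * q)
    tp = (f * K - shift + u * spread) / den
    tm = (f * K + shift + u * spread) / den
    za = np.sum(_GH_W * _avg(_lnH(tp), _lnH(tm), f))
    h = u * np.sqrt(qh) - mh
    zw = np.sum(_GH_W * (h**2 / (2 * dqh) + 0.5 * np.log(2 * np.pi / dqh)
                         + _lnH(-(h + dqh) / np.sqrt(dqh))))
    Qh = 0.5 * (qh - dqh)
    return float(-Q * Qh + 0.5 * q * qh + alpha * za + zw)


def _seed_from_critical(f, K, dq):
    c = critical_capacity(f, K)
    return np.array([
        max(c.Q, dq * 1.5), c.M, c.C / dq**2, c.A / dq,
        c.B * np.sqrt(c.C) / dq, c.alpha_c,
    ])


def entropy_saddle_fixed_dq(f: float, K: float, delta_q: float) -> EntropySolution:
    """Solve the general saddle system with DeltaQ = Q - q held fixed,
    treating the load alpha as an unknown.  As delta_q -> 0 the solved
    alpha converges to the critical capacity."""
    if K <= 0:
        raise ValueError("entropy solver requires K > 0 (the K=0 branch is degenerate)")
    z0 = _seed_from_critical(f, K, delta_q)
    sol = optimize.root(_general_residuals, z0, args=(f, K, delta_q), method="hybr", tol=1e-13)
    res = np.max(np.abs(_general_residuals(sol.x, f, K, delta_q)))
    if not sol.success or res > 1e-8:
        raise ConvergenceError(f"general saddle failed at f={f}, K={K}, dq={delta_q}", float(res))
    Q, M, qh, dqh, mh, alpha = sol.x
    S = _entropy_value(Q, M, qh, dqh, mh, alpha, f, K, delta_q)
    return EntropySolution(f, K, float(alpha), float(Q), float(Q - delta_q),
                           float(M), float(qh), float(dqh), float(mh), S, float(res))


def entropy_saddle(f: float, K: float, alpha: float) -> EntropySolution:
    """General saddle solution at a fixed load alpha below alpha_c.

    Solved by a 1-d search over DeltaQ (each trial DeltaQ fixes the load via
    :func:`entropy_saddle_fixed_dq`), exploiting that alpha(DeltaQ) is
    monotonically decreasing towards alpha_c as DeltaQ -> 0."""
    ac = critical_capacity(f, K).alpha_c
    if not 0 < alpha < ac:
        raise ValueError(f"alpha must lie in (0, alpha_c={ac:.4f})")

    def gap(dq):
        return entropy_saddle_fixed_dq(f, K, dq).alpha - alpha

    lo, hi = 1e-4, 0.5
    while gap(hi) > 0 and hi < 1e3:
        hi *= 2.0
    dq = optimize.brentq(gap, lo, hi, xtol=1e-12)
    return entropy_saddle_fixed_dq(f, K, dq)


def theory_curve(
    f: float,
    eps_grid,
    mean_w: float = INIT_WEIGHT_MEAN,
) -> pd.DataFrame:
    """Critical capacity along a grid of robustness values.

    Maps eps -> K = eps / mean_w and evaluates :func:`critical_capacity`,
    returning a tidy table with columns (f, eps, K, alpha_c, Q, A, B, C, M).
    """
    rows = []
    for eps in np.asarray(eps_grid, dtype=float):
        s = critical_capacity(f, eps / mean_w)
        rows.append({
            "f": f, "eps": eps, "K": s.K, "alpha_c": s.alpha_c,
            "Q": s.Q, "A": s.A, "B": s.B, "C": s.C, "M": s.M,
        })
    return pd.DataFrame(rows)


def gardner_unconstrained(kappa: float) -> float:
    """Capacity of the unconstrained (box-free) perceptron at margin kappa
    and unbiased outputs: alpha = [ (1+kappa^2) Phi(kappa) + kappa phi(kappa) ]^-1."""
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    val = (1.0 + kappa**2) * float(special.ndtr(kappa)) + kappa * float(_G(kappa))
    return 1.0 / val
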