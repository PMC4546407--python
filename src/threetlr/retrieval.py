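"""Basin-of-attraction measurements.

A pattern set counts as successfully stored at basin size ``b`` if, for
every pattern, the network recovers the pattern (within 1% normalized
Hamming distance, in at most 30 free steps) in at least 90% of trials that
start from a state in which a fraction ``b`` of the units was randomized.
"Randomized" means resampled as Bernoulli(f), so at f = 0.5 a basin size b
corresponds to a starting distance of b/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import NetworkParams, WeightMatrix
from .patterns import PatternSet

__all__ = ["RetrievalResult", "perturb_pattern", "retrieval_rate", "basin_size"]

SUCCESS_RATE = 0.9


@dataclass
class RetrievalResult:
    """Outcome of a basin measurement over a grid of perturbation sizes."""

    basin_fraction: float
    rates: np.ndarray          # per-pattern retrieval rates at basin_fraction
    n_trials: int
    success: bool
    table: pd.DataFrame | None = None   # tidy (pattern, b, rate) rows


def _as_arrays(W, patterns):
    Warr = W.W if isinstance(W, WeightMatrix) else np.asarray(W)
    pats = patterns.patterns if isinstance(patterns, PatternSet) else np.asarray(patterns)
    return Warr, np.atleast_2d(pats)


def perturb_pattern(
    pattern: np.ndarray,
    b: float,
    f: float,
    seed_or_rng: int | np.random.Generator,
) -> np.ndarray:
    """Resample a uniformly chosen fraction ``b`` of the units as
    Bernoulli(f); the rest keep the pattern's bits."""
    if not 0.0 <= b <= 1.0:
        raise ValueError(f"b must lie in [0,1], got {b}")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    s = np.asarray(pattern, dtype=np.float64).copy()
    N = len(s)
    k = int(round(b * N))
    if k:
        idx = rng.choice(N, size=k, replace=False)
        s[idx] = (rng.random(k) < f).astype(np.float64)
    return s


def _rates_at_b(Warr, pats, b, params, n_trials, max_steps, tol, rng, stop_below=None):
    """Per-pattern retrieval rates at one perturbation size.

    Trials for one pattern run as a batch; with ``stop_below`` set, patterns
    are abandoned early once the rate can no longer reach that threshold.
    """
    p, N = pats.shape
    rates = np.empty(p)
    max_fail = None if stop_below is None else int(np.floor(n_trials * (1 - stop_below)))
    for mu in range(p):
        xi = pats[mu].astype(np.float64)
        if b == 0.0:
            # deterministic start at the pattern itself: one trial decides
            S = xi[:, None].copy()
        else:
            S = np.column_stack(
                [perturb_pattern(xi, b, params.f, rng) for _ in range(n_trials)]
            )
        fN = params.f * params.N
        for _ in range(max_steps):
            V = Warr @ S - (params.H0 + params.lam * (S.sum(axis=0) - fN))[None, :]
            S_new = (V - params.theta > 0).astype(np.float64)
            if np.array_equal(S_new, S):
                break
            S = S_new
        dist = np.abs(S - xi[:, None]).mean(axis=0)
        rates[mu] = float((dist <= tol).mean())
        if max_fail is not None and (1.0 - rates[mu]) * S.shape[1] > max_fail:
            rates[mu + 1:] = np.nan
            break
    return rates


def retrieval_rate(
    W: WeightMatrix | np.ndarray,
    pattern: np.ndarray,
    b: float,
    params: NetworkParams,
    n_trials: int = 50,
    max_steps: int = 30,
    tol: float = 0.01,
    seed: int = 0,
) -> float:
    """Fraction of trials in which free dynamics started from a perturbed
    copy of ``pattern`` ends within normalized distance ``tol`` of it."""
    if not 0.0 < tol < 1.0:
        raise ValueError("tol must lie in (0,1)")
    Warr, pats = _as_arrays(W, pattern)
    rng = np.random.default_rng(seed)
    return float(_rates_at_b(Warr, pats, b, params, n_trials, max_steps, tol, rng)[0])


def basin_size(
    W: WeightMatrix | np.ndarray,
    patterns: PatternSet | np.ndarray,
    params: NetworkParams,
    b_grid=None,
    seed: int = 0,
    n_trials: int = 50,
    max_steps: int = 30,
    tol: float = 0.01,
) -> RetrievalResult:
    """Largest b on the grid at which every pattern retrieves at >= 90%.

    The grid is scanned in ascending order (default resolution 0.05) and the
    scan stops at the first failing b; the reported basin is the last
    successful one, or 0.0 with ``success=False`` if even b = 0 fails.
    """
    if b_grid is None:
        b_grid = np.arange(0.0, 1.0 + 1e-9, 0.05)
    b_grid = np.sort(np.asarray(b_grid, dtype=float))
    if b_grid.size == 0:
        raise ValueError("b_grid must not be empty")
    Warr, pats = _as_arrays(W, patterns)
    rng = np.random.default_rng(seed)
    rows = []
    best_b = None
    best_rates = None
    for b in b_grid:
        rates = _rates_at_b(
            Warr, pats, b, params, n_trials, max_steps, tol, rng,
            stop_below=SUCCESS_RATE,
        )
        for mu, r in enumerate(rates):
            if np.isfinite(r):
                rows.append({"pattern": mu, "b": b, "rate": r})
        ok = np.all(rates[np.isfinite(rates)] >= SUCCESS_RATE) and np.isfinite(rates).all()
        if not ok:
            break
        best_b, best_rates = float(b), rates
    table = pd.DataFrame(rows, columns=["pattern", "b", "rate"])
    if best_b is None:
        first = table[table["b"] == b_grid[0]]["rate"].to_numpy()
        return RetrievalResult(0.0, first, n_trials, False, table)
    return RetrievalResult(best_b, best_rates, n_trials, True, table)
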