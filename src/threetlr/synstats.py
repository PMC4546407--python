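"""Statistics of the trained connectivity matrix.

Near capacity the weight distribution develops a peak of exactly-zero
("silent" or potential) synapses plus a truncated-Gaussian-like bulk of
positive weights, and the matrix becomes increasingly symmetric as more
patterns are stored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import WeightMatrix

__all__ = ["ConnectivityStats", "silent_fraction", "symmetry_degree", "weight_histogram", "connectivity_stats"]


def _arr(W) -> np.ndarray:
    return W.W if isinstance(W, WeightMatrix) else np.asarray(W)


@dataclass
class ConnectivityStats:
    silent_fraction: float
    symmetry_r: float
    histogram: pd.DataFrame  # columns: bin_left, bin_right, density (nonzero weights)


def silent_fraction(W, tol: float = 0.0) -> float:
    """Fraction of off-diagonal weights <= tol (clipping produces exact
    zeros, so the default tol = 0 counts them exactly)."""
    Warr = _arr(W)
    off = Warr[~np.eye(Warr.shape[0], dtype=bool)]
    return float((off <= tol).mean())


def symmetry_degree(W) -> float:
    """Pearson correlation between reciprocal weights w_ij and w_ji over
    unordered off-diagonal pairs (i < j)."""
    Warr = _arr(W)
    N = Warr.shape[0]
    if N < 3:
        raise ValueError("symmetry degree needs N >= 3")
    iu = np.triu_indices(N, k=1)
    a, b = Warr[iu], Warr.T[iu]
    return float(np.corrcoef(a, b)[0, 1])


def weight_histogram(W, bin_width: float = 0.05) -> pd.DataFrame:
    """Density histogram of the strictly positive off-diagonal weights."""
    Warr = _arr(W)
    off = Warr[~np.eye(Warr.shape[0], dtype=bool)]
    pos = off[off > 0]
    if pos.size == 0:
        return pd.DataFrame(columns=["bin_left", "bin_right", "density"])
    edges = np.arange(0.0, pos.max() + bin_width, bin_width)
    dens, edges = np.histogram(pos, bins=edges, density=True)
    return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "density": dens})


def connectivity_stats(W, tol: float = 0.0, bin_width: float = 0.05) -> ConnectivityStats:
    return ConnectivityStats(
        silent_fraction=silent_fraction(W, tol),
        symmetry_r=symmetry_degree(W),
        histogram=weight_histogram(W, bin_width),
    )
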