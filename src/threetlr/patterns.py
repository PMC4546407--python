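"""Binary memory patterns at a given coding level, optionally organized in
correlated categories.

A pattern set is a ``p x N`` matrix of {0,1} entries.  Each entry of a random
pattern is drawn independently as Bernoulli(f), where ``f`` is the coding
level (the fraction of active units, matched to the network's spontaneous
activity level).  Category-correlated sets are built from ``L`` independent
random prototypes: each stored pattern copies each prototype entry with
probability ``c`` and otherwise resamples it as Bernoulli(f), which makes the
expected Pearson correlation between a pattern and its prototype exactly
``c`` at any coding level, and the expected correlation between two patterns
of the same category ``c**2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "PatternSet",
    "generate_patterns",
    "generate_categorized_patterns",
]


@dataclass
class PatternSet:
    """A set of binary memory patterns.

    Parameters
    ----------
    patterns
        ``(p, N)`` array with entries in {0, 1}.
    coding_level
        Target activation probability ``f`` of each entry.
    category_of
        Optional length-``p`` vector of category indices (``1..L``).
    prototypes
        Optional ``(L, N)`` binary matrix of category prototypes.
    correlation
        Optional pattern-prototype correlation ``c`` in [0, 1].
    seed
        Seed the set was generated from, if any (for provenance).
    """

    patterns: np.ndarray
    coding_level: float
    category_of: np.ndarray | None = None
    prototypes: np.ndarray | None = None
    correlation: float | None = None
    seed: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.patterns = np.asarray(self.patterns, dtype=np.uint8)
        if self.patterns.ndim != 2:
            raise ValueError("patterns must be a 2-d (p, N) array")
        if not np.isin(self.patterns, (0, 1)).all():
            raise ValueError("pattern entries must be 0 or 1")
        if not 0.0 < self.coding_level < 1.0:
            raise ValueError(f"coding_level must lie in (0,1), got {self.coding_level}")
        if self.category_of is not None:
            self.category_of = np.asarray(self.category_of, dtype=np.int64)
            if self.prototypes is None:
                raise ValueError("category_of requires prototypes")
            if len(self.category_of) != self.n_patterns:
                raise ValueError("category_of length must equal n_patterns")
            n_cat = len(np.unique(self.category_of))
            if self.prototypes.shape[0] != n_cat:
                raise ValueError("number of prototypes must equal number of categories")

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_units(self) -> int:
        return self.patterns.shape[1]

    # ------------------------------------------------------------------
    # serialization: plain text (one '0'/'1' string per line) and npz
    # ------------------------------------------------------------------
    def to_text(self, path: str | Path) -> None:
        """Write one pattern per line as a string of '0'/'1' characters."""
        with open(path, "w") as fh:
            for row in self.patterns:
                fh.write("".join("1" if x else "0" for x in row) + "\n")

    @classmethod
    def from_text(cls, path: str | Path, coding_level: float) -> "PatternSet":
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line:
                    rows.append([int(ch) for ch in line])
        return cls(np.array(rows, dtype=np.uint8), coding_level)

    def save(self, path: str | Path) -> None:
        """Save to a compressed ``.npz`` container (lossless round-trip)."""
        extra = {}
        if self.category_of is not None:
            extra["category_of"] = self.category_of
            extra["prototypes"] = self.prototypes
            extra["correlation"] = np.float64(self.correlation)
        np.savez_compressed(
            path,
            patterns=self.patterns,
            coding_level=np.float64(self.coding_level),
            seed=np.int64(-1 if self.seed is None else self.seed),
            **extra,
        )

    @classmethod
    def load(cls, path: str | Path) -> "PatternSet":
        with np.load(path) as z:
            seed = int(z["seed"])
            return cls(
                z["patterns"],
                float(z["coding_level"]),
                category_of=z["category_of"] if "category_of" in z else None,
                prototypes=z["prototypes"] if "prototypes" in z else None,
                correlation=float(z["correlation"]) if "correlation" in z else None,
                seed=None if seed < 0 else seed,
            )


def _pattern_streams(seed: int, n: int) -> list[np.random.Generator]:
    # one independent child stream per pattern: extending a set with more
    # patterns never changes the earlier ones
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_patterns(
    n_units: int,
    n_patterns: int,
    coding_level: float,
    seed: int,
) -> PatternSet:
    """Draw ``n_patterns`` random binary patterns, each entry Bernoulli(f).

    Reproducible: the same seed yields a bit-identical set, and the first
    ``p`` patterns of a larger set equal the patterns of a smaller one drawn
    from the same seed.
    """
    if n_units < 2:
        raise ValueError("n_units must be >= 2")
    if n_patterns < 0:
        raise ValueError("n_patterns must be >= 0")
    if not 0.0 < coding_level < 1.0:
        raise ValueError(f"coding_level must lie in (0,1), got {coding_level}")
    streams = _pattern_streams(seed, n_patterns)
    pats = np.empty((n_patterns, n_units), dtype=np.uint8)
    for mu, rng in enumerate(streams):
        pats[mu] = rng.random(n_units) < coding_level
    return PatternSet(pats, coding_level, seed=seed)


def generate_categorized_patterns(
    n_units: int,
    n_categories: int,
    patterns_per_category: int,
    coding_level: float,
    correlation: float,
    seed: int,
) -> PatternSet:
    """Generate category-structured patterns correlated with prototypes.

    ``n_categories`` prototypes are drawn independently at coding level f.
    Each of the ``patterns_per_category`` patterns of a category copies each
    prototype entry with probability ``correlation`` and resamples it as
    Bernoulli(f) otherwise, so the expected Pearson correlation with the
    prototype equals ``correlation`` and the coding level is preserved.
    """
    if not 0.0 <= correlation <= 1.0:
        raise ValueError(f"correlation must lie in [0,1], got {correlation}")
    if n_categories < 1:
        raise ValueError("n_categories must be >= 1")
    proto_seed, pat_seed = (int(s.generate_state(1)[0] >> 1) for s in np.random.SeedSequence(seed).spawn(2))
    protos = generate_patterns(n_units, n_categories, coding_level, proto_seed).patterns
    p = n_categories * patterns_per_category
    streams = _pattern_streams(pat_seed, p)
    pats = np.empty((p, n_units), dtype=np.uint8)
    cats = np.empty(p, dtype=np.int64)
    for mu, rng in enumerate(streams):
        ell = mu // patterns_per_category
        cats[mu] = ell + 1
        copy = rng.random(n_units) < correlation
        fresh = (rng.random(n_units) < coding_level).astype(np.uint8)
        pats[mu] = np.where(copy, protos[ell], fresh)
    return PatternSet(
        pats,
        coding_level,
        category_of=cats,
        prototypes=protos,
        correlation=correlation,
        seed=seed,
    )
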