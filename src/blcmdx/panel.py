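"""Data model and I/O for cross-classified multi-test count tables.

A panel of K binary diagnostic tests applied to the same subjects yields a
2^K contingency table of joint results. The canonical pattern order used
throughout this package is *binary descending with test 1 as the most
significant bit*: the all-positive pattern (1,1,...,1) comes first and the
all-negative pattern last. For K = 3 the order is

    111, 110, 101, 100, 011, 010, 001, 000

which matches the nesting of the usual published 2 x 2^(K-1) layout
(test 1 on the rows, the remaining tests nested on the columns).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TestPanel",
    "CrossClassifiedCounts",
    "CountTableError",
    "read_counts",
    "write_counts",
]


class CountTableError(ValueError):
    """Raised when a count-table file violates the format contract."""


LOWER = "lower_is_positive"
HIGHER = "higher_is_positive"


@dataclass(frozen=True)
class TestPanel:
    """An ordered collection of binary diagnostic tests.

    Parameters
    ----------
    test_names
        Unique identifiers, length K >= 2. The order fixes the pattern
        convention and the parameter order everywhere else.
    positive_direction
        Per test, ``"lower_is_positive"`` if a *low* continuous score codes
        a positive result (MoCA, MMSE convention) or
        ``"higher_is_positive"`` (ADAS-cog convention). Only used when
        continuous scores enter the picture; defaults to lower-is-positive.
    dependent_pairs
        Index pairs (0-based) of tests modeled as conditionally dependent
        within each latent class. Pairs are unordered, non-repeating and
        must be disjoint.
    """

    test_names: tuple[str, ...]
    positive_direction: tuple[str, ...] = ()
    dependent_pairs: tuple[tuple[int, int], ...] = ()

    __test__ = False  # "Test" prefix is domain vocabulary, not a test case

    def __post_init__(self) -> None:
        names = tuple(self.test_names)
        object.__setattr__(self, "test_names", names)
        if len(names) < 2:
            raise ValueError("a test panel needs at least two tests")
        if len(set(names)) != len(names):
            raise ValueError(f"test names must be unique, got {names}")
        direction = tuple(self.positive_direction) or (LOWER,) * len(names)
        if len(direction) != len(names):
            raise ValueError("positive_direction must have one entry per test")
        for d in direction:
            if d not in (LOWER, HIGHER):
                raise ValueError(f"unknown direction {d!r}")
        object.__setattr__(self, "positive_direction", direction)

        seen: set[int] = set()
        pairs = []
        for pair in self.dependent_pairs:
            i, j = sorted(pair)
            if i == j or not (0 <= i < len(names)) or not (0 <= j < len(names)):
                raise ValueError(f"invalid dependent pair {pair}")
            if i in seen or j in seen:
                raise ValueError(
                    f"dependent pairs must be disjoint; test index repeated in {pair}"
                )
            seen.update((i, j))
            pairs.append((i, j))
        object.__setattr__(self, "dependent_pairs", tuple(pairs))

    @property
    def k(self) -> int:
        return len(self.test_names)

    @property
    def n_patterns(self) -> int:
        return 2 ** self.k

    @property
    def independent_indices(self) -> tuple[int, ...]:
        paired = {i for p in self.dependent_pairs for i in p}
        return tuple(i for i in range(self.k) if i not in paired)

    def patterns(self) -> np.ndarray:
        """The (2^K, K) array of 0/1 result patterns in canonical order.

        Row 0 is the all-positive pattern; row ``2^K - 1`` is all-negative.
        Column 0 (test 1) is the most significant bit.
        """
        m = self.n_patterns
        codes = m - 1 - np.arange(m)
        bits = (codes[:, None] >> np.arange(self.k - 1, -1, -1)[None, :]) & 1
        return bits.astype(np.int8)

    def pattern_index(self, pattern: Sequence[int]) -> int:
        """Position of ``pattern`` in the canonical (descending) order."""
        if len(pattern) != self.k or any(t not in (0, 1) for t in pattern):
            raise ValueError(f"pattern must be a binary {self.k}-tuple, got {pattern}")
        code = sum(int(t) << (self.k - 1 - i) for i, t in enumerate(pattern))
        return self.n_patterns - 1 - code

    def pattern_label(self, row: int) -> str:
        return "".join(str(b) for b in self.patterns()[row])


@dataclass(frozen=True)
class CrossClassifiedCounts:
    """The observed 2^K cell counts of joint test results for a panel."""

    panel: TestPanel
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.shape != (self.panel.n_patterns,):
            raise ValueError(
                f"expected {self.panel.n_patterns} cell counts, got shape {arr.shape}"
            )
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("cell counts must be integers")
            arr = np.round(arr).astype(np.int64)
        if (arr < 0).any():
            raise ValueError("cell counts must be non-negative")
        object.__setattr__(self, "counts", arr.astype(np.int64))

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.panel.patterns(), columns=list(self.panel.test_names))
        df["count"] = self.counts
        return df

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CrossClassifiedCounts):
            return NotImplemented
        return self.panel == other.panel and bool(
            np.array_equal(self.counts, other.counts)
        )


def read_counts(
    path: str | Path, panel: TestPanel, layout: str = "long"
) -> CrossClassifiedCounts:
    """Read a count table from a text file.

    ``layout="long"`` expects one row per pattern: K binary columns named
    after the panel's tests plus a ``count`` column, in any row order.
    ``layout="wide"`` expects the published 2 x 2^(K-1) layout: two rows
    (test 1 = 1, then 0) and columns nested over the remaining tests in
    descending binary order.
    """
    path = Path(path)
    if layout == "wide":
        raw = pd.read_csv(path, header=None).to_numpy()
        if raw.shape != (2, panel.n_patterns // 2):
            raise CountTableError(
                f"wide layout for K={panel.k} needs shape (2, {panel.n_patterns // 2});"
                f" got {raw.shape}"
            )
        flat = np.concatenate([raw[0], raw[1]])
        return _counts_from_values(panel, flat)

    if layout != "long":
        raise ValueError(f"unknown layout {layout!r}")

    df = pd.read_csv(path)
    missing_cols = [c for c in (*panel.test_names, "count") if c not in df.columns]
    if missing_cols:
        raise CountTableError(f"missing columns {missing_cols} in {path}")

    counts = np.full(panel.n_patterns, -1, dtype=np.int64)
    for row_number, row in df.iterrows():
        pattern = tuple(row[name] for name in panel.test_names)
        if any(t not in (0, 1) for t in pattern):
            raise CountTableError(
                f"row {row_number}: pattern {pattern} is not binary"
            )
        value = row["count"]
        if pd.isna(value) or float(value) != int(value):
            raise CountTableError(f"row {row_number}: non-integer count {value!r}")
        if int(value) < 0:
            raise CountTableError(f"row {row_number}: negative count {value}")
        idx = panel.pattern_index([int(t) for t in pattern])
        if counts[idx] >= 0:
            raise CountTableError(
                f"row {row_number}: duplicate pattern {''.join(map(str, map(int, pattern)))}"
            )
        counts[idx] = int(value)
    absent = np.nonzero(counts < 0)[0]
    if absent.size:
        labels = ", ".join(panel.pattern_label(i) for i in absent)
        raise CountTableError(f"missing pattern rows: {labels}")
    return CrossClassifiedCounts(panel, counts)


def _counts_from_values(panel: TestPanel, values: Iterable) -> CrossClassifiedCounts:
    arr = np.asarray(list(values), dtype=float)
    if not np.allclose(arr, np.round(arr)):
        bad = arr[arr != np.round(arr)][0]
        raise CountTableError(f"non-integer count {bad}")
    if (arr < 0).any():
        raise CountTableError(f"negative count {arr[arr < 0][0]}")
    return CrossClassifiedCounts(panel, arr.astype(np.int64))


def write_counts(counts: CrossClassifiedCounts, path: str | Path) -> Path:
    """Write a count table in the long format; round-trips with read_counts."""
    path = Path(path)
    counts.to_frame().to_csv(path, index=False)
    return path
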