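"""Relative expression orderings (REOs): orientation, pairwise consistency, filtering.

The REO of a gene pair within one sample is the sign of the expression
difference between the two genes; it is invariant to any strictly increasing
transform of that sample, which is what makes REO statistics robust to
normalization and — the point of this package — to cell-mixture composition.

``pairwise_consistency`` scores how many gene pairs keep the same non-tie
orientation between two profiles.  The all-pairs path streams the upper
triangle of the gene × gene comparison in fixed-size row chunks, so memory
stays O(chunk × n) rather than O(n²) and large gene universes are feasible.
Tied pairs carry no ordering information and are excluded from the
denominator; their count is reported so the effect is visible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .io_model import RankProfile

Orientation = Literal["i_gt_j", "j_gt_i", "tie"]

#: sentinel meaning "every unordered pair of genes"
ALL_PAIRS = "all"

_DEFAULT_CHUNK = 256


@dataclass
class GenePairSet:
    """Ordered collection of gene index pairs with canonical i < j ordering.

    ``orientation`` (optional) is +1 for i > j in expression, −1 for j > i.
    ``support_frequency`` (optional) is the fraction of cohort samples
    exhibiting that orientation.
    """

    pairs: np.ndarray  # (m, 2) int
    orientation: np.ndarray | None = None  # (m,) int8 in {+1, -1}
    support_frequency: np.ndarray | None = None  # (m,) float in [0, 1]

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=np.int64).reshape(-1, 2)
        if len(self.pairs) and np.any(self.pairs[:, 0] >= self.pairs[:, 1]):
            raise ValueError("pairs must satisfy i < j")
        if len(self.pairs):
            codes = self.pairs[:, 0] * (self.pairs[:, 1].max() + 1) + self.pairs[:, 1]
            codes.sort()
            if len(codes) > 1 and np.any(codes[1:] == codes[:-1]):
                raise ValueError("duplicate pairs")
        if self.orientation is not None:
            self.orientation = np.asarray(self.orientation, dtype=np.int8)
            if self.orientation.shape != (len(self.pairs),):
                raise ValueError("orientation length mismatch")
        if self.support_frequency is not None:
            self.support_frequency = np.asarray(self.support_frequency, dtype=float)
            if self.support_frequency.shape != (len(self.pairs),):
                raise ValueError("support_frequency length mismatch")
            if len(self.support_frequency) and (
                self.support_frequency.min() < 0 or self.support_frequency.max() > 1
            ):
                raise ValueError("support_frequency outside [0, 1]")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class ConsistencyScore:
    """REO-consistency between two profiles over a pair set."""

    n_pairs_evaluated: int
    n_consistent: int
    n_ties_excluded: int

    def __post_init__(self) -> None:
        if self.n_consistent > self.n_pairs_evaluated:
            raise ValueError("n_consistent exceeds n_pairs_evaluated")

    @property
    def score(self) -> float:
        if self.n_pairs_evaluated == 0:
            return float("nan")
        return self.n_consistent / self.n_pairs_evaluated


def reo_orientation(x_i: float, x_j: float) -> Orientation:
    """Within-sample ordering of a gene pair: ``i_gt_j``, ``j_gt_i`` or ``tie``."""
    if not (np.isfinite(x_i) and np.isfinite(x_j)):
        raise ValueError("non-finite expression value")
    if x_i > x_j:
        return "i_gt_j"
    if x_i < x_j:
        return "j_gt_i"
    return "tie"


def all_pairs(n_genes: int) -> GenePairSet:
    """Materialize every unordered pair (i < j) over ``n_genes`` genes."""
    i, j = np.triu_indices(n_genes, k=1)
    return GenePairSet(np.column_stack([i, j]))


def _consistency_all_pairs(a: np.ndarray, b: np.ndarray, chunk: int) -> ConsistencyScore:
    n = len(a)
    cols = np.arange(n)
    n_consistent = 0
    n_ties = 0
    n_total = n * (n - 1) // 2
    for i0 in range(0, n, chunk):
        i1 = min(i0 + chunk, n)
        upper = cols[None, :] > np.arange(i0, i1)[:, None]
        da = a[i0:i1, None] - a[None, :]
        db = b[i0:i1, None] - b[None, :]
        a_pos, a_neg = da > 0, da < 0
        b_pos, b_neg = db > 0, db < 0
        consistent = ((a_pos & b_pos) | (a_neg & b_neg)) & upper
        tie = (~(a_pos | a_neg) | ~(b_pos | b_neg)) & upper
        n_ties += int(tie.sum())
        n_consistent += int(consistent.sum())
    return ConsistencyScore(n_total - n_ties, n_consistent, n_ties)


def pairwise_consistency(
    profile_a: np.ndarray | Sequence[float],
    profile_b: np.ndarray | Sequence[float],
    pair_set: GenePairSet | str = ALL_PAIRS,
    chunk: int = _DEFAULT_CHUNK,
) -> ConsistencyScore:
    """Fraction of gene pairs with identical non-tie REO in both profiles.

    Pairs tied in either profile are excluded from the denominator and
    counted in ``n_ties_excluded``.  ``pair_set=ALL_PAIRS`` evaluates every
    unordered pair by streaming the upper triangle.
    """
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("profiles must be 1-D vectors over the same gene universe")
    if isinstance(pair_set, str):
        if pair_set != ALL_PAIRS:
            raise ValueError(f"unknown pair_set sentinel {pair_set!r}")
        return _consistency_all_pairs(a, b, chunk)
    i, j = pair_set.pairs[:, 0], pair_set.pairs[:, 1]
    if len(i) and int(j.max()) >= len(a):
        raise ValueError("pair index outside gene universe")
    sa = np.sign(a[i] - a[j])
    sb = np.sign(b[i] - b[j])
    tie = (sa == 0) | (sb == 0)
    n_ties = int(tie.sum())
    n_consistent = int((sa * sb > 0).sum())
    return ConsistencyScore(len(i) - n_ties, n_consistent, n_ties)


def filter_small_rank_diff(
    reference_profile: RankProfile | np.ndarray,
    pair_set: GenePairSet | str = ALL_PAIRS,
    delete_fraction: float = 0.1,
) -> GenePairSet:
    """Drop the pairs with the smallest |rank_i − rank_j| in a reference profile.

    Removes ``floor(delete_fraction * n_pairs)`` pairs; ties at the cut are
    broken deterministically by (i, j) lexicographic order (smaller indices
    removed first).  The surviving pairs are returned sorted by (i, j).
    """
    if not (0 <= delete_fraction < 1):
        raise ValueError("delete_fraction must lie in [0, 1)")
    ranks = (
        reference_profile.ranks
        if isinstance(reference_profile, RankProfile)
        else np.asarray(reference_profile, dtype=float)
    )
    if isinstance(pair_set, str):
        if pair_set != ALL_PAIRS:
            raise ValueError(f"unknown pair_set sentinel {pair_set!r}")
        pair_set = all_pairs(len(ranks))
    if len(pair_set) == 0:
        raise ValueError("empty pair set")
    i, j = pair_set.pairs[:, 0], pair_set.pairs[:, 1]
    diff = np.abs(ranks[i] - ranks[j])
    n_remove = int(np.floor(delete_fraction * len(pair_set)))
    if n_remove == 0:
        return pair_set
    # primary key: rank difference; tie-break: lexicographic (i, j)
    order = np.lexsort((j, i, diff))
    keep = np.sort(order[n_remove:])
    return GenePairSet(
        pair_set.pairs[keep],
        None if pair_set.orientation is None else pair_set.orientation[keep],
        None if pair_set.support_frequency is None else pair_set.support_frequency[keep],
    )
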