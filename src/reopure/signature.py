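"""Reversal-gene-pair signature: stability screen, reversal degree, classification.

The signature is a single gene pair whose within-sample ordering is stable in
normal tissue (same REO in more than a threshold fraction of normal samples,
95% by default) and stably *reversed* in tumors.  Among all such reversal
pairs the one with the widest expression gap on both sides is selected: per
sample all genes are ranked ascending, the pair's absolute rank difference
Rij = |Ri − Rj| is taken, and the reversal degree avgRij is the arithmetic
mean of the cohort medians, avgRij = (median[Rij(N)] + median[Rij(T)]) / 2.

Classification of a new sample is purely within-sample: if the pair shows the
normal-cohort orientation the sample is called normal, the opposite
orientation tumor.  An exact tie is surfaced as "unclassifiable" by default;
``tie_policy="tumor"`` reproduces the stricter normal-or-else rule.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_model import ExpressionMatrix
from .reo_core import GenePairSet

logger = logging.getLogger(__name__)

_CHUNK = 128

DEFAULT_PTEC_BIN_EDGES: tuple[float, ...] = (30, 40, 50, 60, 70, 80, 90, 100)


@dataclass
class SignatureModel:
    """A single reversal gene pair and the orientation that defines 'normal'."""

    gene_i: str
    gene_j: str
    normal_orientation: Literal["i_gt_j", "j_gt_i"]
    reversal_degree: float
    normal_support: float
    tumor_support: float
    threshold: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SignatureModel":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class ReversalCandidate:
    pair: tuple[str, str]
    normal_orientation: Literal["i_gt_j", "j_gt_i"]
    normal_support: float
    tumor_support: float
    median_rank_diff_normal: float
    median_rank_diff_tumor: float

    @property
    def avg_rij(self) -> float:
        return (self.median_rank_diff_normal + self.median_rank_diff_tumor) / 2.0


def stable_pairs(
    matrix: ExpressionMatrix,
    sample_ids: Sequence[str] | None = None,
    threshold: float = 0.95,
) -> GenePairSet:
    """Gene pairs with the same non-tie REO in more than ``threshold`` of samples.

    Tied samples count toward the denominator but toward neither orientation,
    and the threshold comparison is strict (support must *exceed* it).
    """
    if not (0.5 < threshold <= 1):
        raise ValueError("threshold must lie in (0.5, 1]")
    X = matrix.values if sample_ids is None else matrix.subset_samples(list(sample_ids)).values
    n, m = X.shape
    if m < 2:
        raise ValueError("need at least 2 samples (empty or singleton cohort)")
    pairs, orients, supports = [], [], []
    cols = np.arange(n)
    for i0 in range(0, n, _CHUNK):
        i1 = min(i0 + _CHUNK, n)
        diff = X[i0:i1, None, :] - X[None, :, :]
        gt = (diff > 0).sum(axis=2)
        lt = (diff < 0).sum(axis=2)
        upper = cols[None, :] > np.arange(i0, i1)[:, None]
        support = np.maximum(gt, lt) / m
        hit = upper & (support > threshold)
        ii, jj = np.nonzero(hit)
        if len(ii):
            pairs.append(np.column_stack([ii + i0, jj]))
            orients.append(np.where(gt[ii, jj] >= lt[ii, jj], 1, -1).astype(np.int8))
            supports.append(support[ii, jj])
    if not pairs:
        return GenePairSet(np.empty((0, 2), dtype=np.int64), np.empty(0, np.int8), np.empty(0))
    return GenePairSet(np.vstack(pairs), np.concatenate(orients), np.concatenate(supports))


def reversal_pairs(normal_stable: GenePairSet, tumor_stable: GenePairSet) -> GenePairSet:
    """Pairs stable in both cohorts with opposite orientations (the reversal set)."""
    if normal_stable.orientation is None or tumor_stable.orientation is None:
        raise ValueError("both pair sets must carry orientations")
    tumor_map = {
        (int(i), int(j)): int(o)
        for (i, j), o in zip(tumor_stable.pairs, tumor_stable.orientation)
    }
    keep = [
        row
        for row, (i, j) in enumerate(normal_stable.pairs)
        if tumor_map.get((int(i), int(j))) == -int(normal_stable.orientation[row])
    ]
    return GenePairSet(
        normal_stable.pairs[keep],
        normal_stable.orientation[keep],
        None if normal_stable.support_frequency is None else normal_stable.support_frequency[keep],
    )


def _rank_matrix(X: np.ndarray) -> np.ndarray:
    """Ascending average-tie ranks within each sample (column)."""
    return rankdata(X, method="average", axis=0)


def reversal_degree(
    pair: tuple[str, str],
    normal_matrix: ExpressionMatrix,
    tumor_matrix: ExpressionMatrix,
) -> ReversalCandidate:
    """Score one pair: cohort medians of the within-sample |rank_i − rank_j|."""
    gi, gj = pair
    in_ = normal_matrix.gene_index(gi), normal_matrix.gene_index(gj)
    it_ = tumor_matrix.gene_index(gi), tumor_matrix.gene_index(gj)
    rn = _rank_matrix(normal_matrix.values)
    rt = _rank_matrix(tumor_matrix.values)
    rij_n = np.abs(rn[in_[0]] - rn[in_[1]])
    rij_t = np.abs(rt[it_[0]] - rt[it_[1]])
    # orientation/support from the normal cohort majority
    s = np.sign(normal_matrix.values[in_[0]] - normal_matrix.values[in_[1]])
    n_gt = int((s > 0).sum())
    n_lt = int((s < 0).sum())
    st = np.sign(tumor_matrix.values[it_[0]] - tumor_matrix.values[it_[1]])
    normal_orient = "i_gt_j" if n_gt >= n_lt else "j_gt_i"
    tumor_support = (
        int((st < 0).sum()) if normal_orient == "i_gt_j" else int((st > 0).sum())
    ) / tumor_matrix.n_samples
    return ReversalCandidate(
        pair=(gi, gj),
        normal_orientation=normal_orient,
        normal_support=max(n_gt, n_lt) / normal_matrix.n_samples,
        tumor_support=tumor_support,
        median_rank_diff_normal=float(np.median(rij_n)),
        median_rank_diff_tumor=float(np.median(rij_t)),
    )


def select_signature(
    normal_matrix: ExpressionMatrix,
    tumor_matrix: ExpressionMatrix,
    threshold: float = 0.95,
) -> SignatureModel:
    """Discover the maximally reversed stable gene pair between the two cohorts.

    Runs the stability screen on each cohort, intersects for reversal pairs,
    scores every candidate by avgRij and returns the argmax; exact ties are
    broken by lexicographic (gene_i, gene_j).
    """
    normal, tumor = normal_matrix.align_genes(tumor_matrix)
    n_stable = stable_pairs(normal, threshold=threshold)
    t_stable = stable_pairs(tumor, threshold=threshold)
    reversals = reversal_pairs(n_stable, t_stable)
    if len(reversals) == 0:
        raise ValueError(f"no reversal pair at threshold {threshold}")
    logger.info(
        "select_signature: %d normal-stable, %d tumor-stable, %d reversal pairs",
        len(n_stable), len(t_stable), len(reversals),
    )
    rn = _rank_matrix(normal.values)
    rt = _rank_matrix(tumor.values)
    i, j = reversals.pairs[:, 0], reversals.pairs[:, 1]
    med_n = np.median(np.abs(rn[i] - rn[j]), axis=1)
    med_t = np.median(np.abs(rt[i] - rt[j]), axis=1)
    avg = (med_n + med_t) / 2.0
    # argmax with deterministic lexicographic tie-break on (gene_i, gene_j)
    best = np.lexsort((j, i, -avg))[0]
    gi, gj = normal.gene_ids[int(i[best])], normal.gene_ids[int(j[best])]
    t_map = {
        (int(a), int(b)): float(s)
        for (a, b), s in zip(t_stable.pairs, t_stable.support_frequency)
    }
    return SignatureModel(
        gene_i=gi,
        gene_j=gj,
        normal_orientation="i_gt_j" if reversals.orientation[best] > 0 else "j_gt_i",
        reversal_degree=float(avg[best]),
        normal_support=float(reversals.support_frequency[best]),
        tumor_support=t_map[(int(i[best]), int(j[best]))],
        threshold=threshold,
    )


def classify(
    sample: Mapping[str, float] | pd.Series,
    model: SignatureModel,
    tie_policy: Literal["unclassifiable", "tumor"] = "unclassifiable",
) -> Literal["normal", "tumor", "unclassifiable"]:
    """Call one sample from the signature pair's within-sample ordering."""
    try:
        xi, xj = float(sample[model.gene_i]), float(sample[model.gene_j])
    except KeyError as exc:
        raise KeyError(f"signature gene {exc.args[0]!r} missing from sample") from None
    if xi == xj:
        if tie_policy == "tumor":
            return "tumor"
        logger.info("classify: exact tie on signature pair, sample unclassifiable")
        return "unclassifiable"
    orientation = "i_gt_j" if xi > xj else "j_gt_i"
    return "normal" if orientation == model.normal_orientation else "tumor"


def classify_matrix(
    matrix: ExpressionMatrix,
    model: SignatureModel,
    tie_policy: Literal["unclassifiable", "tumor"] = "unclassifiable",
) -> pd.Series:
    """Vectorized :func:`classify` over every sample of a matrix."""
    xi = matrix.values[matrix.gene_index(model.gene_i)]
    xj = matrix.values[matrix.gene_index(model.gene_j)]
    want_i_gt_j = model.normal_orientation == "i_gt_j"
    normal_mask = (xi > xj) if want_i_gt_j else (xi < xj)
    tie_mask = xi == xj
    calls = np.where(normal_mask, "normal", "tumor")
    calls = np.where(tie_mask, "tumor" if tie_policy == "tumor" else "unclassifiable", calls)
    return pd.Series(calls, index=matrix.sample_ids, name="call")


def evaluate_accuracy(
    predictions: Sequence[str] | pd.Series,
    labels: Sequence[str] | pd.Series,
    ptec: Sequence[float | None] | None = None,
    bin_edges: Sequence[float] = DEFAULT_PTEC_BIN_EDGES,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Per-class accuracy, optionally binned by tumor cellularity (PTEC).

    Returns ``(per_class, per_bin)``; ``per_bin`` is None unless ``ptec`` is
    given.  Empty bins are reported with count 0 and accuracy NaN.
    """
    pred = np.asarray(list(predictions), dtype=object)
    lab = np.asarray(list(labels), dtype=object)
    if len(pred) != len(lab):
        raise ValueError("predictions and labels length mismatch")
    correct = pred == lab
    per_class = (
        pd.DataFrame({"label": lab, "correct": correct})
        .groupby("label", as_index=False)
        .agg(n=("correct", "size"), accuracy=("correct", "mean"))
    )
    if ptec is None:
        return per_class, None
    ptec_arr = np.array([np.nan if p is None else float(p) for p in ptec])
    if len(ptec_arr) != len(pred):
        raise ValueError("ptec and predictions length mismatch")
    edges = list(bin_edges)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_bin = (ptec_arr >= lo) & (ptec_arr < hi if hi != edges[-1] else ptec_arr <= hi)
        n = int(in_bin.sum())
        rows.append(
            {
                "ptec_low": lo,
                "ptec_high": hi,
                "n": n,
                "accuracy": float(correct[in_bin].mean()) if n else float("nan"),
            }
        )
    return per_class, pd.DataFrame(rows)
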