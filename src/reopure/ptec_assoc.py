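"""Purity-association statistics: PTEC correlation, epithelial-vs-stromal DEGs, concordance.

The question these statistics answer: are the genes whose expression tracks
tumor purity (PTEC) the same genes that differ between tumor epithelial and
stromal cells, with matching direction?  A gene is *concordant* when it is
positively correlated with PTEC and up-regulated in epithelium versus stroma,
or negatively correlated and down-regulated.  With k genes in both significant
lists and s of them concordant, the concordance score is s/k and its
chance probability is the upper tail of Binomial(k, Pe), Pe = 0.5 by default.
"""

from __future__ import annotations

import logging

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_model import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class ConcordanceResult:
    k: int  # genes both PTEC-correlated and differentially expressed
    s: int  # genes with concordant direction
    pe: float = 0.5

    def __post_init__(self) -> None:
        if not (0 <= self.s <= self.k):
            raise ValueError("require 0 <= s <= k")

    @property
    def score(self) -> float:
        return self.s / self.k if self.k else float("nan")

    @property
    def p_value(self) -> float:
        if self.k == 0:
            return 1.0
        return concordance_pvalue(self.k, self.s, self.pe)


def correlate_with_ptec(
    matrix: ExpressionMatrix,
    ptec: np.ndarray | list[float],
    fdr_threshold: float = 0.10,
) -> pd.DataFrame:
    """Per-gene Spearman correlation with PTEC, BH-adjusted.

    Returns a frame indexed by gene_id with columns ``spearman_rho``,
    ``raw_p``, ``fdr``, ``direction`` and ``significant`` (fdr strictly below
    the threshold).  Zero-variance genes are excluded and logged: their rank
    correlation is undefined.
    """
    ptec = np.asarray(ptec, dtype=float)
    if len(ptec) != matrix.n_samples:
        raise ValueError("ptec length does not match sample count")
    if len(ptec) < 3:
        raise ValueError("need at least 3 samples with resolved PTEC")
    var = matrix.values.var(axis=1)
    usable = var > 0
    n_excluded = int((~usable).sum())
    if n_excluded:
        logger.info(
            "correlate_with_ptec: excluded %d zero-variance genes: %s",
            n_excluded,
            [g for g, u in zip(matrix.gene_ids, usable) if not u][:10],
        )
    genes = [g for g, u in zip(matrix.gene_ids, usable) if u]
    rho = np.empty(len(genes))
    raw_p = np.empty(len(genes))
    for row, values in enumerate(matrix.values[usable]):
        res = stats.spearmanr(values, ptec)
        rho[row] = res.statistic
        raw_p[row] = res.pvalue
    raw_p = np.nan_to_num(raw_p, nan=1.0)
    fdr = multipletests(raw_p, method="fdr_bh")[1] if len(genes) else np.array([])
    table = pd.DataFrame(
        {
            "spearman_rho": rho,
            "raw_p": raw_p,
            "fdr": fdr,
            "direction": np.where(rho >= 0, "positive", "negative"),
        },
        index=pd.Index(genes, name="gene_id"),
    )
    table["significant"] = table["fdr"] < fdr_threshold
    return table


def differential_expression(
    epithelial: ExpressionMatrix,
    stromal: ExpressionMatrix,
    fdr_threshold: float = 0.10,
) -> pd.DataFrame:
    """Student's (pooled-variance) t-test per gene, epithelial vs stromal, BH-adjusted.

    ``regulation`` is ``up`` when the epithelial mean exceeds the stromal
    mean.  Degenerate genes with zero pooled variance get t = 0, p = 1 when
    the group means agree (no evidence either way).
    """
    epi, stro = epithelial.align_genes(stromal)
    if epi.n_samples < 2 or stro.n_samples < 2:
        raise ValueError("need at least 2 samples per group")
    t, p = stats.ttest_ind(epi.values, stro.values, axis=1, equal_var=True)
    mean_diff = epi.values.mean(axis=1) - stro.values.mean(axis=1)
    degenerate = ~np.isfinite(t)
    t = np.where(degenerate & (mean_diff == 0), 0.0, t)
    p = np.where(degenerate & (mean_diff == 0), 1.0, p)
    p = np.where(degenerate & (mean_diff != 0), 0.0, p)
    fdr = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "t_statistic": t,
            "raw_p": p,
            "fdr": fdr,
            "regulation": np.where(mean_diff > 0, "up", "down"),
        },
        index=pd.Index(epi.gene_ids, name="gene_id"),
    )
    table["significant"] = table["fdr"] < fdr_threshold
    return table


def concordance_score(
    corr: pd.DataFrame, degs: pd.DataFrame, pe: float = 0.5
) -> ConcordanceResult:
    """Concordance between PTEC-correlation direction and regulation direction.

    Operates on the *significant* subsets of the two tables (the full tables
    may be passed; rows with ``significant == False`` are ignored when the
    column is present).
    """
    if "significant" in corr.columns:
        corr = corr[corr["significant"]]
    if "significant" in degs.columns:
        degs = degs[degs["significant"]]
    shared = corr.index.intersection(degs.index)
    k = len(shared)
    if k == 0:
        logger.info("concordance_score: empty overlap, score undefined")
        return ConcordanceResult(0, 0, pe)
    concordant = (
        (corr.loc[shared, "direction"].to_numpy() == "positive")
        & (degs.loc[shared, "regulation"].to_numpy() == "up")
    ) | (
        (corr.loc[shared, "direction"].to_numpy() == "negative")
        & (degs.loc[shared, "regulation"].to_numpy() == "down")
    )
    return ConcordanceResult(k, int(concordant.sum()), pe)


def concordance_pvalue(k: int, s: int, pe: float = 0.5) -> float:
    """Upper-tail binomial probability of observing ≥ s concordant genes of k.

    P = 1 − Σ_{i=0}^{s−1} C(k, i) Pe^i (1 − Pe)^{k−i}, evaluated through the
    binomial survival function so it stays accurate for k up to ~1e5.
    """
    if not (0 <= s <= k):
        raise ValueError("require 0 <= s <= k")
    if not (0 < pe < 1):
        raise ValueError("require 0 < Pe < 1")
    if not (isinstance(k, (int, np.integer)) and isinstance(s, (int, np.integer))):
        raise TypeError("k and s must be integer counts")
    if s == 0:
        return 1.0
    return float(stats.binom.sf(s - 1, k, pe))
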