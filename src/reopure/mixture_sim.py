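"""In-silico mixing of purified epithelial/stromal profiles at controlled tumor purity.

A simulated bulk tumor profile is the convex combination
``E = Ee * Pi + Es * (1 - Pi)`` of the patient's tumor-epithelial profile Ee
and stromal profile Es, where Pi is the proportion of tumor epithelial cells
(PTEC) in the simulated tissue, strictly between 0 and 1 in pipeline mode.
By default mixing happens on the linear intensity scale — cells contribute
transcripts additively — with log2 inputs unlogged before and re-logged
after; ``mixing_scale="as_given"`` combines the values as provided.

``ptec_sweep`` runs the mixture across a PTEC grid for a list of patients and
scores, per patient and purity level, how many gene-pair REOs of the pure
epithelial profile survive in the mixture, both over all pairs and after
discarding the pairs with the smallest rank differences in the epithelial
profile.  The sweep is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .io_model import rank_profile
from .reo_core import ALL_PAIRS, ConsistencyScore, filter_small_rank_diff, pairwise_consistency

DEFAULT_PI_LEVELS: tuple[float, ...] = tuple(np.round(np.arange(0.9, 0.0, -0.1), 1))
REPORTED_PI_LEVELS: tuple[float, ...] = (0.7, 0.5, 0.3)


@dataclass
class MixtureSpec:
    """Purity fraction and mixing-scale policy for one simulated tissue."""

    pi: float
    mixing_scale: Literal["linear", "as_given"] = "linear"
    allow_endpoints: bool = False  # test mode: permit Pi exactly 0 or 1

    def __post_init__(self) -> None:
        lo, hi = (0.0, 1.0)
        if self.allow_endpoints:
            ok = lo <= self.pi <= hi
        else:
            ok = lo < self.pi < hi
        if not ok:
            raise ValueError(f"Pi={self.pi} outside the open interval (0, 1)")


@dataclass
class SweepResult:
    """Per-patient-per-Pi consistency scores and their per-Pi summaries.

    ``scores`` is long-format with columns patient, pi, filtered, n_pairs,
    n_consistent, n_ties_excluded, score; ``summary`` aggregates mean, sd
    (ddof=1) and min of the score per (pi, filtered).
    """

    scores: pd.DataFrame
    summary: pd.DataFrame


def mix_profiles(
    ee: np.ndarray | Sequence[float],
    es: np.ndarray | Sequence[float],
    spec: MixtureSpec,
    input_scale: Literal["linear", "log2"] = "linear",
) -> np.ndarray:
    """Convex combination of epithelial and stromal profiles with weight Pi on Ee."""
    ee = np.asarray(ee, dtype=float)
    es = np.asarray(es, dtype=float)
    if ee.shape != es.shape:
        raise ValueError("profiles must share the gene universe")
    # endpoint identities are exact by construction, not by arithmetic
    if spec.allow_endpoints and spec.pi == 1.0:
        return ee.copy()
    if spec.allow_endpoints and spec.pi == 0.0:
        return es.copy()
    if spec.mixing_scale == "linear":
        if input_scale == "log2":
            mixed = spec.pi * np.exp2(ee) + (1.0 - spec.pi) * np.exp2(es)
            return np.log2(mixed)
        if np.any(ee < 0) or np.any(es < 0):
            raise ValueError("negative linear-scale values")
        return spec.pi * ee + (1.0 - spec.pi) * es
    return spec.pi * ee + (1.0 - spec.pi) * es


def ptec_sweep(
    paired_profiles: Sequence[tuple[np.ndarray, np.ndarray]],
    pi_levels: Sequence[float] = DEFAULT_PI_LEVELS,
    filter_fraction: float = 0.1,
    mixing_scale: Literal["linear", "as_given"] = "linear",
    input_scale: Literal["linear", "log2"] = "linear",
) -> SweepResult:
    """Simulate mixtures over a PTEC grid and score REO survival per patient.

    For each patient the reference is always that patient's own epithelial
    profile; the filtered pair set discards ``filter_fraction`` of pairs with
    the smallest epithelial rank differences.
    """
    if len(paired_profiles) == 0:
        raise ValueError("empty patient list")
    pi_levels = [float(p) for p in pi_levels]
    if any(not (0 < p < 1) for p in pi_levels):
        raise ValueError("pi levels must lie strictly in (0, 1)")
    rows = []
    for patient, (ee, es) in enumerate(paired_profiles):
        ee = np.asarray(ee, dtype=float)
        es = np.asarray(es, dtype=float)
        ref_ranks = rank_profile(ee, [str(g) for g in range(len(ee))])
        kept = filter_small_rank_diff(ref_ranks, ALL_PAIRS, filter_fraction)
        for pi in pi_levels:
            spec = MixtureSpec(pi, mixing_scale=mixing_scale)
            mixture = mix_profiles(ee, es, spec, input_scale=input_scale)
            for filtered, score in (
                (False, pairwise_consistency(mixture, ee, ALL_PAIRS)),
                (True, pairwise_consistency(mixture, ee, kept)),
            ):
                rows.append(
                    {
                        "patient": patient,
                        "pi": pi,
                        "filtered": filtered,
                        "n_pairs": score.n_pairs_evaluated,
                        "n_consistent": score.n_consistent,
                        "n_ties_excluded": score.n_ties_excluded,
                        "score": score.score,
                    }
                )
    scores = pd.DataFrame(rows)
    summary = (
        scores.groupby(["pi", "filtered"], as_index=False)["score"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0, min="min")
        .sort_values(["pi", "filtered"], ascending=[False, True])
        .reset_index(drop=True)
    )
    return SweepResult(scores, summary)


def gene_fold_change(mixture_value: float, ee_value: float) -> float:
    """Direction-free fold change of one gene between mixture and epithelial profile."""
    if mixture_value <= 0 or ee_value <= 0:
        raise ValueError("fold change requires positive linear-scale values")
    ratio = mixture_value / ee_value
    return max(ratio, 1.0 / ratio)


def max_fold_change_report(
    paired_profiles: Sequence[tuple[np.ndarray, np.ndarray]],
    gene_indices: Sequence[int],
    pi_levels: Sequence[float] = REPORTED_PI_LEVELS,
    gene_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Largest per-gene fold change over patients at each purity level.

    Mirrors the marker-gene analysis: how far mixture dilution moves an
    individual gene's measurement away from its pure-epithelial value.
    """
    if gene_names is None:
        gene_names = [f"g{idx}" for idx in gene_indices]
    rows = []
    for pi in pi_levels:
        spec = MixtureSpec(float(pi))
        for name, idx in zip(gene_names, gene_indices):
            fc = max(
                gene_fold_change(
                    mix_profiles(ee, es, spec)[idx], float(np.asarray(ee, dtype=float)[idx])
                )
                for ee, es in paired_profiles
            )
            rows.append({"gene": name, "pi": float(pi), "max_fold_change": fc})
    return pd.DataFrame(rows)
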