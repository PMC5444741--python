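"""Composed study workflows over the core modules.

Each function here is one complete experiment of the purity-robustness
analysis, run end to end on synthetic data: realized between-cell-type REO
concordance, the PTEC mixture sweep, the purity-correlation/DEG concordance
analysis, planted-signature recovery, and purity robustness of the final
classifier.  The ``analysis/`` drivers and the acceptance script are thin
wrappers over these.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import ExpressionMatrix
from .mixture_sim import MixtureSpec, SweepResult, mix_profiles, ptec_sweep
from .ptec_assoc import (
    ConcordanceResult,
    concordance_score,
    correlate_with_ptec,
    differential_expression,
)
from .reo_core import pairwise_consistency
from .signature import SignatureModel, classify_matrix, evaluate_accuracy, select_signature
from .synthetic_data import CellPairConfig, CohortConfig, CohortData, generate_cohort, \
    generate_paired_celltype_profiles


def split_cohort(cohort: CohortData) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """(normal, tumor) sub-matrices of a generated cohort."""
    normal_ids = [m.sample_id for m in cohort.metadata if m.class_label == "normal"]
    tumor_ids = [m.sample_id for m in cohort.metadata if m.class_label == "tumor"]
    return cohort.matrix.subset_samples(normal_ids), cohort.matrix.subset_samples(tumor_ids)


def cellpair_concordance(config: CellPairConfig) -> pd.DataFrame:
    """Generate paired cell-type profiles and measure their realized REO concordance."""
    patients = generate_paired_celltype_profiles(config)
    rows = [
        {
            "patient": k,
            "concordance": pairwise_consistency(np.log2(ee), np.log2(es)).score,
        }
        for k, (ee, es) in enumerate(patients)
    ]
    return pd.DataFrame(rows)


def purity_sweep_experiment(
    config: CellPairConfig,
    pi_levels=(0.7, 0.5, 0.3),
    filter_fraction: float = 0.1,
) -> SweepResult:
    """Mixture sweep over freshly generated paired cell-type profiles."""
    patients = generate_paired_celltype_profiles(config)
    return ptec_sweep(patients, pi_levels=pi_levels, filter_fraction=filter_fraction)


@dataclass
class PtecConcordanceAnalysis:
    """Outputs of the purity-correlation / DEG concordance experiment."""

    correlation: pd.DataFrame
    degs: pd.DataFrame
    concordance: ConcordanceResult


def ptec_concordance_analysis(
    n_genes: int = 1500,
    n_celltype_samples: int = 10,
    n_bulk: int = 60,
    noise_sd: float = 0.3,
    ptec_range: tuple[float, float] = (30.0, 90.0),
    fdr_threshold: float = 0.10,
    seed: int = 0,
) -> PtecConcordanceAnalysis:
    """Do PTEC-correlated genes match epithelial-vs-stromal DEGs in direction?

    One epithelial and one stromal cell-type baseline are generated at the
    default between-cell-type REO concordance; replicate microdissected
    profiles of each cell type (log2 noise ``noise_sd``) feed the DEG t-test,
    and bulk tumor samples — per-sample noisy cell-type profiles mixed at a
    PTEC drawn uniformly from ``ptec_range`` — feed the Spearman correlation
    with PTEC.  Both gene lists are thresholded at BH FDR < ``fdr_threshold``
    and their directional concordance is scored with its exact binomial tail.
    """
    ss = np.random.SeedSequence(seed)
    base_seed, noise_seed = (int(s) % 2**31 for s in ss.generate_state(2))
    ee, es = generate_paired_celltype_profiles(
        CellPairConfig(n_genes=n_genes, n_patients=1, seed=base_seed)
    )[0]
    ee_log, es_log = np.log2(ee), np.log2(es)
    rng = np.random.default_rng(noise_seed)
    genes = [f"g{i:04d}" for i in range(n_genes)]

    epi = ExpressionMatrix(
        genes,
        [f"epi{k:02d}" for k in range(n_celltype_samples)],
        ee_log[:, None] + rng.normal(0, noise_sd, (n_genes, n_celltype_samples)),
        "log2",
    )
    stro = ExpressionMatrix(
        genes,
        [f"str{k:02d}" for k in range(n_celltype_samples)],
        es_log[:, None] + rng.normal(0, noise_sd, (n_genes, n_celltype_samples)),
        "log2",
    )
    degs = differential_expression(epi, stro, fdr_threshold)

    lo, hi = ptec_range
    ptec = rng.uniform(lo, hi, n_bulk)
    bulk = np.empty((n_genes, n_bulk))
    for k in range(n_bulk):
        e_k = np.exp2(ee_log + rng.normal(0, noise_sd, n_genes))
        s_k = np.exp2(es_log + rng.normal(0, noise_sd, n_genes))
        bulk[:, k] = mix_profiles(e_k, s_k, MixtureSpec(float(ptec[k]) / 100.0))
    bulk_matrix = ExpressionMatrix(genes, [f"bulk{k:03d}" for k in range(n_bulk)], bulk)
    corr = correlate_with_ptec(bulk_matrix, ptec, fdr_threshold)

    return PtecConcordanceAnalysis(corr, degs, concordance_score(corr, degs))


def signature_recovery_rate(
    base_config: CohortConfig | None = None, n_seeds: int = 40, seed: int = 0
) -> float:
    """Fraction of seeds on which discovery returns the planted reversal pair."""
    base_config = base_config or CohortConfig()
    child_seeds = np.random.SeedSequence(seed).generate_state(n_seeds) % 2**31
    hits = 0
    for child in child_seeds:
        cohort = generate_cohort(
            CohortConfig(**{**base_config.__dict__, "seed": int(child)})
        )
        normal, tumor = split_cohort(cohort)
        model = select_signature(normal, tumor)
        gi, gj, _ = cohort.planted_pairs[0]
        hits += (model.gene_i, model.gene_j) == (gi, gj)
    return hits / n_seeds


@dataclass
class PurityRobustnessResult:
    """Trained signature, training accuracy, and per-purity call agreement."""

    model: SignatureModel
    training_accuracy: pd.DataFrame  # per class
    agreement_by_pi: pd.DataFrame  # pi, n, agreement with pure-epithelial calls


def purity_robustness_experiment(
    config: CohortConfig | None = None,
    pi_levels=(0.7, 0.5, 0.3),
    seed: int = 0,
) -> PurityRobustnessResult:
    """Train a signature, then re-mix each tumor's pure epithelial profile
    with its stromal profile at fixed purity levels and check the calls."""
    config = config or CohortConfig(seed=seed)
    cohort = generate_cohort(config)
    normal, tumor = split_cohort(cohort)
    model = select_signature(normal, tumor)

    calls = pd.concat([classify_matrix(normal, model), classify_matrix(tumor, model)])
    labels = ["normal"] * normal.n_samples + ["tumor"] * tumor.n_samples
    per_class, _ = evaluate_accuracy(calls.to_numpy(), labels)

    epi, stro = cohort.tumor_epithelial, cohort.tumor_stromal
    pure_calls = classify_matrix(epi, model).to_numpy()
    rows = []
    for pi in pi_levels:
        spec = MixtureSpec(float(pi))
        mixed_values = np.column_stack(
            [
                mix_profiles(epi.values[:, k], stro.values[:, k], spec)
                for k in range(epi.n_samples)
            ]
        )
        mixed = ExpressionMatrix(epi.gene_ids, epi.sample_ids, mixed_values, "linear")
        agree = classify_matrix(mixed, model).to_numpy() == pure_calls
        rows.append({"pi": float(pi), "n": len(agree), "agreement": float(agree.mean())})
    return PurityRobustnessResult(model, per_class, pd.DataFrame(rows))
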