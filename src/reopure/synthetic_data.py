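"""Synthetic inputs for every pipeline stage.

Two generators, all randomness flowing from a single seed:

* :func:`generate_paired_celltype_profiles` — per-patient paired tumor
  epithelial / stromal profiles whose pairwise REO concordance is calibrated
  to a target (default 0.85, inside the 82–93% range observed between
  microdissected cell types).  The epithelial profile is a log-normal
  baseline (log2 values ~ Normal(6, 2), resembling RMA-processed array
  intensities); the stromal profile perturbs it by cyclically permuting the
  values of a calibrated subset of genes — chosen by bisection until the
  realized all-pairs consistency is within ±0.02 of the target — then adds
  log-scale Gaussian noise.

* :func:`generate_cohort` — tumor/normal cohorts with planted reversal gene
  pairs at controlled rank separation.  Normal samples scatter around a
  baseline ordering; each tumor sample is a pure epithelial profile (baseline
  with the planted pairs' values swapped, plus background swaps and noise)
  mixed with a cohort stromal profile at a per-sample PTEC drawn uniformly
  from ``ptec_distribution``.  The stromal profile shares the planted pairs'
  *tumor* orientation (tumor stroma shows reversal REOs similar to tumor
  epithelium relative to normal tissue), so a planted reversal survives
  mixing the way the real signature does.

The generators emit the same containers — and, via the ``write_*`` helpers,
the same TSV formats — that the io layer reads, so fixtures and analysis
scripts share one code path.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .io_model import ExpressionMatrix, SampleMetadata, write_expression_matrix, write_metadata
from .mixture_sim import MixtureSpec, mix_profiles
from .reo_core import ALL_PAIRS, pairwise_consistency

_CONCORDANCE_TOL = 0.02


@dataclass
class CellPairConfig:
    """Paired epithelial/stromal profile generator settings."""

    n_genes: int = 2000
    n_patients: int = 8
    target_concordance: float = 0.85
    noise_sd: float = 0.05  # log2-scale sd added to the stromal profile
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 10:
            raise ValueError("n_genes must be >= 10")
        if not (0.5 < self.target_concordance <= 1):
            raise ValueError("target_concordance must lie in (0.5, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CellPairConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class CohortConfig:
    """Tumor/normal cohort generator settings.

    ``planted_pairs`` holds (gene_index_i, gene_index_j, rank_separation)
    triples; ``None`` plants a single pair at maximal separation
    (n_genes − 1).  ``ptec_distribution`` is the (min, max) percentage range
    tumor-sample purity is drawn from.
    """

    n_genes: int = 200
    n_tumor: int = 50
    n_normal: int = 50
    planted_pairs: list[tuple[int, int, int]] | None = None
    background_reversal_rate: float = 0.02
    ptec_distribution: tuple[float, float] = (30.0, 100.0)
    noise_sd: float = 0.3  # log2-scale per-sample noise
    stromal_discordance: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.ptec_distribution
        if not (0 < lo <= hi <= 100):
            raise ValueError("ptec_distribution bounds must satisfy 0 < min <= max <= 100")
        for i, j, sep in self.resolved_planted_pairs():
            if not (0 <= i < self.n_genes and 0 <= j < self.n_genes and i != j):
                raise ValueError(f"planted pair ({i}, {j}) out of range")
            if not (1 <= sep <= self.n_genes - 1):
                raise ValueError(f"planted rank separation {sep} out of range")

    def resolved_planted_pairs(self) -> list[tuple[int, int, int]]:
        if self.planted_pairs is None:
            return [(0, 1, self.n_genes - 1)]
        return [tuple(p) for p in self.planted_pairs]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "ptec_distribution" in data:
            data["ptec_distribution"] = tuple(data["ptec_distribution"])
        return cls(**data)


@dataclass
class CohortData:
    """Generated cohort plus the ground truth behind it.

    ``matrix``/``metadata`` are the pipeline-facing outputs; the pure
    epithelial and stromal matrices expose what each tumor sample looked like
    before mixing, for purity-robustness experiments.
    """

    matrix: ExpressionMatrix
    metadata: list[SampleMetadata]
    planted_pairs: list[tuple[str, str, int]]  # (gene_i id, gene_j id, rank separation)
    tumor_epithelial: ExpressionMatrix  # linear scale, pre-mixing
    tumor_stromal: ExpressionMatrix  # linear scale, per-sample stromal profiles
    ptec: np.ndarray  # per-tumor-sample percentages, matrix column order


def _cyclic_value_swap(base: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Permute the values at ``idx`` cyclically, leaving all other genes fixed."""
    out = base.copy()
    if len(idx) >= 2:
        out[idx] = base[np.roll(idx, 1)]
    return out


def generate_paired_celltype_profiles(
    config: CellPairConfig,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-patient (Ee, Es) linear-scale profile pairs at calibrated REO concordance.

    Calibration bisects on the number of stromal genes whose values are
    cyclically permuted, measuring the realized all-pairs consistency of the
    emitted (noise-included) pair with the pipeline's own scorer, until it is
    within ±0.02 of the target.  Raises with the attainable range if the
    target cannot be reached at the configured gene count.
    """
    rng = np.random.default_rng(config.seed)
    patients: list[tuple[np.ndarray, np.ndarray]] = []
    for _ in range(config.n_patients):
        ee_log = rng.normal(6.0, 2.0, config.n_genes)
        order = rng.permutation(config.n_genes)
        noise = (
            rng.normal(0.0, config.noise_sd, config.n_genes)
            if config.noise_sd > 0
            else np.zeros(config.n_genes)
        )

        def realized(m: int) -> tuple[float, np.ndarray]:
            es = _cyclic_value_swap(ee_log, order[:m]) + noise
            return pairwise_consistency(ee_log, es, ALL_PAIRS).score, es

        target = config.target_concordance
        lo, hi = 0, config.n_genes  # consistency is maximal at lo, minimal at hi
        c_min, _ = realized(hi)
        if target < c_min - _CONCORDANCE_TOL:
            raise ValueError(
                f"target_concordance {target} unattainable at n_genes={config.n_genes}; "
                f"attainable range is about [{c_min:.3f}, 1.0]"
            )
        c, es_log = realized(lo)
        if abs(c - target) > _CONCORDANCE_TOL:
            while hi - lo > 1:
                mid = (lo + hi) // 2
                c, es_log = realized(mid)
                if abs(c - target) <= _CONCORDANCE_TOL:
                    break
                if c > target:
                    lo = mid
                else:
                    hi = mid
            else:
                c, es_log = realized(hi)
            if abs(c - target) > _CONCORDANCE_TOL:
                raise ValueError(
                    f"could not calibrate concordance to {target} ± {_CONCORDANCE_TOL} "
                    f"(closest realized {c:.4f})"
                )
        patients.append((np.exp2(ee_log), np.exp2(es_log)))
    return patients


def generate_cohort(config: CohortConfig) -> CohortData:
    """Tumor/normal expression cohort with planted reversal pairs and per-sample PTEC."""
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    planted = config.resolved_planted_pairs()
    planted_genes = {g for i, j, _ in planted for g in (i, j)}

    # baseline ordering: sorted log2 values assigned to genes by a random rank map
    vals = np.sort(rng.normal(6.0, 2.0, n))
    rank_of = rng.permutation(n)  # rank_of[g] = 0-based ascending rank of gene g

    def force_rank(gene: int, rank: int) -> None:
        holder = int(np.nonzero(rank_of == rank)[0][0])
        rank_of[holder], rank_of[gene] = rank_of[gene], rank

    for gi, gj, sep in planted:
        r_lo = (n - 1 - sep) // 2
        force_rank(gi, r_lo + sep)  # gene_i high → normal orientation i_gt_j
        force_rank(gj, r_lo)
    normal_base = vals[rank_of]

    # tumor epithelial baseline: planted pairs swapped, plus background swaps
    tumor_base = normal_base.copy()
    for gi, gj, _ in planted:
        tumor_base[[gi, gj]] = tumor_base[[gj, gi]]
    eligible = np.array(sorted(set(range(n)) - planted_genes))
    n_bg_pairs = int(round(config.background_reversal_rate * n))
    if n_bg_pairs:
        chosen = rng.choice(eligible, size=min(2 * n_bg_pairs, len(eligible)) // 2 * 2, replace=False)
        for a, b in chosen.reshape(-1, 2):
            tumor_base[[a, b]] = tumor_base[[b, a]]

    # cohort stromal baseline: shares the tumor orientation of planted pairs
    n_permuted = int(round(config.stromal_discordance * n))
    stromal_base = _cyclic_value_swap(
        tumor_base, rng.permutation(eligible)[:n_permuted]
    )

    gene_ids = [f"g{k:04d}" for k in range(n)]
    normal_ids = [f"N{k:03d}" for k in range(config.n_normal)]
    tumor_ids = [f"T{k:03d}" for k in range(config.n_tumor)]

    normal_log = normal_base[:, None] + rng.normal(0, config.noise_sd, (n, config.n_normal))
    epi_log = tumor_base[:, None] + rng.normal(0, config.noise_sd, (n, config.n_tumor))
    stro_log = stromal_base[:, None] + rng.normal(0, config.noise_sd, (n, config.n_tumor))
    lo, hi = config.ptec_distribution
    ptec = rng.uniform(lo, hi, config.n_tumor) if hi > lo else np.full(config.n_tumor, lo)

    epi_lin = np.exp2(epi_log)
    stro_lin = np.exp2(stro_log)
    mixed = np.empty_like(epi_lin)
    for k in range(config.n_tumor):
        spec = MixtureSpec(float(ptec[k]) / 100.0, allow_endpoints=True)
        mixed[:, k] = mix_profiles(epi_lin[:, k], stro_lin[:, k], spec)

    matrix = ExpressionMatrix(
        gene_ids, normal_ids + tumor_ids, np.hstack([np.exp2(normal_log), mixed]), "linear"
    )
    metadata = [SampleMetadata(s, "normal") for s in normal_ids] + [
        SampleMetadata(s, "tumor", ptec=float(p)) for s, p in zip(tumor_ids, ptec)
    ]
    return CohortData(
        matrix=matrix,
        metadata=metadata,
        planted_pairs=[(gene_ids[i], gene_ids[j], sep) for i, j, sep in planted],
        tumor_epithelial=ExpressionMatrix(gene_ids, tumor_ids, epi_lin, "linear"),
        tumor_stromal=ExpressionMatrix(gene_ids, list(tumor_ids), stro_lin, "linear"),
        ptec=ptec,
    )


def write_patient_profiles(
    patients: Sequence[tuple[np.ndarray, np.ndarray]], out_dir: str | Path
) -> list[tuple[Path, Path]]:
    """Write per-patient <patient>.epi.tsv / <patient>.stroma.tsv profile pairs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, (ee, es) in enumerate(patients):
        gene_ids = [f"g{i:04d}" for i in range(len(ee))]
        sample = f"patient{k:02d}"
        epi = ExpressionMatrix(gene_ids, [sample], np.asarray(ee)[:, None], "linear")
        stro = ExpressionMatrix(gene_ids, [sample], np.asarray(es)[:, None], "linear")
        p_epi = out_dir / f"{sample}.epi.tsv"
        p_stro = out_dir / f"{sample}.stroma.tsv"
        write_expression_matrix(epi, p_epi)
        write_expression_matrix(stro, p_stro)
        paths.append((p_epi, p_stro))
    return paths


def write_cohort(cohort: CohortData, out_dir: str | Path) -> tuple[Path, Path]:
    """Write a cohort's expression matrix and metadata as TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    matrix_path = out_dir / "expression.tsv"
    meta_path = out_dir / "metadata.tsv"
    write_expression_matrix(cohort.matrix, matrix_path)
    write_metadata(cohort.metadata, meta_path)
    return matrix_path, meta_path
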