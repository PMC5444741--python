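"""Expression-matrix IO, probe collapsing, within-sample ranking, and sample metadata.

The central container is :class:`ExpressionMatrix`, a validated genes-by-samples
numeric matrix tagged with its measurement scale (``linear`` intensities or
``log2`` of them).  Within-sample ascending ranks — the quantity every
relative-expression-ordering (REO) statistic is built on — are computed by
:func:`rank_profile` with average ranks for ties, so rank sums stay fixed at
n(n+1)/2.

Supported on-disk formats: plain TSV (first column = gene id, header row =
sample ids) and the GCT v1.2 dialect (two header lines, a Description column
that is dropped on load).  Rows containing missing values are dropped at load
time and logged; duplicate gene rows are collapsed by their per-sample mean,
mirroring the probe-to-gene collapse rule used for array platforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

Scale = Literal["linear", "log2"]
ClassLabel = Literal["tumor", "normal", "epithelial", "stromal", "unknown"]


class ParseError(ValueError):
    """Raised when an on-disk table cannot be interpreted."""


@dataclass
class ExpressionMatrix:
    """Genes × samples numeric expression matrix.

    Parameters
    ----------
    gene_ids
        Unique gene (or probe) identifiers, one per row.
    sample_ids
        Unique sample identifiers, one per column.
    values
        Finite float matrix of shape ``(len(gene_ids), len(sample_ids))``.
    scale
        ``"linear"`` (non-negative intensities) or ``"log2"``.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale: Scale = "linear"

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene_ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample_ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale == "linear" and np.any(self.values < 0):
            raise ValueError("negative values on linear scale")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"gene {gene_id!r} not in matrix") from None

    def sample(self, sample_id: str) -> np.ndarray:
        """Expression vector of one sample (view into ``values``)."""
        return self.values[:, self.sample_ids.index(sample_id)]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionMatrix(
            list(self.gene_ids), list(sample_ids), self.values[:, idx], self.scale
        )

    def align_genes(self, other: "ExpressionMatrix") -> tuple["ExpressionMatrix", "ExpressionMatrix"]:
        """Restrict both matrices to their shared genes, in this matrix's order."""
        shared = [g for g in self.gene_ids if g in set(other.gene_ids)]
        if not shared:
            raise ValueError("matrices share no genes")
        ia = [self.gene_ids.index(g) for g in shared]
        ib = [other.gene_ids.index(g) for g in shared]
        a = ExpressionMatrix(shared, list(self.sample_ids), self.values[ia], self.scale)
        b = ExpressionMatrix(shared, list(other.sample_ids), other.values[ib], other.scale)
        return a, b

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def to_linear(self) -> "ExpressionMatrix":
        if self.scale == "linear":
            return self
        return ExpressionMatrix(
            list(self.gene_ids), list(self.sample_ids), np.exp2(self.values), "linear"
        )


@dataclass
class RankProfile:
    """Per-sample ascending ranks of gene expression (smallest value → rank 1)."""

    gene_ids: list[str]
    ranks: np.ndarray
    tie_policy: Literal["average"] = "average"

    def __post_init__(self) -> None:
        self.ranks = np.asarray(self.ranks, dtype=float)
        if len(self.ranks) != len(self.gene_ids):
            raise ValueError("ranks and gene_ids length mismatch")
        n = len(self.ranks)
        if n and (self.ranks.min() < 1 or not np.isclose(self.ranks.sum(), n * (n + 1) / 2)):
            raise ValueError("ranks are not a valid average-tie ranking")


@dataclass
class SampleMetadata:
    """Class label and tumor-cell-percentage information for one sample.

    ``slide_purities`` holds per-slide 'percentage of tumor cells' readings
    (``None`` for an unavailable slide); ``ptec`` is the resolved per-sample
    percentage in [0, 100].
    """

    sample_id: str
    class_label: ClassLabel = "unknown"
    slide_purities: list[float | None] | None = None
    ptec: float | None = None
    dropped: bool = False

    def __post_init__(self) -> None:
        if self.class_label not in ("tumor", "normal", "epithelial", "stromal", "unknown"):
            raise ValueError(f"unknown class_label {self.class_label!r}")
        if self.ptec is not None and not (0 <= self.ptec <= 100):
            raise ValueError(f"ptec {self.ptec} outside [0, 100]")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _frame_to_matrix(df: pd.DataFrame, scale: Scale, source: str) -> ExpressionMatrix:
    # exact float() conversion (bit-exact round trips); bad cells get coordinates
    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        try:
            numeric[col] = df[col].astype(float)
        except (ValueError, TypeError):
            for r, raw in enumerate(df[col]):
                try:
                    float(raw)
                except (ValueError, TypeError):
                    raise ParseError(
                        f"{source}: non-numeric value {raw!r} at gene "
                        f"{df.index[r]!r}, sample {col!r}"
                    ) from None
    n_before = len(numeric)
    numeric = numeric.dropna(axis=0, how="any")
    if len(numeric) < n_before:
        logger.info("%s: dropped %d rows with missing values", source, n_before - len(numeric))
    if numeric.index.has_duplicates:
        n_dup = len(numeric) - numeric.index.nunique()
        logger.info("%s: collapsed %d duplicate gene rows by mean", source, n_dup)
        numeric = numeric.groupby(level=0, sort=False).mean()
    logger.info("%s: loaded %d genes x %d samples", source, numeric.shape[0], numeric.shape[1])
    return ExpressionMatrix(
        [str(g) for g in numeric.index],
        [str(s) for s in numeric.columns],
        numeric.to_numpy(dtype=float),
        scale,
    )


def read_expression_matrix(
    path: str | Path, dialect: Literal["tsv", "gct"] = "tsv", scale: Scale = "linear"
) -> ExpressionMatrix:
    """Read a genes-by-samples matrix from TSV or GCT v1.2.

    TSV: header row of sample ids, first column gene ids.  GCT: two header
    lines (``#1.2`` then ``<genes> <samples>``), then ``Name``/``Description``
    columns followed by samples; the Description column is dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "gct":
        with open(path) as fh:
            first = fh.readline().strip()
        if not first.startswith("#1.2"):
            raise ParseError(f"{path}: line 1: expected GCT version tag '#1.2', got {first!r}")
        df = pd.read_csv(path, sep="\t", skiprows=2, index_col=0, dtype=object)
        if df.empty and df.columns.empty:
            raise ParseError(f"{path}: empty GCT body")
        if "Description" in df.columns:
            df = df.drop(columns="Description")
        elif len(df.columns) > 0:
            df = df.drop(columns=df.columns[0])  # GCT column 2 is Description by position
    elif dialect == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0, dtype=object)
        except pd.errors.EmptyDataError:
            raise ParseError(f"{path}: empty file") from None
        if df.columns.empty:
            raise ParseError(f"{path}: line 1: malformed header (no sample columns)")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return _frame_to_matrix(df, scale, str(path))


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a TSV that :func:`read_expression_matrix` round-trips bit-exactly."""
    df = matrix.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read sample metadata TSV (sample_id, class_label, ptec, slide_purities).

    ``slide_purities`` is semicolon-separated; an empty field within the list
    marks an unavailable slide reading.
    """
    df = pd.read_csv(path, sep="\t", dtype=object)
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: metadata requires a sample_id column")
    out: list[SampleMetadata] = []
    for _, row in df.iterrows():
        slides: list[float | None] | None = None
        raw = row.get("slide_purities")
        if isinstance(raw, str) and raw != "":
            slides = [float(tok) if tok.strip() != "" else None for tok in raw.split(";")]
        ptec_raw = row.get("ptec")
        ptec = float(ptec_raw) if isinstance(ptec_raw, str) and ptec_raw != "" else None
        out.append(
            SampleMetadata(
                sample_id=str(row["sample_id"]),
                class_label=str(row.get("class_label", "unknown") or "unknown"),
                slide_purities=slides,
                ptec=ptec,
            )
        )
    return out


def write_metadata(meta: Iterable[SampleMetadata], path: str | Path) -> None:
    rows = []
    for m in meta:
        slides = (
            ";".join("" if s is None else format(s, "g") for s in m.slide_purities)
            if m.slide_purities is not None
            else ""
        )
        rows.append(
            {
                "sample_id": m.sample_id,
                "class_label": m.class_label,
                "ptec": "" if m.ptec is None else format(m.ptec, "g"),
                "slide_purities": slides,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Probe collapse and PTEC resolution
# ---------------------------------------------------------------------------

def read_probe_map(path: str | Path) -> pd.DataFrame:
    """Two-column probe_id → gene_id table; multi-mapped probes occupy several rows."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = {"probe_id", "gene_id"}
    if not expected.issubset(df.columns):
        raise ParseError(f"{path}: probe map requires columns {sorted(expected)}")
    return df[["probe_id", "gene_id"]]


def collapse_probes(matrix: ExpressionMatrix, probe_map: pd.DataFrame) -> ExpressionMatrix:
    """Collapse a probe-level matrix to gene level.

    Probes with no gene mapping are dropped, probes mapped to more than one
    gene are dropped, and probes sharing a gene are averaged per sample.
    """
    pm = probe_map[["probe_id", "gene_id"]].dropna().astype(str).drop_duplicates()
    multi = pm.groupby("probe_id")["gene_id"].nunique()
    ambiguous = set(multi[multi > 1].index)
    if ambiguous:
        logger.info("collapse_probes: dropped %d multi-mapped probes", len(ambiguous))
    pm = pm[~pm["probe_id"].isin(ambiguous)]
    mapping = dict(zip(pm["probe_id"], pm["gene_id"]))

    keep = [i for i, p in enumerate(matrix.gene_ids) if p in mapping]
    if not keep:
        raise ValueError("no mappable probes")
    n_unmapped = matrix.n_genes - len(keep)
    if n_unmapped:
        logger.info("collapse_probes: dropped %d unmapped probes", n_unmapped)
    genes = [mapping[matrix.gene_ids[i]] for i in keep]
    df = pd.DataFrame(matrix.values[keep], index=genes, columns=matrix.sample_ids)
    collapsed = df.groupby(level=0, sort=True).mean()
    return ExpressionMatrix(
        [str(g) for g in collapsed.index],
        list(matrix.sample_ids),
        collapsed.to_numpy(dtype=float),
        matrix.scale,
    )


def rank_profile(sample_values: np.ndarray | Sequence[float], gene_ids: Sequence[str]) -> RankProfile:
    """Ascending within-sample ranks (rank 1 = lowest expression; ties averaged)."""
    values = np.asarray(sample_values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite values in sample")
    if len(values) != len(gene_ids):
        raise ValueError("values and gene_ids length mismatch")
    return RankProfile(list(gene_ids), rankdata(values, method="average"))


def resolve_ptec(meta: SampleMetadata) -> SampleMetadata | None:
    """Resolve per-sample PTEC as the mean of per-slide tumor-cell percentages.

    Returns ``None`` (sample dropped) when any slide reading is unavailable,
    matching the preprocessing rule for multi-slide samples.  A sample that
    already carries ``ptec`` and no slide readings is returned as is.
    """
    if meta.slide_purities is not None:
        if any(s is None for s in meta.slide_purities) or not meta.slide_purities:
            logger.info("resolve_ptec: dropping %s (missing slide purity)", meta.sample_id)
            return None
        return replace(meta, ptec=float(np.mean([float(s) for s in meta.slide_purities])))
    if meta.ptec is not None:
        return meta
    logger.info("resolve_ptec: dropping %s (no purity information)", meta.sample_id)
    return None
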