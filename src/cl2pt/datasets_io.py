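"""Two-domain expression/response data model and pre-processing.

The pipeline works on a *source* domain (drug-screened cell lines with
IC50-derived binary response) and a *target* domain (patient tumors or
patient-derived xenografts with clinical response).  Expression matrices
are genes x samples, log-scale expected.  Labels are 1 = sensitive /
responder, 0 = resistant / non-responder throughout.
"""

from __future__ import annotations

import difflib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Domain = Literal["source", "target"]


class DataError(ValueError):
    """Raised for malformed or inconsistent input data."""


@dataclass
class ExpressionMatrix:
    """A genes x samples real-valued expression matrix with identifiers."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("values must be a 2-D array (genes x samples)")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DataError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataError("duplicate sample identifiers")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def gene_row(self, gene: str) -> np.ndarray:
        try:
            i = self.gene_ids.index(gene)
        except ValueError:
            raise DataError(f"gene {gene!r} not present") from None
        return self.values[i]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise DataError(f"genes not present: {missing[:10]}")
        rows = [index[g] for g in genes]
        return ExpressionMatrix(list(genes), list(self.sample_ids), self.values[rows])

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(list(self.gene_ids), list(self.sample_ids), self.values.copy())


@dataclass
class ResponseLabels:
    """Binary drug response per sample (1 = sensitive/responder)."""

    sample_ids: list[str]
    y: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.y = np.asarray(self.y)
        if self.y.ndim != 1 or len(self.y) != len(self.sample_ids):
            raise DataError("labels must be a vector aligned with sample_ids")
        if not np.isin(self.y, [0, 1]).all():
            raise DataError("labels must be binary (0 = resistant, 1 = sensitive)")
        self.y = self.y.astype(int)

    @property
    def n_sensitive(self) -> int:
        return int(self.y.sum())

    @property
    def n_resistant(self) -> int:
        return int((1 - self.y).sum())


@dataclass
class DomainDataset:
    """An expression matrix paired with response labels for one domain."""

    expr: ExpressionMatrix
    labels: ResponseLabels
    domain: Domain
    drug_name: str = ""

    def __post_init__(self) -> None:
        if self.expr.sample_ids != self.labels.sample_ids:
            raise DataError("expression and label sample_ids differ (order matters)")
        if self.domain not in ("source", "target"):
            raise DataError(f"domain must be 'source' or 'target', got {self.domain!r}")

    def class_values(self, gene_index: int, label: int) -> np.ndarray:
        """Expression values of one gene restricted to one response class."""
        return self.expr.values[gene_index, self.labels.y == label]


# ---------------------------------------------------------------------------
# I/O


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        head = fh.readline()
    return "\t" if head.count("\t") >= head.count(",") else ","


def read_expression_matrix(
    path: str | Path,
    orientation: Literal["genes_in_rows", "samples_in_rows"] = "genes_in_rows",
) -> ExpressionMatrix:
    """Read a delimited expression table.

    First column holds row identifiers, header holds column identifiers.
    Duplicate gene rows are collapsed by their mean.  Decimal separator is
    always the dot, independent of locale.
    """
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise DataError(f"empty or missing expression file: {path}")
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise DataError(f"expression file has no data body: {path}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[int(np.flatnonzero(bad.to_numpy())[0])]
            raise DataError(
                f"non-numeric value in {path.name} at row {row!r}, column {col!r}"
            )
        df[col] = coerced
    if orientation == "samples_in_rows":
        df = df.T
    df.index = df.index.map(str)
    if df.index.duplicated().any():
        n_dup = int(df.index.duplicated().sum())
        logger.info("collapsing %d duplicate gene rows by mean", n_dup)
        order = list(dict.fromkeys(df.index))
        df = df.groupby(level=0, sort=False).mean().loc[order]
    return ExpressionMatrix.from_frame(df)


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path, sep: str = "\t") -> None:
    expr.to_frame().to_csv(path, sep=sep, index_label="gene_id", float_format="%.17g")


def read_response_table(
    path: str | Path, max_conc: float | None = None
) -> ResponseLabels:
    """Read a two-column (sample_id, label-or-IC50) table.

    If ``max_conc`` is given the second column is treated as IC50 and
    dichotomized; otherwise it must already be binary.
    """
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise DataError(f"empty or missing response file: {path}")
    df = pd.read_csv(path, sep=_sniff_sep(path))
    if df.shape[1] < 2:
        raise DataError(f"response file needs two columns, got {df.shape[1]}")
    ids = df.iloc[:, 0].astype(str).tolist()
    vals = df.iloc[:, 1].to_numpy(dtype=float)
    if max_conc is not None:
        return dichotomize_ic50(vals, max_conc, sample_ids=ids)
    return ResponseLabels(ids, vals.astype(int))


# ---------------------------------------------------------------------------
# Pre-processing operations


def dichotomize_ic50(
    ic50: Sequence[float] | np.ndarray,
    max_conc: float,
    sample_ids: Sequence[str] | None = None,
) -> ResponseLabels:
    """Binarize IC50: sensitive (1) iff IC50 <= maximum screening concentration."""
    ic50 = np.asarray(ic50, dtype=float)
    if max_conc <= 0:
        raise DataError("max_conc must be positive")
    if not np.isfinite(ic50).all():
        bad = np.flatnonzero(~np.isfinite(ic50))
        ids = sample_ids or [str(i) for i in range(len(ic50))]
        raise DataError(f"non-finite IC50 for samples: {[ids[i] for i in bad[:10]]}")
    y = (ic50 <= max_conc).astype(int)
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(len(ic50))]
    return ResponseLabels(list(sample_ids), y)


def standardize_genes(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Center and scale each gene to mean 0, unit sample s.d. (ddof=1).

    Genes with zero variance become all-zero rows so downstream matrices
    stay finite; such genes can never pass differential-expression ranking.
    """
    if expr.n_samples < 2:
        raise DataError("standardization needs at least 2 samples per gene")
    mean = expr.values.mean(axis=1, keepdims=True)
    sd = expr.values.std(axis=1, ddof=1, keepdims=True)
    centered = expr.values - mean
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(sd > 0, centered / np.where(sd > 0, sd, 1.0), 0.0)
    return ExpressionMatrix(list(expr.gene_ids), list(expr.sample_ids), out)


def normalize_housekeeping(expr: ExpressionMatrix, hk_gene: str = "GAPDH") -> ExpressionMatrix:
    """Subtract the housekeeping gene's value from every sample column.

    On log-scale expression this is division by the housekeeping gene; the
    housekeeping row itself becomes identically zero.
    """
    if hk_gene not in expr.gene_ids:
        near = difflib.get_close_matches(hk_gene, expr.gene_ids, n=3)
        raise DataError(
            f"housekeeping gene {hk_gene!r} not found; near matches: {near}"
        )
    hk = expr.gene_row(hk_gene)
    return ExpressionMatrix(
        list(expr.gene_ids), list(expr.sample_ids), expr.values - hk[None, :]
    )


def intersect_genes(
    a: ExpressionMatrix, b: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both matrices to the shared genes, in a's gene order."""
    b_set = set(b.gene_ids)
    common = [g for g in a.gene_ids if g in b_set]
    if not common:
        raise DataError("no genes in common between the two matrices")
    logger.info("gene intersection: %d genes in common", len(common))
    return a.subset_genes(common), b.subset_genes(common)


def harmonize_domains(
    source: ExpressionMatrix,
    target: ExpressionMatrix,
    method: Literal["location_scale", "none"] = "location_scale",
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Match per-gene location and scale across the two domains.

    ``location_scale`` centers and scales every gene within each domain
    separately, a deliberately simple batch harmonizer; ``none`` passes the
    inputs through untouched (for data already harmonized upstream).
    """
    if source.gene_ids != target.gene_ids:
        raise DataError("gene sets/order differ; run intersect_genes first")
    if method == "none":
        return source, target
    if method != "location_scale":
        raise DataError(f"unknown harmonization method {method!r}")
    return standardize_genes(source), standardize_genes(target)


def load_domain_dataset(
    expr_path: str | Path,
    resp_path: str | Path,
    domain: Domain,
    drug_name: str = "",
    max_conc: float | None = None,
    orientation: Literal["genes_in_rows", "samples_in_rows"] = "genes_in_rows",
) -> DomainDataset:
    """Read an expression matrix and response table into one DomainDataset.

    Samples are aligned by identifier; samples lacking either expression or
    response are dropped with a log message.
    """
    expr = read_expression_matrix(expr_path, orientation=orientation)
    labels = read_response_table(resp_path, max_conc=max_conc)
    lab_map = dict(zip(labels.sample_ids, labels.y))
    keep = [s for s in expr.sample_ids if s in lab_map]
    if not keep:
        raise DataError("no samples shared between expression and response tables")
    if len(keep) < expr.n_samples or len(keep) < len(labels.sample_ids):
        logger.info(
            "aligning samples: %d kept of %d expression / %d response",
            len(keep), expr.n_samples, len(labels.sample_ids),
        )
    cols = [expr.sample_ids.index(s) for s in keep]
    expr = ExpressionMatrix(list(expr.gene_ids), keep, expr.values[:, cols])
    labels = ResponseLabels(keep, np.array([lab_map[s] for s in keep]))
    return DomainDataset(expr, labels, domain, drug_name)
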