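"""Expression-matrix and sample-sheet I/O, validation, filtering and log transform.

The on-disk formats are plain tab-delimited text: the matrix has library ids
as header and gene ids in the first column; the sample sheet has columns
``library``, ``tissue``, ``animal``, ``state`` with state in {PRE, POST}.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

STATES = ("PRE", "POST")

DEFAULT_RPKM_THRESHOLD = 0.2


@dataclass
class ExpressionMatrix:
    """Genes x libraries matrix of nonnegative RPKM values."""

    gene_ids: list[str]
    library_ids: list[str]
    values: np.ndarray  # shape (n_genes, n_libraries)

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.library_ids = [str(l) for l in self.library_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.library_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.library_ids)} libraries"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValidationError(f"duplicate gene ids: {dupes}")
        if len(set(self.library_ids)) != len(self.library_ids):
            raise ValidationError("duplicate library ids")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValidationError("matrix contains non-finite values")
        if self.values.size and self.values.min() < 0:
            raise ValidationError("matrix contains negative values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_libraries(self) -> int:
        return len(self.library_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.library_ids)

    def write_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "gene"
        df.to_csv(path, sep="\t")


@dataclass
class SampleSheet:
    """Per-library metadata: tissue, animal and physiological state."""

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"library", "tissue", "animal", "state"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValidationError(f"sample sheet missing columns: {sorted(missing)}")
        self.frame = self.frame.reset_index(drop=True).astype(
            {"library": str, "tissue": str, "animal": str, "state": str}
        )
        if self.frame["library"].duplicated().any():
            raise ValidationError("duplicate libraries in sample sheet")
        bad_states = set(self.frame["state"]) - set(STATES)
        if bad_states:
            raise ValidationError(f"unknown states: {sorted(bad_states)}")

    @property
    def libraries(self) -> list[str]:
        return list(self.frame["library"])

    @property
    def tissues(self) -> list[str]:
        return sorted(self.frame["tissue"].unique())

    @property
    def animals(self) -> list[str]:
        return sorted(self.frame["animal"].unique())

    def mask(self, tissue: str | None = None, state: str | None = None) -> np.ndarray:
        m = np.ones(len(self.frame), dtype=bool)
        if tissue is not None:
            m &= (self.frame["tissue"] == tissue).to_numpy()
        if state is not None:
            m &= (self.frame["state"] == state).to_numpy()
        return m

    def reordered(self, library_order: list[str]) -> "SampleSheet":
        idx = self.frame.set_index("library").loc[library_order].reset_index()
        return SampleSheet(idx)

    def write_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def read_expression(matrix_path, sheet_path) -> tuple[ExpressionMatrix, SampleSheet]:
    """Read and cross-validate a matrix/sheet pair, harmonizing library order.

    Raises :class:`ValidationError` listing offending libraries if the two
    files disagree, and :class:`ParseError` with coordinates for a negative
    or non-numeric matrix entry.
    """
    raw = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype=str)
    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        parsed = pd.to_numeric(raw[col], errors="coerce")
        bad = np.where(parsed.isna().to_numpy())[0]
        if bad.size:
            i = int(bad[0])
            raise ParseError(
                f"non-numeric value {raw[col].iloc[i]!r} at gene "
                f"{raw.index[i]!r}, library {col!r}"
            )
        neg = np.where((parsed < 0).to_numpy())[0]
        if neg.size:
            i = int(neg[0])
            raise ParseError(
                f"negative value {parsed.iloc[i]} at gene {raw.index[i]!r}, "
                f"library {col!r}"
            )
        values[:, j] = parsed.to_numpy()

    sheet_df = pd.read_csv(sheet_path, sep="\t", dtype=str)
    sheet = SampleSheet(sheet_df)

    matrix_libs = [str(c) for c in raw.columns]
    sheet_libs = set(sheet.libraries)
    only_matrix = sorted(set(matrix_libs) - sheet_libs)
    only_sheet = sorted(sheet_libs - set(matrix_libs))
    if only_matrix or only_sheet:
        raise ValidationError(
            f"library mismatch: in matrix only {only_matrix}, in sheet only {only_sheet}"
        )

    mat = ExpressionMatrix([str(g) for g in raw.index], matrix_libs, values)
    return mat, sheet.reordered(matrix_libs)


def filter_expressed(
    mat: ExpressionMatrix,
    sheet: SampleSheet,
    threshold: float = DEFAULT_RPKM_THRESHOLD,
) -> set[str]:
    """Genes whose mean RPKM in at least one (tissue, state) cell is >= threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if mat.n_genes == 0:
        return set()
    keep = np.zeros(mat.n_genes, dtype=bool)
    for tissue in sheet.tissues:
        for state in STATES:
            m = sheet.mask(tissue=tissue, state=state)
            if not m.any():
                continue
            keep |= mat.values[:, m].mean(axis=1) >= threshold
    return {g for g, k in zip(mat.gene_ids, keep) if k}


def log_transform(
    mat: ExpressionMatrix, floor: float = DEFAULT_RPKM_THRESHOLD
) -> np.ndarray:
    """Base-2 log of RPKM, flooring values at the detection threshold.

    Flooring keeps unexpressed entries at a finite log2(floor) instead of -inf.
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    return np.log2(np.maximum(mat.values, floor))
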