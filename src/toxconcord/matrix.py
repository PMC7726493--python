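"""Expression matrix container and plain-text I/O.

The central data structure is :class:`ExpressionMatrix`: a probes x samples
table of log2 intensities plus a per-sample annotation sheet (cell line,
treatment, replicate).  Matrices are exchanged as tab-delimited text (first
column probe IDs, header row of sample IDs) and the sample sheet as CSV with
columns ``sample_id, cell_line, treatment, replicate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

SAMPLE_SHEET_COLUMNS = ("cell_line", "treatment", "replicate")


class MatrixValidationError(ValueError):
    """Raised when an expression matrix or sample sheet is inconsistent."""


@dataclass
class ExpressionMatrix:
    """Log2 expression values with sample annotations.

    Parameters
    ----------
    values
        DataFrame of log2 intensities, indexed by probe ID with one column
        per sample ID.
    samples
        DataFrame indexed by sample ID with columns ``cell_line``,
        ``treatment`` and ``replicate``; rows must match the columns of
        ``values`` one-to-one.
    """

    values: pd.DataFrame
    samples: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise MatrixValidationError(f"duplicate probe identifier: {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise MatrixValidationError(f"duplicate sample identifier: {dup!r}")
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in self.samples.columns]
        if missing:
            raise MatrixValidationError(
                f"sample sheet is missing columns: {missing}"
            )
        if set(self.samples.index) != set(self.values.columns):
            extra = set(self.values.columns) ^ set(self.samples.index)
            raise MatrixValidationError(
                f"sample sheet and matrix columns disagree on: {sorted(extra)}"
            )
        # keep annotation rows in matrix column order
        self.samples = self.samples.loc[self.values.columns]

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def treatments(self) -> list[str]:
        return list(pd.unique(self.samples["treatment"]))

    def samples_for(self, treatment: str) -> list[str]:
        """Sample IDs carrying the given treatment label.

        Raises a :class:`KeyError` naming the label when absent.
        """
        mask = self.samples["treatment"] == treatment
        if not mask.any():
            raise KeyError(
                f"treatment label {treatment!r} not present in sample sheet "
                f"(available: {self.treatments})"
            )
        return list(self.samples.index[mask])

    def subset_probes(self, probe_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(probe_ids)], self.samples.copy())

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        ids = list(sample_ids)
        return ExpressionMatrix(self.values[ids], self.samples.loc[ids].copy())


def write_matrix(matrix: ExpressionMatrix, matrix_path, sample_sheet_path) -> None:
    """Write the matrix as tab-delimited text and the sample sheet as CSV."""
    out = matrix.values.copy()
    out.index.name = "probe_id"
    out.to_csv(matrix_path, sep="\t", float_format="%.6f")
    sheet = matrix.samples.copy()
    sheet.index.name = "sample_id"
    sheet.to_csv(sample_sheet_path)


def read_matrix(matrix_path, sample_sheet_path) -> ExpressionMatrix:
    """Read a tab-delimited matrix plus CSV sample sheet back into memory."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    samples = pd.read_csv(sample_sheet_path, index_col=0)
    samples.index = samples.index.astype(str)
    values.columns = values.columns.astype(str)
    return ExpressionMatrix(values, samples)


def read_gene_list(path) -> list[str]:
    """One identifier per line; blank lines ignored."""
    text = Path(path).read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]


def write_gene_list(ids, path) -> None:
    Path(path).write_text("".join(f"{i}\n" for i in ids))
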