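"""Reading, validating and writing gene × sample TPM matrices.

The co-expression workflow consumes a dense matrix of non-negative TPM
(transcripts per million) values with locus identifiers as rows and
tissue/stage labels as columns.  Everything downstream — the zero-mean
filter, the mean-normalized profiles, the Δsum ranking — operates on the
samples present in the matrix *at the time of the call*, so sample
subsetting is an explicit, separate step (:func:`subset_samples`).

Missing cells are not permitted: the input is a dense quantification
table and absence of expression must be encoded upstream as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MatrixValidationError",
    "ExpressionMatrix",
    "load_tpm_matrix",
    "write_tpm_matrix",
    "subset_samples",
    "gene_means",
    "write_gene_means",
    "drop_unexpressed",
]


class MatrixValidationError(ValueError):
    """Raised when an expression matrix violates its invariants."""


def _find_duplicates(labels: pd.Index) -> list[str]:
    dup = labels[labels.duplicated()]
    return sorted(set(str(d) for d in dup))


@dataclass(frozen=True)
class ExpressionMatrix:
    """A validated gene × sample matrix of non-negative TPM values.

    Parameters
    ----------
    data
        DataFrame with unique gene identifiers as the index and unique
        sample (tissue/stage) labels as the columns.  All values must be
        finite and ≥ 0, with at least one gene and at least two samples
        (a profile over a single sample carries no pattern).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        dup_genes = _find_duplicates(df.index)
        if dup_genes:
            raise MatrixValidationError(
                f"duplicate gene identifier(s): {', '.join(dup_genes)}"
            )
        dup_samples = _find_duplicates(df.columns)
        if dup_samples:
            raise MatrixValidationError(
                f"duplicate sample label(s): {', '.join(dup_samples)}"
            )
        if df.shape[0] < 1:
            raise MatrixValidationError("matrix must contain at least 1 gene")
        if df.shape[1] < 2:
            raise MatrixValidationError(
                f"matrix must contain at least 2 samples, got {df.shape[1]}"
            )
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            # locate the first non-numeric cell for the error message
            for gene in df.index:
                for sample in df.columns:
                    try:
                        float(df.at[gene, sample])
                    except (TypeError, ValueError):
                        raise MatrixValidationError(
                            f"non-numeric value {df.at[gene, sample]!r} at "
                            f"(gene={gene}, sample={sample})"
                        ) from None
            raise MatrixValidationError("non-numeric values in matrix")
        bad = ~np.isfinite(values)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise MatrixValidationError(
                f"non-finite value at (gene={df.index[i]}, sample={df.columns[j]})"
            )
        neg = values < 0
        if neg.any():
            i, j = np.argwhere(neg)[0]
            raise MatrixValidationError(
                f"negative TPM value {values[i, j]} at "
                f"(gene={df.index[i]}, sample={df.columns[j]})"
            )
        object.__setattr__(self, "data", df.astype(float))

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.data.index]

    @property
    def sample_labels(self) -> list[str]:
        return [str(s) for s in self.data.columns]

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()


def load_tpm_matrix(path: str | Path, *, transpose: bool = False) -> ExpressionMatrix:
    """Read a TSV matrix (first row sample labels, first column gene ids).

    With ``transpose=True`` the file is interpreted as samples-as-rows
    and flipped into the canonical genes-as-rows orientation.  Row and
    column order are preserved from the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"matrix file not found: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if transpose:
        df = df.T
    return ExpressionMatrix(df)


def write_tpm_matrix(
    matrix: ExpressionMatrix, path: str | Path, *, sig_digits: int = 6
) -> None:
    """Write the matrix as TSV with at least ``sig_digits`` significant digits."""
    if sig_digits < 6:
        raise ValueError("sig_digits must be >= 6 to guarantee round-trips")
    matrix.data.to_csv(path, sep="\t", float_format=f"%.{sig_digits}g")


def subset_samples(matrix: ExpressionMatrix, keep: Sequence[str]) -> ExpressionMatrix:
    """Restrict the matrix to ``keep`` (in that order); genes unchanged."""
    keep = list(keep)
    if len(keep) < 2:
        raise MatrixValidationError(
            f"at least 2 samples must be kept, got {len(keep)}"
        )
    known = set(matrix.sample_labels)
    unknown = [k for k in keep if k not in known]
    if unknown:
        raise MatrixValidationError(
            f"unknown sample label(s): {', '.join(unknown)}"
        )
    if len(set(keep)) != len(keep):
        raise MatrixValidationError("sample labels in keep must be unique")
    return ExpressionMatrix(matrix.data.loc[:, keep])


def gene_means(matrix: ExpressionMatrix) -> pd.Series:
    """Arithmetic mean TPM per gene over the matrix's current samples.

    Returns a Series named ``mean_tpm`` indexed by gene identifier.  A
    mean of exactly 0 occurs iff every value for that gene is 0, since
    TPM values are non-negative.
    """
    means = matrix.data.mean(axis=1)
    means.name = "mean_tpm"
    means.index.name = "gene_id"
    return means


def write_gene_means(means: pd.Series, path: str | Path) -> None:
    """Write a two-column TSV (gene_id, mean_tpm)."""
    means.to_csv(path, sep="\t", header=True)


def drop_unexpressed(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Remove genes whose mean over the current samples is zero.

    Genes with a mean of zero are expressed in no sample and carry no
    profile; they are eliminated before normalization.  Gene order is
    preserved.  Raises if nothing would remain.
    """
    means = gene_means(matrix)
    keep = means > 0
    if not keep.any():
        raise MatrixValidationError(
            "all genes have zero mean expression; nothing to analyse"
        )
    return ExpressionMatrix(matrix.data.loc[keep])
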