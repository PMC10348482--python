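"""Reading, validation and writing of binary genome x function matrices.

The expected on-disk layout follows KEGG-Decoder-style output: a header row
of function names, a first column of genome identifiers, and 0/1 cells
indicating pathway presence calls. Rows are genomes, columns are functions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_TRUTHY = {"1", "1.0", "true"}
_FALSY = {"0", "0.0", "false"}


class MatrixValidationError(ValueError):
    """Raised when an input matrix violates the binary-matrix contract."""


@dataclass
class BinaryMatrix:
    """An observed G x F presence/absence matrix with row/column labels.

    Attributes
    ----------
    genome_ids : list of str
        Unique row labels (length G).
    function_ids : list of str
        Unique column labels (length F).
    values : ndarray of shape (G, F)
        Entries are exactly 0 or 1 (stored as uint8).
    """

    genome_ids: list[str]
    function_ids: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.genome_ids = [str(g) for g in self.genome_ids]
        self.function_ids = [str(f) for f in self.function_ids]
        if len(self.genome_ids) < 1:
            raise MatrixValidationError("matrix must have at least one genome")
        if len(self.function_ids) < 1:
            raise MatrixValidationError("matrix must have at least one function")
        if len(set(self.genome_ids)) != len(self.genome_ids):
            dupes = _duplicates(self.genome_ids)
            raise MatrixValidationError(f"duplicate genome IDs: {dupes}")
        if len(set(self.function_ids)) != len(self.function_ids):
            dupes = _duplicates(self.function_ids)
            raise MatrixValidationError(f"duplicate function IDs: {dupes}")
        values = np.asarray(self.values)
        if values.shape != (len(self.genome_ids), len(self.function_ids)):
            raise MatrixValidationError(
                f"values shape {values.shape} does not match "
                f"{len(self.genome_ids)} genomes x {len(self.function_ids)} functions"
            )
        bad = ~np.isin(values, (0, 1))
        if bad.any():
            g, f = np.argwhere(bad)[0]
            raise MatrixValidationError(
                f"non-binary cell {values[g, f]!r} at genome "
                f"{self.genome_ids[g]!r}, function {self.function_ids[f]!r}"
            )
        self.values = values.astype(np.uint8)
        zero_rows = int((self.values.sum(axis=1) == 0).sum())
        zero_cols = int((self.values.sum(axis=0) == 0).sum())
        # all-zero rows/columns still inform the per-aspect presence
        # probabilities, so they are kept rather than dropped
        if zero_rows:
            logger.warning("matrix has %d all-zero genome row(s); retained", zero_rows)
        if zero_cols:
            logger.warning("matrix has %d all-zero function column(s); retained", zero_cols)

    @property
    def G(self) -> int:
        return len(self.genome_ids)

    @property
    def F(self) -> int:
        return len(self.function_ids)

    def genome_index(self, genome_id: str) -> int:
        try:
            return self.genome_ids.index(genome_id)
        except ValueError:
            raise KeyError(f"unknown genome ID {genome_id!r}") from None

    def function_index(self, function_id: str) -> int:
        try:
            return self.function_ids.index(function_id)
        except ValueError:
            raise KeyError(f"unknown function ID {function_id!r}") from None

    def column_density(self) -> np.ndarray:
        """Fraction of genomes carrying each function."""
        return self.values.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.genome_ids, name="genome"),
            columns=self.function_ids,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinaryMatrix):
            return NotImplemented
        return (
            self.genome_ids == other.genome_ids
            and self.function_ids == other.function_ids
            and np.array_equal(self.values, other.values)
        )


def _duplicates(items: list[str]) -> list[str]:
    seen: set[str] = set()
    out = []
    for x in items:
        if x in seen and x not in out:
            out.append(x)
        seen.add(x)
    return out


def _sep_for(dialect: str) -> str:
    if dialect == "tsv":
        return "\t"
    if dialect == "csv":
        return ","
    raise ValueError(f"unknown dialect {dialect!r}; expected 'tsv' or 'csv'")


def _parse_cell(raw: object, genome: str, function: str,
                binarize_threshold: float | None) -> int:
    text = str(raw).strip().lower()
    if text in _TRUTHY:
        return 1
    if text in _FALSY:
        return 0
    if binarize_threshold is not None:
        try:
            return 1 if float(text) >= binarize_threshold else 0
        except ValueError:
            pass
    raise MatrixValidationError(
        f"non-binary cell {raw!r} at genome {genome!r}, function {function!r}"
        + ("" if binarize_threshold is not None
           else " (pass binarize_threshold to threshold continuous completeness values)")
    )


def read_matrix(path: str | Path, dialect: str = "tsv", *,
                transpose: bool = False,
                binarize_threshold: float | None = None) -> BinaryMatrix:
    """Read a delimited presence/absence table into a :class:`BinaryMatrix`.

    Parameters
    ----------
    path : path
        Delimited text file: header of function names, first column genome
        IDs, remaining cells 0/1 (``0``/``1``, ``0.0``/``1.0`` and
        ``TRUE``/``FALSE`` are accepted, case-insensitively).
    dialect : {"tsv", "csv"}
        Field separator.
    transpose : bool
        Set when the file stores functions as rows and genomes as columns.
        Orientation is never guessed.
    binarize_threshold : float, optional
        When given, continuous cells (e.g. KEGG-Decoder completeness
        fractions) are mapped to 1 iff value >= threshold. By default
        continuous input is refused: completeness thresholds belong to the
        upstream annotation step and silently re-thresholding would change
        results.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _sep_for(dialect)
    try:
        df = pd.read_csv(path, sep=sep, header=0, index_col=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise MatrixValidationError(f"malformed table in {path}: {exc}") from exc
    if df.isna().any().any():
        row = df.index[df.isna().any(axis=1)][0]
        raise MatrixValidationError(f"ragged or missing cells in row {row!r} of {path}")
    if transpose:
        df = df.T
    genome_ids = [str(g) for g in df.index]
    function_ids = [str(f) for f in df.columns]
    values = np.empty(df.shape, dtype=np.uint8)
    raw = df.to_numpy()
    for i, g in enumerate(genome_ids):
        for j, f in enumerate(function_ids):
            values[i, j] = _parse_cell(raw[i, j], g, f, binarize_threshold)
    return BinaryMatrix(genome_ids, function_ids, values)


def write_matrix(matrix: BinaryMatrix, path: str | Path, dialect: str = "tsv") -> None:
    """Write a matrix in the same layout :func:`read_matrix` accepts."""
    sep = _sep_for(dialect)
    matrix.to_frame().to_csv(Path(path), sep=sep)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a pipeline output table as TSV without the index."""
    df.to_csv(Path(path), sep="\t", index=False)
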