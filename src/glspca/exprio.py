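"""Expression-matrix I/O and core containers.

The in-memory convention throughout the package is fixed: an expression
matrix ``X`` has shape ``m x n`` with the ``m`` genes (variables) on rows
and the ``n`` samples on columns.  Files may store either orientation;
readers normalize to genes-on-rows.

No normalization or log-transform is ever applied implicitly.  The
optional transforms :func:`log2_transform` and :func:`zscore_genes` are
explicit, opt-in steps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ReferenceGeneTable",
    "GeneRanking",
    "LabelTable",
    "read_expression",
    "write_expression",
    "read_labels",
    "align_labels",
    "read_reference_table",
    "write_gene_ranking",
    "read_gene_ranking",
    "log2_transform",
    "zscore_genes",
]


class ExpressionIOError(ValueError):
    """Raised for malformed or inconsistent expression-data files."""


def _detect_delimiter(header_line: str) -> str:
    # TCGA-style exports come as either TSV or CSV; tab wins when both occur
    # because sample ids may legally contain commas but never tabs.
    if "\t" in header_line:
        return "\t"
    if "," in header_line:
        return ","
    raise ExpressionIOError(
        "could not detect delimiter (no tab or comma in header line)"
    )


@dataclass(frozen=True)
class ExpressionMatrix:
    """A validated genes x samples real matrix.

    Parameters
    ----------
    values
        Real matrix of shape ``(m, n)``; genes on rows, samples on columns.
    gene_ids
        ``m`` unique gene identifiers.
    sample_ids
        ``n`` unique sample identifiers.
    """

    values: np.ndarray
    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", tuple(map(str, self.gene_ids)))
        object.__setattr__(self, "sample_ids", tuple(map(str, self.sample_ids)))
        if values.ndim != 2:
            raise ExpressionIOError(f"expected a 2-D matrix, got ndim={values.ndim}")
        m, n = values.shape
        if m < 2 or n < 2:
            raise ExpressionIOError(f"need at least 2 genes and 2 samples, got {m}x{n}")
        if len(self.gene_ids) != m:
            raise ExpressionIOError(
                f"{len(self.gene_ids)} gene ids for {m} rows"
            )
        if len(self.sample_ids) != n:
            raise ExpressionIOError(
                f"{len(self.sample_ids)} sample ids for {n} columns"
            )
        for kind, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                seen: set[str] = set()
                dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
                raise ExpressionIOError(f"duplicate {kind} id: {dup!r}")
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ExpressionIOError(
                "non-finite value at gene "
                f"{self.gene_ids[bad[0]]!r}, sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def transpose(self) -> "ExpressionMatrix":
        """Swap the roles of genes and samples (used by orientation tests)."""
        return ExpressionMatrix(self.values.T, self.sample_ids, self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.sample_ids)
        )


@dataclass(frozen=True)
class ReferenceGeneTable:
    """Map from gene id to a nonnegative relevance score.

    Mirrors curated disease-gene tables (e.g. GeneCards exports) used to
    judge a ranked gene list: membership gives identification accuracy,
    the scores sum into the total relevance score.
    """

    entries: Mapping[str, float]

    def __post_init__(self) -> None:
        entries = dict(self.entries)
        for gene, score in entries.items():
            score = float(score)
            if not np.isfinite(score) or score < 0:
                raise ExpressionIOError(
                    f"reference score for {gene!r} must be finite and >= 0, got {score}"
                )
            entries[gene] = score
        object.__setattr__(self, "entries", entries)

    def __contains__(self, gene: str) -> bool:
        return gene in self.entries

    def score(self, gene: str) -> float:
        """Relevance score of ``gene``; 0 when absent from the table."""
        return self.entries.get(gene, 0.0)


@dataclass(frozen=True)
class GeneRanking:
    """Genes ordered by descending score.

    ``gene_ids[i]`` has score ``scores[i]``; the sequence is already sorted
    descending, ties broken by the gene's position in the source matrix.
    """

    gene_ids: tuple[str, ...]
    scores: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "gene_ids", tuple(map(str, self.gene_ids)))
        if len(self.gene_ids) != scores.shape[0]:
            raise ExpressionIOError("gene_ids and scores length mismatch")
        if scores.size == 0:
            raise ExpressionIOError("empty gene ranking")
        if not np.isfinite(scores).all():
            raise ExpressionIOError("non-finite gene score")
        if np.any(np.diff(scores) > 0):
            raise ExpressionIOError("ranking scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass(frozen=True)
class LabelTable:
    """Sample class labels with both original strings and integer codes."""

    sample_ids: tuple[str, ...]
    codes: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes, dtype=int)
        object.__setattr__(self, "codes", codes)
        if len(self.sample_ids) != codes.shape[0]:
            raise ExpressionIOError("sample_ids and codes length mismatch")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)


def read_expression(
    path: str | Path,
    delimiter: str | None = None,
    genes_on_rows: bool = True,
) -> ExpressionMatrix:
    """Read a delimited expression matrix with row and column labels.

    The first row holds sample ids (or gene ids when ``genes_on_rows`` is
    false) and the first column holds the other axis' ids.  The delimiter
    is auto-detected from the header line unless given.

    Raises
    ------
    ExpressionIOError
        On non-numeric cells (named by row and column), duplicate ids, or
        missing values.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = delimiter or _detect_delimiter(header)
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    raw.index = raw.index.astype(str)
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().to_numpy()
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        cell = raw.iat[i, j]
        if cell.strip() in ("", "NA", "NaN", "nan", "null"):
            raise ExpressionIOError(
                f"missing value at row {raw.index[i]!r}, column {raw.columns[j]!r}"
            )
        raise ExpressionIOError(
            f"non-numeric cell {cell!r} at row {raw.index[i]!r}, "
            f"column {raw.columns[j]!r}"
        )
    # python float() is correctly rounded, unlike the fast pandas parser,
    # so write -> read round-trips bitwise
    values = np.vectorize(float, otypes=[float])(raw.to_numpy())
    row_ids = tuple(raw.index)
    col_ids = tuple(raw.columns.astype(str))
    if not genes_on_rows:
        values = values.T
        row_ids, col_ids = col_ids, row_ids
    return ExpressionMatrix(values, row_ids, col_ids)


def write_expression(
    matrix: ExpressionMatrix, path: str | Path, delimiter: str = "\t"
) -> None:
    """Write a matrix as delimited text, genes on rows, full double precision."""
    _write_frame(matrix.to_frame(), Path(path), delimiter, index_label="gene_id")


def _write_frame(
    frame: pd.DataFrame, path: Path, delimiter: str, index_label: str | None
) -> None:
    # repr() of a float is the shortest string that round-trips the double,
    # so read(write(x)) is exact.
    frame = frame.map(lambda v: repr(float(v)) if isinstance(v, (int, float, np.floating)) else v)
    frame.to_csv(path, sep=delimiter, index_label=index_label)


def write_gene_ranking(ranking: GeneRanking, path: str | Path) -> None:
    """Write a ranking as TSV with columns rank, gene_id, score (descending)."""
    if len(ranking) == 0:
        raise ExpressionIOError("cannot write an empty ranking")
    with open(path, "w") as fh:
        fh.write("rank\tgene_id\tscore\n")
        for rank, (gene, score) in enumerate(zip(ranking.gene_ids, ranking.scores), 1):
            fh.write(f"{rank}\t{gene}\t{float(score)!r}\n")


def read_gene_ranking(path: str | Path) -> GeneRanking:
    frame = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if not {"rank", "gene_id", "score"}.issubset(frame.columns):
        raise ExpressionIOError(f"{path}: expected columns rank, gene_id, score")
    return GeneRanking(tuple(frame["gene_id"]), frame["score"].to_numpy(float))


def read_labels(path: str | Path, delimiter: str | None = None) -> LabelTable:
    """Read a two-column (sample id, class label) file.

    Class labels may be arbitrary strings; they are re-encoded as
    consecutive integers in order of first appearance, with the original
    strings kept in ``class_names``.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    sep = delimiter or _detect_delimiter(first)
    frame = pd.read_csv(path, sep=sep, header=None, dtype=str, keep_default_na=False)
    if frame.shape[1] < 2:
        raise ExpressionIOError(f"{path}: expected two columns, got {frame.shape[1]}")
    # tolerate an optional header line
    if frame.iloc[0, 0].lower() in ("sample", "sample_id", "id"):
        frame = frame.iloc[1:]
    sample_ids = tuple(frame.iloc[:, 0])
    raw_labels = list(frame.iloc[:, 1])
    if any(lbl.strip() == "" for lbl in raw_labels):
        raise ExpressionIOError(f"{path}: empty class label")
    class_names: list[str] = []
    lookup: dict[str, int] = {}
    codes = np.empty(len(raw_labels), dtype=int)
    for i, lbl in enumerate(raw_labels):
        if lbl not in lookup:
            lookup[lbl] = len(class_names)
            class_names.append(lbl)
        codes[i] = lookup[lbl]
    return LabelTable(sample_ids, codes, tuple(class_names))


def align_labels(labels: LabelTable, sample_ids: Sequence[str]) -> np.ndarray:
    """Integer codes re-ordered to match ``sample_ids``.

    Raises
    ------
    KeyError
        If a requested sample id has no label.
    """
    lookup = dict(zip(labels.sample_ids, labels.codes))
    missing = [s for s in sample_ids if s not in lookup]
    if missing:
        raise KeyError(f"no label for sample id(s): {missing[:5]}")
    return np.array([lookup[s] for s in sample_ids], dtype=int)


def read_reference_table(path: str | Path, delimiter: str | None = None) -> ReferenceGeneTable:
    """Read a two-column (gene id, relevance score) table."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    sep = delimiter or _detect_delimiter(first)
    frame = pd.read_csv(path, sep=sep, header=None, dtype=str, keep_default_na=False)
    if frame.shape[1] < 2:
        raise ExpressionIOError(f"{path}: expected two columns, got {frame.shape[1]}")
    if frame.iloc[0, 0].lower() in ("gene", "gene_id", "id"):
        frame = frame.iloc[1:]
    genes = list(frame.iloc[:, 0])
    if len(set(genes)) != len(genes):
        raise ExpressionIOError(f"{path}: duplicate gene id in reference table")
    try:
        scores = [float(s) for s in frame.iloc[:, 1]]
    except ValueError as exc:
        raise ExpressionIOError(f"{path}: non-numeric relevance score") from exc
    return ReferenceGeneTable(dict(zip(genes, scores)))


def log2_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """log2(x + 1), the usual variance-stabilizing step for count-like data."""
    if (matrix.values < 0).any():
        raise ExpressionIOError("log2 transform requires nonnegative values")
    return ExpressionMatrix(
        np.log2(matrix.values + 1.0), matrix.gene_ids, matrix.sample_ids
    )


def zscore_genes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Center and scale each gene row to zero mean, unit variance.

    Constant rows are centered but left unscaled to avoid division by zero.
    """
    values = matrix.values
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return ExpressionMatrix((values - mu) / sd, matrix.gene_ids, matrix.sample_ids)
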