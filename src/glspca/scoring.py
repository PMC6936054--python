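"""Gene ranking from the fitted factors and reference-based evaluation.

Genes are scored by aggregating the rows of the gene-side factor U = X H:
a gene loading strongly on the retained components gets a high score.
The top-N genes form the candidate differentially-expressed set, judged
against a curated reference table by identification accuracy (IA, the
percentage of selected genes present in the reference) and total
relevance score (TRS, the sum of the reference scores of the selected
genes).
"""

from __future__ import annotations

from typing import Literal, Sequence

import numpy as np

from .exprio import ExpressionMatrix, GeneRanking, ReferenceGeneTable

__all__ = [
    "gene_scores",
    "select_top",
    "identification_accuracy",
    "total_relevance_score",
]

ScoreMode = Literal["l1", "l2"]


def gene_scores(U: np.ndarray, mode: ScoreMode = "l1") -> np.ndarray:
    """Per-gene scores from the rows of the gene-side factor U (m x k).

    ``l1`` (default) sums absolute loadings across components; ``l2``
    takes the row-wise Euclidean norm.  Scores are nonnegative and
    equivariant under row permutations of U.
    """
    U = np.asarray(U, dtype=float)
    if U.ndim != 2 or U.size == 0:
        raise ValueError("U must be a nonempty 2-D factor matrix")
    if mode == "l1":
        return np.abs(U).sum(axis=1)
    if mode == "l2":
        return np.linalg.norm(U, axis=1)
    raise ValueError(f"unknown score mode {mode!r}")


def select_top(
    scores: np.ndarray, n: int, gene_ids: Sequence[str]
) -> GeneRanking:
    """The n genes of largest score, in descending order.

    Ties are broken by ascending gene index, so the selection is
    deterministic.
    """
    scores = np.asarray(scores, dtype=float)
    m = scores.shape[0]
    if len(gene_ids) != m:
        raise ValueError(f"{len(gene_ids)} gene ids for {m} scores")
    if not 1 <= n <= m:
        raise ValueError(f"n must be in [1, {m}], got {n}")
    # stable sort on -scores: equal scores keep original (ascending) index order
    order = np.argsort(-scores, kind="stable")[:n]
    return GeneRanking(tuple(gene_ids[i] for i in order), scores[order])


def identification_accuracy(
    selected: GeneRanking, reference: ReferenceGeneTable
) -> float:
    """Percentage of the selected genes present in the reference table."""
    if len(selected) == 0:
        raise ValueError("empty selection")
    hits = sum(1 for gene in selected.gene_ids if gene in reference)
    return 100.0 * hits / len(selected)


def total_relevance_score(
    selected: GeneRanking, reference: ReferenceGeneTable
) -> float:
    """Sum of reference relevance scores over the selected genes.

    Genes absent from the reference contribute 0 — curated tables cover
    only a subset of the genome.
    """
    if len(selected) == 0:
        raise ValueError("empty selection")
    return float(sum(reference.score(gene) for gene in selected.gene_ids))
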