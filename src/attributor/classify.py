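"""Entropy-matrix construction, per-class mean normalization, attribution.

Scoring a batch of test documents under every candidate author's PPM model
yields an *entropy matrix* (rows = documents, columns = authors, values =
cross-entropy in bits/symbol).  Raw entropies are not directly comparable
across authors: an author whose training text is short or heterogeneous
yields systematically higher entropies for everyone.  The normalization step
divides each column by its mean over the current test batch, so each
author's entropies average to 1 and a value below 1 means "this document
fits the author better than typical".  Attribution assigns each document to
the author with the minimum normalized entropy.

Note the transductive flavor of the normalization: column means are taken
over the test batch itself, so a single-document batch degenerates (every
value becomes 1) and attribution refuses it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .ppm import ContextModel, cross_entropy

log = logging.getLogger(__name__)

__all__ = ["EntropyMatrix", "Attribution", "entropy_matrix", "normalize_matrix", "attribute"]


@dataclass
class EntropyMatrix:
    """Cross-entropies of test documents (rows) under class models (columns)."""

    values: pd.DataFrame
    normalized: bool = False

    @property
    def doc_ids(self) -> list:
        return list(self.values.index)

    @property
    def authors(self) -> list:
        return list(self.values.columns)

    def to_csv(self, path) -> None:
        self.values.to_csv(path, index_label="doc_id")


@dataclass
class Attribution:
    """Prediction for one test document.

    ``ranking`` is the full author list ordered from best (lowest entropy)
    to worst, enabling top-k analyses; ``margin`` is the entropy gap between
    winner and runner-up.
    """

    doc_id: object
    predicted: str
    entropy: float
    margin: float
    ranking: tuple = field(default_factory=tuple)


def entropy_matrix(
    models: Mapping[str, ContextModel], docs: Sequence[tuple[object, str]]
) -> EntropyMatrix:
    """Score every document under every author model.

    ``docs`` is a sequence of ``(doc_id, text)`` pairs.  Requires at least
    two models (a one-author "attribution" is vacuous) and non-empty texts.
    """
    if len(models) < 2:
        raise ValueError("need at least 2 author models")
    if not docs:
        raise ValueError("need at least 1 test document")
    for doc_id, text in docs:
        if not text:
            raise ValueError(f"document {doc_id!r} is empty")
    authors = sorted(models)
    data = {
        a: [cross_entropy(models[a], text) for _, text in docs] for a in authors
    }
    frame = pd.DataFrame(data, index=[doc_id for doc_id, _ in docs])
    return EntropyMatrix(values=frame, normalized=False)


def normalize_matrix(m: EntropyMatrix) -> EntropyMatrix:
    """Divide each column by its mean entropy over the test batch.

    After normalization every column mean equals 1.  Double normalization is
    refused (it would silently be a no-op and hide pipeline bugs).
    """
    if m.normalized:
        raise ValueError("matrix is already normalized")
    if (m.values.values <= 0).any():
        raise ValueError("raw entropies must be strictly positive")
    col_means = m.values.mean(axis=0)
    if (col_means <= 0).any():
        raise ValueError("column means must be strictly positive")
    if len(m.values) == 1:
        log.warning("single-document batch: normalization forces all values to 1")
    return EntropyMatrix(values=m.values / col_means, normalized=True)


def attribute(m: EntropyMatrix, allow_raw: bool = False) -> list[Attribution]:
    """Assign each document to its minimum-entropy author.

    Operates on a normalized matrix unless ``allow_raw=True``.  Ties are
    broken by the lexicographically smallest author label (logged).  A
    normalized single-row matrix is rejected: per-class mean normalization
    makes every value 1, so attribution would be undefined.
    """
    if not m.normalized and not allow_raw:
        raise ValueError("matrix is not normalized (pass allow_raw=True to override)")
    if m.normalized and len(m.values) == 1:
        raise ValueError(
            "cannot attribute a single-document batch: per-class mean "
            "normalization degenerates (all values 1); score at least 2 documents"
        )
    out: list[Attribution] = []
    for doc_id, row in m.values.iterrows():
        ranked = sorted(zip(row.values, row.index))  # (entropy, label): lex tie-break
        best_e, best_a = ranked[0]
        if len(ranked) > 1 and ranked[1][0] == best_e:
            log.warning(
                "tie for document %r between %r and %r; chose %r",
                doc_id, best_a, ranked[1][1], best_a,
            )
        margin = (ranked[1][0] - best_e) if len(ranked) > 1 else float("nan")
        out.append(
            Attribution(
                doc_id=doc_id,
                predicted=best_a,
                entropy=float(best_e),
                margin=float(margin),
                ranking=tuple(label for _, label in ranked),
            )
        )
    return out
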