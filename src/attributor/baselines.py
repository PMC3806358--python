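"""Comparison methods: word-based PPM and feature-table classifiers.

The character-level PPM classifier is compared against the standard
word-feature pipeline: build a vocabulary from the training split only,
count features per document, and classify with multinomial Naive Bayes or a
linear SVM.  Three feature sets are supported:

``FREQ_WORDS``
    all word tokens whose training-corpus frequency exceeds a threshold
    (strictly greater, default 10);
``FREQ_WORDS_PLUS``
    the same vocabulary plus 24 punctuation-character counts, a digit count
    and a capital-letter count, computed on the original (un-normalized)
    character stream;
``CHAR5_SEQS``
    all character 5-grams whose training-corpus frequency exceeds the
    threshold.

Naive Bayes is implemented natively (multinomial, add-one smoothing over
raw counts); the linear SVM sits behind a thin adapter contract so
experiments degrade gracefully when no SVM implementation is available.
The word-based PPM baseline reuses the :mod:`attributor.ppm` machinery with
``unit="word"``.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

from .ppm import tokenize_words

log = logging.getLogger(__name__)

__all__ = [
    "FeatureKind",
    "FeatureSpec",
    "DEFAULT_PUNCTUATION",
    "build_vocabulary",
    "featurize",
    "save_feature_table",
    "load_feature_table",
    "NaiveBayes",
    "nb_train",
    "nb_predict",
    "svm_available",
    "svm_adapter",
]


class FeatureKind(str, Enum):
    FREQ_WORDS = "freq_words"
    FREQ_WORDS_PLUS = "freq_words_plus"
    CHAR5_SEQS = "char5_seqs"


# 24 ASCII punctuation/symbol characters common in forum text; counted as
# individual character features alongside one digit count and one
# capital-letter count.
DEFAULT_PUNCTUATION = tuple(".,!?;:'\"()-/@#$%&*+=<>[]")

_DIGIT_FEATURE = "<digits>"
_CAPITAL_FEATURE = "<capitals>"


@dataclass(frozen=True)
class FeatureSpec:
    """Which features to extract and how."""

    kind: FeatureKind = FeatureKind.FREQ_WORDS
    min_frequency: int = 10  # strictly-greater-than threshold
    punctuation: tuple = DEFAULT_PUNCTUATION
    length_normalize: bool = False

    def __post_init__(self) -> None:
        if self.min_frequency < 1:
            raise ValueError("min_frequency must be >= 1")
        if len(set(self.punctuation)) != len(self.punctuation):
            raise ValueError("punctuation features must be unique")

    @property
    def extra_features(self) -> tuple:
        if self.kind is FeatureKind.FREQ_WORDS_PLUS:
            return tuple(self.punctuation) + (_DIGIT_FEATURE, _CAPITAL_FEATURE)
        return ()


def _char5_grams(text: str) -> list[str]:
    return [text[i : i + 5] for i in range(len(text) - 4)]


def build_vocabulary(train_texts: Sequence[str], spec: FeatureSpec) -> list[str]:
    """Ordered feature list from the training split only.

    Tokens (or character 5-grams) are kept when their total training-corpus
    frequency is strictly greater than ``spec.min_frequency``; ordering is
    by descending frequency, then lexicographic, so two builds on the same
    corpus are identical.
    """
    if not train_texts:
        raise ValueError("training set is empty")
    freq: Counter = Counter()
    if spec.kind is FeatureKind.CHAR5_SEQS:
        for t in train_texts:
            freq.update(_char5_grams(t))
    else:
        for t in train_texts:
            freq.update(tokenize_words(t))
    kept = [(item, n) for item, n in freq.items() if n > spec.min_frequency]
    kept.sort(key=lambda kv: (-kv[1], kv[0]))
    vocabulary = [item for item, _ in kept] + list(spec.extra_features)
    if not vocabulary:
        raise ValueError(
            f"empty vocabulary: no item has frequency > {spec.min_frequency}"
        )
    return vocabulary


def featurize(
    texts: Sequence[str], vocabulary: Sequence[str], spec: FeatureSpec
) -> pd.DataFrame:
    """Per-document raw counts of every vocabulary feature.

    Word and 5-gram features count token/substring occurrences;
    punctuation, digit and capital features count characters of the
    original text.  Out-of-vocabulary tokens are ignored.  With
    ``spec.length_normalize`` the counts are divided by document character
    length.
    """
    if not len(vocabulary):
        raise ValueError("vocabulary is empty")
    extra = set(spec.extra_features)
    col_index = {f: j for j, f in enumerate(vocabulary)}
    mat = np.zeros((len(texts), len(vocabulary)))
    for i, text in enumerate(texts):
        if spec.kind is FeatureKind.CHAR5_SEQS:
            items: Counter = Counter(_char5_grams(text))
        else:
            items = Counter(tokenize_words(text))
        for item, n in items.items():
            j = col_index.get(item)
            if j is not None and item not in extra:
                mat[i, j] = n
        if extra:
            char_counts = Counter(text)
            for p in spec.punctuation:
                mat[i, col_index[p]] = char_counts.get(p, 0)
            mat[i, col_index[_DIGIT_FEATURE]] = sum(
                n for ch, n in char_counts.items() if ch.isdigit()
            )
            mat[i, col_index[_CAPITAL_FEATURE]] = sum(
                n for ch, n in char_counts.items() if ch.isupper()
            )
        if spec.length_normalize and len(text):
            mat[i] /= len(text)
    return pd.DataFrame(mat, columns=list(vocabulary))


def save_feature_table(table: pd.DataFrame, path, format: str = "csv") -> None:
    """Export a feature table as CSV or sparse Matrix Market (MTX).

    The MTX format stores values only, so the column names go to a
    ``<path>.cols.tsv`` companion file; :func:`load_feature_table` reads
    both back.
    """
    from pathlib import Path

    path = Path(path)
    if format == "csv":
        table.to_csv(path, index=False)
    elif format == "mtx":
        from scipy import io as scipy_io
        from scipy import sparse

        scipy_io.mmwrite(str(path), sparse.csr_matrix(table.values))
        path.with_suffix(path.suffix + ".cols.tsv").write_text(
            "\n".join(str(c) for c in table.columns) + "\n", encoding="utf-8"
        )
    else:
        raise ValueError(f"unknown format {format!r}")


def load_feature_table(path, format: str = "csv") -> pd.DataFrame:
    """Read back a feature table written by :func:`save_feature_table`."""
    from pathlib import Path

    path = Path(path)
    if format == "csv":
        return pd.read_csv(path)
    if format == "mtx":
        from scipy import io as scipy_io

        values = scipy_io.mmread(str(path)).toarray()
        columns = (
            path.with_suffix(path.suffix + ".cols.tsv")
            .read_text(encoding="utf-8")
            .splitlines()
        )
        return pd.DataFrame(values, columns=columns)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# native multinomial Naive Bayes


@dataclass
class NaiveBayes:
    """Multinomial Naive Bayes with add-one smoothing over raw counts."""

    classes: list[str]
    log_prior: np.ndarray  # (C,)
    log_likelihood: np.ndarray  # (C, F)
    features: list[str]


def nb_train(table: pd.DataFrame, labels: Sequence[str]) -> NaiveBayes:
    """Fit class priors and smoothed feature log-probabilities."""
    if len(table) != len(labels):
        raise ValueError("table and labels disagree in length")
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    X = table.values
    if not X.any():
        raise ValueError("feature table is all zeros")
    y = np.asarray(list(labels))
    n_features = X.shape[1]
    log_prior = np.empty(len(classes))
    log_likelihood = np.empty((len(classes), n_features))
    for ci, c in enumerate(classes):
        rows = X[y == c]
        log_prior[ci] = np.log(len(rows) / len(X))
        counts = rows.sum(axis=0)
        log_likelihood[ci] = np.log((counts + 1.0) / (counts.sum() + n_features))
    return NaiveBayes(
        classes=classes,
        log_prior=log_prior,
        log_likelihood=log_likelihood,
        features=list(table.columns),
    )


def nb_predict(model: NaiveBayes, table: pd.DataFrame) -> list[str]:
    """Argmax of the class log-posterior; ties broken by class label order."""
    if list(table.columns) != model.features:
        raise ValueError("feature columns do not match the trained model")
    scores = table.values @ model.log_likelihood.T + model.log_prior
    out = []
    for row in scores:
        best = int(np.argmax(row))  # first index wins ties = smallest label
        if (row == row[best]).sum() > 1:
            log.warning("posterior tie; chose %r by label order", model.classes[best])
        out.append(model.classes[best])
    return out


# ---------------------------------------------------------------------------
# pluggable linear SVM


def svm_available() -> bool:
    try:
        from sklearn.svm import LinearSVC  # noqa: F401

        return True
    except ImportError:  # pragma: no cover - environment dependent
        return False


def svm_adapter(
    train_table: pd.DataFrame,
    train_labels: Sequence[str],
    test_table: pd.DataFrame,
    seed: int = 0,
) -> list[str]:
    """Fit a one-vs-rest linear SVM and predict test labels.

    Thin contract around an external implementation; raises
    ``RuntimeError`` when none is available so callers can drop the SVM
    rows and continue.
    """
    if not svm_available():  # pragma: no cover - environment dependent
        raise RuntimeError("no linear-SVM implementation available")
    from sklearn.svm import LinearSVC

    clf = LinearSVC(random_state=seed, max_iter=5000)
    clf.fit(train_table.values, list(train_labels))
    return [str(p) for p in clf.predict(test_table.values)]
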