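"""Cross-validated evaluation: confusion matrices, macro P/R/F, factor sweeps.

Evaluation follows the standard closed-set attribution protocol: balance
every author to the same number of posts, run k-fold cross-validation where
each fold trains one PPM model per author and attributes the held-out posts,
accumulate a confusion matrix per fold, and report macro-averaged precision,
recall and F.  Macro averaging (unweighted mean over authors) keeps the
metric insensitive to class size.

Two aggregation flavors are reported: metrics of the pooled confusion over
all folds, and the mean of per-fold metrics.  The fold-averaged numbers are
the headline because they provide the paired replicates that the paired
t-test needs when comparing methods on identical splits.

Factor experiments rerun the cross-validation while sweeping one design
factor — number of candidate authors, number of training files per author,
or test-chunk size in words — holding everything else fixed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import attribute, entropy_matrix, normalize_matrix
from .corpus import AuthorCorpus, balance_and_split, chunk_documents
from .ppm import train_model

log = logging.getLogger(__name__)

__all__ = [
    "MetricReport",
    "CVSettings",
    "CVResult",
    "ExperimentGrid",
    "TTestResult",
    "confusion_matrix",
    "prf",
    "cross_validate",
    "run_factor_experiment",
    "feature_scorer",
    "compare_methods",
    "paired_ttest",
]


def confusion_matrix(
    pairs: Sequence[tuple[str, str]], labels: Sequence[str] | None = None
) -> pd.DataFrame:
    """Square count table of (true author x predicted author).

    ``pairs`` is a sequence of ``(true, predicted)`` labels; ``labels``
    fixes the row/column order (default: sorted union).
    """
    if labels is None:
        labels = sorted({t for t, _ in pairs} | {p for _, p in pairs})
    labels = list(labels)
    conf = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for true, pred in pairs:
        conf.loc[true, pred] += 1
    return conf


@dataclass
class MetricReport:
    """Per-class and macro-averaged precision / recall / F."""

    per_class: pd.DataFrame  # index = class, columns = precision, recall, f
    macro_precision: float
    macro_recall: float
    macro_f: float
    n_documents: int

    def as_dict(self) -> dict:
        return {
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f": self.macro_f,
            "n_documents": self.n_documents,
        }


def prf(conf: pd.DataFrame) -> MetricReport:
    """Precision, recall and F per class plus macro averages.

    Uses the one-vs-rest definitions ``P = TP/(TP+FP)``, ``R = TP/(TP+FN)``
    and ``F = 2PR/(P+R)``.  A class that is never predicted gets precision 0
    (standard convention, logged); F is 0 whenever P + R = 0.
    """
    total = int(conf.values.sum())
    if total < 1:
        raise ValueError("confusion matrix is empty")
    rows = {}
    for c in conf.index:
        tp = int(conf.loc[c, c])
        fp = int(conf[c].sum()) - tp
        fn = int(conf.loc[c].sum()) - tp
        if tp + fp == 0:
            log.warning("class %r never predicted; precision set to 0", c)
            precision = 0.0
        else:
            precision = tp / (tp + fp)
        recall = 0.0 if tp + fn == 0 else tp / (tp + fn)
        f = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
        rows[c] = {"precision": precision, "recall": recall, "f": f}
    per_class = pd.DataFrame.from_dict(rows, orient="index")
    return MetricReport(
        per_class=per_class,
        macro_precision=float(per_class["precision"].mean()),
        macro_recall=float(per_class["recall"].mean()),
        macro_f=float(per_class["f"].mean()),
        n_documents=total,
    )


# ---------------------------------------------------------------------------
# cross-validation driver


@dataclass(frozen=True)
class CVSettings:
    """Everything a cross-validated attribution run needs besides the corpus.

    ``n_train_files`` truncates each author's per-fold training list (for
    the training-volume factor); ``chunk_words`` merges each author's test
    posts and re-cuts them into equal fragments (for the test-size factor).
    ``scorer`` swaps the per-fold classifier; the default trains PPM models
    and attributes by normalized minimum entropy.
    """

    n_per_author: int = 100
    k: int = 10
    seed: int = 0
    max_order: int = 5
    unit: str = "character"
    n_train_files: int | None = None
    chunk_words: int | None = None
    scorer: Callable | None = None


@dataclass
class CVResult:
    """Per-fold and pooled metrics of one cross-validated run."""

    fold_reports: list[MetricReport]
    pooled: MetricReport
    pooled_confusion: pd.DataFrame
    settings: CVSettings

    @property
    def macro_f(self) -> float:
        """Headline metric: per-fold macro-F averaged over folds."""
        return float(np.mean([r.macro_f for r in self.fold_reports]))

    @property
    def macro_precision(self) -> float:
        return float(np.mean([r.macro_precision for r in self.fold_reports]))

    @property
    def macro_recall(self) -> float:
        return float(np.mean([r.macro_recall for r in self.fold_reports]))

    @property
    def fold_f(self) -> list[float]:
        return [r.macro_f for r in self.fold_reports]


def _fold_test_docs(
    test: AuthorCorpus, chunk_words: int | None, fold: int
) -> tuple[list[tuple[str, str]], dict[str, str]]:
    """Build (doc_id, text) pairs and the doc_id -> true author map."""
    docs: list[tuple[str, str]] = []
    truth: dict[str, str] = {}
    for author in test.authors:
        texts = test.documents[author]
        if chunk_words is not None:
            texts = chunk_documents(texts, chunk_words)
        for i, text in enumerate(texts):
            doc_id = f"f{fold}:{author}:{i}"
            docs.append((doc_id, text))
            truth[doc_id] = author
    return docs, truth


def _ppm_fold_scorer(settings: CVSettings):
    """Default per-fold scorer: PPM models + normalized minimum entropy."""

    def run(train: AuthorCorpus, docs: list[tuple[str, str]]) -> dict[str, str]:
        models = {
            a: train_model(train.documents[a], settings.max_order, settings.unit)
            for a in train.authors
        }
        m = normalize_matrix(entropy_matrix(models, docs))
        return {att.doc_id: att.predicted for att in attribute(m)}

    return run


def _run_fold(
    corpus: AuthorCorpus, settings: CVSettings, fold: int
) -> tuple[pd.DataFrame, MetricReport]:
    n_test = settings.n_per_author // settings.k
    train, test = balance_and_split(
        corpus, settings.n_per_author, n_test, fold, settings.k, settings.seed
    )
    if settings.n_train_files is not None:
        if settings.n_train_files > settings.n_per_author - n_test:
            raise ValueError(
                f"n_train_files={settings.n_train_files} exceeds available "
                f"{settings.n_per_author - n_test} training documents"
            )
        train = AuthorCorpus(
            {a: d[: settings.n_train_files] for a, d in train.documents.items()},
            train.variant,
            train.metadata,
        )
    docs, truth = _fold_test_docs(test, settings.chunk_words, fold)
    if not docs:
        raise ValueError(f"fold {fold} has no test documents")
    scorer = settings.scorer or _ppm_fold_scorer(settings)
    predictions = scorer(train, docs)
    labels = corpus.authors
    conf = confusion_matrix(
        [(truth[d], predictions[d]) for d, _ in docs], labels=labels
    )
    return conf, prf(conf)


def cross_validate(corpus: AuthorCorpus, settings: CVSettings) -> CVResult:
    """k-fold cross-validated attribution over a balanced corpus.

    Each fold trains per-author models on the training split, scores,
    normalizes and attributes the held-out split, and accumulates a
    confusion matrix.  Fully deterministic given the settings seed.
    """
    if settings.k < 2:
        raise ValueError("k must be >= 2")
    fold_reports: list[MetricReport] = []
    pooled_conf: pd.DataFrame | None = None
    for fold in range(settings.k):
        conf, report = _run_fold(corpus, settings, fold)
        fold_reports.append(report)
        pooled_conf = conf if pooled_conf is None else pooled_conf + conf
    return CVResult(
        fold_reports=fold_reports,
        pooled=prf(pooled_conf),
        pooled_confusion=pooled_conf,
        settings=settings,
    )


# ---------------------------------------------------------------------------
# factor experiments


@dataclass(frozen=True)
class ExperimentGrid:
    """Declarative sweep over one design factor.

    ``factor`` is one of ``n_authors``, ``n_train_files``, ``chunk_words``;
    ``levels`` must be strictly increasing and feasible for the corpus.
    """

    factor: str
    levels: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.factor not in ("n_authors", "n_train_files", "chunk_words"):
            raise ValueError(f"unknown factor {self.factor!r}")
        if not self.levels:
            raise ValueError("grid needs at least one level")
        if any(b <= a for a, b in zip(self.levels, self.levels[1:])):
            raise ValueError("levels must be strictly increasing")


def _check_grid_feasible(grid: ExperimentGrid, corpus: AuthorCorpus,
                         settings: CVSettings) -> None:
    counts = corpus.counts()
    eligible = [a for a, n in counts.items() if n >= settings.n_per_author]
    if grid.factor == "n_authors":
        if grid.levels[-1] > len(eligible):
            raise ValueError(
                f"level {grid.levels[-1]} authors requested but only "
                f"{len(eligible)} have >= {settings.n_per_author} posts"
            )
    else:
        if len(eligible) < len(counts):
            missing = sorted(set(counts) - set(eligible))
            raise ValueError(f"authors with too few posts: {missing}")
        if grid.factor == "n_train_files":
            avail = settings.n_per_author - settings.n_per_author // settings.k
            if grid.levels[-1] > avail:
                raise ValueError(
                    f"level {grid.levels[-1]} training files exceeds available {avail}"
                )


def run_factor_experiment(
    grid: ExperimentGrid, corpus: AuthorCorpus, settings: CVSettings
) -> pd.DataFrame:
    """One cross-validated run per factor level; table ordered by level.

    For ``n_authors`` the corpus is restricted to the first N authors in
    sorted label order.  For ``chunk_words``, each fold's per-author test
    posts are merged and re-cut into equal fragments; models are shared
    across chunk levels within a fold (training does not depend on the
    chunk size), which is computationally free of any statistical cost.
    Returns columns ``level, f, precision, recall`` (fold-averaged).
    """
    _check_grid_feasible(grid, corpus, settings)
    rows = []
    if grid.factor == "chunk_words":
        # share trained fold models across levels
        per_level_reports: dict[int, list[MetricReport]] = {lv: [] for lv in grid.levels}
        n_test = settings.n_per_author // settings.k
        for fold in range(settings.k):
            train, test = balance_and_split(
                corpus, settings.n_per_author, n_test, fold, settings.k, settings.seed
            )
            models = {
                a: train_model(train.documents[a], settings.max_order, settings.unit)
                for a in train.authors
            }
            for level in grid.levels:
                docs, truth = _fold_test_docs(test, level, fold)
                if not docs:
                    raise ValueError(
                        f"chunk level {level}: fold {fold} yields no chunks"
                    )
                m = normalize_matrix(entropy_matrix(models, docs))
                preds = {att.doc_id: att.predicted for att in attribute(m)}
                conf = confusion_matrix(
                    [(truth[d], preds[d]) for d, _ in docs], labels=corpus.authors
                )
                per_level_reports[level].append(prf(conf))
        for level in grid.levels:
            reports = per_level_reports[level]
            rows.append(
                {
                    "level": level,
                    "f": float(np.mean([r.macro_f for r in reports])),
                    "precision": float(np.mean([r.macro_precision for r in reports])),
                    "recall": float(np.mean([r.macro_recall for r in reports])),
                }
            )
    else:
        for level in grid.levels:
            if grid.factor == "n_authors":
                counts = corpus.counts()
                eligible = [
                    a for a in corpus.authors if counts[a] >= settings.n_per_author
                ]
                sub = AuthorCorpus(
                    {a: corpus.documents[a] for a in eligible[:level]},
                    corpus.variant,
                )
                result = cross_validate(sub, settings)
            else:  # n_train_files
                result = cross_validate(corpus, replace(settings, n_train_files=level))
            rows.append(
                {
                    "level": level,
                    "f": result.macro_f,
                    "precision": result.macro_precision,
                    "recall": result.macro_recall,
                }
            )
    table = pd.DataFrame(rows).sort_values("level").reset_index(drop=True)
    trend = np.diff(table["f"].values)
    if grid.factor == "n_authors" and (trend > 0).any():
        log.info("macro-F not monotonically non-increasing in n_authors: %s", table)
    return table


# ---------------------------------------------------------------------------
# method comparison (character PPM vs word PPM vs feature classifiers)


def feature_scorer(spec, algorithm: str = "nb", seed: int = 0) -> Callable:
    """Per-fold scorer for a feature-table classifier.

    Builds the vocabulary from the fold's training texts only, featurizes
    both splits, and classifies with native Naive Bayes (``"nb"``) or the
    linear-SVM adapter (``"svm"``).
    """
    from . import baselines

    def run(train: AuthorCorpus, docs: list[tuple[str, str]]) -> dict[str, str]:
        train_texts: list[str] = []
        train_labels: list[str] = []
        for author in train.authors:
            for text in train.documents[author]:
                train_texts.append(text)
                train_labels.append(author)
        vocab = baselines.build_vocabulary(train_texts, spec)
        x_train = baselines.featurize(train_texts, vocab, spec)
        x_test = baselines.featurize([text for _, text in docs], vocab, spec)
        if algorithm == "nb":
            preds = baselines.nb_predict(baselines.nb_train(x_train, train_labels), x_test)
        elif algorithm == "svm":
            preds = baselines.svm_adapter(x_train, train_labels, x_test, seed)
        else:
            raise ValueError(f"unknown algorithm {algorithm!r}")
        return {doc_id: p for (doc_id, _), p in zip(docs, preds)}

    return run


def compare_methods(
    corpus: AuthorCorpus,
    settings: CVSettings,
    feature_spec=None,
    word_max_order: int = 2,
    include_svm: bool = True,
) -> dict:
    """Run PPM5, word-PPM, NB and SVM under identical CV splits.

    Returns ``{"results": {method: CVResult}, "ttests": {method:
    TTestResult}}`` where each t-test pairs the character-PPM per-fold
    macro-F values against the named baseline's (same folds, same data).
    SVM rows are dropped with a log message when no implementation is
    available.
    """
    from . import baselines

    if feature_spec is None:
        feature_spec = baselines.FeatureSpec(
            kind=baselines.FeatureKind.FREQ_WORDS_PLUS
        )
    results: dict = {}
    results["ppm5"] = cross_validate(corpus, settings)
    results["word_ppm"] = cross_validate(
        corpus, replace(settings, unit="word", max_order=word_max_order)
    )
    results["naive_bayes"] = cross_validate(
        corpus,
        replace(settings, scorer=feature_scorer(feature_spec, "nb", settings.seed)),
    )
    if include_svm:
        if baselines.svm_available():
            results["svm"] = cross_validate(
                corpus,
                replace(
                    settings, scorer=feature_scorer(feature_spec, "svm", settings.seed)
                ),
            )
        else:  # pragma: no cover - environment dependent
            log.warning("linear SVM unavailable; skipping SVM comparison rows")
    ttests = {
        name: paired_ttest(results["ppm5"].fold_f, res.fold_f)
        for name, res in results.items()
        if name != "ppm5"
    }
    return {"results": results, "ttests": ttests}


# ---------------------------------------------------------------------------
# paired t-test


@dataclass
class TTestResult:
    t: float
    p: float
    se: float  # standard error of the mean difference
    df: int


def paired_ttest(values_a: Sequence[float], values_b: Sequence[float]) -> TTestResult:
    """Classical paired t-test on per-replicate differences (two-sided).

    Replicates are paired by index (same fold, same measure).  With zero
    variance of the differences: a nonzero mean difference is reported as
    ``t = +/-inf, p = 0.0`` (below any machine-epsilon bound), identical
    vectors as ``t = 0, p = 1``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 paired values")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        if mean == 0.0:
            return TTestResult(t=0.0, p=1.0, se=0.0, df=df)
        return TTestResult(t=math.copysign(math.inf, mean), p=0.0, se=0.0, df=df)
    se = sd / math.sqrt(n)
    t = mean / se
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TTestResult(t=t, p=p, se=se, df=df)
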