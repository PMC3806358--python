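"""Metrics, cross-validation driver, factor experiments, paired t-test."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as scipy_stats

from attributor.evaluate import (
    CVSettings,
    ExperimentGrid,
    confusion_matrix,
    cross_validate,
    paired_ttest,
    prf,
    run_factor_experiment,
)


def brute_force_prf(conf: pd.DataFrame):
    """Independent per-class counter over explicit (true, pred) pairs."""
    pairs = []
    for t in conf.index:
        for p in conf.columns:
            pairs.extend([(t, p)] * int(conf.loc[t, p]))
    out = {}
    for c in conf.index:
        tp = sum(1 for t, p in pairs if t == c and p == c)
        fp = sum(1 for t, p in pairs if t != c and p == c)
        fn = sum(1 for t, p in pairs if t == c and p != c)
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        out[c] = (precision, recall, f)
    return out


class TestPrf:
    def test_perfect_diagonal(self):
        conf = pd.DataFrame(np.eye(4, dtype=int) * 5, index=list("abcd"),
                            columns=list("abcd"))
        report = prf(conf)
        assert report.macro_precision == report.macro_recall == report.macro_f == 1.0

    def test_hand_computed_class(self):
        # class "x": TP=1, FP=1, FN=3
        conf = pd.DataFrame(
            [[1, 3], [1, 5]], index=["x", "y"], columns=["x", "y"]
        )
        report = prf(conf)
        row = report.per_class.loc["x"]
        assert row["precision"] == pytest.approx(0.5)
        assert row["recall"] == pytest.approx(0.25)
        assert row["f"] == pytest.approx(1 / 3)

    def test_equal_precision_recall_gives_same_f(self):
        # harmonic mean of equal values is that value
        conf = pd.DataFrame([[1, 1], [1, 1]], index=["x", "y"], columns=["x", "y"])
        report = prf(conf)
        assert report.per_class.loc["x", "f"] == pytest.approx(0.5)

    def test_never_predicted_class_gets_zero_precision(self, caplog):
        conf = pd.DataFrame([[0, 2], [0, 3]], index=["x", "y"], columns=["x", "y"])
        with caplog.at_level("WARNING"):
            report = prf(conf)
        assert report.per_class.loc["x", "precision"] == 0.0
        assert "never predicted" in caplog.text

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            n = rng.integers(2, 11)
            labels = [f"c{i}" for i in range(n)]
            conf = pd.DataFrame(rng.integers(0, 9, size=(n, n)),
                                index=labels, columns=labels)
            if conf.values.sum() == 0:
                continue
            report = prf(conf)
            expected = brute_force_prf(conf)
            for c in labels:
                p, r, f = expected[c]
                assert report.per_class.loc[c, "precision"] == pytest.approx(p)
                assert report.per_class.loc[c, "recall"] == pytest.approx(r)
                assert report.per_class.loc[c, "f"] == pytest.approx(f)

    def test_macro_f_invariant_under_relabeling(self):
        rng = np.random.default_rng(3)
        labels = list("abcd")
        m = rng.integers(0, 9, size=(4, 4))
        base = prf(pd.DataFrame(m, index=labels, columns=labels))
        renamed = prf(pd.DataFrame(m, index=list("wxyz"), columns=list("wxyz")))
        assert base.macro_f == pytest.approx(renamed.macro_f)


class TestConfusionMatrix:
    def test_conservation(self):
        pairs = [("a", "a"), ("a", "b"), ("b", "b")]
        conf = confusion_matrix(pairs)
        assert conf.values.sum() == len(pairs)
        assert conf.loc["a", "b"] == 1


class TestPairedTTest:
    def test_identical_vectors_null(self):
        res = paired_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (res.t, res.p) == (0.0, 1.0)

    def test_constant_nonzero_difference_degenerate(self):
        res = paired_ttest([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])
        assert res.t == math.inf
        assert res.p == 0.0
        assert res.se == 0.0

    def test_textbook_toy(self):
        res = paired_ttest([0.80, 0.85, 0.90], [0.70, 0.80, 0.75])
        assert res.t == pytest.approx(0.10 / (0.05 / math.sqrt(3)), abs=1e-9)
        assert res.t == pytest.approx(3.464, abs=1e-3)
        assert res.df == 2
        assert res.se == pytest.approx(0.05 / math.sqrt(3), abs=1e-12)

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n = int(rng.integers(2, 12))
            a = rng.normal(0.8, 0.1, n)
            b = a + rng.normal(0.0, 0.05, n)
            mine = paired_ttest(a, b)
            ref = scipy_stats.ttest_rel(a, b)
            assert mine.t == pytest.approx(ref.statistic, abs=1e-10)
            assert mine.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            paired_ttest([1.0, 2.0], [1.0])


class TestCrossValidate:
    def test_deterministic_and_conserving(self, small_corpus):
        settings = CVSettings(n_per_author=20, k=4, seed=5)
        one = cross_validate(small_corpus, settings)
        two = cross_validate(small_corpus, settings)
        assert one.fold_f == two.fold_f
        n_authors = len(small_corpus.authors)
        for report in one.fold_reports:
            assert report.n_documents == n_authors * 5  # 20/4 test docs per author
        assert one.pooled.n_documents == n_authors * 20

    def test_separated_sources_recovered(self, small_corpus):
        result = cross_validate(small_corpus, CVSettings(n_per_author=20, k=4, seed=5))
        assert result.macro_f > 0.9

    def test_k_must_be_at_least_two(self, small_corpus):
        with pytest.raises(ValueError):
            cross_validate(small_corpus, CVSettings(n_per_author=20, k=1, seed=0))


class TestFactorExperiment:
    def test_single_level_matches_direct_call(self, small_corpus):
        settings = CVSettings(n_per_author=20, k=4, seed=5)
        grid = ExperimentGrid(factor="n_authors", levels=(4,))
        table = run_factor_experiment(grid, small_corpus, settings)
        direct = cross_validate(small_corpus, settings)
        assert len(table) == 1
        assert table.loc[0, "f"] == pytest.approx(direct.macro_f)
        assert table.loc[0, "level"] == 4

    def test_levels_must_increase(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            ExperimentGrid(factor="n_authors", levels=(10, 10))

    def test_unknown_factor_rejected(self):
        with pytest.raises(ValueError, match="unknown factor"):
            ExperimentGrid(factor="bogus", levels=(1, 2))

    def test_infeasible_level_fatal_before_compute(self, small_corpus):
        grid = ExperimentGrid(factor="n_authors", levels=(4, 99))
        with pytest.raises(ValueError, match="99"):
            run_factor_experiment(grid, small_corpus,
                                  CVSettings(n_per_author=20, k=4, seed=0))

    def test_train_volume_truncates(self, small_corpus):
        settings = CVSettings(n_per_author=20, k=4, seed=5)
        grid = ExperimentGrid(factor="n_train_files", levels=(5, 15))
        table = run_factor_experiment(grid, small_corpus, settings)
        assert list(table["level"]) == [5, 15]

    def test_chunk_factor_returns_all_levels(self, small_corpus):
        settings = CVSettings(n_per_author=20, k=4, seed=5)
        grid = ExperimentGrid(factor="chunk_words", levels=(10, 30))
        table = run_factor_experiment(grid, small_corpus, settings)
        assert list(table["level"]) == [10, 30]
        assert ((table["f"] >= 0) & (table["f"] <= 1)).all()
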