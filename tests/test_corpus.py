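"""Corpus reading, cleaning, normalization, balancing and splitting."""

import json

import pytest
from hypothesis import given
from hypothesis import strategies as st

from attributor.corpus import (
    AuthorCorpus,
    EmptyDocumentError,
    Post,
    RecordError,
    TextVariant,
    balance_and_split,
    build_author_corpus,
    chunk_documents,
    normalize_text,
    read_posts,
    read_posts_html,
    remove_inclusions,
    split_by_group,
    write_posts,
)


class TestReadPosts:
    def test_jsonl_read_back(self, tmp_path):
        path = tmp_path / "posts.jsonl"
        path.write_text(
            "\n".join(
                json.dumps(r)
                for r in [
                    {"author": "A", "text": "first post"},
                    {"author": "B", "text": "second post"},
                    {"author": "A", "text": "third post"},
                ]
            ),
            encoding="utf-8",
        )
        posts = read_posts(path)
        assert len(posts) == 3
        assert {p.author for p in posts} == {"A", "B"}
        assert posts[0].text == "first post"

    def test_empty_text_rejected_with_warning(self, tmp_path, caplog):
        path = tmp_path / "posts.jsonl"
        path.write_text(
            json.dumps({"author": "A", "text": ""})
            + "\n"
            + json.dumps({"author": "A", "text": "ok"}),
            encoding="utf-8",
        )
        with caplog.at_level("WARNING"):
            posts = read_posts(path)
        assert len(posts) == 1
        assert "record 1" in caplog.text

    def test_missing_author_reports_line_number(self, tmp_path):
        path = tmp_path / "posts.jsonl"
        path.write_text(
            json.dumps({"author": "A", "text": "ok"})
            + "\n"
            + json.dumps({"text": "no author"}),
            encoding="utf-8",
        )
        with pytest.raises(RecordError, match="record 2"):
            read_posts(path)

    def test_csv_roundtrip_preserves_quoted_commas(self, tmp_path):
        original = [
            Post(author="A", text='She said, "hello, world", then left.\nNew line.'),
            Post(author="B", text="plain text", group="G1"),
        ]
        path = tmp_path / "posts.csv"
        write_posts(original, path, format="csv")
        back = read_posts(path)
        assert [p.text for p in back] == [p.text for p in original]
        assert back[1].group == "G1"

    def test_jsonl_roundtrip(self, tmp_path, tiny_posts):
        path = tmp_path / "posts.jsonl"
        write_posts(tiny_posts, path)
        back = read_posts(path)
        assert [p.text for p in back] == [p.text for p in tiny_posts]
        # quote markup re-detected on read
        assert [p.has_inclusion for p in back] == [False, False, True]

    def test_unreadable_file_fatal(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_posts(tmp_path / "missing.jsonl")

    def test_html_fixture_parser(self, tmp_path):
        page = """<html><body>
        <article class="post" data-author="ann" data-group="G1">
          Hello from the first post.
        </article>
        <article class="post" data-author="bob">
          <blockquote>Hello from the first post.</blockquote>
          Quoting you!
        </article>
        <div class="sidebar">not a post</div>
        </body></html>"""
        path = tmp_path / "page.html"
        path.write_text(page, encoding="utf-8")
        posts = read_posts_html(path)
        assert [p.author for p in posts] == ["ann", "bob"]
        assert posts[0].group == "G1"
        assert [p.has_inclusion for p in posts] == [False, True]


class TestRemoveInclusions:
    def test_marked_posts_removed(self, tiny_posts):
        kept = remove_inclusions(tiny_posts)
        assert len(kept) == 2
        assert all(not p.has_inclusion for p in kept)

    def test_no_inclusions_identity(self):
        posts = [Post(author="A", text="hello"), Post(author="B", text="world")]
        assert remove_inclusions(posts) == posts

    def test_exact_arithmetic(self):
        posts = [
            Post(author="A", text=f"post {i}", has_inclusion=(i % 10 == 0))
            for i in range(200)
        ]
        kept = remove_inclusions(posts)
        assert len(kept) == 180


class TestNormalizeText:
    def test_original_keeps_everything(self):
        assert normalize_text("Hi @Bob!! :-)", TextVariant.ORIGINAL) == "Hi @Bob!! :-)"

    def test_lowercase_maps_case_only(self):
        assert (
            normalize_text("Hi @Bob!! :-)", TextVariant.LOWERCASE_ALL_CHARS)
            == "hi @bob!! :-)"
        )

    def test_letters_only_filters_and_collapses(self):
        assert normalize_text("Hi @Bob!! :-)", TextVariant.LETTERS_ONLY) == "hi bob"

    def test_letters_only_empty_raises(self):
        with pytest.raises(EmptyDocumentError):
            normalize_text("!!! 123", TextVariant.LETTERS_ONLY)

    def test_crlf_runs_collapse_to_newline(self):
        assert (
            normalize_text("one\r\n\r\ntwo", TextVariant.ORIGINAL) == "one\ntwo"
        )

    @pytest.mark.parametrize("variant", list(TextVariant))
    @given(text=st.text(min_size=1, max_size=60))
    def test_idempotent(self, variant, text):
        try:
            once = normalize_text(text, variant)
        except EmptyDocumentError:
            return
        assert normalize_text(once, variant) == once


class TestBalanceAndSplit:
    @pytest.fixture
    def corpus(self):
        docs = {f"a{i}": [f"doc {i} {j} text" for j in range(25)] for i in range(4)}
        return AuthorCorpus(docs, TextVariant.ORIGINAL)

    def test_fold_sizes(self, corpus):
        train, test = balance_and_split(corpus, 20, 4, fold=0, k=5, seed=9)
        for author in corpus.authors:
            assert len(train.documents[author]) == 16
            assert len(test.documents[author]) == 4

    def test_folds_partition_retained_documents(self, corpus):
        per_author_test: dict = {a: [] for a in corpus.authors}
        for fold in range(5):
            _, test = balance_and_split(corpus, 20, 4, fold, 5, seed=9)
            for a in corpus.authors:
                per_author_test[a].extend(test.documents[a])
        for a, docs in per_author_test.items():
            assert len(docs) == 20
            assert len(set(docs)) == 20  # each retained doc in test exactly once

    def test_deterministic_given_seed(self, corpus):
        one = balance_and_split(corpus, 20, 4, 2, 5, seed=3)
        two = balance_and_split(corpus, 20, 4, 2, 5, seed=3)
        assert one[0].documents == two[0].documents
        assert one[1].documents == two[1].documents

    def test_k_one_rejected(self, corpus):
        with pytest.raises(ValueError, match="k must be >= 2"):
            balance_and_split(corpus, 20, 20, 0, 1, seed=0)

    def test_wrong_n_test_rejected(self, corpus):
        with pytest.raises(ValueError, match="n_test"):
            balance_and_split(corpus, 20, 5, 0, 5, seed=0)

    def test_indivisible_rejected(self, corpus):
        with pytest.raises(ValueError, match="not divisible"):
            balance_and_split(corpus, 21, 4, 0, 5, seed=0)

    def test_underfilled_author_named(self, corpus):
        corpus.documents["a0"] = corpus.documents["a0"][:3]
        with pytest.raises(ValueError, match="a0"):
            balance_and_split(corpus, 20, 4, 0, 5, seed=0)


class TestSplitByGroup:
    def test_counts_per_group(self):
        posts = [Post(author="A", text=f"t{i}", group="G1") for i in range(278)]
        posts += [Post(author="A", text=f"u{i}", group="G2") for i in range(9)]
        train, test = split_by_group(posts, "G1")
        assert (len(train), len(test)) == (278, 9)

    def test_partition(self):
        posts = [
            Post(author="A", text="x", group="G1"),
            Post(author="B", text="y", group="G2"),
        ]
        train, test = split_by_group(posts, "G1")
        assert sorted(p.text for p in train + test) == ["x", "y"]
        assert not (set(id(p) for p in train) & set(id(p) for p in test))

    def test_all_in_train_group_warns(self, caplog):
        posts = [Post(author="A", text="x", group="G1")]
        with caplog.at_level("WARNING"):
            train, test = split_by_group(posts, "G1")
        assert test == [] and len(train) == 1
        assert "empty" in caplog.text

    def test_absent_group_fatal(self):
        with pytest.raises(ValueError, match="G9"):
            split_by_group([Post(author="A", text="x", group="G1")], "G9")


class TestChunkDocuments:
    def test_equal_chunks_with_remainder_dropped(self):
        texts = ["word " * 525, "word " * 525]  # 1050 words total
        chunks = chunk_documents(texts, 100)
        assert len(chunks) == 10
        assert all(len(c.split()) == 100 for c in chunks)

    def test_exact_fit_is_identity(self):
        text = " ".join(f"w{i}" for i in range(25))
        assert chunk_documents([text], 25) == [text]

    def test_too_few_words_warns_empty(self, caplog):
        with caplog.at_level("WARNING"):
            assert chunk_documents(["just three words"], 50) == []
        assert "fewer than" in caplog.text

    def test_invalid_size_rejected(self):
        with pytest.raises(ValueError):
            chunk_documents(["a b"], 0)


class TestBuildAuthorCorpus:
    def test_drops_inclusions_and_normalizes(self, tiny_posts):
        corpus = build_author_corpus(tiny_posts, TextVariant.LOWERCASE_ALL_CHARS)
        assert corpus.counts() == {"alice": 1, "bob": 1}
        assert corpus.documents["alice"][0].islower()

    def test_empty_under_variant_dropped(self):
        posts = [
            Post(author="A", text="!!!"),
            Post(author="A", text="real words here"),
        ]
        corpus = build_author_corpus(posts, TextVariant.LETTERS_ONLY)
        assert corpus.counts() == {"A": 1}

    def test_serialization(self, tmp_path, tiny_posts):
        corpus = build_author_corpus(tiny_posts, TextVariant.ORIGINAL)
        out = tmp_path / "corpus.jsonl"
        corpus.to_jsonl(out)
        manifest = json.loads(
            (tmp_path / "corpus.jsonl.manifest.json").read_text()
        )
        assert manifest["variant"] == "original"
        assert manifest["counts"] == {"alice": 1, "bob": 1}
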