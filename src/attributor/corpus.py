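"""Reading, cleaning, balancing and splitting of forum post collections.

The preprocessing pipeline mirrors what authorship-attribution studies on
forum data require before any modeling: drop posts that embed quoted text of
other posts (they mix several authors' styles into one message), normalize
the character stream, balance every author to the same number of documents,
and deal documents into cross-validation folds deterministically.

Three text variants control which character information survives:

``LETTERS_ONLY``
    only alphabetic characters, lowercased, non-letter runs collapsed to one
    space — the weakest stylometric signal.
``LOWERCASE_ALL_CHARS``
    every character kept (punctuation, digits, emoticons, newlines) but
    letters lowercased.
``ORIGINAL``
    the full character stream with original capitalization.
"""

from __future__ import annotations

import csv
import json
import logging
import re
import unicodedata
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

log = logging.getLogger(__name__)

__all__ = [
    "Post",
    "TextVariant",
    "AuthorCorpus",
    "EmptyDocumentError",
    "RecordError",
    "read_posts",
    "read_posts_html",
    "write_posts",
    "remove_inclusions",
    "normalize_text",
    "build_author_corpus",
    "balance_and_split",
    "split_by_group",
    "chunk_documents",
]


class EmptyDocumentError(ValueError):
    """A document became empty under the requested text variant."""


class RecordError(ValueError):
    """An input record is malformed; carries the 1-based line number."""

    def __init__(self, line_no: int, message: str):
        super().__init__(f"record {line_no}: {message}")
        self.line_no = line_no


# Quote-span markup that flags an embedded post.  BBCode-style tags are what
# forum exports actually carry; plain-text quoting heuristics are deliberately
# not attempted (too many false positives on short posts).
_QUOTE_RE = re.compile(r"\[quote\b|\[/quote\]|<blockquote\b", re.IGNORECASE)


@dataclass
class Post:
    """One forum message: author label, optional grouping metadata, raw text."""

    author: str
    text: str
    group: str | None = None
    topic: str | None = None
    has_inclusion: bool = False

    def __post_init__(self) -> None:
        if not self.author:
            raise ValueError("author label must be non-empty")
        if len(self.text) < 1:
            raise ValueError("post text must be non-empty")


class TextVariant(str, Enum):
    LETTERS_ONLY = "letters"
    LOWERCASE_ALL_CHARS = "lowercase"
    ORIGINAL = "original"


_CRLF_RUN = re.compile(r"[\r\n]+")
# runs of anything that is not a Unicode letter
_NON_LETTER = re.compile(r"[\W\d_]+", re.UNICODE)


def _encode_normalize(text: str) -> str:
    """UTF-8/NFC normalization shared by all variants.

    CR/LF runs collapse to a single newline which is *retained* as an
    ordinary symbol: line-breaking habits are stylometric signal.
    """
    return _CRLF_RUN.sub("\n", unicodedata.normalize("NFC", text))


def normalize_text(text: str, variant: TextVariant) -> str:
    """Apply one of the three character-set variants to ``text``.

    Raises :class:`EmptyDocumentError` if nothing remains (possible under
    ``LETTERS_ONLY`` for e.g. ``"!!!"``); callers filter such documents.
    """
    if not text:
        raise ValueError("text must be non-empty")
    out = _encode_normalize(text)
    if variant is TextVariant.ORIGINAL:
        return out
    if variant is TextVariant.LOWERCASE_ALL_CHARS:
        return out.lower()
    if variant is TextVariant.LETTERS_ONLY:
        out = _NON_LETTER.sub(" ", out).strip().lower()
        # collapse any residual double spaces from adjacent replacements
        out = re.sub(r" +", " ", out)
        if not out:
            raise EmptyDocumentError("document empty under LETTERS_ONLY")
        return out
    raise ValueError(f"unknown variant {variant!r}")


# ---------------------------------------------------------------------------
# reading and writing posts


def _post_from_record(rec: dict, line_no: int) -> Post | None:
    """Build a Post from a parsed record; None signals a skipped empty text."""
    if "author" not in rec or rec["author"] in (None, ""):
        raise RecordError(line_no, "missing required field 'author'")
    if "text" not in rec or rec["text"] is None:
        raise RecordError(line_no, "missing required field 'text'")
    text = str(rec["text"])
    if text == "":
        log.warning("record %d: empty text, post rejected", line_no)
        return None
    return Post(
        author=str(rec["author"]),
        text=text,
        group=rec.get("group") or None,
        topic=rec.get("topic") or None,
        has_inclusion=bool(rec.get("has_inclusion"))
        or bool(_QUOTE_RE.search(text)),
    )


def read_posts(path: str | Path, format: str | None = None) -> list[Post]:
    """Read posts from a JSON-lines or CSV file.

    Each record needs ``author`` and ``text`` fields; ``group`` and ``topic``
    are optional.  Records with empty text are rejected with a logged
    warning; a missing required field raises :class:`RecordError` with the
    line number.  A post is flagged ``has_inclusion`` when its text carries
    quote-span markup (``[quote]...[/quote]`` or an HTML ``blockquote``).
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    posts: list[Post] = []
    if format == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for line_no, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise RecordError(line_no, f"invalid JSON: {exc}") from exc
                post = _post_from_record(rec, line_no)
                if post is not None:
                    posts.append(post)
    elif format == "csv":
        with path.open(encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            for line_no, rec in enumerate(reader, start=2):  # 1 = header
                post = _post_from_record(rec, line_no)
                if post is not None:
                    posts.append(post)
    else:
        raise ValueError(f"unknown format {format!r}")
    return posts


def read_posts_html(path: str | Path) -> list[Post]:
    """Offline parser for saved forum pages (fixture format, no crawling).

    Expects the minimal structure used by archived forum-page fixtures:
    each post is an element whose ``class`` contains ``post``, carrying
    ``data-author`` (required) plus optional ``data-group``/``data-topic``
    attributes, with the message as its text content.  An embedded
    ``<blockquote>`` marks a quoted inclusion.  Posts with empty text are
    rejected with a logged warning, mirroring :func:`read_posts`.
    """
    from lxml import html as lxml_html

    tree = lxml_html.parse(str(path))
    posts: list[Post] = []
    nodes = tree.xpath(
        '//*[contains(concat(" ", normalize-space(@class), " "), " post ")]'
    )
    for idx, node in enumerate(nodes, start=1):
        author = node.get("data-author")
        if not author:
            raise RecordError(idx, "post element missing data-author")
        text = node.text_content().strip()
        if not text:
            log.warning("post element %d: empty text, post rejected", idx)
            continue
        posts.append(
            Post(
                author=author,
                text=text,
                group=node.get("data-group") or None,
                topic=node.get("data-topic") or None,
                has_inclusion=bool(node.xpath(".//blockquote")),
            )
        )
    return posts


def write_posts(posts: Iterable[Post], path: str | Path, format: str = "jsonl") -> None:
    """Serialize posts as JSON-lines or CSV (inverse of :func:`read_posts`)."""
    path = Path(path)
    if format == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for p in posts:
                rec = {"author": p.author, "text": p.text}
                if p.group:
                    rec["group"] = p.group
                if p.topic:
                    rec["topic"] = p.topic
                fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
    elif format == "csv":
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["author", "group", "topic", "text"])
            writer.writeheader()
            for p in posts:
                writer.writerow(
                    {"author": p.author, "group": p.group or "",
                     "topic": p.topic or "", "text": p.text}
                )
    else:
        raise ValueError(f"unknown format {format!r}")


def remove_inclusions(posts: Sequence[Post]) -> list[Post]:
    """Drop every post that embeds quoted text of another post.

    Quoted inclusions mix several authors' writing into one message and
    would contaminate per-author models.  The number of removed posts is
    logged; the returned list preserves order.
    """
    kept = [p for p in posts if not p.has_inclusion]
    removed = len(posts) - len(kept)
    if removed:
        log.info("removed %d of %d posts with quoted inclusions", removed, len(posts))
    return kept


# ---------------------------------------------------------------------------
# per-author document sets


@dataclass
class AuthorCorpus:
    """Mapping author -> ordered list of normalized documents."""

    documents: dict[str, list[str]]
    variant: TextVariant
    metadata: dict = field(default_factory=dict)

    @property
    def authors(self) -> list[str]:
        return sorted(self.documents)

    def counts(self) -> dict[str, int]:
        return {a: len(d) for a, d in sorted(self.documents.items())}

    def to_jsonl(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w", encoding="utf-8") as fh:
            for author in self.authors:
                for text in self.documents[author]:
                    fh.write(json.dumps({"author": author, "text": text},
                                        ensure_ascii=False) + "\n")
        manifest = {
            "variant": self.variant.value,
            "counts": self.counts(),
            **self.metadata,
        }
        path.with_suffix(path.suffix + ".manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
        )


def build_author_corpus(
    posts: Sequence[Post],
    variant: TextVariant = TextVariant.ORIGINAL,
    drop_inclusions: bool = True,
) -> AuthorCorpus:
    """Clean and normalize posts into per-author document lists.

    Removes quoted-inclusion posts (unless ``drop_inclusions=False``),
    applies the text variant, and silently drops documents that become empty
    under it (with a logged warning).
    """
    if drop_inclusions:
        posts = remove_inclusions(posts)
    documents: dict[str, list[str]] = {}
    dropped = 0
    for p in posts:
        try:
            text = normalize_text(p.text, variant)
        except EmptyDocumentError:
            dropped += 1
            continue
        documents.setdefault(p.author, []).append(text)
    if dropped:
        log.warning("%d documents empty under %s were dropped", dropped, variant)
    return AuthorCorpus(documents=documents, variant=variant)


def _fold_assignment(n_docs: int, n_per_author: int, k: int, seed: int,
                     author: str) -> tuple[list[int], list[int]]:
    """Seeded shuffle of an author's doc indices + round-robin fold deal.

    Returns (retained indices in shuffled order, fold id per position).
    """
    import random

    rng = random.Random(f"{seed}:{author}")
    idx = list(range(n_docs))
    rng.shuffle(idx)
    retained = idx[:n_per_author]
    folds = [i % k for i in range(n_per_author)]
    return retained, folds


def balance_and_split(
    corpus: AuthorCorpus,
    n_per_author: int,
    n_test: int,
    fold: int,
    k: int,
    seed: int,
) -> tuple[AuthorCorpus, AuthorCorpus]:
    """Balance every author to ``n_per_author`` documents and cut one CV fold.

    Documents are shuffled once per author with the run seed, the first
    ``n_per_author`` retained, and dealt round-robin to ``k`` folds; the
    requested ``fold`` becomes the test set.  Across the k folds every
    retained document appears in test exactly once.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if not 0 <= fold < k:
        raise ValueError(f"fold must be in [0, {k})")
    if n_per_author % k != 0:
        raise ValueError(f"n_per_author={n_per_author} not divisible by k={k}")
    if n_test != n_per_author // k:
        raise ValueError(
            f"n_test={n_test} must equal n_per_author/k={n_per_author // k}"
        )
    train_docs: dict[str, list[str]] = {}
    test_docs: dict[str, list[str]] = {}
    for author in corpus.authors:
        docs = corpus.documents[author]
        if len(docs) < n_per_author:
            raise ValueError(
                f"author {author!r} has {len(docs)} documents, needs {n_per_author}"
            )
        retained, folds = _fold_assignment(len(docs), n_per_author, k, seed, author)
        train_docs[author] = [docs[j] for j, f in zip(retained, folds) if f != fold]
        test_docs[author] = [docs[j] for j, f in zip(retained, folds) if f == fold]
    meta = {"seed": seed, "fold": fold, "k": k, "n_per_author": n_per_author}
    return (
        AuthorCorpus(train_docs, corpus.variant, {**meta, "split": "train"}),
        AuthorCorpus(test_docs, corpus.variant, {**meta, "split": "test"}),
    )


def split_by_group(
    posts: Sequence[Post], train_group: str
) -> tuple[list[Post], list[Post]]:
    """Cross-group split: train on one subforum, test on all the others."""
    groups = {p.group for p in posts}
    if train_group not in groups:
        raise ValueError(f"train_group {train_group!r} not present (have {sorted(g or '' for g in groups)})")
    train = [p for p in posts if p.group == train_group]
    test = [p for p in posts if p.group != train_group]
    if not test:
        log.warning("all posts are in train_group %r; test set is empty", train_group)
    return train, test


def chunk_documents(texts: Sequence[str], words_per_chunk: int) -> list[str]:
    """Merge texts and cut them into equal fragments of exactly N words.

    All input texts are joined with single spaces, split on whitespace, and
    dealt into consecutive chunks of ``words_per_chunk`` tokens; the
    trailing partial chunk is dropped so every fragment has exactly the
    stated size.
    """
    if words_per_chunk < 1:
        raise ValueError("words_per_chunk must be >= 1")
    words = " ".join(texts).split()
    n_chunks = len(words) // words_per_chunk
    if n_chunks == 0:
        log.warning(
            "only %d words available, fewer than words_per_chunk=%d",
            len(words), words_per_chunk,
        )
        return []
    return [
        " ".join(words[i * words_per_chunk : (i + 1) * words_per_chunk])
        for i in range(n_chunks)
    ]
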