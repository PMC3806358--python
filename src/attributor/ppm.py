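"""Prediction-by-partial-matching (PPM) statistical text models.

A PPM model predicts the next symbol of a stream from the longest matching
context of up to ``max_order`` preceding symbols, blending predictions from
shorter contexts through an *escape mechanism*: at each context length the
model reserves some probability mass for symbols it has not seen there, and
that mass is passed down to the next shorter context, ultimately to a
uniform distribution over the alphabet (the order(-1) model).  Escape mass
uses PPMD accounting: a symbol seen ``c`` times after a context with ``T``
total successors contributes ``(2c - 1) / (2T)``, and the escape mass of
the context is ``d / (2T)`` where ``d`` is the number of distinct
successors.  The blend is additive — every matched order contributes its
share, weighted by the product of the escape masses of all longer matched
orders — so the predictive distribution sums to exactly 1 by construction.
No exclusions are applied: the blend is a pure escape-chain product.

With ``max_order=5`` over characters this is the classic PPM5 text model.
Used as a classifier, one model is trained per class and a test document is
scored by its cross-entropy (bits/symbol) under each model: the lower the
entropy, the better the model predicts the document, and the document is
attributed to the minimum-entropy class.

Models are *frozen*: counts are fixed at training time and scoring never
adapts them, so results are exactly reproducible and scoring cost is
independent across documents and classes.

Implementation note: n-grams are stored as sentinel-tagged packed integers
(``code = ((1 << B | id_1) << B | id_2) ...``) so count lookups hash
machine ints instead of strings; dropping the last symbol of a gram is a
single right shift.  The packing is invisible outside this module —
serialization and the introspection helpers speak symbols.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "OOV",
    "BOUNDARY",
    "ContextModel",
    "train_model",
    "symbol_probability",
    "cross_entropy",
    "tokenize_words",
]

# Reserved symbols, shared between the character and word units: a character
# stream never contains control characters after encoding normalization, and
# word tokens are purely alphabetic, so collisions with real data are
# impossible.
OOV = "\x00"  #: alphabet slot for symbols never seen in training
BOUNDARY = "\x01"  #: separator between training documents

_WORD_RE = re.compile(r"[^\W\d_]+")

_LOG2 = math.log(2.0)


def tokenize_words(text: str) -> list[str]:
    """Lowercased alphabetic word tokens of ``text``.

    Punctuation, digits and every other non-alphabetic character are
    discarded; what remains is the symbol stream for word-unit models.
    """
    return [m.group(0).lower() for m in _WORD_RE.finditer(text)]


def _bits_for(n_symbols: int) -> int:
    return max(4, (n_symbols - 1).bit_length())


@dataclass
class ContextModel:
    """Frozen per-class PPM statistics.

    Attributes
    ----------
    max_order:
        Longest context length used for prediction (5 for PPM5).
    unit:
        ``"character"`` or ``"word"``; decides how raw text is segmented.
    alphabet:
        Ordered tuple of all symbols seen in training plus the reserved
        :data:`OOV` and :data:`BOUNDARY` symbols.  A symbol's id is its
        index here.
    counts:
        Mapping ``packed n-gram code -> occurrence count`` for every n-gram
        of length ``1..max_order+1`` of the training stream.  Use
        :meth:`successors` for a symbol-level view.
    n_symbols:
        Length of the concatenated training stream.
    """

    max_order: int
    unit: str
    alphabet: tuple
    counts: dict
    n_symbols: int
    # optional precomputed context stats (training fast path); not serialized
    precomputed_stats: dict | None = field(default=None, repr=False, compare=False)
    # all derived state below is rebuilt in __post_init__, never serialized
    _bits: int = field(init=False, repr=False, compare=False)
    _sym_id: dict = field(init=False, repr=False, compare=False)
    _ctx_stats: dict = field(init=False, repr=False, compare=False)
    _score_cache: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.unit not in ("character", "word"):
            raise ValueError(f"unknown unit {self.unit!r}")
        if len(self.alphabet) < 2:
            raise ValueError("alphabet must contain OOV plus at least one symbol")
        self._bits = _bits_for(len(self.alphabet))
        self._sym_id = {s: i for i, s in enumerate(self.alphabet)}
        self._score_cache = {}
        if self.precomputed_stats is not None:
            self._ctx_stats = self.precomputed_stats
            self.precomputed_stats = None
        else:
            self._build_ctx_stats()

    def _build_ctx_stats(self) -> None:
        """Precompute (1/(2T), d/(2T)) for every context from the gram counts."""
        totals: dict = {}
        distinct: dict = {}
        bits = self._bits
        for code, c in self.counts.items():
            ctx = code >> bits
            if ctx in totals:
                totals[ctx] += c
                distinct[ctx] += 1
            else:
                totals[ctx] = c
                distinct[ctx] = 1
        self._ctx_stats = {
            ctx: (0.5 / t, 0.5 * distinct[ctx] / t) for ctx, t in totals.items()
        }

    # -- packing helpers ---------------------------------------------------

    def _decode(self, code: int) -> tuple:
        syms = []
        bits, mask = self._bits, (1 << self._bits) - 1
        while code > 1:
            syms.append(self.alphabet[code & mask])
            code >>= bits
        return tuple(reversed(syms))

    def _encode(self, symbols) -> int:
        bits = self._bits
        code = 1
        for s in symbols:
            code = code << bits | self._sym_id[s]
        return code

    # -- introspection -----------------------------------------------------

    def successors(self, context) -> dict:
        """Symbol -> count table for the given context (empty if unseen)."""
        if self.unit == "character":
            ctx = tuple(context)
        else:
            ctx = tuple(context)
        out = {}
        for code, c in self.counts.items():
            gram = self._decode(code)
            if len(gram) == len(ctx) + 1 and gram[:-1] == ctx:
                out[gram[-1]] = c
        return out

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        """Versioned plain-dict dump; round-trips exactly."""
        if self.unit == "character":
            items = sorted("".join(self._decode(k)) for k in self.counts)
            pairs = [[g, self.counts[self._encode(g)]] for g in items]
        else:
            decoded = sorted(self._decode(k) for k in self.counts)
            pairs = [["\x1f".join(g), self.counts[self._encode(g)]] for g in decoded]
        return {
            "format": "attributor-ppm/1",
            "max_order": self.max_order,
            "unit": self.unit,
            "escape": "D",
            "oov": OOV,
            "boundary": BOUNDARY,
            "alphabet": list(self.alphabet),
            "n_symbols": self.n_symbols,
            "counts": pairs,
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "ContextModel":
        if payload.get("format") != "attributor-ppm/1":
            raise ValueError("unrecognized model format")
        unit = payload["unit"]
        alphabet = tuple(payload["alphabet"])
        sym_id = {s: i for i, s in enumerate(alphabet)}
        bits = _bits_for(len(alphabet))

        def encode(symbols) -> int:
            code = 1
            for s in symbols:
                code = code << bits | sym_id[s]
            return code

        counts = {}
        for key, v in payload["counts"]:
            gram = tuple(key) if unit == "character" else tuple(key.split("\x1f"))
            counts[encode(gram)] = int(v)
        return cls(
            max_order=int(payload["max_order"]),
            unit=unit,
            alphabet=alphabet,
            counts=counts,
            n_symbols=int(payload["n_symbols"]),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), ensure_ascii=True, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ContextModel":
        return cls.from_dict(json.loads(text))


def _segment(text: str, unit: str):
    """Raw text -> symbol sequence (str for characters, token list for words)."""
    if unit == "character":
        return text
    return tokenize_words(text)


def train_model(
    texts: Sequence[str] | Iterable[str],
    max_order: int = 5,
    unit: str = "character",
) -> ContextModel:
    """Count every n-gram of length ``1..max_order+1`` of the training stream.

    Training documents are joined into one stream separated by a reserved
    :data:`BOUNDARY` symbol, which participates in contexts (so statistics
    never bleed across a document boundary for free) but is never emitted
    during test scoring.  Documents empty after segmentation are dropped;
    training fails only if nothing remains.  Deterministic: identical texts
    give byte-identical serialized models.
    """
    if max_order < 0:
        raise ValueError("max_order must be >= 0")
    segments = [s for s in (_segment(t, unit) for t in texts) if len(s) > 0]
    if not segments:
        raise ValueError("all training texts are empty after segmentation")

    stream: list = []
    for seg in segments:
        if stream:
            stream.append(BOUNDARY)
        stream.extend(seg)

    alphabet = tuple(sorted(set(stream) | {OOV, BOUNDARY}))
    sym_id = {s: i for i, s in enumerate(alphabet)}
    bits = _bits_for(len(alphabet))
    n = len(stream)
    maxlen = min(max_order + 1, n)

    counts: dict = {}
    stats: dict | None = None
    if (maxlen * bits + 1) <= 62:  # packed codes fit in int64: vectorized path
        stats = {}
        ids = np.array([sym_id[s] for s in stream], dtype=np.int64)
        gram = ids | (1 << bits)
        for length in range(1, maxlen + 1):
            u, c = np.unique(gram[length - 1 :], return_counts=True)
            counts.update(zip(u.tolist(), c.tolist()))
            # contexts of length-1 shorter: group the sorted gram codes by
            # their prefix (code >> bits is monotone on same-length codes)
            ctx, first, distinct = np.unique(
                u >> bits, return_index=True, return_counts=True
            )
            totals = np.add.reduceat(c, first)
            inv2t = 0.5 / totals
            esc = 0.5 * distinct / totals
            stats.update(
                zip(ctx.tolist(), zip(inv2t.tolist(), esc.tolist()))
            )
            if length < maxlen:
                gram = gram.copy()
                gram[length:] = (gram[length - 1 : n - 1] << bits) | ids[length:]
    else:  # arbitrarily large alphabets/orders: plain-int fallback
        ids_list = [sym_id[s] for s in stream]
        for length in range(1, maxlen + 1):
            for i in range(length - 1, n):
                code = 1
                for j in range(i - length + 1, i + 1):
                    code = code << bits | ids_list[j]
                counts[code] = counts.get(code, 0) + 1

    return ContextModel(
        max_order=max_order,
        unit=unit,
        alphabet=alphabet,
        counts=counts,
        n_symbols=n,
        precomputed_stats=stats,
    )


def _blend_codes(model: ContextModel, codes: Sequence[int]) -> float:
    """Escape-chain blend for one window given its suffix codes.

    ``codes[l]`` is the packed code of the window's last ``l`` symbols
    (``codes[0]`` is the empty-context sentinel).  Walks suffixes from
    longest to shortest; contexts never seen in training are skipped
    without consuming escape mass; the order(-1) term is uniform over the
    alphabet.  Memoized on the suffix code via the recursion
    ``B(w) = [PPMD term of longest context] + [its escape mass] * B(w[1:])``.
    """
    cache = model._score_cache
    ctx_stats = model._ctx_stats
    counts = model.counts
    bits = model._bits
    top = len(codes) - 1
    level = top
    value = None
    while level >= 1:
        value = cache.get(codes[level])
        if value is not None:
            break
        level -= 1
    if value is None:
        value = 1.0 / len(model.alphabet)
        level = 0
    while level < top:
        level += 1
        code = codes[level]
        stats = ctx_stats.get(code >> bits)  # context = gram minus last symbol
        if stats is not None:
            c = counts.get(code)
            term = (2 * c - 1) * stats[0] if c is not None else 0.0
            value = term + stats[1] * value
        cache[code] = value
    return value


def symbol_probability(model: ContextModel, context, symbol) -> float:
    """Predictive probability of ``symbol`` after ``context``.

    ``context`` is a string (character unit) or a sequence of tokens (word
    unit); only its last ``max_order`` symbols are used.  Symbols outside
    the training alphabet — in the context or as the prediction target —
    map to the reserved OOV slot, so the result is always in ``(0, 1]``.
    """
    sym_id = model._sym_id
    oov = sym_id[OOV]
    window = [sym_id.get(s, oov) for s in tuple(context)[-model.max_order :]]
    window.append(sym_id.get(symbol, oov))
    bits = model._bits
    # codes[l] = packed code of the last l window symbols
    codes = [1]
    for l in range(1, len(window) + 1):
        code = 1
        for s in window[-l:]:
            code = code << bits | s
        codes.append(code)
    return _blend_codes(model, codes)


def cross_entropy(model: ContextModel, text: str) -> float:
    """Cross-entropy of ``text`` under ``model`` in bits per symbol.

    Returns ``-(1/N) * sum_i log2 P(s_i | s_{i-max_order} .. s_{i-1})``
    over the N symbols of the segmented text.  Scoring starts with an empty
    context (orders grow from 0 over the first symbols) and never mutates
    the model's statistics.  Raises ``ValueError`` for text empty after
    segmentation.
    """
    sym_id = model._sym_id
    oov = sym_id[OOV]
    syms = _segment(text, model.unit)
    n = len(syms)
    if n == 0:
        raise ValueError("cannot score an empty document")

    bits = model._bits
    maxlen = min(model.max_order + 1, n)
    sentinel = 1 << bits
    ids = [sym_id.get(s, oov) for s in syms]
    # grams[l][i] = packed code of the l-gram ending at position i (i >= l-1)
    grams: list = [None, [sentinel | s for s in ids]]
    for length in range(2, maxlen + 1):
        prev = grams[length - 1]
        cur = [0] * (length - 1)
        cur.extend(
            (p << bits) | s for p, s in zip(prev[length - 2 : n - 1], ids[length - 1 :])
        )
        grams.append(cur)

    cache = model._score_cache
    cache_get = cache.get
    stats_get = model._ctx_stats.get
    counts_get = model.counts.get
    uniform = 1.0 / len(model.alphabet)
    log = math.log
    top_gram = grams[maxlen]
    log_total = 0.0
    for i in range(n):
        if i + 1 >= maxlen:
            top = maxlen
            code = top_gram[i]
        else:
            top = i + 1
            code = grams[top][i]
        v = cache_get(code)
        if v is None:
            level = top - 1
            while level >= 1:
                v = cache_get(grams[level][i])
                if v is not None:
                    break
                level -= 1
            else:
                v = uniform
                level = 0
            while level < top:
                level += 1
                code = grams[level][i]
                stats = stats_get(code >> bits)
                if stats is not None:
                    c = counts_get(code)
                    term = (2 * c - 1) * stats[0] if c is not None else 0.0
                    v = term + stats[1] * v
                cache[code] = v
        log_total += log(v)
    return -log_total / (n * _LOG2)
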