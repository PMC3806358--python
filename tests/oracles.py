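"""Independent brute-force oracles used by the test suite.

These deliberately re-derive everything from first principles — successor
tables by scanning the training stream position by position, probabilities
by the escape-chain recursion written out longhand — so they share no code
path with the implementation they check.
"""

from __future__ import annotations

OOV = "\x00"
BOUNDARY = "\x01"


def oracle_tables(texts, max_order):
    """Successor count tables for every context of length 0..max_order."""
    stream = BOUNDARY.join(t for t in texts if t)
    tables: dict = {}
    for length in range(max_order + 1):
        for i in range(length, len(stream)):
            ctx = stream[i - length : i]
            tables.setdefault(ctx, {})
            tables[ctx][stream[i]] = tables[ctx].get(stream[i], 0) + 1
    alphabet = sorted(set(stream) | {OOV, BOUNDARY})
    return tables, alphabet


def oracle_probability(tables, alphabet, max_order, context, symbol):
    """Recursive escape-chain evaluation of P(symbol | context).

    At each matched context the symbol's PPMD share is (2c-1)/(2T) and the
    escape mass d/(2T) is passed to the next shorter context; the recursion
    bottoms out at the uniform order(-1) distribution over the alphabet.
    """
    aset = set(alphabet)
    ctx = "".join(c if c in aset else OOV for c in context[-max_order:])
    sym = symbol if symbol in aset else OOV

    def prob(c, done):
        if done:
            return 1.0 / len(alphabet)
        shorter = (c[1:], False) if c else ("", True)
        tbl = tables.get(c)
        if tbl is None:
            return prob(*shorter)
        total = sum(tbl.values())
        distinct = len(tbl)
        count = tbl.get(sym, 0)
        share = (2 * count - 1) / (2 * total) if count else 0.0
        return share + (distinct / (2 * total)) * prob(*shorter)

    return prob(ctx, False)


def oracle_cross_entropy(tables, alphabet, max_order, text):
    """Mean negative log2 oracle probability over the text's positions."""
    import math

    total = 0.0
    for i in range(len(text)):
        p = oracle_probability(tables, alphabet, max_order, text[:i], text[i])
        total += math.log2(p)
    return -total / len(text)
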