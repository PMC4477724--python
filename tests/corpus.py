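"""Shared test helpers: brute-force matching oracle and random corpora.

The oracle is deliberately independent of the production matcher: it
enumerates every (start, end) candidate substring, filters by word
boundaries and dictionary membership after whitespace normalization and
case folding, and greedily keeps leftmost-longest non-overlapping spans.
"""

from __future__ import annotations

import random

from whg.glossary_model import Glossary, WordType, add_term, create_glossary


def _word_char(c: str) -> bool:
    # letters/digits plus hyphen; underscore is a boundary
    return (c.isalnum() and c != "_") or c == "-"


def oracle_find(text: str, keys: set[str]) -> list[tuple[int, int, str]]:
    """All-candidates brute-force reference for leftmost-longest matching."""
    n = len(text)
    candidates: list[tuple[int, int, str]] = []
    for i in range(n):
        if i > 0 and _word_char(text[i - 1]):
            continue
        for j in range(i + 1, n + 1):
            s = text[i:j]
            if s != s.strip():
                continue
            if j < n and _word_char(text[j]):
                continue
            norm = " ".join(s.split()).casefold()
            if norm in keys:
                candidates.append((i, j, norm))
    candidates.sort(key=lambda t: (t[0], -(t[1] - t[0])))
    chosen: list[tuple[int, int, str]] = []
    last_end = 0
    for i, j, k in candidates:
        if i >= last_end:
            chosen.append((i, j, k))
            last_end = j
    return chosen


_ALPHABET = ["ab", "cd", "ox", "zone", "gas", "flux", "acid", "q", "redox"]
_PUNCT = [".", ",", ";", ":", "(", ")", "-", "_"]
_WS = [" ", "  ", "\n", "\t ", " \n "]


def random_terms(rng: random.Random, max_terms: int = 20) -> set[str]:
    terms = set()
    for _ in range(rng.randint(1, max_terms)):
        nwords = rng.randint(1, 3)
        terms.add(" ".join(rng.choice(_ALPHABET) for _ in range(nwords)))
    return terms


def random_text(rng: random.Random, terms: set[str], max_len: int = 500) -> str:
    ordered = sorted(terms)
    parts: list[str] = []
    length = 0
    target = rng.randint(20, max_len)
    while length < target:
        r = rng.random()
        if r < 0.35:
            tok = rng.choice(_ALPHABET)
        elif r < 0.55:
            tok = rng.choice(ordered)
        elif r < 0.65:
            tok = rng.choice(_PUNCT)
        else:
            tok = rng.choice(_WS)
        if rng.random() < 0.2:
            tok = tok.upper()
        parts.append(tok)
        length += len(tok)
    return "".join(parts)[:max_len]


def glossary_from_terms(terms: set[str], name: str = "rand") -> Glossary:
    g = create_glossary(name, 1, [False])
    for t in sorted(terms):
        add_term(g, t, WordType.NO_TYPE, None, [f"definition of {t}"])
    return g


def random_html_document(rng: random.Random, terms: set[str]) -> str:
    """Small well-formed HTML with text, anchors and a script block."""
    ordered = sorted(terms)
    body_bits: list[str] = []
    for _ in range(rng.randint(1, 4)):
        body_bits.append("<p>" + random_text(rng, terms, 160) + "</p>")
        if rng.random() < 0.7:
            t = rng.choice(ordered)
            body_bits.append(f'<a href="#{rng.randrange(100)}">{t}</a>')
        if rng.random() < 0.4:
            t = rng.choice(ordered)
            body_bits.append(f'<script>var x = "{t}";</script>')
    return (
        "<html><head><title>t</title></head><body>"
        + "".join(body_bits)
        + "</body></html>"
    )


def anchors_of(html: str) -> list[tuple[str, str]]:
    """(href, inner text) of every anchor, via a throwaway parser."""
    from html.parser import HTMLParser

    out: list[tuple[str, str]] = []

    class P(HTMLParser):
        def __init__(self):
            super().__init__(convert_charrefs=False)
            self._href = None
            self._buf: list[str] = []

        def handle_starttag(self, tag, attrs):
            if tag == "a":
                self._href = dict(attrs).get("href", "")
                self._buf = []

        def handle_data(self, data):
            if self._href is not None:
                self._buf.append(data)

        def handle_endtag(self, tag):
            if tag == "a" and self._href is not None:
                out.append((self._href, "".join(self._buf)))
                self._href = None

    p = P()
    p.feed(html)
    return out
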