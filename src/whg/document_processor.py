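"""Document annotation: safe/unsafe segmentation, term matching, HG tagging.

The processing pipeline mirrors a server-side hyperglossary: an input
document (HTML or plain text) is split into contiguous character segments
classified *safe* (plain text eligible for tagging) or *unsafe* (markup,
pre-existing anchors, scripts, styles, head content, comments, character
references and previously inserted HG spans — all preserved byte-for-byte).
Glossary terms are located in safe segments with leftmost-longest,
case-insensitive whole-word matching, and each hit is wrapped in an HG tag:

    <span class="hg3" context="search" wordterm="KEY">MATCHED TEXT</span>

where ``KEY`` is the case-folded canonical glossary key and the display
text keeps its original casing.  Because HG spans are themselves unsafe on
re-entry, processing is idempotent.

Offsets are 0-based half-open throughout.  Word characters are Unicode
letters, digits and the hyphen, so "ozone-depleting" does not match
"ozone"; phrase-internal spaces match any run of whitespace.
"""

from __future__ import annotations

import html as _htmllib
import re
from dataclasses import dataclass, field
from enum import Enum
from html.parser import HTMLParser
from typing import Iterable, Optional

from .errors import (
    EmptyGlossaryError,
    InactiveGlossaryError,
    OverlapError,
    SegmentSafetyError,
)
from .glossary_model import Glossary, term_key

#: Elements whose entire content (and the tags themselves) is never tagged.
DEFAULT_UNSAFE_ELEMENTS = frozenset(
    {"a", "script", "style", "head", "title", "textarea"}
)

HG_CLASS = "hg3"
HG_CONTEXT = "search"

_VOID_ELEMENTS = frozenset(
    {"area", "base", "br", "col", "embed", "hr", "img", "input",
     "link", "meta", "param", "source", "track", "wbr"}
)


class Safety(Enum):
    SAFE = "safe"
    UNSAFE = "unsafe"


@dataclass(frozen=True)
class DocumentSegment:
    """A contiguous slice of the source document."""

    text: str
    safety: Safety
    start: int
    end: int

    @property
    def safe(self) -> bool:
        return self.safety is Safety.SAFE


@dataclass(frozen=True)
class HGTagSpan:
    """A matched term occurrence inside one safe segment.

    ``start``/``end`` index into the segment's text, not the document.
    """

    start: int
    end: int
    matched_text: str
    wordterm: str
    glossary_name: str
    segment_index: int = 0


@dataclass
class ProcessedDocument:
    source: str
    segments: list[DocumentSegment]
    spans: list[HGTagSpan]
    html_out: str

    def spans_payload(self) -> list[dict]:
        """JSON-ready sidecar listing every span for portlet assembly."""
        out = []
        for s in self.spans:
            seg = self.segments[s.segment_index]
            out.append(
                {
                    "wordterm": s.wordterm,
                    "matched_text": s.matched_text,
                    "glossary": s.glossary_name,
                    "start": seg.start + s.start,
                    "end": seg.start + s.end,
                }
            )
        return out


class _Segmenter(HTMLParser):
    """Tolerant HTML tokenizer that classifies raw character ranges.

    Built on the stdlib forgiving parser with ``convert_charrefs=False``
    so that entity/character references surface as distinct (unsafe)
    tokens and every safe data token is a literal substring of the source.
    """

    def __init__(self, source: str, unsafe_elements: frozenset[str]):
        super().__init__(convert_charrefs=False)
        self.source = source
        self.unsafe_elements = unsafe_elements
        # (offset, length, safe) for data tokens; everything else is unsafe
        self.tokens: list[tuple[int, int, bool]] = []
        self._stack: list[str] = []  # open unsafe elements (incl. hg spans)
        self._span_depth = 0  # nested plain <span> inside an hg span
        self._line_starts = [0]
        for m in re.finditer("\n", source):
            self._line_starts.append(m.end())

    def _abs(self) -> int:
        line, col = self.getpos()
        return self._line_starts[line - 1] + col

    def _unsafe_now(self) -> bool:
        return bool(self._stack)

    def _is_hg_span(self, tag: str, attrs) -> bool:
        if tag != "span":
            return False
        for k, v in attrs:
            if k == "class" and v and HG_CLASS in v.split():
                return True
        return False

    def handle_starttag(self, tag, attrs):
        if self._stack and self._stack[-1] == "span" and tag == "span":
            self._span_depth += 1
        elif tag in self.unsafe_elements and tag not in _VOID_ELEMENTS:
            self._stack.append(tag)
        elif self._is_hg_span(tag, attrs):
            self._stack.append("span")

    def handle_endtag(self, tag):
        if self._stack:
            if self._stack[-1] == "span" and tag == "span":
                if self._span_depth:
                    self._span_depth -= 1
                else:
                    self._stack.pop()
            elif tag in self._stack:
                while self._stack and self._stack[-1] != tag:
                    self._stack.pop()
                if self._stack:
                    self._stack.pop()

    def handle_startendtag(self, tag, attrs):
        pass  # self-closing: never opens an unsafe scope

    def handle_data(self, data):
        start = self._abs()
        self.tokens.append((start, len(data), not self._unsafe_now()))


def segment(
    source: str,
    unsafe_elements: Iterable[str] = DEFAULT_UNSAFE_ELEMENTS,
) -> list[DocumentSegment]:
    """Split a document into contiguous safe/unsafe segments.

    Safe segments are exactly the text-node content outside unsafe
    elements; all markup, attributes, comments and character references
    are unsafe.  Plain text without markup yields a single safe segment;
    an empty document yields an empty list.  Adjacent ranges of equal
    safety are merged, and the segments concatenate to the source.
    """
    if source == "":
        return []
    parser = _Segmenter(source, frozenset(unsafe_elements))
    parser.feed(source)
    parser.close()

    # Safe character ranges; gaps between them are unsafe markup.
    safe_ranges = [
        (off, off + n) for off, n, safe in parser.tokens if safe and n > 0
    ]
    safe_ranges.sort()
    segments: list[DocumentSegment] = []
    pos = 0
    for start, end in safe_ranges:
        if start < pos:  # overlapping token from a parser quirk: keep first
            start = pos
            if start >= end:
                continue
        if start > pos:
            segments.append(
                DocumentSegment(source[pos:start], Safety.UNSAFE, pos, start)
            )
        segments.append(DocumentSegment(source[start:end], Safety.SAFE, start, end))
        pos = end
    if pos < len(source):
        segments.append(
            DocumentSegment(source[pos:], Safety.UNSAFE, pos, len(source))
        )
    # merge adjacent equal-safety segments
    merged: list[DocumentSegment] = []
    for seg in segments:
        if merged and merged[-1].safety is seg.safety:
            prev = merged[-1]
            merged[-1] = DocumentSegment(
                prev.text + seg.text, prev.safety, prev.start, seg.end
            )
        else:
            merged.append(seg)
    return merged


_WORD_CHAR = r"[^\W_]|-"  # Unicode letters/digits plus hyphen
_LEFT_BOUNDARY = r"(?<![^\W_])(?<!-)"
_RIGHT_BOUNDARY = r"(?![^\W_])(?!-)"


def _phrase_pattern(key: str) -> str:
    words = key.split(" ")
    body = r"\s+".join(re.escape(w) for w in words)
    return _LEFT_BOUNDARY + body + _RIGHT_BOUNDARY


@dataclass
class Matcher:
    """Compiled whole-word, case-insensitive recognizer for one glossary."""

    glossary_name: str
    keys: list[str]
    _combined: re.Pattern = field(repr=False, default=None)
    _per_key: list[tuple[str, re.Pattern]] = field(repr=False, default_factory=list)

    def find(self, text: str) -> list[tuple[int, int, str]]:
        """Leftmost-longest non-overlapping matches as (start, end, key)."""
        out: list[tuple[int, int, str]] = []
        pos = 0
        while pos <= len(text):
            m = self._combined.search(text, pos)
            if m is None:
                break
            at = m.start()
            # pick the longest actual match anchored at this position
            best: Optional[tuple[int, str]] = None
            for key, pat in self._per_key:
                km = pat.match(text, at)
                if km and (best is None or km.end() > best[0]):
                    best = (km.end(), key)
            assert best is not None
            out.append((at, best[0], best[1]))
            pos = best[0] if best[0] > at else at + 1
        return out


def build_matcher(glossary: Glossary) -> Matcher:
    """Compile the glossary's term keys into a phrase matcher.

    Longer phrases take precedence, matching is case-insensitive, and
    multi-word keys match across any internal whitespace run.
    """
    if not glossary.active:
        raise InactiveGlossaryError(f"glossary {glossary.name!r} is inactive")
    keys = sorted(glossary.terms, key=lambda k: (-len(k), k))
    if not keys:
        raise EmptyGlossaryError(f"glossary {glossary.name!r} has no terms")
    combined = re.compile(
        "|".join(_phrase_pattern(k) for k in keys),
        re.IGNORECASE | re.UNICODE,
    )
    per_key = [
        (k, re.compile(_phrase_pattern(k), re.IGNORECASE | re.UNICODE)) for k in keys
    ]
    return Matcher(glossary.name, keys, combined, per_key)


def find_matches(
    matcher: Matcher, seg: DocumentSegment, segment_index: int = 0
) -> list[HGTagSpan]:
    """Locate glossary terms in one safe segment."""
    if not seg.safe:
        raise SegmentSafetyError("find_matches requires a safe segment")
    spans = []
    for start, end, key in matcher.find(seg.text):
        spans.append(
            HGTagSpan(
                start=start,
                end=end,
                matched_text=seg.text[start:end],
                wordterm=key,
                glossary_name=matcher.glossary_name,
                segment_index=segment_index,
            )
        )
    return spans


def _hg_open_tag(wordterm: str) -> str:
    escaped = _htmllib.escape(wordterm, quote=True)
    return f'<span class="{HG_CLASS}" context="{HG_CONTEXT}" wordterm="{escaped}">'


def render(
    source: str,
    segments: list[DocumentSegment],
    spans: list[HGTagSpan],
) -> str:
    """Reassemble the document with HG tags inserted around matches.

    Unsafe segments are copied byte-for-byte; within safe segments the
    matched display text is preserved verbatim inside the tag.
    """
    by_segment: dict[int, list[HGTagSpan]] = {}
    for s in spans:
        by_segment.setdefault(s.segment_index, []).append(s)
    out: list[str] = []
    for i, seg in enumerate(segments):
        seg_spans = sorted(by_segment.get(i, []), key=lambda s: s.start)
        if not seg.safe:
            if seg_spans:
                raise SegmentSafetyError("spans attached to an unsafe segment")
            out.append(seg.text)
            continue
        pos = 0
        for s in seg_spans:
            if s.start < pos:
                raise OverlapError(
                    f"overlapping spans at offset {s.start} in segment {i}"
                )
            out.append(seg.text[pos : s.start])
            out.append(_hg_open_tag(s.wordterm))
            out.append(seg.text[s.start : s.end])
            out.append("</span>")
            pos = s.end
        out.append(seg.text[pos:])
    return "".join(out)


def process_document(source: str, glossary: Glossary) -> ProcessedDocument:
    """Segment, match and tag a document against one active glossary.

    Re-processing the output inserts no new tags inside existing HG spans,
    so processing is idempotent on its own output.
    """
    matcher = build_matcher(glossary)
    segments = segment(source)
    spans: list[HGTagSpan] = []
    for i, seg in enumerate(segments):
        if seg.safe:
            spans.extend(find_matches(matcher, seg, segment_index=i))
    html_out = render(source, segments, spans)
    return ProcessedDocument(
        source=source, segments=segments, spans=spans, html_out=html_out
    )


_HG_TAG_RE = re.compile(
    r'<span class="%s" context="%s" wordterm="[^"]*">|</span>' % (HG_CLASS, HG_CONTEXT)
)


def strip_hg_tags(html_out: str) -> str:
    """Remove HG tags (keeping inner text); inverse of :func:`render`.

    Only exact HG open tags and their closers are removed, so applying
    this to a processed document recovers the source text byte-for-byte
    when the source contained no bare ``</span>`` closers of its own.
    """

    out = []
    pos = 0
    depth = 0
    for m in _HG_TAG_RE.finditer(html_out):
        text = m.group(0)
        if text == "</span>":
            if depth == 0:
                continue  # closer belonging to the source, keep it
            depth -= 1
        else:
            depth += 1
        out.append(html_out[pos : m.start()])
        pos = m.end()
    out.append(html_out[pos:])
    return "".join(out)
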