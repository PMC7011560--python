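"""Visible-text extraction and lexicon term counting.

The counter reports *occurrence* counts (every mention), not page-level
presence.  Matching semantics:

* tokens are maximal letter/digit runs; matches respect word boundaries,
  so "HRT" never fires inside "Hrthe" and "breast density" never fires on
  the token "breast" alone;
* multi-word variants tolerate any single run of whitespace and/or hyphens
  between their tokens ("endocrine-disrupting chemicals" matches);
* at any position the longest matching variant of a group wins, and a
  character span contributes to at most one match within the group
  (non-overlapping matches);
* acronym-flagged variants match case-sensitively, all others
  case-insensitively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import TYPE_CHECKING, Mapping

import lxml.etree
import lxml.html

from .lexicon import Lexicon, TermGroup
from .text import Token, is_phrase_gap, tokenize, tokens as _token_strings

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .cleaning import PageRecord

__all__ = [
    "PageTermCounts",
    "extract_visible_text",
    "count_group_mentions",
    "count_page",
    "counts_long_frame",
]


def counts_long_frame(counts: "list[PageTermCounts]"):
    """Long-format table (org_id, url, factor, count) as a DataFrame."""
    import pandas as pd

    return pd.DataFrame([
        {"org_id": c.org_id, "url": c.url, "factor": f, "count": n}
        for c in counts
        for f, n in c.counts.items()
    ])


@dataclass(frozen=True)
class PageTermCounts:
    """Factor -> occurrence count for one kept page."""

    org_id: str
    url: str
    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for factor, n in self.counts.items():
            if not isinstance(n, int) or n < 0:
                raise ValueError(f"count for {factor!r} must be a non-negative int")

    def total(self) -> int:
        return sum(self.counts.values())


# --------------------------------------------------------------------------
# Text extraction
# --------------------------------------------------------------------------

_SKIP_TAGS = {"script", "style", "noscript"}


def _collect_text(el, pieces: list[str]) -> None:
    tag = el.tag if isinstance(el.tag, str) else None
    if tag is None:
        # comment / processing instruction: drop content, keep tail
        if el.tail:
            pieces.append(el.tail)
        return
    if tag.lower() in _SKIP_TAGS:
        if el.tail:
            pieces.append(el.tail)
        return
    if el.text:
        pieces.append(el.text)
    for child in el:
        _collect_text(child, pieces)
    if el.tail:
        pieces.append(el.tail)


def extract_visible_text(html: str) -> str:
    """Visible text of *html*: script/style/comment content removed, entity
    references resolved, element boundaries rendered as whitespace.

    Lenient on malformed markup; idempotent on plain text (up to
    whitespace normalization).  Returns "" for empty or unparseable input.
    """
    if html is None or not html.strip():
        return ""
    try:
        doc = lxml.html.fromstring(html)
    except (lxml.etree.ParserError, lxml.etree.XMLSyntaxError, ValueError):
        return ""
    pieces: list[str] = []
    _collect_text(doc, pieces)
    return " ".join(" ".join(pieces).split())


# --------------------------------------------------------------------------
# Matching
# --------------------------------------------------------------------------


def _compile_group(group: TermGroup) -> tuple[tuple[tuple[str, ...], bool], ...]:
    """Variants as token tuples, longest first so longest-match wins.

    Case-insensitive variants are stored casefolded; acronym variants keep
    their exact form.  Ties in token length are broken by variant order,
    which is irrelevant because distinct variants of equal length cannot
    match the same token span.
    """
    compiled = []
    for variant, acronym in zip(group.variants, group.acronym_flags):
        toks = tuple(_token_strings(variant))
        if not acronym:
            toks = tuple(t.casefold() for t in toks)
        compiled.append((toks, acronym))
    compiled.sort(key=lambda item: -len(item[0]))
    return tuple(compiled)


@lru_cache(maxsize=512)
def _compiled_cached(group: TermGroup):
    return _compile_group(group)


def _match_at(
    text: str,
    toks: list[Token],
    folded: list[str],
    i: int,
    variant_tokens: tuple[str, ...],
    acronym: bool,
) -> bool:
    k = len(variant_tokens)
    if i + k > len(toks):
        return False
    for j, want in enumerate(variant_tokens):
        have = toks[i + j].text if acronym else folded[i + j]
        if have != want:
            return False
    # inter-token gaps must be whitespace/hyphen runs only
    for j in range(k - 1):
        if not is_phrase_gap(text, toks[i + j].end, toks[i + j + 1].start):
            return False
    return True


def _count_group_tokens(
    text: str, toks: list[Token], folded: list[str], group: TermGroup
) -> int:
    compiled = _compiled_cached(group)
    count = 0
    i = 0
    n = len(toks)
    while i < n:
        advanced = False
        for variant_tokens, acronym in compiled:
            if _match_at(text, toks, folded, i, variant_tokens, acronym):
                count += 1
                i += len(variant_tokens)
                advanced = True
                break
        if not advanced:
            i += 1
    return count


def count_group_mentions(text: str, group: TermGroup) -> int:
    """Number of non-overlapping mentions of *group*'s variants in *text*."""
    toks = tokenize(text)
    folded = [t.text.casefold() for t in toks]
    return _count_group_tokens(text, toks, folded, group)


def count_page(page: "PageRecord", lexicon: Lexicon) -> PageTermCounts:
    """Count every lexicon group on a kept page.

    The result has exactly one entry per lexicon factor (zeros included).
    Passing a dropped page is a contract violation.
    """
    if page.status != "kept":
        raise ValueError(
            f"count_page requires a kept page; {page.url} is {page.status} "
            f"({page.drop_reason})"
        )
    text = page.text or ""
    toks = tokenize(text)
    folded = [t.text.casefold() for t in toks]
    counts = {
        g.factor_name: _count_group_tokens(text, toks, folded, g) for g in lexicon
    }
    return PageTermCounts(org_id=page.org_id, url=page.url, counts=counts)
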