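"""Page-exclusion rules applied to crawled pages.

Pages leave this stage either *kept* (decoded, with visible text) or
*dropped* with exactly one reason, assigned by a fixed rule precedence so
drop-reason tallies are stable:

    broken -> undecodable -> manual -> subset_pattern
           -> sponsor_shop_forum -> language

``broken`` covers failed fetches (HTTP errors and transport failures);
``undecodable`` pages could not be decoded under any candidate charset;
``manual`` is an exact per-organization URL exclusion; ``subset_pattern``
enforces per-organization include/exclude URL substrings (e.g. restricting
a general women's-health site to its breast-cancer pages); ``sponsor_shop_
forum`` drops shop/product/donation/forum-style URLs; ``language`` drops
Spanish-language pages, since the lexicon holds English terms only.

Language identification is a stopword-ratio heuristic over fixed embedded
English and Spanish function-word lists, with an explicit ``<html lang>``
attribute taking precedence when present.  Pages with fewer tokens than
``min_tokens_for_language_call`` are labelled ``unknown`` and kept.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional

from .acquisition import FetchResult, OrgRecord
from .counting import extract_visible_text
from .text import ENGLISH_STOPWORDS, SPANISH_STOPWORDS, tokens

__all__ = [
    "DROP_REASONS",
    "PageRecord",
    "FilterRuleset",
    "decode_page",
    "detect_language",
    "apply_filters",
    "clean_pages",
    "drop_report",
    "read_pages_jsonl",
    "write_pages_jsonl",
]

DROP_REASONS = (
    "broken",
    "undecodable",
    "manual",
    "subset_pattern",
    "sponsor_shop_forum",
    "language",
)


@dataclass(frozen=True)
class PageRecord:
    org_id: str
    url: str
    provenance: str
    html: Optional[str] = None
    text: Optional[str] = None
    status: str = "kept"  # kept | dropped
    drop_reason: Optional[str] = None

    def __post_init__(self) -> None:
        if self.status not in ("kept", "dropped"):
            raise ValueError(f"bad status {self.status!r}")
        if self.status == "dropped":
            if self.drop_reason not in DROP_REASONS:
                raise ValueError(
                    f"dropped page {self.url} requires a drop_reason from "
                    f"{DROP_REASONS}, got {self.drop_reason!r}"
                )
        else:
            if self.drop_reason is not None:
                raise ValueError("kept page must not carry a drop_reason")
            if self.text is None:
                raise ValueError(f"kept page {self.url} requires text")


@dataclass(frozen=True)
class FilterRuleset:
    """Tunable exclusion rules.

    ``url_pattern_drops`` are case-insensitive substrings of the canonical
    URL; the defaults encode the sponsor/shop/forum page categories.
    """

    url_pattern_drops: tuple[str, ...] = (
        "shop", "store", "product", "cart", "donate-shop",
        "forum", "board", "sponsor",
    )
    min_tokens_for_language_call: int = 25
    spanish_stopword_threshold: float = 0.12

    def __post_init__(self) -> None:
        if not 0.0 <= self.spanish_stopword_threshold <= 1.0:
            raise ValueError("spanish_stopword_threshold must be in [0, 1]")


DEFAULT_RULESET = FilterRuleset()

_CHARSET_CANDIDATES = ("utf-8-sig", "cp1252")


def decode_page(fetch: FetchResult, org_id: str = "") -> PageRecord:
    """Turn a FetchResult into a provisional PageRecord.

    Failed fetches become ``dropped/broken``.  The body is decoded with
    the declared charset first, then UTF-8, then cp1252 (all strict); if
    every candidate fails the page is ``dropped/undecodable``.  On success
    the page is provisionally kept with its visible text extracted.
    """
    if not fetch.ok:
        return PageRecord(
            org_id=org_id, url=fetch.url, provenance=fetch.provenance,
            status="dropped", drop_reason="broken",
        )
    candidates = []
    if fetch.declared_charset:
        candidates.append(fetch.declared_charset)
    candidates.extend(_CHARSET_CANDIDATES)
    html = None
    for charset in candidates:
        try:
            html = fetch.body.decode(charset)
            break
        except (UnicodeDecodeError, LookupError):
            continue
    if html is None:
        return PageRecord(
            org_id=org_id, url=fetch.url, provenance=fetch.provenance,
            status="dropped", drop_reason="undecodable",
        )
    return PageRecord(
        org_id=org_id, url=fetch.url, provenance=fetch.provenance,
        html=html, text=extract_visible_text(html), status="kept",
    )


def detect_language(text: str, ruleset: FilterRuleset = DEFAULT_RULESET) -> str:
    """``en`` | ``es`` | ``unknown`` by stopword ratio.

    Spanish is called when the Spanish-stopword fraction both exceeds the
    threshold and exceeds the English-stopword fraction; otherwise English.
    Texts below the minimum token count are ``unknown``.
    """
    toks = [t.casefold() for t in tokens(text or "")]
    if len(toks) < ruleset.min_tokens_for_language_call:
        return "unknown"
    counts = Counter(toks)
    es = sum(n for t, n in counts.items() if t in SPANISH_STOPWORDS)
    en = sum(n for t, n in counts.items() if t in ENGLISH_STOPWORDS)
    es_frac = es / len(toks)
    en_frac = en / len(toks)
    if es_frac > ruleset.spanish_stopword_threshold and es_frac > en_frac:
        return "es"
    return "en"


_LANG_ATTR_RE = re.compile(
    r"<html\b[^>]*\blang\s*=\s*[\"']?([A-Za-z-]+)", re.IGNORECASE
)


def _declared_language(html: Optional[str]) -> Optional[str]:
    if not html:
        return None
    m = _LANG_ATTR_RE.search(html)
    if not m:
        return None
    code = m.group(1).split("-")[0].casefold()
    if code in ("en", "es"):
        return code
    return None


def apply_filters(
    page: PageRecord,
    org: OrgRecord,
    ruleset: FilterRuleset = DEFAULT_RULESET,
) -> PageRecord:
    """Apply the exclusion rules in fixed precedence; first failing rule
    wins.  Already-dropped pages (broken/undecodable) pass through."""
    if page.status == "dropped":
        return page
    url_lower = page.url.lower()
    if page.url in org.manual_url_excludes:
        return _dropped(page, "manual")
    if org.include_patterns and not any(
        p.lower() in url_lower for p in org.include_patterns
    ):
        return _dropped(page, "subset_pattern")
    if any(p.lower() in url_lower for p in org.exclude_patterns):
        return _dropped(page, "subset_pattern")
    if any(p.lower() in url_lower for p in ruleset.url_pattern_drops):
        return _dropped(page, "sponsor_shop_forum")
    lang = _declared_language(page.html) or detect_language(page.text or "", ruleset)
    if lang == "es":
        return _dropped(page, "language")
    return page


def _dropped(page: PageRecord, reason: str) -> PageRecord:
    return replace(page, status="dropped", drop_reason=reason, text=None)


def clean_pages(
    fetches: Iterable[FetchResult],
    org: OrgRecord,
    ruleset: FilterRuleset = DEFAULT_RULESET,
) -> list[PageRecord]:
    """decode + filter every fetched page of one organization."""
    return [
        apply_filters(decode_page(f, org_id=org.org_id), org, ruleset)
        for f in fetches
    ]


def drop_report(pages: Iterable[PageRecord]) -> dict[str, int]:
    """Tally of pages by outcome; reasons sum with 'kept' to the total."""
    tally = {"kept": 0, **{r: 0 for r in DROP_REASONS}}
    for p in pages:
        tally["kept" if p.status == "kept" else p.drop_reason] += 1
    return tally


# --------------------------------------------------------------------------
# JSON-lines round trip (html omitted unless requested; text kept)
# --------------------------------------------------------------------------


def write_pages_jsonl(
    pages: Iterable[PageRecord], path: str | Path, include_html: bool = False
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in pages:
            rec = {
                "org_id": p.org_id, "url": p.url, "provenance": p.provenance,
                "status": p.status, "drop_reason": p.drop_reason, "text": p.text,
            }
            if include_html:
                rec["html"] = p.html
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def read_pages_jsonl(path: str | Path) -> list[PageRecord]:
    pages = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            pages.append(PageRecord(
                org_id=rec["org_id"], url=rec["url"],
                provenance=rec.get("provenance", "fixture"),
                html=rec.get("html"), text=rec.get("text"),
                status=rec.get("status", "kept"),
                drop_reason=rec.get("drop_reason"),
            ))
    return pages
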