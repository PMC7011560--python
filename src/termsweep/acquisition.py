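"""Page enumeration and retrieval.

An organization's site is enumerated by breadth-first crawling from its
homepage(s), following only links whose *registered domain* (public-suffix
aware, so ``www.example.com`` and ``blog.example.com`` are one site) matches
a homepage.  Content can come from three provenances: live HTTP, a dated
archive snapshot, or a local fixture directory; every retrieved page
records which.

Fetchers and archive clients are plain callables so the crawl logic is
testable offline:

* fetcher: ``(url: str) -> FetchResult``
* archive client: ``(url: str, target_date: date, window_days: int)
  -> FetchResult | None`` (returns the capture nearest the target date
  within the window, or None)

Transport failures are data, not exceptions: a failed fetch yields a
:class:`FetchResult` whose ``status`` is the HTTP code, or the sentinel
``0`` for a transport-level failure.
"""

from __future__ import annotations

import csv
import json
import logging
import time
import urllib.error
import urllib.parse
import urllib.request
import urllib.robotparser
from collections import deque
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import Callable, Optional

import lxml.etree
import lxml.html

__all__ = [
    "UrlError",
    "OrgRecord",
    "FetchResult",
    "CrawlReport",
    "canonicalize_url",
    "registered_domain",
    "crawl_site",
    "snapshot_fetch",
    "FixtureFetcher",
    "MappingFetcher",
    "LiveFetcher",
    "WaybackClient",
    "load_registry",
    "save_registry",
]

logger = logging.getLogger(__name__)

#: status sentinel for transport-level failure (DNS, timeout, no content)
TRANSPORT_FAILURE = 0

Fetcher = Callable[[str], "FetchResult"]


class UrlError(ValueError):
    """URL failed to parse or canonicalize."""


# --------------------------------------------------------------------------
# Records
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class OrgRecord:
    """One organization in the registry.

    More than one homepage models merged sites (a main site plus a campaign
    site counted as one organization).  ``include_patterns`` restrict the
    analysis to URLs containing any of the substrings (empty list = keep
    all); ``exclude_patterns`` and ``manual_url_excludes`` drop URLs.
    """

    org_id: str
    name: str
    homepages: tuple[str, ...]
    scope: str  # "national" | "local_regional"
    include_patterns: tuple[str, ...] = ()
    exclude_patterns: tuple[str, ...] = ()
    manual_url_excludes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.homepages:
            raise ValueError(f"org {self.org_id!r}: homepages must be non-empty")
        if self.scope not in ("national", "local_regional"):
            raise ValueError(
                f"org {self.org_id!r}: scope must be national|local_regional, "
                f"got {self.scope!r}"
            )
        for hp in self.homepages:
            canonicalize_url(hp)  # raises UrlError if invalid


@dataclass(frozen=True)
class FetchResult:
    url: str
    status: int
    body: bytes = b""
    declared_charset: Optional[str] = None
    provenance: str = "live"  # live | archived | fixture
    snapshot_timestamp: Optional[date] = None

    def __post_init__(self) -> None:
        if self.provenance not in ("live", "archived", "fixture"):
            raise ValueError(f"bad provenance {self.provenance!r}")
        if self.provenance == "archived" and self.snapshot_timestamp is None:
            raise ValueError("archived FetchResult requires snapshot_timestamp")

    @property
    def ok(self) -> bool:
        return 200 <= self.status < 300


@dataclass
class CrawlReport:
    """Outcome of crawling one organization.

    ``discovered_urls`` lists every same-domain canonical URL the crawl
    fetched (including ones that failed; failures are additionally listed
    in ``fetch_failures``), in deterministic breadth-first order.
    ``results`` carries the corresponding FetchResults so downstream stages
    need not re-fetch.
    """

    org_id: str
    discovered_urls: list[str] = field(default_factory=list)
    frontier_truncated: bool = False
    fetch_failures: list[tuple[str, int]] = field(default_factory=list)
    results: list[FetchResult] = field(default_factory=list)


# --------------------------------------------------------------------------
# URL handling
# --------------------------------------------------------------------------

# Minimal embedded public-suffix knowledge: two-label suffixes under which
# a third label is required to identify a site.  Anything else uses the
# final label as the suffix.
_TWO_LABEL_SUFFIXES = frozenset(
    {
        "co.uk", "org.uk", "ac.uk", "gov.uk", "me.uk", "net.uk", "ltd.uk",
        "com.au", "net.au", "org.au", "edu.au", "gov.au",
        "co.nz", "org.nz", "net.nz", "govt.nz",
        "com.br", "org.br", "net.br",
        "com.mx", "org.mx",
        "co.jp", "or.jp", "ne.jp", "ac.jp", "go.jp",
        "co.in", "org.in", "net.in", "gov.in",
        "co.za", "org.za", "web.za",
        "com.cn", "org.cn", "net.cn", "gov.cn",
        "com.ar", "com.tr", "com.sg", "com.hk", "co.kr", "or.kr",
    }
)


def registered_domain(url_or_host: str) -> str:
    """Public-suffix-aware site identity, e.g. ``www.example.com`` →
    ``example.com`` and ``a.b.example.co.uk`` → ``example.co.uk``.

    IP addresses and single-label hosts are returned unchanged.
    """
    host = url_or_host
    if "//" in host or host.startswith(("http:", "https:")):
        host = urllib.parse.urlsplit(url_or_host).hostname or ""
    host = host.strip().rstrip(".").lower()
    if host.count(":") >= 1 and "]" not in host:  # strip :port on bare host
        host = host.split(":", 1)[0]
    labels = host.split(".")
    if len(labels) < 2 or all(part.isdigit() for part in labels):
        return host
    if len(labels) >= 3 and ".".join(labels[-2:]) in _TWO_LABEL_SUFFIXES:
        return ".".join(labels[-3:])
    return ".".join(labels[-2:])


def canonicalize_url(url: str) -> str:
    """Canonical form used for deduplication.

    Lowercases scheme and host, strips the fragment, removes a trailing
    slash on non-root paths, drops ``utm_*`` tracking parameters (other
    query parameters are preserved in order).
    """
    if not isinstance(url, str) or not url.strip():
        raise UrlError(f"unparseable URL: {url!r}")
    try:
        parts = urllib.parse.urlsplit(url.strip())
    except ValueError:
        raise UrlError(f"unparseable URL: {url!r}") from None
    if not parts.scheme or not parts.netloc:
        raise UrlError(f"URL requires scheme and host: {url!r}")
    scheme = parts.scheme.lower()
    netloc = parts.netloc.lower()
    path = parts.path or "/"
    if path != "/" and path.endswith("/"):
        path = path.rstrip("/") or "/"
    query = ""
    if parts.query:
        kept = [
            (k, v)
            for k, v in urllib.parse.parse_qsl(parts.query, keep_blank_values=True)
            if not k.lower().startswith("utm_")
        ]
        query = urllib.parse.urlencode(kept)
    return urllib.parse.urlunsplit((scheme, netloc, path, query, ""))


def _extract_links(result: FetchResult) -> list[str]:
    """Absolute link targets in document order (best-effort decode)."""
    if not result.body:
        return []
    charset = result.declared_charset or "utf-8"
    try:
        html = result.body.decode(charset, errors="replace")
    except LookupError:
        html = result.body.decode("utf-8", errors="replace")
    if not html.strip():
        return []
    try:
        doc = lxml.html.fromstring(html)
    except (lxml.etree.ParserError, lxml.etree.XMLSyntaxError, ValueError):
        return []
    links = []
    for el in doc.iter("a"):
        href = el.get("href")
        if href:
            links.append(urllib.parse.urljoin(result.url, href.strip()))
    return links


# --------------------------------------------------------------------------
# Crawling
# --------------------------------------------------------------------------


def crawl_site(
    org: OrgRecord,
    fetcher: Fetcher,
    max_pages: int = 1000,
    max_depth: int = 10,
) -> CrawlReport:
    """Breadth-first same-domain crawl from the organization's homepages.

    Each canonical URL is fetched at most once; links leave the frontier in
    document order, so discovery order is deterministic for a deterministic
    fetcher and increasing ``max_pages`` only extends the discovered
    prefix.  Unreachable homepages are recorded as failures and the crawl
    continues (an org whose homepages all fail simply yields no usable
    pages).
    """
    if max_pages < 1 or max_depth < 1:
        raise ValueError("max_pages and max_depth must be positive")
    report = CrawlReport(org_id=org.org_id)
    allowed = {registered_domain(hp) for hp in org.homepages}
    queue: deque[tuple[str, int]] = deque()
    seen: set[str] = set()
    for hp in org.homepages:
        canon = canonicalize_url(hp)
        if canon not in seen:
            seen.add(canon)
            queue.append((canon, 0))
    while queue:
        if len(report.discovered_urls) >= max_pages:
            report.frontier_truncated = True
            break
        url, depth = queue.popleft()
        try:
            result = fetcher(url)
        except Exception as exc:  # transport failures are data
            logger.warning("fetch failed for %s: %s", url, exc)
            result = FetchResult(url=url, status=TRANSPORT_FAILURE, provenance="live")
        report.discovered_urls.append(url)
        report.results.append(result)
        if not result.ok:
            report.fetch_failures.append((url, result.status))
            continue
        if depth >= max_depth:
            continue
        for link in _extract_links(result):
            try:
                canon = canonicalize_url(link)
            except UrlError:
                continue
            parts = urllib.parse.urlsplit(canon)
            if parts.scheme not in ("http", "https"):
                continue
            if registered_domain(parts.hostname or "") not in allowed:
                continue
            if canon not in seen:
                seen.add(canon)
                queue.append((canon, depth + 1))
    if report.results and not any(r.ok for r in report.results):
        logger.warning(
            "org %s: no homepage reachable; recorded with zero usable pages",
            org.org_id,
        )
    return report


# --------------------------------------------------------------------------
# Snapshot-first retrieval
# --------------------------------------------------------------------------


def snapshot_fetch(
    url: str,
    target_date: date,
    archive_client: Optional[Callable[[str, date, int], Optional[FetchResult]]],
    live_fetcher: Optional[Fetcher],
    window_days: int = 45,
) -> FetchResult:
    """Archive-first retrieval with live fallback.

    Returns the archived capture nearest ``target_date`` within
    ``±window_days`` when one exists; otherwise a live fetch; otherwise a
    FetchResult with a failure status.  Provenance is always recorded.
    """
    if archive_client is not None:
        try:
            result = archive_client(url, target_date, window_days)
        except Exception as exc:
            logger.warning("archive lookup failed for %s: %s", url, exc)
            result = None
        if result is not None:
            return result
    if live_fetcher is not None:
        try:
            return live_fetcher(url)
        except Exception as exc:
            logger.warning("live fetch failed for %s: %s", url, exc)
    return FetchResult(url=url, status=TRANSPORT_FAILURE, provenance="live")


# --------------------------------------------------------------------------
# Fetchers
# --------------------------------------------------------------------------


class FixtureFetcher:
    """Serves pages from a local directory via an index CSV (url, path).

    Paths are relative to the index file's directory.  Unknown URLs get a
    404; URLs listed with a missing file get a transport failure.
    """

    def __init__(self, index_path: str | Path):
        self.index_path = Path(index_path)
        if self.index_path.is_dir():
            self.index_path = self.index_path / "index.csv"
        self.root = self.index_path.parent
        self._paths: dict[str, Path] = {}
        with open(self.index_path, newline="", encoding="utf-8") as fh:
            for rec in csv.DictReader(fh):
                self._paths[canonicalize_url(rec["url"])] = self.root / rec["path"]

    def __call__(self, url: str) -> FetchResult:
        canon = canonicalize_url(url)
        path = self._paths.get(canon)
        if path is None:
            return FetchResult(url=canon, status=404, provenance="fixture")
        try:
            body = path.read_bytes()
        except OSError:
            return FetchResult(
                url=canon, status=TRANSPORT_FAILURE, provenance="fixture"
            )
        return FetchResult(url=canon, status=200, body=body, provenance="fixture")

    def urls(self) -> list[str]:
        return list(self._paths)


class MappingFetcher:
    """In-memory fetcher over a {url: html} mapping (tests, examples)."""

    def __init__(self, pages: dict[str, str], status_overrides: dict[str, int] | None = None):
        self.pages = {canonicalize_url(u): html for u, html in pages.items()}
        self.status_overrides = {
            canonicalize_url(u): s for u, s in (status_overrides or {}).items()
        }

    def __call__(self, url: str) -> FetchResult:
        canon = canonicalize_url(url)
        if canon in self.status_overrides:
            return FetchResult(
                url=canon, status=self.status_overrides[canon], provenance="fixture"
            )
        if canon not in self.pages:
            return FetchResult(url=canon, status=404, provenance="fixture")
        return FetchResult(
            url=canon,
            status=200,
            body=self.pages[canon].encode("utf-8"),
            declared_charset="utf-8",
            provenance="fixture",
        )


class LiveFetcher:
    """Polite live HTTP fetcher: robots.txt respected, fixed delay between
    requests to the same host, bounded timeout."""

    user_agent = "termsweep/0.1 (website term-frequency audit)"

    def __init__(self, delay_seconds: float = 1.0, timeout: float = 20.0,
                 respect_robots: bool = True):
        self.delay_seconds = delay_seconds
        self.timeout = timeout
        self.respect_robots = respect_robots
        self._robots: dict[str, urllib.robotparser.RobotFileParser] = {}
        self._last_request: dict[str, float] = {}

    def _allowed(self, url: str) -> bool:
        if not self.respect_robots:
            return True
        parts = urllib.parse.urlsplit(url)
        base = f"{parts.scheme}://{parts.netloc}"
        rp = self._robots.get(base)
        if rp is None:
            rp = urllib.robotparser.RobotFileParser(base + "/robots.txt")
            try:
                rp.read()
            except OSError:
                rp.allow_all = True
            self._robots[base] = rp
        return rp.can_fetch(self.user_agent, url)

    def __call__(self, url: str) -> FetchResult:
        if not self._allowed(url):
            return FetchResult(url=url, status=403, provenance="live")
        host = urllib.parse.urlsplit(url).netloc
        wait = self._last_request.get(host, 0) + self.delay_seconds - time.monotonic()
        if wait > 0:
            time.sleep(wait)
        req = urllib.request.Request(url, headers={"User-Agent": self.user_agent})
        try:
            with urllib.request.urlopen(req, timeout=self.timeout) as resp:
                body = resp.read()
                charset = resp.headers.get_content_charset()
                status = getattr(resp, "status", 200)
        except urllib.error.HTTPError as err:
            return FetchResult(url=url, status=err.code, provenance="live")
        except (urllib.error.URLError, OSError, ValueError):
            return FetchResult(url=url, status=TRANSPORT_FAILURE, provenance="live")
        finally:
            self._last_request[host] = time.monotonic()
        return FetchResult(
            url=url, status=status, body=body,
            declared_charset=charset, provenance="live",
        )


class WaybackClient:
    """Nearest-capture lookup against the Internet Archive availability API.

    Callable with ``(url, target_date, window_days)``; returns an archived
    FetchResult or None when no capture falls inside the window.
    """

    api = "https://archive.org/wayback/available"

    def __init__(self, timeout: float = 30.0):
        self.timeout = timeout

    def __call__(self, url: str, target_date: date, window_days: int
                 ) -> Optional[FetchResult]:
        ts = target_date.strftime("%Y%m%d")
        query = urllib.parse.urlencode({"url": url, "timestamp": ts})
        try:
            with urllib.request.urlopen(
                f"{self.api}?{query}", timeout=self.timeout
            ) as resp:
                payload = json.load(resp)
        except (urllib.error.URLError, OSError, ValueError):
            return None
        closest = (payload.get("archived_snapshots") or {}).get("closest")
        if not closest or not closest.get("available"):
            return None
        snap_ts = datetime.strptime(closest["timestamp"][:8], "%Y%m%d").date()
        if abs((snap_ts - target_date).days) > window_days:
            return None
        # id_ form serves the original bytes without archive chrome
        raw_url = closest["url"].replace("/web/", "/web/").replace(
            closest["timestamp"], closest["timestamp"] + "id_", 1
        )
        try:
            with urllib.request.urlopen(raw_url, timeout=self.timeout) as resp:
                body = resp.read()
                charset = resp.headers.get_content_charset()
        except (urllib.error.URLError, OSError, ValueError):
            return None
        return FetchResult(
            url=url, status=200, body=body, declared_charset=charset,
            provenance="archived", snapshot_timestamp=snap_ts,
        )


def window_bounds(target_date: date, window_days: int) -> tuple[date, date]:
    return (target_date - timedelta(days=window_days),
            target_date + timedelta(days=window_days))


# --------------------------------------------------------------------------
# Registry I/O: CSV with pipe-separated multi-valued columns
# --------------------------------------------------------------------------

_REGISTRY_COLUMNS = [
    "org_id", "name", "homepages", "scope",
    "include_patterns", "exclude_patterns", "manual_url_excludes",
]


def _split_pipes(value: str | None) -> tuple[str, ...]:
    if not value:
        return ()
    return tuple(v.strip() for v in value.split("|") if v.strip())


def load_registry(path: str | Path) -> list[OrgRecord]:
    orgs: list[OrgRecord] = []
    seen: set[str] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        for rec in csv.DictReader(fh):
            org = OrgRecord(
                org_id=rec["org_id"].strip(),
                name=(rec.get("name") or rec["org_id"]).strip(),
                homepages=_split_pipes(rec.get("homepages")),
                scope=rec["scope"].strip(),
                include_patterns=_split_pipes(rec.get("include_patterns")),
                exclude_patterns=_split_pipes(rec.get("exclude_patterns")),
                manual_url_excludes=_split_pipes(rec.get("manual_url_excludes")),
            )
            if org.org_id in seen:
                raise ValueError(f"duplicate org_id {org.org_id!r} in registry")
            seen.add(org.org_id)
            orgs.append(org)
    return orgs


def save_registry(orgs: list[OrgRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_REGISTRY_COLUMNS)
        for o in orgs:
            writer.writerow([
                o.org_id, o.name, "|".join(o.homepages), o.scope,
                "|".join(o.include_patterns), "|".join(o.exclude_patterns),
                "|".join(o.manual_url_excludes),
            ])
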