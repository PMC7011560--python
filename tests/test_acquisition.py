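from __future__ import annotations

import random
from datetime import date

import pytest

from termsweep.acquisition import (
    FetchResult,
    FixtureFetcher,
    MappingFetcher,
    OrgRecord,
    UrlError,
    canonicalize_url,
    crawl_site,
    load_registry,
    registered_domain,
    save_registry,
    snapshot_fetch,
)


def _org(homepage="https://site.example.org/", **kw):
    defaults = dict(org_id="o1", name="Org One", homepages=(homepage,),
                    scope="national")
    defaults.update(kw)
    return OrgRecord(**defaults)


def _site(pages: dict[str, list[str]], base="https://site.example.org"):
    """Build a MappingFetcher from {path: [linked paths]}."""
    html = {
        base + path: "<html><body>"
        + "".join(f'<a href="{base + t}">x</a>' for t in links)
        + "</body></html>"
        for path, links in pages.items()
    }
    return MappingFetcher(html)


class TestCanonicalizeUrl:
    @pytest.mark.parametrize("raw,expected", [
        ("HTTP://Example.com/Page/#top", "http://example.com/Page"),
        ("http://example.com/", "http://example.com/"),
        ("http://example.com", "http://example.com/"),
        ("http://example.com/a?utm_source=x&id=2", "http://example.com/a?id=2"),
        ("http://example.com/a?id=2&utm_campaign=y&b=1",
         "http://example.com/a?id=2&b=1"),
        ("https://Example.COM/Deep/Path/", "https://example.com/Deep/Path"),
    ])
    def test_examples(self, raw, expected):
        assert canonicalize_url(raw) == expected

    def test_idempotent(self):
        urls = ["http://a.example.com/x/y/?q=1#frag", "https://b.org/"]
        for u in urls:
            once = canonicalize_url(u)
            assert canonicalize_url(once) == once

    @pytest.mark.parametrize("bad", ["", "not a url", "/relative/only", None])
    def test_unparseable_rejected(self, bad):
        with pytest.raises(UrlError):
            canonicalize_url(bad)


class TestRegisteredDomain:
    @pytest.mark.parametrize("host,expected", [
        ("www.example.com", "example.com"),
        ("example.com", "example.com"),
        ("a.b.example.co.uk", "example.co.uk"),
        ("https://blog.example.org/page", "example.org"),
        ("localhost", "localhost"),
        ("192.168.0.1", "192.168.0.1"),
    ])
    def test_examples(self, host, expected):
        assert registered_domain(host) == expected


class TestCrawlSite:
    def test_closed_link_graph_fully_discovered(self):
        fetcher = _site({
            "/": ["/a", "/b"], "/a": ["/", "/b"], "/b": ["/a"],
        })
        report = crawl_site(_org(), fetcher, max_pages=100)
        assert len(report.discovered_urls) == 3
        assert not report.frontier_truncated

    def test_external_domain_not_followed(self):
        base = "https://site.example.org"
        fetcher = MappingFetcher({
            base + "/": f'<a href="{base}/a">a</a>'
                        '<a href="https://other-domain.org/x">ext</a>',
            base + "/a": "",
        })
        report = crawl_site(_org(), fetcher)
        assert all("other-domain" not in u for u in report.discovered_urls)
        assert len(report.discovered_urls) == 2

    def test_subdomains_of_same_site_followed(self):
        base = "https://site.example.org"
        fetcher = MappingFetcher({
            base + "/": '<a href="https://www.site.example.org/a">a</a>',
            "https://www.site.example.org/a": "",
        })
        report = crawl_site(_org(), fetcher)
        assert len(report.discovered_urls) == 2

    def test_cycle_terminates_each_listed_once(self):
        fetcher = _site({"/x": ["/y"], "/y": ["/x"], "/": ["/x"]})
        report = crawl_site(_org(), fetcher)
        assert sorted(report.discovered_urls) == sorted({
            "https://site.example.org/",
            "https://site.example.org/x",
            "https://site.example.org/y",
        })

    def test_broken_link_recorded_as_failure(self):
        base = "https://site.example.org"
        fetcher = MappingFetcher({base + "/": f'<a href="{base}/gone">g</a>'})
        report = crawl_site(_org(), fetcher)
        assert (base + "/gone", 404) in report.fetch_failures
        assert base + "/gone" in report.discovered_urls

    def test_all_homepages_unreachable_yields_zero_ok_pages(self):
        fetcher = MappingFetcher({}, status_overrides={
            "https://site.example.org/": 500,
        })
        report = crawl_site(_org(), fetcher)
        assert not any(r.ok for r in report.results)
        assert report.fetch_failures == [("https://site.example.org/", 500)]

    def test_max_pages_truncates_frontier(self):
        fetcher = _site({"/": ["/a", "/b", "/c"], "/a": [], "/b": [], "/c": []})
        report = crawl_site(_org(), fetcher, max_pages=2)
        assert len(report.discovered_urls) == 2
        assert report.frontier_truncated

    def test_multiple_homepages_merged(self):
        base = "https://site.example.org"
        other = "https://campaign.example.net"
        fetcher = MappingFetcher({base + "/": "", other + "/": ""})
        org = _org(homepages=(base + "/", other + "/"))
        report = crawl_site(org, fetcher)
        assert len(report.discovered_urls) == 2

    def test_max_depth_limits_traversal(self):
        fetcher = _site({"/": ["/d1"], "/d1": ["/d2"], "/d2": ["/d3"], "/d3": []})
        report = crawl_site(_org(), fetcher, max_depth=2)
        assert "https://site.example.org/d3" not in report.discovered_urls
        assert "https://site.example.org/d2" in report.discovered_urls


def _random_graph_fetcher(rng: random.Random, n: int):
    """Random reachable site with planted external links; returns fetcher."""
    base = "https://rnd.example.org"
    paths = ["/"] + [f"/p{i}" for i in range(1, n)]
    links: dict[str, list[str]] = {p: [] for p in paths}
    for i in range(1, n):
        links[paths[rng.randrange(i)]].append(base + paths[i])
    for _ in range(n):
        a, b = rng.choice(paths), rng.choice(paths)
        links[a].append(base + b)
    for p in rng.sample(paths, max(1, n // 4)):
        links[p].append(f"https://external-{rng.randrange(5)}.net/x")
    html = {
        base + p: "".join(f'<a href="{t}">t</a>' for t in targets)
        for p, targets in links.items()
    }
    return MappingFetcher(html), base


class TestCrawlProperties:
    """Domain closure, termination, idempotence and max_pages monotonicity
    over randomized link graphs with planted external links."""

    def test_randomized_graph_properties(self):
        rng = random.Random(1234)
        for trial in range(50):
            n = rng.randint(2, 12)
            fetcher, base = _random_graph_fetcher(rng, n)
            org = OrgRecord(org_id=f"r{trial}", name="r", scope="national",
                            homepages=(base + "/",))
            full = crawl_site(org, fetcher, max_pages=100)
            # termination + complete discovery of the reachable closure
            assert len(full.discovered_urls) == len(set(full.discovered_urls))
            # domain closure
            for url in full.discovered_urls:
                assert registered_domain(url) == "example.org"
            # idempotence
            again = crawl_site(org, fetcher, max_pages=100)
            assert again.discovered_urls == full.discovered_urls
            assert again.fetch_failures == full.fetch_failures
            # monotonicity: smaller budget discovers a prefix
            cut = rng.randint(1, len(full.discovered_urls))
            partial = crawl_site(org, fetcher, max_pages=cut)
            assert partial.discovered_urls == full.discovered_urls[:cut]


class TestSnapshotFetch:
    def _archived(self, url, when):
        return FetchResult(url=url, status=200, body=b"arc",
                           provenance="archived", snapshot_timestamp=when)

    def test_exact_capture_preferred(self):
        target = date(2018, 11, 15)
        client = lambda url, d, w: self._archived(url, d)
        live = lambda url: FetchResult(url=url, status=200, body=b"live")
        result = snapshot_fetch("https://x.org/", target, client, live)
        assert result.provenance == "archived"
        assert result.snapshot_timestamp == target

    def test_live_fallback_when_archive_empty(self):
        client = lambda url, d, w: None
        live = lambda url: FetchResult(url=url, status=200, body=b"live")
        result = snapshot_fetch("https://x.org/", date(2018, 11, 15), client, live)
        assert result.provenance == "live"
        assert result.ok

    def test_failure_recorded_not_raised(self):
        client = lambda url, d, w: None
        live = lambda url: FetchResult(url=url, status=404)
        result = snapshot_fetch("https://x.org/", date(2018, 11, 15), client, live)
        assert result.status == 404
        assert not result.ok

    def test_both_sources_failing_gives_sentinel(self):
        result = snapshot_fetch("https://x.org/", date(2018, 11, 15), None, None)
        assert result.status == 0


class TestFixtureFetcher:
    def test_serves_indexed_files_and_404s_unknown(self, tmp_path):
        (tmp_path / "a.html").write_text("<p>hello</p>")
        (tmp_path / "index.csv").write_text(
            "url,path\nhttps://f.example.org/,a.html\n"
        )
        fetcher = FixtureFetcher(tmp_path)
        hit = fetcher("https://f.example.org/")
        assert hit.ok and b"hello" in hit.body
        assert hit.provenance == "fixture"
        assert fetcher("https://f.example.org/missing").status == 404


class TestRegistry:
    def test_round_trip(self, tmp_path):
        orgs = [
            OrgRecord("a", "Org A", ("https://a.org/",), "national",
                      include_patterns=("breast",)),
            OrgRecord("b", "Org B",
                      ("https://b.org/", "https://campaign.b.org/"),
                      "local_regional",
                      exclude_patterns=("shop",),
                      manual_url_excludes=("https://b.org/old",)),
        ]
        path = tmp_path / "registry.csv"
        save_registry(orgs, path)
        assert load_registry(path) == orgs

    def test_scope_validated(self):
        with pytest.raises(ValueError, match="scope"):
            OrgRecord("x", "X", ("https://x.org/",), "worldwide")

    def test_homepages_required(self):
        with pytest.raises(ValueError, match="homepages"):
            OrgRecord("x", "X", (), "national")
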