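"""Crawl a small in-memory website and show what the crawler records.

The crawler does breadth-first traversal from the homepage, follows only
links on the same registered domain, deduplicates canonical URLs, and
records failed fetches as data rather than raising.
"""

from termsweep import MappingFetcher, OrgRecord, crawl_site

BASE = "https://demo.example.org"
fetcher = MappingFetcher({
    BASE + "/": (
        f'<a href="{BASE}/about">about</a>'
        f'<a href="{BASE}/about/">duplicate</a>'
        f'<a href="{BASE}/gone">broken</a>'
        '<a href="https://unrelated.org/x">external</a>'
    ),
    BASE + "/about": f'<a href="{BASE}/">home</a>',  # cycle back
})

org = OrgRecord(org_id="demo", name="Demo Org",
                homepages=(BASE + "/",), scope="national")
report = crawl_site(org, fetcher, max_pages=100)

print("discovered (in BFS order):")
for url in report.discovered_urls:
    print(" ", url)
print("fetch failures:", report.fetch_failures)
print("frontier truncated:", report.frontier_truncated)

# Three URLs are discovered: the homepage, /about (listed once despite the
# trailing-slash duplicate and the cycle), and /gone which is recorded as
# a 404 failure.  The external link is never followed.
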