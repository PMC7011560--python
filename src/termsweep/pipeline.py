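"""End-to-end orchestration: acquisition -> cleaning -> counting -> aggregation.

The pipeline operates per organization (crawl its site, clean the pages,
count kept pages) and then rolls all organizations up into the corpus
report.  All stages are pure given a fetcher, so the same entry points
serve fixture-backed tests, archive-backed reproduction runs, and live
crawls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .acquisition import CrawlReport, Fetcher, FixtureFetcher, OrgRecord, load_registry
from .aggregation import (
    CorpusReport,
    OrgSummary,
    corpus_table,
    corpus_table_frame,
    fig1_frame,
    plot_fig1,
    summarize_org,
)
from .cleaning import DEFAULT_RULESET, FilterRuleset, PageRecord, clean_pages, drop_report
from .counting import PageTermCounts, count_page
from .lexicon import Lexicon, build_default_lexicon

__all__ = ["OrgResult", "PipelineResult", "run_org", "run_corpus",
           "run_fixture_corpus", "write_reports"]

from .acquisition import crawl_site


@dataclass
class OrgResult:
    org: OrgRecord
    crawl: CrawlReport
    pages: list[PageRecord]
    counts: list[PageTermCounts]
    summary: OrgSummary


@dataclass
class PipelineResult:
    org_results: list[OrgResult]
    report: CorpusReport

    @property
    def pages(self) -> list[PageRecord]:
        return [p for r in self.org_results for p in r.pages]

    @property
    def counts(self) -> list[PageTermCounts]:
        return [c for r in self.org_results for c in r.counts]

    @property
    def summaries(self) -> list[OrgSummary]:
        return [r.summary for r in self.org_results]

    def drop_tally(self) -> dict[str, int]:
        return drop_report(self.pages)


def run_org(
    org: OrgRecord,
    fetcher: Fetcher,
    lexicon: Optional[Lexicon] = None,
    ruleset: FilterRuleset = DEFAULT_RULESET,
    max_pages: int = 1000,
    max_depth: int = 100,
) -> OrgResult:
    """Crawl, clean, count and summarize one organization.

    ``max_depth`` defaults higher than the crawler's own default so that
    long chain-shaped sites are fully enumerated.
    """
    lexicon = lexicon or build_default_lexicon()
    crawl = crawl_site(org, fetcher, max_pages=max_pages, max_depth=max_depth)
    pages = clean_pages(crawl.results, org, ruleset)
    counts = [count_page(p, lexicon) for p in pages if p.status == "kept"]
    summary = summarize_org(counts, org, lexicon)
    return OrgResult(org=org, crawl=crawl, pages=pages, counts=counts,
                     summary=summary)


def run_corpus(
    orgs: Sequence[OrgRecord],
    fetcher: Fetcher,
    lexicon: Optional[Lexicon] = None,
    ruleset: FilterRuleset = DEFAULT_RULESET,
    max_pages: int = 1000,
    max_depth: int = 100,
) -> PipelineResult:
    """Run the full pipeline over a registry of organizations."""
    lexicon = lexicon or build_default_lexicon()
    results = [
        run_org(org, fetcher, lexicon, ruleset, max_pages, max_depth)
        for org in orgs
    ]
    report = corpus_table([r.summary for r in results], lexicon)
    return PipelineResult(org_results=results, report=report)


def run_fixture_corpus(
    fixture_dir: str | Path,
    registry_path: str | Path | None = None,
    lexicon: Optional[Lexicon] = None,
    ruleset: FilterRuleset = DEFAULT_RULESET,
    max_pages: int = 1000,
    max_depth: int = 100,
) -> PipelineResult:
    """Convenience wrapper for a fixture directory produced by the
    synthetic generator (index.csv + registry.csv)."""
    fixture_dir = Path(fixture_dir)
    registry_path = registry_path or fixture_dir / "registry.csv"
    orgs = load_registry(registry_path)
    fetcher = FixtureFetcher(fixture_dir / "index.csv")
    return run_corpus(orgs, fetcher, lexicon, ruleset, max_pages, max_depth)


def write_reports(
    result: PipelineResult,
    out_dir: str | Path,
    lexicon: Optional[Lexicon] = None,
    plot: bool = False,
) -> None:
    """Write corpus_table.csv, fig1_points.csv, drops.csv (and optionally
    fig1.png) under *out_dir*."""
    lexicon = lexicon or build_default_lexicon()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    corpus_table_frame(result.report, lexicon).to_csv(
        out_dir / "corpus_table.csv", index=False
    )
    fig1_frame(result.report).to_csv(out_dir / "fig1_points.csv", index=False)
    import pandas as pd

    pd.DataFrame([result.drop_tally()]).to_csv(
        out_dir / "drops.csv", index=False
    )
    if plot:
        plot_fig1(result.report, out_dir / "fig1.png")
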