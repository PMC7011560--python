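"""Roll-ups of page-level term counts to organization and corpus level.

Three output surfaces:

* a corpus table — one row per factor with the number and integer percent
  of organizations mentioning it (total > 0 across the org's kept pages)
  and the total mentions summed over all organizations;
* a per-site table — per-factor mention totals for a single site, ordered
  by descending total (ties alphabetical);
* per-organization scatter points — average mentions per kept page of
  environmental factors (general + specific) versus all other risk
  factors, annotated with the organization's national/local-regional
  scope.

Percentages are rounded to the nearest integer, half away from zero.
Averages are undefined (None) for organizations with zero kept pages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Sequence

import pandas as pd

from .acquisition import OrgRecord
from .counting import PageTermCounts
from .lexicon import CATEGORIES, Lexicon

__all__ = [
    "OrgSummary",
    "CorpusRow",
    "Fig1Point",
    "CorpusReport",
    "summarize_org",
    "percent_mentioning",
    "corpus_table",
    "site_report",
    "corpus_table_frame",
    "fig1_frame",
    "site_report_frame",
    "plot_fig1",
    "read_counts_jsonl",
    "write_counts_jsonl",
]

ENV_CATEGORIES = ("general_environmental", "specific_environmental")


@dataclass(frozen=True)
class OrgSummary:
    org_id: str
    scope: str
    n_pages_kept: int
    totals: dict[str, int]
    category_totals: dict[str, int]
    mentions_any_general_env: bool
    mentions_any_specific_env: bool
    mentions_any_other: bool
    env_avg_per_page: Optional[float]  # None when n_pages_kept == 0
    other_avg_per_page: Optional[float]


class CorpusRow(NamedTuple):
    factor_name: str
    category: str
    n_orgs_mentioning: int
    pct_orgs_mentioning: int
    total_mentions: int


class Fig1Point(NamedTuple):
    org_id: str
    scope: str
    env_avg_per_page: float
    other_avg_per_page: float


class SiteRow(NamedTuple):
    factor_name: str
    category: str
    total_mentions: int


@dataclass
class CorpusReport:
    n_orgs: int
    rows: list[CorpusRow]
    headline: dict[str, int]
    fig1_points: list[Fig1Point] = field(default_factory=list)


def percent_mentioning(k: int, n: int) -> int:
    """Integer percent of *n* organizations, rounded half away from zero."""
    if n <= 0:
        raise ValueError("total organization count must be positive")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} must lie in [0, {n}]")
    return (200 * k + n) // (2 * n)


def summarize_org(
    pages: Sequence[PageTermCounts],
    org: OrgRecord,
    lexicon: Lexicon,
) -> OrgSummary:
    """Aggregate one organization's kept-page counts.

    ``pages`` must all belong to *org*; the kept-page count is the length
    of ``pages`` (dropped pages never produce PageTermCounts).
    """
    for p in pages:
        if p.org_id != org.org_id:
            raise ValueError(
                f"page {p.url} belongs to org {p.org_id!r}, not {org.org_id!r}"
            )
    totals = {g.factor_name: 0 for g in lexicon}
    for p in pages:
        for factor, n in p.counts.items():
            if factor not in totals:
                raise ValueError(f"page {p.url}: unknown factor {factor!r}")
            totals[factor] += n
    category_totals = {c: 0 for c in CATEGORIES}
    for g in lexicon:
        category_totals[g.category] += totals[g.factor_name]
    n_kept = len(pages)
    env_total = sum(category_totals[c] for c in ENV_CATEGORIES)
    other_total = category_totals["other"]
    return OrgSummary(
        org_id=org.org_id,
        scope=org.scope,
        n_pages_kept=n_kept,
        totals=totals,
        category_totals=category_totals,
        mentions_any_general_env=category_totals["general_environmental"] > 0,
        mentions_any_specific_env=category_totals["specific_environmental"] > 0,
        mentions_any_other=category_totals["other"] > 0,
        env_avg_per_page=env_total / n_kept if n_kept else None,
        other_avg_per_page=other_total / n_kept if n_kept else None,
    )


def corpus_table(
    summaries: Sequence[OrgSummary],
    lexicon: Lexicon,
) -> CorpusReport:
    """Corpus-level report over all organizations.

    Rows are ordered by descending organization count, ties keeping
    lexicon order.  Headline shares are the percent of organizations with
    any general-environmental / specific-environmental / other mention.
    Scatter points are emitted for every organization whose per-page
    averages are defined (at least one kept page).
    """
    if not summaries:
        raise ValueError("summaries must be non-empty")
    seen: set[str] = set()
    for s in summaries:
        if s.org_id in seen:
            raise ValueError(f"duplicate org_id {s.org_id!r}")
        seen.add(s.org_id)
    n_orgs = len(summaries)
    rows = []
    for g in lexicon:
        k = sum(1 for s in summaries if s.totals.get(g.factor_name, 0) > 0)
        total = sum(s.totals.get(g.factor_name, 0) for s in summaries)
        rows.append(CorpusRow(
            factor_name=g.factor_name,
            category=g.category,
            n_orgs_mentioning=k,
            pct_orgs_mentioning=percent_mentioning(k, n_orgs),
            total_mentions=total,
        ))
    rows.sort(key=lambda r: -r.n_orgs_mentioning)  # stable: lexicon order on ties
    headline = {
        "pct_general_env": percent_mentioning(
            sum(s.mentions_any_general_env for s in summaries), n_orgs),
        "pct_specific_env": percent_mentioning(
            sum(s.mentions_any_specific_env for s in summaries), n_orgs),
        "pct_other": percent_mentioning(
            sum(s.mentions_any_other for s in summaries), n_orgs),
    }
    points = [
        Fig1Point(s.org_id, s.scope, s.env_avg_per_page, s.other_avg_per_page)
        for s in summaries
        if s.env_avg_per_page is not None and s.other_avg_per_page is not None
    ]
    return CorpusReport(n_orgs=n_orgs, rows=rows, headline=headline,
                        fig1_points=points)


def site_report(
    pages: Sequence[PageTermCounts],
    lexicon: Lexicon,
) -> list[SiteRow]:
    """Per-factor mention totals for one site, descending by total with
    alphabetical tie-breaks."""
    totals = {g.factor_name: 0 for g in lexicon}
    for p in pages:
        for factor, n in p.counts.items():
            if factor not in totals:
                raise ValueError(f"page {p.url}: unknown factor {factor!r}")
            totals[factor] += n
    categories = {g.factor_name: g.category for g in lexicon}
    rows = [SiteRow(f, categories[f], t) for f, t in totals.items()]
    rows.sort(key=lambda r: (-r.total_mentions, r.factor_name))
    return rows


# --------------------------------------------------------------------------
# Tabular / graphical output
# --------------------------------------------------------------------------


def _representative_terms(lexicon: Lexicon) -> dict[str, str]:
    return {g.factor_name: ", ".join(g.variants) for g in lexicon}


def corpus_table_frame(report: CorpusReport, lexicon: Lexicon) -> pd.DataFrame:
    terms = _representative_terms(lexicon)
    return pd.DataFrame([
        {
            "factor": r.factor_name,
            "category": r.category,
            "representative_terms": terms.get(r.factor_name, ""),
            "pct_orgs": r.pct_orgs_mentioning,
            "n_orgs": r.n_orgs_mentioning,
            "total_mentions": r.total_mentions,
        }
        for r in report.rows
    ])


def fig1_frame(report: CorpusReport) -> pd.DataFrame:
    return pd.DataFrame(
        report.fig1_points,
        columns=["org_id", "scope", "env_avg_per_page", "other_avg_per_page"],
    )


def site_report_frame(rows: Sequence[SiteRow], lexicon: Lexicon) -> pd.DataFrame:
    terms = _representative_terms(lexicon)
    return pd.DataFrame([
        {
            "factor": r.factor_name,
            "representative_terms": terms.get(r.factor_name, ""),
            "total_mentions": r.total_mentions,
        }
        for r in rows
    ])


def plot_fig1(report: CorpusReport, path: str | Path) -> None:
    """Scatter of per-org average mentions per page, environmental versus
    other risk factors, with scope-coded markers and an equal-usage
    diagonal."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    for scope, marker, color, label in (
        ("national", "o", "tab:blue", "National"),
        ("local_regional", "s", "tab:purple", "Local / regional"),
    ):
        xs = [p.other_avg_per_page for p in report.fig1_points if p.scope == scope]
        ys = [p.env_avg_per_page for p in report.fig1_points if p.scope == scope]
        ax.scatter(xs, ys, marker=marker, color=color, label=label, alpha=0.8)
    lim = max(
        [0.1]
        + [max(p.env_avg_per_page, p.other_avg_per_page)
           for p in report.fig1_points]
    ) * 1.1
    ax.plot([0, lim], [0, lim], "--", color="gray", linewidth=1)
    ax.set_xlim(0, lim)
    ax.set_ylim(0, lim)
    ax.set_xlabel("Average mentions per page, other risk factors")
    ax.set_ylabel("Average mentions per page, environmental factors")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# --------------------------------------------------------------------------
# Counts JSONL round trip
# --------------------------------------------------------------------------


def write_counts_jsonl(counts: Iterable[PageTermCounts], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for c in counts:
            fh.write(json.dumps(
                {"org_id": c.org_id, "url": c.url, "counts": dict(c.counts)},
                ensure_ascii=False,
            ) + "\n")


def read_counts_jsonl(path: str | Path) -> list[PageTermCounts]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                rec = json.loads(line)
                out.append(PageTermCounts(
                    org_id=rec["org_id"], url=rec["url"], counts=rec["counts"]
                ))
    return out
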