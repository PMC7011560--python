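"""Synthetic multi-page websites with exactly known planted term counts.

The generator emulates the structure of the study corpus — linked HTML
pages on one registered domain per organization, with nuisance content the
cleaning stage must remove — while keeping every expected number derivable
from the site specification alone:

* content pages embed exactly the requested number of occurrences of one
  designated variant per factor, separated by filler drawn from a
  vocabulary disjoint (at token level) from every lexicon variant token;
* decoy insertions ("chemical", "toxic", "environment", "chemotherapy",
  "toxicity") never change any count, because none is a lexicon variant;
* Spanish pages are stopword-dense Spanish filler; forum pages carry
  ``/forum/`` URL paths (and deliberately contain lexicon terms, which
  must *not* be counted because the page is dropped); broken links point
  at URLs absent from the fixture index;
* script/style blocks and HTML comments on content pages deliberately
  contain lexicon terms, so any leak in visible-text extraction breaks the
  ground truth loudly.

Everything is seeded: the same spec and seed produce byte-identical
fixture files.
"""

from __future__ import annotations

import csv
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .acquisition import OrgRecord, canonicalize_url, save_registry
from .lexicon import CATEGORIES, Lexicon
from .text import tokens as _token_strings

__all__ = [
    "DECOY_TERMS",
    "SyntheticSiteSpec",
    "GroundTruth",
    "CorpusGroundTruth",
    "generate_site",
    "generate_corpus",
    "random_corpus_specs",
]

#: Ambiguous terms excluded from the lexicon, planted as decoys.
DECOY_TERMS = ("chemical", "toxic", "environment", "chemotherapy", "toxicity")

# Invented filler vocabulary; generation asserts it shares no token with
# any lexicon variant.
_FILLER_VOCAB = (
    "varnel", "tresk", "omblin", "quade", "ferrow", "listel", "branth",
    "coyle", "misken", "dorvale", "pleggit", "sarnow", "tumber", "wrello",
    "ashter", "bindle", "crofty", "delmot", "ervane", "fostick", "galder",
    "hention", "ivrell", "jasper", "kelvane", "lumet", "marrow", "nestle",
    "opaline", "prindle", "quorvis", "rastel", "sithern", "tovald",
    "umbrell", "vastin", "welkin", "yonder", "zephrin", "caldrim",
)

# Spanish page vocabulary: function words (dense) plus content words; all
# checked against the lexicon token set like the English filler.
_SPANISH_FUNCTION = (
    "de", "la", "que", "el", "en", "los", "se", "las", "por", "un",
    "para", "con", "una", "su", "al", "lo", "como", "del", "pero", "sus",
)
_SPANISH_CONTENT = (
    "casa", "tiempo", "mundo", "ciudad", "persona", "trabajo", "agua",
    "libro", "camino", "ventana", "puerta", "cielo", "noche", "fuego",
    "piedra", "palabra", "historia", "momento", "manera", "lugar",
)

_FORUM_BAIT = (
    "pesticides exercise BPA parabens pollution diet family history "
    "phthalates alcohol flame retardants"
)

_PAGE_TEMPLATE = """<!DOCTYPE html>
<html>
<head>
<meta charset="utf-8">
<title>{title}</title>
<!-- pesticides pollution exercise diet -->
<script>var bait = "BPA phthalates parabens";</script>
<style>/* flame retardant styles */ p {{ margin: 1em; }}</style>
</head>
<body>
<nav>
{nav}
</nav>
{body}
</body>
</html>
"""


@dataclass(frozen=True)
class SyntheticSiteSpec:
    """Specification of one synthetic organization site.

    ``n_pages`` counts content pages (page 0 is the homepage); Spanish,
    forum and broken-link pages are additional nuisance pages.
    ``planted_counts`` maps ``(page_index, factor_name)`` to the exact
    number of occurrences to embed on that content page.
    """

    org_id: str
    n_pages: int = 1
    planted_counts: dict = field(default_factory=dict)
    n_spanish_pages: int = 0
    n_forum_pages: int = 0
    n_broken_links: int = 0
    decoy_density: float = 0.0
    link_topology: str = "chain"  # chain | star | complete | random
    seed: int = 0
    scope: str = "national"

    def __post_init__(self) -> None:
        if self.n_pages < 1:
            raise ValueError("n_pages must be >= 1")
        if not 0.0 <= self.decoy_density <= 1.0:
            raise ValueError("decoy_density must be in [0, 1]")
        if self.link_topology not in ("chain", "star", "complete", "random"):
            raise ValueError(f"unknown link_topology {self.link_topology!r}")
        for (page, _factor), count in self.planted_counts.items():
            if not 0 <= page < self.n_pages:
                raise ValueError(f"planted page index {page} out of range")
            if count < 0:
                raise ValueError("planted counts must be non-negative")

    @property
    def base_url(self) -> str:
        return f"https://{self.org_id}.example.org"

    def page_url(self, index: int) -> str:
        return self.base_url + ("/" if index == 0 else f"/page-{index}")

    def spanish_url(self, j: int) -> str:
        return f"{self.base_url}/es/pagina-{j + 1}"

    def forum_url(self, j: int) -> str:
        return f"{self.base_url}/forum/topic-{j + 1}"

    def broken_url(self, j: int) -> str:
        return f"{self.base_url}/missing-{j + 1}"


@dataclass
class GroundTruth:
    """Expected pipeline outcome for one generated site."""

    org_id: str
    org: OrgRecord
    page_counts: dict  # url -> {factor: int}, kept pages only, zero-filled
    page_status: dict  # url -> (status, drop_reason | None), all pages
    n_pages_kept: int
    totals: dict  # factor -> int
    category_totals: dict  # category -> int
    mentions_any_general_env: bool
    mentions_any_specific_env: bool
    mentions_any_other: bool
    env_avg_per_page: Optional[float]
    other_avg_per_page: Optional[float]
    index_rows: list  # (url, relative path)


@dataclass
class CorpusGroundTruth:
    sites: list[GroundTruth]
    n_orgs: int
    corpus_rows: dict  # factor -> (n_orgs_mentioning, pct, total_mentions)
    headline: dict  # pct_general_env / pct_specific_env / pct_other


def _pct(k: int, n: int) -> int:
    # round half away from zero, integer arithmetic
    return (200 * k + n) // (2 * n)


def _lexicon_token_set(lexicon: Lexicon) -> set[str]:
    toks: set[str] = set()
    for g in lexicon:
        for v in g.variants:
            toks.update(t.casefold() for t in _token_strings(v))
    return toks


def _check_filler_safety(lexicon: Lexicon) -> None:
    """Filler must share no token with any lexicon variant.

    Decoys are exempt: "chemical" legitimately occurs *inside* multi-word
    variants, and decoy neutrality instead rests on no decoy being a
    complete variant (checked here) and decoys only ever being inserted
    into filler blocks, never between the tokens of a planted phrase.
    """
    lex_tokens = _lexicon_token_set(lexicon)
    for vocab in (_FILLER_VOCAB, _SPANISH_FUNCTION, _SPANISH_CONTENT):
        clash = {w for w in vocab if w.casefold() in lex_tokens}
        if clash:
            raise RuntimeError(
                f"filler vocabulary collides with lexicon tokens: {clash}"
            )
    variants = {
        v.casefold() for g in lexicon for v in g.variants
    }
    decoy_clash = {d for d in DECOY_TERMS if d.casefold() in variants}
    if decoy_clash:
        raise RuntimeError(f"decoy terms are lexicon variants: {decoy_clash}")


def _count_subsequence(phrase_tokens: list[str], group) -> int:
    """Matches of *group*'s variants inside an isolated token sequence.

    Naive longest-first non-overlapping scan, used to credit cross-group
    containment in the ground truth: groups count independently, so a
    planted "air pollution" also yields one Pollution-group mention.
    Gap semantics are irrelevant here because planted phrases are written
    with single spaces.
    """
    compiled = sorted(
        (
            (tuple(_token_strings(v)), acr)
            for v, acr in zip(group.variants, group.acronym_flags)
        ),
        key=lambda item: -len(item[0]),
    )
    count = 0
    i = 0
    n = len(phrase_tokens)
    while i < n:
        for toks_v, acronym in compiled:
            k = len(toks_v)
            if i + k <= n and all(
                (phrase_tokens[i + j] == toks_v[j]) if acronym
                else (phrase_tokens[i + j].casefold() == toks_v[j].casefold())
                for j in range(k)
            ):
                count += 1
                i += k
                break
        else:
            i += 1
    return count


def _containment_extras(lexicon: Lexicon) -> dict:
    """Per planted factor, mentions its designated variant contributes to
    *other* groups (e.g. {"Air pollution": {"Pollution": 1}})."""
    extras: dict = {}
    for g in lexicon:
        phrase = _token_strings(g.variants[0])
        for h in lexicon:
            if h.factor_name == g.factor_name:
                continue
            hits = _count_subsequence(phrase, h)
            if hits:
                extras.setdefault(g.factor_name, {})[h.factor_name] = hits
    return extras


def _filler_block(rng: random.Random, decoy_density: float) -> list[str]:
    words = [rng.choice(_FILLER_VOCAB) for _ in range(rng.randint(2, 6))]
    if decoy_density and rng.random() < decoy_density:
        words.insert(rng.randrange(len(words) + 1), rng.choice(DECOY_TERMS))
    return words


def _content_page_body(
    spec: SyntheticSiteSpec,
    page_index: int,
    lexicon: Lexicon,
    rng: random.Random,
) -> str:
    """Filler paragraphs with the planted variants embedded in order."""
    planted: list[str] = []
    for g in lexicon:  # lexicon order keeps output deterministic
        count = spec.planted_counts.get((page_index, g.factor_name), 0)
        planted.extend([g.variants[0]] * count)
    pieces: list[str] = []
    pieces.extend(_filler_block(rng, spec.decoy_density))
    for phrase in planted:
        pieces.append(phrase)
        pieces.extend(_filler_block(rng, spec.decoy_density))
    # break into paragraphs of ~12 pieces
    paras = []
    for i in range(0, len(pieces), 12):
        paras.append("<p>" + " ".join(pieces[i:i + 12]) + "</p>")
    return "\n".join(paras)


def _spanish_page_body(rng: random.Random) -> str:
    # 60 tokens, half function words: stopword fraction ~0.5, far above
    # the 0.12 threshold and above any English-stopword fraction.
    words = []
    for _ in range(30):
        words.append(rng.choice(_SPANISH_FUNCTION))
        words.append(rng.choice(_SPANISH_CONTENT))
    paras = []
    for i in range(0, len(words), 15):
        paras.append("<p>" + " ".join(words[i:i + 15]) + "</p>")
    return "\n".join(paras)


def _links_for_page(
    spec: SyntheticSiteSpec,
    page_index: int,
    adjacency: Optional[list[list[bool]]],
) -> list[str]:
    """Outgoing link URLs for content page *page_index* (deterministic)."""
    n = spec.n_pages
    targets: list[int] = []
    if spec.link_topology == "chain":
        if page_index + 1 < n:
            targets = [page_index + 1]
    elif spec.link_topology == "star":
        targets = list(range(1, n)) if page_index == 0 else [0]
    elif spec.link_topology == "complete":
        targets = [j for j in range(n) if j != page_index]
    else:  # random: spanning tree + extra seeded edges
        targets = [j for j in range(n)
                   if j != page_index and adjacency[page_index][j]]
    links = [spec.page_url(j) for j in targets]
    if page_index == 0:
        links += [spec.spanish_url(j) for j in range(spec.n_spanish_pages)]
        links += [spec.forum_url(j) for j in range(spec.n_forum_pages)]
        links += [spec.broken_url(j) for j in range(spec.n_broken_links)]
    return links


def _random_adjacency(spec: SyntheticSiteSpec,
                      rng: random.Random) -> list[list[bool]]:
    n = spec.n_pages
    adj = [[False] * n for _ in range(n)]
    for child in range(1, n):  # spanning tree keeps every page reachable
        parent = rng.randrange(child)
        adj[parent][child] = True
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < 0.15:
                adj[i][j] = True
    return adj


def _nav_html(links: list[str]) -> str:
    return "\n".join(f'<a href="{u}">{u}</a>' for u in links)


def generate_site(
    spec: SyntheticSiteSpec,
    lexicon: Lexicon,
    out_dir: str | Path,
) -> GroundTruth:
    """Write one synthetic site's HTML files under ``out_dir/<org_id>/``
    plus an ``index.csv``, and return its ground truth.

    Raises ``ValueError`` if a planted factor is not in the lexicon.
    """
    for (_page, factor) in spec.planted_counts:
        if factor not in lexicon:
            raise ValueError(f"planted factor {factor!r} not in lexicon")
    _check_filler_safety(lexicon)
    out_dir = Path(out_dir)
    site_dir = out_dir / spec.org_id
    site_dir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(spec.seed)
    adjacency = (
        _random_adjacency(spec, rng) if spec.link_topology == "random" else None
    )
    extras = _containment_extras(lexicon)

    index_rows: list[tuple[str, str]] = []
    page_status: dict = {}
    page_counts: dict = {}

    def _write(url: str, rel_path: str, html: str) -> None:
        (out_dir / rel_path).write_text(html, encoding="utf-8", newline="\n")
        index_rows.append((canonicalize_url(url), rel_path))

    for i in range(spec.n_pages):
        url = canonicalize_url(spec.page_url(i))
        body = _content_page_body(spec, i, lexicon, rng)
        nav = _nav_html(_links_for_page(spec, i, adjacency))
        html = _PAGE_TEMPLATE.format(
            title=f"{spec.org_id} page {i}", nav=nav, body=body
        )
        _write(url, f"{spec.org_id}/page{i}.html", html)
        page_status[url] = ("kept", None)
        expected = {
            g.factor_name: spec.planted_counts.get((i, g.factor_name), 0)
            for g in lexicon
        }
        # cross-group containment: a planted phrase may embed another
        # group's variant, which counts for that group too
        for g in lexicon:
            planted_here = spec.planted_counts.get((i, g.factor_name), 0)
            if planted_here:
                for other, hits in extras.get(g.factor_name, {}).items():
                    expected[other] += planted_here * hits
        page_counts[url] = expected
    for j in range(spec.n_spanish_pages):
        url = canonicalize_url(spec.spanish_url(j))
        html = _PAGE_TEMPLATE.format(
            title=f"pagina {j}", nav=_nav_html([spec.page_url(0)]),
            body=_spanish_page_body(rng),
        )
        _write(url, f"{spec.org_id}/es_pagina{j}.html", html)
        page_status[url] = ("dropped", "language")
    for j in range(spec.n_forum_pages):
        url = canonicalize_url(spec.forum_url(j))
        html = _PAGE_TEMPLATE.format(
            title=f"forum topic {j}", nav=_nav_html([spec.page_url(0)]),
            body=f"<p>{_FORUM_BAIT}</p>",
        )
        _write(url, f"{spec.org_id}/forum_topic{j}.html", html)
        page_status[url] = ("dropped", "sponsor_shop_forum")
    for j in range(spec.n_broken_links):
        # target is linked from the homepage but absent from the index
        page_status[canonicalize_url(spec.broken_url(j))] = ("dropped", "broken")

    with open(out_dir / "index.csv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["url", "path"])
        writer.writerows(index_rows)

    totals = {g.factor_name: 0 for g in lexicon}
    for counts in page_counts.values():
        for f, n in counts.items():
            totals[f] += n
    category_totals = {c: 0 for c in CATEGORIES}
    for g in lexicon:
        category_totals[g.category] += totals[g.factor_name]
    n_kept = spec.n_pages
    env_total = (category_totals["general_environmental"]
                 + category_totals["specific_environmental"])
    other_total = category_totals["other"]
    org = OrgRecord(
        org_id=spec.org_id,
        name=spec.org_id,
        homepages=(spec.page_url(0),),
        scope=spec.scope,
    )
    return GroundTruth(
        org_id=spec.org_id,
        org=org,
        page_counts=page_counts,
        page_status=page_status,
        n_pages_kept=n_kept,
        totals=totals,
        category_totals=category_totals,
        mentions_any_general_env=category_totals["general_environmental"] > 0,
        mentions_any_specific_env=category_totals["specific_environmental"] > 0,
        mentions_any_other=category_totals["other"] > 0,
        env_avg_per_page=env_total / n_kept if n_kept else None,
        other_avg_per_page=other_total / n_kept if n_kept else None,
        index_rows=index_rows,
    )


def generate_corpus(
    specs: list[SyntheticSiteSpec],
    lexicon: Lexicon,
    out_dir: str | Path,
) -> CorpusGroundTruth:
    """Generate several sites sharing one fixture index and registry.

    Writes ``out_dir/index.csv`` (all sites), ``out_dir/registry.csv`` and
    per-site HTML directories; returns corpus-level ground truth.
    """
    ids = [s.org_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate org_id in corpus specs")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sites = [generate_site(spec, lexicon, out_dir) for spec in specs]

    # merged fixture index covering every site
    all_rows = [row for gt in sites for row in gt.index_rows]
    with open(out_dir / "index.csv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["url", "path"])
        writer.writerows(all_rows)
    save_registry([gt.org for gt in sites], out_dir / "registry.csv")

    n_orgs = len(sites)
    corpus_rows = {}
    for g in lexicon:
        k = sum(1 for gt in sites if gt.totals[g.factor_name] > 0)
        total = sum(gt.totals[g.factor_name] for gt in sites)
        corpus_rows[g.factor_name] = (k, _pct(k, n_orgs), total)
    headline = {
        "pct_general_env": _pct(
            sum(gt.mentions_any_general_env for gt in sites), n_orgs),
        "pct_specific_env": _pct(
            sum(gt.mentions_any_specific_env for gt in sites), n_orgs),
        "pct_other": _pct(
            sum(gt.mentions_any_other for gt in sites), n_orgs),
    }
    return CorpusGroundTruth(
        sites=sites, n_orgs=n_orgs, corpus_rows=corpus_rows, headline=headline
    )


def random_corpus_specs(
    seed: int,
    lexicon: Lexicon,
    n_orgs: Optional[int] = None,
) -> list[SyntheticSiteSpec]:
    """Randomized but fully seeded corpus specifications for stress runs.

    Emulates the study conditions at desk scale: 5-10 organizations of
    3-50 pages each over mixed link topologies, planted counts 0-25 per
    (page, factor), a few Spanish/forum pages and broken links per site,
    and decoy densities up to 0.5.
    """
    rng = random.Random(seed)
    if n_orgs is None:
        n_orgs = rng.randint(5, 10)
    factor_names = [g.factor_name for g in lexicon]
    topologies = ("chain", "star", "complete", "random")
    specs = []
    for i in range(n_orgs):
        n_pages = rng.randint(3, 50)
        planted: dict = {}
        for page in range(n_pages):
            for factor in rng.sample(factor_names, rng.randint(0, 3)):
                planted[(page, factor)] = rng.randint(0, 25)
        specs.append(SyntheticSiteSpec(
            org_id=f"org{i}",
            n_pages=n_pages,
            planted_counts=planted,
            n_spanish_pages=rng.randint(0, 2),
            n_forum_pages=rng.randint(0, 2),
            n_broken_links=rng.randint(0, 2),
            decoy_density=rng.choice((0.0, 0.2, 0.5)),
            link_topology=topologies[i % len(topologies)],
            seed=rng.randrange(2**31),
            scope=rng.choice(("national", "local_regional")),
        ))
    return specs


def ground_truth_mismatches(truth: CorpusGroundTruth, result) -> list[str]:
    """Compare a pipeline run against corpus ground truth.

    *result* is a pipeline result over the generated fixtures.  Returns a
    list of human-readable discrepancies (empty = exact agreement at page,
    organization and corpus level, integer equality throughout).
    """
    problems: list[str] = []
    by_org = {r.org.org_id: r for r in result.org_results}
    for gt in truth.sites:
        r = by_org.get(gt.org_id)
        if r is None:
            problems.append(f"{gt.org_id}: missing from pipeline result")
            continue
        got_status = {p.url: (p.status, p.drop_reason) for p in r.pages}
        for url, expect in gt.page_status.items():
            if got_status.get(url) != expect:
                problems.append(
                    f"{url}: status {got_status.get(url)} != {expect}"
                )
        got_counts = {c.url: dict(c.counts) for c in r.counts}
        for url, expect in gt.page_counts.items():
            if got_counts.get(url) != expect:
                problems.append(f"{url}: counts differ")
        s = r.summary
        if s.n_pages_kept != gt.n_pages_kept:
            problems.append(f"{gt.org_id}: n_pages_kept {s.n_pages_kept} "
                            f"!= {gt.n_pages_kept}")
        if s.totals != gt.totals:
            problems.append(f"{gt.org_id}: totals differ")
        if s.category_totals != gt.category_totals:
            problems.append(f"{gt.org_id}: category totals differ")
        if (s.mentions_any_general_env, s.mentions_any_specific_env,
                s.mentions_any_other) != (gt.mentions_any_general_env,
                                          gt.mentions_any_specific_env,
                                          gt.mentions_any_other):
            problems.append(f"{gt.org_id}: category booleans differ")
        if (s.env_avg_per_page, s.other_avg_per_page) != (
                gt.env_avg_per_page, gt.other_avg_per_page):
            problems.append(f"{gt.org_id}: per-page averages differ")
    got_rows = {
        r.factor_name: (r.n_orgs_mentioning, r.pct_orgs_mentioning,
                        r.total_mentions)
        for r in result.report.rows
    }
    if got_rows != truth.corpus_rows:
        problems.append("corpus rows differ")
    if result.report.headline != truth.headline:
        problems.append("headline shares differ")
    return problems
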