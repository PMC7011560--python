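# termsweep

**Lexicon-based term-frequency audits of organization websites.**

`termsweep` is for researchers in health communication and infodemiology
who want to measure, reproducibly, how often a set of topics is mentioned
across the websites of a population of organizations. It was built around
a concrete study design: auditing how U.S. breast cancer organizations
discuss environmental versus lifestyle/genetic risk factors on their
websites, using a fixed vocabulary of risk-factor terms. The same
machinery applies to any "does this population of websites talk about X,
and how much?" question.

The pipeline has four stages, each usable on its own:

1. **acquisition** — enumerate an organization's pages by breadth-first,
   same-domain crawling from its homepage(s), fetching content live, from
   a dated Internet Archive snapshot, or from a local fixture directory
   (provenance is recorded per page);
2. **cleaning** — drop pages by reproducible exclusion rules: broken
   links, undecodable content, shop/sponsor/forum-style URLs,
   per-organization URL subsetting, and Spanish-language pages (stopword-
   ratio heuristic with `<html lang>` override);
3. **counting** — extract visible text (script/style/comment content
   removed) and count occurrences of every term group in a categorized
   lexicon: word-boundary matching, longest-variant-wins,
   non-overlapping within a group, case-sensitive acronyms;
4. **aggregation** — roll counts up to per-site tables, per-organization
   summaries, and a corpus table of organization shares.

A seeded **synthetic-website generator** produces linked multi-page HTML
sites with exactly known planted counts and nuisance content (Spanish
pages, forum pages, broken links, ambiguous decoy terms), so every stage
is verifiable offline against ground truth.

## The statistic

For factor $f$ with term-group variants $V_f$, the mention count on page
$p$ is the number of non-overlapping, word-boundary matches of any
$v \in V_f$ in the page's visible text. An organization's total is the sum
over its kept pages, and the corpus table reports, per factor,

$$\mathrm{pct}_f = \mathrm{round}\!\left(100 \cdot k_f / N\right),$$

where $k_f$ of $N$ organizations have a positive total (rounding half
away from zero). Per-organization scatter points compare average mentions
per kept page of environmental factors (general + specific categories)
against all other risk factors.

## Worked example

`examples/synthetic_pipeline.py` plants known counts on three synthetic
sites, runs the full pipeline over the generated fixtures, and checks the
result against ground truth. Its output:

```
drop tally: {'kept': 9, 'broken': 1, 'undecodable': 0, 'manual': 0,
             'subset_pattern': 0, 'sponsor_shop_forum': 1, 'language': 1}

corpus table (non-zero rows):
factor                               pct n_orgs mentions
Exercise                              33      1        6
Diet                                  33      1        2
Pesticides                            33      1        3
Phthalates                            33      1        5

headline shares: {'pct_general_env': 0, 'pct_specific_env': 33, 'pct_other': 33}
per-org averages (env vs other mentions per kept page):
  greenorg   [national] env=2.00 other=0.00
  lifestyle  [local_regional] env=0.00 other=2.67
  quietorg   [national] env=0.00 other=0.00

ground-truth mismatches: none
```

Reading this: of the 12 fetched pages, 9 survived cleaning (one broken
link, one forum page, one Spanish page were dropped with their reasons
tallied). Each planted factor is mentioned by 1 of 3 organizations
(33%), with mention totals equal to the planted occurrences. The
per-organization averages show the two "specialized" sites sitting on the
axes — one mentions only environmental factors, the other only lifestyle
factors — and the pipeline output agrees with the planted ground truth
exactly.

Other examples: `build_lexicon.py` (the default 23-factor vocabulary),
`count_page_mentions.py` (matching semantics on one HTML page),
`crawl_fixture_site.py` (crawler behavior), and
`reproduce_percent_column.py` (re-deriving the published survey table's
percent column).

## Command line

Each stage is exposed as a thin subcommand moving data through plain-text
formats (JSON-lines pages/counts, CSV registries and reports):

```bash
termsweep simulate  --out-dir fixtures/ --seed 7 --n-orgs 5
termsweep crawl     --registry fixtures/registry.csv --fixture-dir fixtures/ --out pages.jsonl
termsweep clean     --pages pages.jsonl --registry fixtures/registry.csv --out cleaned.jsonl --report drops.csv
termsweep count     --pages cleaned.jsonl --out counts.jsonl
termsweep aggregate --counts counts.jsonl --registry fixtures/registry.csv --out-dir reports/ --plot
```

Live crawling (`termsweep crawl` without `--fixture-dir`) respects
robots.txt and applies a politeness delay; `--archive-date YYYY-MM-DD`
prefers Internet Archive snapshots nearest that date, falling back to
live fetches.

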