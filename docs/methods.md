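# Methods

## Problem and scope

The package measures how often a fixed, categorized vocabulary of
breast-cancer risk-factor terms appears on organization websites. The
design follows a website content-analysis of 81 U.S. breast cancer
organizations (pages archived mid-November 2018; ~14,000 kept URLs):
crawl each organization's site, exclude non-relevant pages, count term
occurrences in visible text, and aggregate to organization shares and
mention totals. Qualitative analysis of page prose is out of scope; the
package automates only the quantitative term-frequency arm.

## The lexicon

The default vocabulary has 23 factor groups, each a set of surface
variants whose occurrences are summed, categorized three ways:

* `general_environmental` (3 groups): contamination, pollution, the
  precautionary principle;
* `specific_environmental` (10 groups): pesticides, bisphenols,
  parabens, endocrine-disrupting chemicals, phthalates, flame
  retardants, air pollution, PAHs, PFAS, oxybenzone;
* `other` (10 groups): exercise, family history, diet, genetics,
  alcohol, breast density, body weight, HRT, birth control, DES.

Choices that needed making:

* **"(s)" expansion, no stemming.** "Pesticide(s)" becomes the explicit
  pair {pesticide, pesticides}. Stemming would silently widen matching
  beyond the declared term list.
* **Printed versus supplementary variants.** The published term table
  expands to exactly 52 surface forms; the summary helper reports this
  count. Three supplementary variants are added and flagged as such:
  BRCA1/BRCA2 (the table prints the almost certainly misspelled BRAC1/
  BRAC2; both spellings are kept so either convention is counted) and
  the spelled-out "hormone replacement therapy" beside HRT.
* **Excluded ambiguous terms.** "environment", "toxic", "chemical" and
  "hormone therapy" are banned as standalone variants because on cancer
  sites they frequently refer to chemotherapy, treatment toxicity, or
  endocrine treatment rather than exposures. The ban is on a variant
  *equal to* the term: "endocrine disrupting chemicals" is a legitimate
  multi-word variant that merely contains the token "chemical".
* **Acronym case.** All-caps variants (BPA, HRT, DES, PAH/PAHs, PFOA,
  PFOS, PFAS, PFC/PFCs, BRAC1/2, BRCA1/2) match case-sensitively so
  that "des moines" is not a DES mention. Other variants match
  case-insensitively; whether the original analysis was case-sensitive
  is not recoverable, and the asymmetric rule is the conservative
  reading.

## Matching semantics

Tokens are maximal letter/digit runs; punctuation and underscores are
boundaries (so "BPA," matches). Multi-word variants tolerate any single
run of whitespace and/or hyphens between tokens ("endocrine-disrupting
chemicals" matches), while other punctuation breaks the phrase. Within a
group, the longest variant matching at a position wins and matches do
not overlap; occurrences (not page-level presence) are counted, because
the published mention totals (e.g. 2796 for exercise) far exceed page
counts. Groups count independently of one another, so a planted "air
pollution" phrase also registers one "Pollution"-group mention — the only
cross-group containment in the default lexicon.

The test suite holds the counter to a character-level brute-force oracle
(enumerate every start position, try every variant regex, longest match
wins) on randomized planted texts; the two implementations share no code.

## Acquisition

Crawling is breadth-first from the homepage(s) with a document-order
frontier, following only links whose public-suffix-aware registered
domain matches a homepage (so `www.` and subdomain variants are one
site). Canonical URLs (lowercased scheme/host, fragment stripped,
non-root trailing slash removed, `utm_*` parameters dropped) are fetched
at most once; transport failures are recorded as data (status sentinel
0), never raised. Defaults: `max_pages=1000` (the study's largest site
had 894 URLs), crawler `max_depth=10`; the pipeline wrapper passes
`max_depth=100` so long chain-shaped sites enumerate fully. The
registered-domain logic uses a small embedded multi-label suffix list
rather than a full public-suffix database — adequate for `.org/.com`
style hosts and the fixture domains used throughout.

Retrieval is archive-first when a target date is given: the capture
nearest the date within ±45 days (the study archived mid-November 2018
and accepted "comparable period" fallbacks) is used with provenance
`archived`, then a live fetch (`live`), then a recorded failure. Live
fetching respects robots.txt and a fixed politeness delay; fixture
fetchers bypass both.

## Cleaning

The study curated pages manually; the package encodes the stated
exclusion categories as reproducible rules plus a per-organization
manual exclude list for cases patterns cannot express. Precedence is
fixed so drop-reason tallies are stable: broken → undecodable → manual →
subset_pattern → sponsor_shop_forum → language; the first failing rule
wins. Decoding tries the declared charset, UTF-8, then cp1252, all
strict; pages failing all three are dropped as undecodable (the study
reported 843 such URLs). Pages with empty extracted text are kept and
count zero everywhere.

Language identification is a stopword-ratio heuristic over fixed
embedded English and Spanish function-word lists: a page is Spanish when
its Spanish-stopword fraction exceeds 0.12 *and* exceeds the English
fraction; texts under 25 tokens are `unknown` and kept. An explicit
`<html lang>` attribute overrides the heuristic. This keeps the stage
dependency-free and exactly testable; it is a two-class decision and
would misjudge other languages (out of scope — the study's corpus was
English with Spanish sections).

## Aggregation

"Mentions a factor" means a positive total over the organization's kept
pages — the only reading consistent with a percent-of-organizations
column. Percentages round half away from zero; all 23 published percents
are reproduced from their printed counts at N=81 (no half-cases occur).
Corpus rows sort by descending organization count with lexicon order on
ties, which reproduces the published row order. Per-organization
averages divide by kept pages (whether the original denominators
included later-excluded pages is unstated; kept pages is the defensible
choice) and are flagged undefined (`None`) for organizations with zero
kept pages, which are likewise omitted from the scatter points. The
scatter's axis assignment is emitted as labeled pairs so either
orientation can be plotted.

## Synthetic sites and what they show

The generator plants one designated variant per factor (the group's
first variant), separated by filler drawn from an invented vocabulary
checked at generation time to share no token with any lexicon variant.
Decoys (the excluded ambiguous terms) are inserted only into filler
blocks at the requested density and can never complete a variant, so
expected counts are invariant to decoy density. Ground truth accounts
for the one cross-group containment ("air pollution" ⊃ "pollution") via
an independent token-subsequence scan. Content pages carry lexicon terms
inside script/style blocks and HTML comments, so an extraction leak
breaks the ground-truth comparison loudly. Spanish nuisance pages are
half function words (well above the 0.12 threshold); forum pages carry
`/forum/` paths and deliberately contain countable terms that must be
excluded by the URL rule; broken links point at URLs absent from the
fixture index. All randomness flows from the spec's seed; fixtures are
byte-identical across regenerations.

Passing the synthetic end-to-end checks shows the pipeline's stages
compose correctly and count exactly under known conditions. It does not
show that the cleaning heuristics match a human curator's judgment on
real pages (sponsor/shop/forum URL patterns are an approximation of a
manual process), nor that real-site boilerplate (repeated navigation and
footers, which are counted on every page, as the original analysis
appears to have done) is handled differently — both are properties of
real data the generator does not emulate.

## Problem sizes

The randomized verification runs use 5–10 organizations of 3–50 pages
(mixed chain/star/complete/random topologies), planted counts 0–25,
up to two each of Spanish/forum/broken nuisance pages, and decoy
densities up to 0.5; 20 such corpora per run, 110 randomized texts for
the counter/oracle comparison, and 50 randomized link graphs for the
crawler properties. These sizes exercise every code path at desk scale;
the published corpus (81 organizations, ~14,000 pages) depends on the
live 2018 web and cannot be regenerated.

## Known limitations

* No JavaScript rendering, sitemap parsing, or authenticated crawling;
  dynamic content is invisible.
* The language heuristic distinguishes only English from Spanish.
* URL-pattern cleaning can both over-drop (a legitimate page containing
  "board" in its path) and under-drop (a sponsor page with a neutral
  URL); the per-organization manual exclude list is the escape hatch.
* Term counting is context-blind by design: ambiguity is handled by
  excluding four ambiguous terms, not by disambiguation, so residual
  off-topic matches (e.g. post-surgery "exercises") are counted.
* The embedded registered-domain suffix list is minimal; unusual
  country-code suffixes may be grouped too coarsely.
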