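from __future__ import annotations

import math
import random

import pytest
from hypothesis import given, settings, strategies as st

from termsweep.acquisition import OrgRecord
from termsweep.aggregation import (
    corpus_table,
    corpus_table_frame,
    fig1_frame,
    percent_mentioning,
    site_report,
    summarize_org,
)
from termsweep.counting import PageTermCounts
from termsweep.reference import N_SURVEY_ORGS, SURVEY_TABLE


def _org(org_id="o1", scope="national"):
    return OrgRecord(org_id=org_id, name=org_id,
                     homepages=(f"https://{org_id}.org/",), scope=scope)


def _counts(org_id, url, lexicon, **factor_counts):
    counts = {g.factor_name: 0 for g in lexicon}
    counts.update(factor_counts)
    return PageTermCounts(org_id=org_id, url=url, counts=counts)


class TestPercentMentioning:
    @pytest.mark.parametrize("k,n,expected", [
        (60, 81, 74),
        (6, 81, 7),
        (0, 81, 0),
        (81, 81, 100),
        (1, 2, 50),
    ])
    def test_examples(self, k, n, expected):
        assert percent_mentioning(k, n) == expected

    def test_reproduces_every_published_row(self):
        for row in SURVEY_TABLE:
            assert percent_mentioning(row.n_orgs_mentioning, N_SURVEY_ORGS) \
                == row.pct_orgs_mentioning

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            percent_mentioning(0, 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            percent_mentioning(5, 3)

    @given(st.integers(0, 500), st.integers(1, 500))
    @settings(max_examples=200, deadline=None)
    def test_matches_half_away_from_zero_rounding(self, k, n):
        k = min(k, n)
        expected = math.floor(100 * k / n + 0.5)
        assert percent_mentioning(k, n) == expected


class TestSummarizeOrg:
    def test_totals_sum_over_pages(self, lexicon):
        org = _org()
        pages = [
            _counts("o1", "https://o1.org/a", lexicon, Pesticides=2),
            _counts("o1", "https://o1.org/b", lexicon, Pesticides=1),
        ]
        s = summarize_org(pages, org, lexicon)
        assert s.totals["Pesticides"] == 3
        assert s.mentions_any_specific_env is True
        assert s.mentions_any_general_env is False

    def test_averages(self, lexicon):
        org = _org()
        pages = (
            [_counts("o1", f"https://o1.org/p{i}", lexicon) for i in range(8)]
            + [
                _counts("o1", "https://o1.org/e", lexicon, Pollution=5),
                _counts("o1", "https://o1.org/o", lexicon, Exercise=20),
            ]
        )
        s = summarize_org(pages, org, lexicon)
        assert s.n_pages_kept == 10
        assert s.env_avg_per_page == 0.5
        assert s.other_avg_per_page == 2.0

    def test_zero_pages_flagged_undefined(self, lexicon):
        s = summarize_org([], _org(), lexicon)
        assert s.env_avg_per_page is None
        assert s.other_avg_per_page is None
        assert all(v == 0 for v in s.totals.values())

    def test_foreign_page_rejected(self, lexicon):
        with pytest.raises(ValueError, match="belongs"):
            summarize_org(
                [_counts("other", "https://x.org/", lexicon)], _org(), lexicon
            )


class TestCorpusTable:
    def _summaries(self, lexicon, profiles):
        out = []
        for i, factor_counts in enumerate(profiles):
            org = _org(f"org{i}")
            page = _counts(org.org_id, f"https://org{i}.org/", lexicon,
                           **factor_counts)
            out.append(summarize_org([page], org, lexicon))
        return out

    def test_single_mentioning_org_of_two(self, lexicon):
        summaries = self._summaries(lexicon, [{"Parabens": 2}, {}])
        report = corpus_table(summaries, lexicon)
        row = next(r for r in report.rows if r.factor_name == "Parabens")
        assert row.n_orgs_mentioning == 1
        assert row.pct_orgs_mentioning == 50
        assert row.total_mentions == 2

    def test_headline_from_planted_category_profiles(self, lexicon):
        # env-only, other-only, both -> specific-env share = pct(2, 3) = 67
        summaries = self._summaries(lexicon, [
            {"Phthalates": 1},
            {"Exercise": 3},
            {"Phthalates": 2, "Exercise": 1},
        ])
        report = corpus_table(summaries, lexicon)
        assert report.headline["pct_specific_env"] == 67
        assert report.headline["pct_other"] == 67
        assert report.headline["pct_general_env"] == 0

    def test_single_org_percents_are_0_or_100(self, lexicon):
        report = corpus_table(self._summaries(lexicon, [{"Diet": 5}]), lexicon)
        assert {r.pct_orgs_mentioning for r in report.rows} <= {0, 100}

    def test_permutation_invariance(self, lexicon):
        summaries = self._summaries(lexicon, [
            {"Diet": 1}, {"Pollution": 4}, {"Bisphenols": 0, "Alcohol": 2},
        ])
        report_a = corpus_table(summaries, lexicon)
        rng = random.Random(5)
        for _ in range(5):
            shuffled = summaries[:]
            rng.shuffle(shuffled)
            report_b = corpus_table(shuffled, lexicon)
            assert report_b.rows == report_a.rows
            assert report_b.headline == report_a.headline

    def test_conservation_of_mentions(self, lexicon):
        rng = random.Random(11)
        factor_names = [g.factor_name for g in lexicon]
        summaries = []
        page_level: dict[str, int] = {f: 0 for f in factor_names}
        for i in range(6):
            org = _org(f"org{i}")
            pages = []
            for p in range(rng.randint(1, 4)):
                fc = {f: rng.randint(0, 3)
                      for f in rng.sample(factor_names, 4)}
                for f, n in fc.items():
                    page_level[f] += n
                pages.append(_counts(org.org_id, f"https://org{i}.org/p{p}",
                                     lexicon, **fc))
            summaries.append(summarize_org(pages, org, lexicon))
        report = corpus_table(summaries, lexicon)
        for row in report.rows:
            assert row.total_mentions == page_level[row.factor_name]

    def test_duplicate_org_rejected(self, lexicon):
        s = self._summaries(lexicon, [{"Diet": 1}])
        with pytest.raises(ValueError, match="duplicate"):
            corpus_table(s + s, lexicon)

    def test_empty_rejected(self, lexicon):
        with pytest.raises(ValueError):
            corpus_table([], lexicon)

    def test_specialized_orgs_sit_on_axes(self, lexicon):
        # env-only org -> other average 0; other-only org -> env average 0
        summaries = self._summaries(lexicon, [
            {"Phthalates": 7}, {"Exercise": 9},
        ])
        report = corpus_table(summaries, lexicon)
        points = {p.org_id: p for p in report.fig1_points}
        assert points["org0"].other_avg_per_page == 0
        assert points["org0"].env_avg_per_page > 0
        assert points["org1"].env_avg_per_page == 0
        assert points["org1"].other_avg_per_page > 0

    def test_org_without_pages_has_no_scatter_point(self, lexicon):
        org = _org("empty")
        summaries = self._summaries(lexicon, [{"Diet": 1}])
        summaries.append(summarize_org([], org, lexicon))
        report = corpus_table(summaries, lexicon)
        assert all(p.org_id != "empty" for p in report.fig1_points)

    def test_frames_have_expected_columns(self, lexicon):
        report = corpus_table(self._summaries(lexicon, [{"Diet": 1}]), lexicon)
        frame = corpus_table_frame(report, lexicon)
        assert list(frame.columns) == [
            "factor", "category", "representative_terms",
            "pct_orgs", "n_orgs", "total_mentions",
        ]
        assert len(frame) == len(lexicon)
        assert list(fig1_frame(report).columns) == [
            "org_id", "scope", "env_avg_per_page", "other_avg_per_page",
        ]


class TestSiteReport:
    def test_planted_totals_reported(self, lexicon):
        pages = [
            _counts("site", "https://s.org/a", lexicon, **{"Family history": 3}),
            _counts("site", "https://s.org/b", lexicon, **{"Family history": 2}),
        ]
        rows = site_report(pages, lexicon)
        by_factor = {r.factor_name: r.total_mentions for r in rows}
        assert by_factor["Family history"] == 5
        assert by_factor["Parabens"] == 0

    def test_empty_page_set_all_zero(self, lexicon):
        rows = site_report([], lexicon)
        assert len(rows) == len(lexicon)
        assert all(r.total_mentions == 0 for r in rows)

    def test_descending_with_alphabetical_ties(self, lexicon):
        pages = [_counts("site", "https://s.org/", lexicon,
                         Diet=3, Alcohol=7, Exercise=7)]
        rows = site_report(pages, lexicon)
        assert [r.factor_name for r in rows[:3]] == ["Alcohol", "Exercise", "Diet"]
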