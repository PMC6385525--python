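"""Association statistics: cohort MAF, odds ratios, one-sided Fisher test,
Bonferroni correction, gene aggregation, and the burden model surface."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poolburden import (
    ConfigurationError,
    ContingencyTable,
    GeneBurdenModel,
    PoolObservation,
    ReferencePanel,
    ValidationError,
    VariantKey,
    VariantRecord,
    aggregate_gene_table,
    bonferroni_correct,
    cohort_maf,
    fisher_one_sided,
    odds_ratio_ci,
    prioritize_rare_variants,
    run_burden_analysis,
    variant_odds_ratio,
)


def enumeration_oracle(a, b, c, d):
    """Exact upper-tail probability by summing binomial-coefficient products
    over all tables with the same margins and case-alt >= a."""
    total, k_alt, n_case = a + b + c + d, a + c, a + b
    if total == 0:
        return 1.0
    num = sum(
        math.comb(k_alt, k) * math.comb(total - k_alt, n_case - k)
        for k in range(a, min(k_alt, n_case) + 1)
    )
    return num / math.comb(total, n_case)


class TestCohortMaf:
    @pytest.mark.parametrize(
        "ac,expected",
        [(6, 0.003614), (0, 0.0), (14, 0.008434), (28, 0.016867), (40, 0.024096)],
    )
    def test_cohort_frequencies_at_830_cases(self, ac, expected):
        assert round(cohort_maf(ac, 830), 6) == expected

    def test_zero_individuals_rejected(self):
        with pytest.raises(ConfigurationError):
            cohort_maf(1, 0)

    def test_count_above_allele_total_rejected(self):
        with pytest.raises(ValidationError):
            cohort_maf(1661 * 2, 830)


class TestOddsRatio:
    def test_identical_frequencies_give_unity(self):
        or_point, lo, hi = odds_ratio_ci((10, 990, 10, 990))
        assert or_point == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_closed_form_cross_product_and_woolf_ci(self):
        """6/1654 vs 4/119996: checked against an independent evaluation of
        the cross-product OR and the log-normal CI."""
        a, b, c, d = 6, 1654, 4, 119996
        or_point, lo, hi = odds_ratio_ci((a, b, c, d))
        expected_or = (a * d) / (b * c)
        assert expected_or == pytest.approx(108.8227, rel=1e-4)
        assert or_point == pytest.approx(expected_or)
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        assert lo == pytest.approx(expected_or * math.exp(-1.959963984540054 * se))
        assert hi == pytest.approx(expected_or * math.exp(+1.959963984540054 * se))

    def test_zero_cell_haldane_correction(self):
        a, b, c, d = 5, 95, 0, 100
        or_point, lo, hi = odds_ratio_ci((a, b, c, d))
        expected = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        assert or_point == pytest.approx(expected)
        assert math.isfinite(lo) and math.isfinite(hi)

    def test_no_alt_anywhere_is_undefined(self):
        result = variant_odds_ratio(0, 100, 0, 200)
        assert math.isnan(result.or_point)
        assert result.note is not None
        assert result.p == 1.0

    @given(
        a=st.integers(1, 30),
        b=st.integers(1, 30),
        c=st.integers(1, 30),
        d=st.integers(1, 30),
    )
    @settings(derandomize=True, max_examples=100)
    def test_column_swap_reciprocal(self, a, b, c, d):
        or_ab, _, _ = odds_ratio_ci((a, b, c, d))
        or_ba, _, _ = odds_ratio_ci((c, d, a, b))
        assert or_ab == pytest.approx(1.0 / or_ba)

    def test_ci_brackets_point_estimate(self):
        result = variant_odds_ratio(6, 1660, 4, 120000)
        assert result.ci_low <= result.or_point <= result.ci_high
        assert result.m == 1
        assert result.p_corrected == result.p


class TestFisherOneSided:
    def test_least_enriched_table_gives_one(self):
        assert fisher_one_sided((0, 10, 5, 5)) == pytest.approx(1.0)

    def test_most_enriched_table_exact_value(self):
        # P(X >= 5), X ~ Hypergeom(N=20, K=5, n=10) = C(15,5)/C(20,10)
        expected = math.comb(15, 5) / math.comb(20, 10)
        assert fisher_one_sided((5, 5, 0, 10)) == pytest.approx(expected, rel=1e-12)

    @given(
        a=st.integers(0, 12),
        b=st.integers(0, 12),
        c=st.integers(0, 12),
        d=st.integers(0, 12),
    )
    @settings(derandomize=True, max_examples=300)
    def test_matches_enumeration_oracle(self, a, b, c, d):
        assert fisher_one_sided((a, b, c, d)) == pytest.approx(
            enumeration_oracle(a, b, c, d), abs=1e-12
        )

    @given(
        a=st.integers(0, 10),
        b=st.integers(0, 10),
        c=st.integers(0, 10),
        d=st.integers(0, 10),
    )
    @settings(derandomize=True, max_examples=200)
    def test_enrichment_equals_mirror_depletion(self, a, b, c, d):
        """Enrichment p of a table equals the depletion p (lower tail) of its
        column-swapped mirror."""
        enrichment = fisher_one_sided((a, b, c, d))
        # depletion of (c, d, a, b): P(X' <= c) = 1 - P(X' >= c + 1)
        if d >= 1 and a >= 1:
            above = fisher_one_sided((c + 1, d - 1, a - 1, b + 1))
        else:
            above = 0.0
        assert abs((1.0 - above) - enrichment) < 1e-9

    def test_large_cells_no_overflow(self):
        p = fisher_one_sided((500, 10**6, 100, 10**6))
        assert 0.0 < p < 1.0

    def test_negative_cell_rejected(self):
        with pytest.raises(ValidationError):
            ContingencyTable(-1, 2, 3, 4)


class TestBonferroni:
    @pytest.mark.parametrize(
        "p,m,expected",
        [
            (7.81e-04, 10, 7.81e-03),
            (4.69e-04, 10, 4.69e-03),
            (5.36e-03, 10, 5.36e-02),
            (0.5, 3, 1.0),
        ],
    )
    def test_values(self, p, m, expected):
        assert bonferroni_correct(p, m) == pytest.approx(expected, rel=1e-9)

    @given(
        p=st.floats(0, 1, allow_nan=False),
        m1=st.integers(1, 50),
        m2=st.integers(1, 50),
    )
    @settings(derandomize=True, max_examples=200)
    def test_monotone_and_capped(self, p, m1, m2):
        lo, hi = sorted((m1, m2))
        assert bonferroni_correct(p, lo) <= bonferroni_correct(p, hi) <= 1.0
        assert bonferroni_correct(p, lo) >= p


def make_record(pos, case_ac, gene="G1", fclass="missense", n_case_pools=4, cadd=None):
    """Record with the given total case alt count spread over pools."""
    pools = []
    remaining = case_ac
    for i in range(n_case_pools):
        take = min(remaining, 20)
        remaining -= take
        reads = min(2 * take + 4, 200)
        pools.append(
            PoolObservation(
                pool_id=f"CASE{i:03d}",
                alt_count=take,
                depth=250,
                gq=99,
                fwd_alt=reads // 2,
                rev_alt=reads - reads // 2,
            )
        )
    assert remaining == 0
    return VariantRecord(
        key=VariantKey("chr1", pos, "C", "A"),
        pools=pools,
        gene=gene,
        functional_class=fclass,
        cadd_phred=cadd,
    )


class TestAggregateGeneTable:
    def test_single_variant_matches_per_variant_table(self):
        rec = make_record(100, 6)
        panel = ReferencePanel("p", 60000, {rec.key: (4, 120000)})
        table, m = aggregate_gene_table([rec], 830, panel)
        assert (table.cells, m) == ((6, 1654, 4, 119996), 1)

    def test_additivity(self):
        recs = [make_record(100, 6), make_record(200, 6)]
        panel = ReferencePanel(
            "p", 60000, {r.key: (4, 120000) for r in recs}
        )
        table, m = aggregate_gene_table(recs, 830, panel)
        assert (table.cells, m) == ((12, 3308, 8, 239992), 2)

    def test_partition_additivity(self):
        recs = [make_record(100 * i, i) for i in range(1, 6)]
        panel = ReferencePanel(
            "p", 60000, {r.key: (i, 120000) for i, r in enumerate(recs)}
        )
        whole, _ = aggregate_gene_table(recs, 830, panel)
        part1, _ = aggregate_gene_table(recs[:2], 830, panel)
        part2, _ = aggregate_gene_table(recs[2:], 830, panel)
        assert whole.cells == tuple(
            x + y for x, y in zip(part1.cells, part2.cells)
        )

    def test_missing_entry_contributes_full_an(self):
        rec = make_record(100, 3)
        panel = ReferencePanel("spanish", 1579, {})
        table, m = aggregate_gene_table([rec], 830, panel)
        assert (table.c, table.d) == (0, 3158)

    def test_empty_gene_rejected(self):
        with pytest.raises(ValidationError):
            aggregate_gene_table([], 830, ReferencePanel("p", 100, {}))


class TestGeneBurdenModel:
    def make_panels(self, records, spanish_described=None):
        spanish_described = spanish_described or set()
        global_freqs = {r.key: (4, 121412) for r in records}
        spanish_freqs = {
            r.key: (2, 3158) for r in records if r.key in spanish_described
        }
        return {
            "global": ReferencePanel("global", 60706, global_freqs),
            "spanish": ReferencePanel("spanish", 1579, spanish_freqs),
        }

    def test_single_variant_gene_matches_per_variant_result(self):
        rec = make_record(100, 6)
        panels = self.make_panels([rec], spanish_described={rec.key})
        results = run_burden_analysis([rec], panels, 830)
        row = results.gene_panel("G1", "global")
        expected = variant_odds_ratio(6, 1660, 4, 121412)
        assert row["m"] == 1
        assert row["odds_ratio"] == pytest.approx(expected.or_point)
        assert row["p_value"] == pytest.approx(expected.p)
        assert row["p_corrected"] == pytest.approx(expected.p)

    def test_bonferroni_uses_gene_variant_count(self):
        recs = [make_record(100 * (i + 1), 2) for i in range(5)]
        panels = self.make_panels(recs)
        results = run_burden_analysis(recs, panels, 830)
        row = results.gene_panel("G1", "global")
        assert row["m"] == 5
        assert row["p_corrected"] == pytest.approx(
            min(1.0, 5 * row["p_value"])
        )

    def test_percent_retained_bookkeeping(self):
        """15 variants, 6 of them missense and described in the Spanish
        panel: the restricted analysis retains 40%."""
        recs = []
        for i in range(7):
            recs.append(make_record(100 + i, 2, fclass="missense"))
        for i in range(8):
            recs.append(make_record(200 + i, 2, fclass="synonymous"))
        described = {r.key for r in recs[:6]}  # 6 of the 7 missense
        panels = self.make_panels(recs, spanish_described=described)
        results = run_burden_analysis(
            recs, panels, 830, restrict_to_described_missense=True
        )
        row = results.gene_panel("G1", "spanish")
        assert row["m"] == 6
        assert row["m_unrestricted"] == 15
        assert row["percent_retained"] == pytest.approx(40.0)

    def test_restriction_requires_spanish_panel(self):
        rec = make_record(100, 2)
        panels = {"global": ReferencePanel("global", 60706, {rec.key: (4, 121412)})}
        model = GeneBurdenModel([rec], panels, 830)
        with pytest.raises(ConfigurationError, match="global"):
            model.fit(restrict_to_described_missense=True)

    def test_summary_renders(self):
        rec = make_record(100, 6)
        panels = self.make_panels([rec], spanish_described={rec.key})
        text = run_burden_analysis([rec], panels, 830).summary()
        assert "G1" in text and "P corrected" in text


class TestPrioritizeRareVariants:
    def make_panels(self, freqs):
        return {"global": ReferencePanel("global", 60706, freqs)}

    def test_rare_retained_common_removed(self):
        rare = make_record(100, 8, cadd=35.0)
        common = make_record(200, 8, cadd=20.0)
        panels = self.make_panels(
            {
                rare.key: (int(0.0005 * 121412), 121412),
                common.key: (int(0.01 * 121412), 121412),
            }
        )
        frame = prioritize_rare_variants([rare, common], 830, panels)
        assert list(frame["pos"]) == [100]
        assert frame.iloc[0]["cohort_maf"] == pytest.approx(8 / 1660)

    def test_cadd_ranking_and_missing_last(self):
        high = make_record(100, 2, cadd=35.0)
        low = make_record(200, 2, cadd=22.1)
        missing = make_record(300, 2, cadd=None)
        frame = prioritize_rare_variants(
            [low, missing, high], 830, self.make_panels({})
        )
        assert list(frame["pos"]) == [100, 200, 300]
        assert bool(frame.iloc[0]["novel"]) is True

    def test_cadd_cut_truncates(self):
        high = make_record(100, 2, cadd=35.0)
        low = make_record(200, 2, cadd=10.0)
        frame = prioritize_rare_variants(
            [high, low], 830, self.make_panels({}), cadd_cut=20.0
        )
        assert list(frame["pos"]) == [100]

    def test_empty_input(self):
        assert prioritize_rare_variants([], 830, self.make_panels({})).empty
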