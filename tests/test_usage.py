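"""Splice-site usage: windows, the USS statistic, screen and enrichment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from lariatuss import usage as us
from lariatuss.annotation import ACCEPTOR, DONOR, GeneModel, SpliceSite


class TestSiteWindows:
    def _gene(self, strand="+"):
        # exon [0,100) | intron [100,300) | exon [300,400)
        return GeneModel("g", "c", strand, {"t": [(0, 100), (300, 400)]})

    def test_plus_donor_abutting_forty_mers(self):
        g = self._gene()
        exonic, intronic, short = us.site_windows(SpliceSite("c", "+", 100, DONOR), [g])
        assert exonic == (60, 100) and intronic == (100, 140)
        assert not short

    def test_short_intron_truncated_and_flagged(self):
        g = GeneModel("g", "c", "+", {"t": [(0, 100), (130, 230)]})  # 30-nt intron
        exonic, intronic, short = us.site_windows(SpliceSite("c", "+", 100, DONOR), [g])
        assert intronic == (100, 130)
        assert exonic == (60, 100)
        assert short

    def test_minus_donor_exon_window_right_of_boundary(self):
        g = self._gene("-")
        donor = SpliceSite("c", "-", 299, DONOR)
        exonic, intronic, short = us.site_windows(donor, [g])
        assert exonic == (300, 340)  # genomically right of the boundary
        assert intronic == (260, 300)
        assert not short

    def test_unknown_site_raises(self):
        with pytest.raises(LookupError):
            us.site_windows(SpliceSite("c", "+", 55, DONOR), [self._gene()])


class TestComputeUss:
    @pytest.mark.parametrize("a,b,expected", [(100, 0, 1.0), (50, 50, 0.5), (90, 10, 0.9)])
    def test_exonic_share_values(self, a, b, expected):
        assert us.compute_uss(a, b) == pytest.approx(expected)

    def test_undefined_and_invalid(self):
        assert us.compute_uss(0, 0) is None
        with pytest.raises(ValueError):
            us.compute_uss(-1, 2)
        with pytest.raises(ValueError):
            us.compute_uss(1, 2, formula="nope")

    def test_alternative_formula(self):
        assert us.compute_uss(100, 0, "one_minus_ratio") == 1.0
        assert us.compute_uss(100, 50, "one_minus_ratio") == pytest.approx(0.5)
        assert us.compute_uss(10, 100, "one_minus_ratio") == 0.0  # clipped
        assert us.compute_uss(0, 5, "one_minus_ratio") is None

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(a=hst.integers(1, 10_000), b=hst.integers(0, 10_000))
    def test_bounded_and_decreasing_in_intronic_count(self, a, b):
        u = us.compute_uss(a, b)
        assert 0.0 <= u <= 1.0
        assert us.compute_uss(a, b + 1) < u or u == us.compute_uss(a, b + 1) == 0.0

    def test_formula_inversion_roundtrip(self):
        for formula in us.USS_FORMULAS:
            for u in (0.0, 0.3, 0.9, 1.0):
                a, b = us.expected_counts_for_uss(u, 1000.0, formula)
                assert us.compute_uss(a, b, formula) == pytest.approx(u)


def _wcounts(rows):
    return pd.DataFrame(
        rows, columns=["site_id", "sample", "condition", "exonic_count", "intronic_count"]
    )


class TestDifferentialUss:
    def test_identical_counts_not_significant(self):
        tab = us.differential_uss(
            _wcounts([("s", "c1", "control", 500, 500), ("s", "m1", "mutant", 500, 500)])
        )
        assert tab.iloc[0]["delta_uss"] == 0.0
        assert not tab.iloc[0]["significant"]

    def test_planted_shift_detected_with_both_flags(self):
        tab = us.differential_uss(
            _wcounts([("s", "c1", "control", 900, 100), ("s", "m1", "mutant", 700, 300)])
        )
        row = tab.iloc[0]
        assert row["delta_uss"] == pytest.approx(-0.20)
        assert row["significant"] and row["significant_raw_p"]

    def test_tiny_delta_fails_threshold_despite_tiny_p(self):
        tab = us.differential_uss(
            _wcounts(
                [
                    ("s", "c1", "control", 900_000, 100_000),
                    ("s", "m1", "mutant", 895_000, 105_000),
                ]
            )
        )
        row = tab.iloc[0]
        assert row["p_value"] < 1e-6
        assert abs(row["delta_uss"]) < 0.01
        assert not row["significant"] and not row["significant_raw_p"]

    def test_undefined_usage_untestable(self):
        tab = us.differential_uss(
            _wcounts([("s", "c1", "control", 0, 0), ("s", "m1", "mutant", 10, 10)])
        )
        assert not tab.iloc[0]["testable"]
        assert np.isnan(tab.iloc[0]["p_value"])


class TestEnrichment:
    def test_no_usage_changes_means_no_enrichment(self, toy, toy_counts):
        _, _, truth = toy
        ec, _, wc = toy_counts
        from lariatuss import events as ev

        psi_table = ev.differential_psi(ec, truth.events)
        uss_table = us.differential_uss(wc)
        uss_table["significant"] = False
        res = us.uss_event_enrichment(uss_table, truth.events, psi_table)
        assert not res["significant"].any()

    def test_planted_ri_donor_changes_enrich_only_ri_donors(self):
        from lariatuss import events as ev
        from lariatuss import simulate as sim

        _, models, truth = sim.make_toy_genome(
            120, seed=77, uss_change_strategy="ri_donors"
        )
        ec, _, wc = sim.simulate_counts(truth, seed=78)
        psi_table = ev.differential_psi(ec, truth.events)
        uss_table = us.differential_uss(wc)
        res = us.uss_event_enrichment(uss_table, truth.events, psi_table)
        ri_donor = res[(res["event_type"] == "RI") & (res["site_kind"] == DONOR)].iloc[0]
        assert ri_donor["odds_ratio"] > 1 and ri_donor["significant"]
        others = res[res["event_type"] != "RI"]
        assert not others["significant"].any()

    def test_independent_random_flags_give_odds_near_one(self, rng):
        # pure 2x2 sampling under independence, no planted structure
        ors = []
        for _ in range(30):
            flags_a = rng.random(400) < 0.3
            flags_b = rng.random(400) < 0.3
            n11 = int((flags_a & flags_b).sum())
            n10 = int((flags_a & ~flags_b).sum())
            n01 = int((~flags_a & flags_b).sum())
            n00 = int((~flags_a & ~flags_b).sum())
            from lariatuss.stats import fisher_exact_2x2

            _, oddsr = fisher_exact_2x2(n11, n10, n01, n00)
            ors.append(oddsr[0])
        assert 0.6 < np.median(ors) < 1.7
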