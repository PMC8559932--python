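"""Event extraction patterns, PSI arithmetic and the differential screen."""

import numpy as np
import pandas as pd
import pytest

from lariatuss import events as ev
from lariatuss.annotation import GeneModel


def _gene(strand, t1, t2):
    return GeneModel("g", "c", strand, {"t1": t1, "t2": t2})


class TestExtractEvents:
    def test_cassette_exon(self):
        g = _gene("+", [(0, 10), (20, 30), (40, 50)], [(0, 10), (40, 50)])
        (e,) = ev.extract_events([g])
        assert e.type == "SE"
        assert e.coords == (10, 20, 30, 40)
        assert len(e.inclusion_junctions) == 2 and len(e.skipping_junctions) == 1

    def test_retained_intron(self):
        g = _gene("+", [(0, 10), (20, 30)], [(0, 30)])
        (e,) = ev.extract_events([g])
        assert e.type == "RI"
        assert e.coords == (10, 20)
        assert e.distance() == 10
        (ret,) = e.inclusion_junctions
        assert "^" in ret  # retention evidence, not a spliced junction

    @pytest.mark.parametrize(
        "strand,expected_type",
        [("+", "A5SS"), ("-", "A3SS")],
    )
    def test_alternative_left_edge_maps_by_strand(self, strand, expected_type):
        # two donors (plus strand) 6 nt apart sharing one acceptor
        g = _gene(strand, [(0, 16), (30, 40)], [(0, 10), (30, 40)])
        (e,) = ev.extract_events([g])
        assert e.type == expected_type
        assert e.coords == (10, 16, 30)
        assert e.distance() == 6

    @pytest.mark.parametrize(
        "strand,expected_type",
        [("+", "A3SS"), ("-", "A5SS")],
    )
    def test_alternative_right_edge_maps_by_strand(self, strand, expected_type):
        g = _gene(strand, [(0, 10), (18, 40)], [(0, 10), (30, 40)])
        (e,) = ev.extract_events([g])
        assert e.type == expected_type
        assert e.distance() == 12

    def test_mutually_exclusive_exons(self):
        g = _gene("+", [(0, 10), (20, 30), (60, 70)], [(0, 10), (40, 50), (60, 70)])
        (e,) = ev.extract_events([g])
        assert e.type == "MXE"
        assert e.coords == (10, 20, 30, 40, 50, 60)

    def test_single_isoform_gene_yields_nothing(self):
        g = GeneModel("g", "c", "+", {"t1": [(0, 10), (20, 30)]})
        assert ev.extract_events([g]) == []

    def test_events_deduplicated_across_isoform_pairs(self):
        g = GeneModel(
            "g",
            "c",
            "+",
            {
                "t1": [(0, 10), (20, 30), (40, 50)],
                "t2": [(0, 10), (40, 50)],
                "t3": [(0, 10), (40, 50), (60, 70)],  # shares the skip form
            },
        )
        events = ev.extract_events([g])
        assert [e.type for e in events].count("SE") == 1


class TestComputePsi:
    @pytest.mark.parametrize(
        "inc,skp,expected",
        [(10, 0, 1.0), (0, 7, 0.0), (30, 10, 0.75)],
    )
    def test_arithmetic(self, inc, skp, expected):
        g = _gene("+", [(0, 10), (20, 30)], [(0, 30)])
        (e,) = ev.extract_events([g])
        counts = {next(iter(e.inclusion_junctions)): inc, next(iter(e.skipping_junctions)): skp}
        psi, support = ev.compute_psi(e, counts)
        assert psi == pytest.approx(expected)
        assert support == inc + skp

    def test_undefined_when_no_reads(self):
        g = _gene("+", [(0, 10), (20, 30)], [(0, 30)])
        (e,) = ev.extract_events([g])
        assert ev.compute_psi(e, {}) == (None, 0)


def _counts(rows):
    return pd.DataFrame(rows, columns=["event_id", "sample", "condition", "inclusion", "skipping"])


class TestDifferentialPsi:
    def test_identical_counts_not_significant(self):
        tab = ev.differential_psi(
            _counts([("e", "c1", "control", 50, 50), ("e", "m1", "mutant", 50, 50)])
        )
        row = tab.iloc[0]
        assert row["delta_psi"] == 0.0
        assert not row["significant"]

    def test_planted_shift_detected(self):
        tab = ev.differential_psi(
            _counts([("e", "c1", "control", 500, 500), ("e", "m1", "mutant", 700, 300)])
        )
        row = tab.iloc[0]
        assert row["delta_psi"] == pytest.approx(0.20)
        assert row["p_value"] < 1e-6
        assert row["significant"]

    def test_supporting_reads_threshold_boundary(self):
        tab = ev.differential_psi(
            _counts(
                [
                    ("hi", "c1", "control", 6, 4),
                    ("hi", "m1", "mutant", 4, 6),
                    ("lo", "c1", "control", 2, 1),
                    ("lo", "m1", "mutant", 1, 2),
                ]
            )
        )
        by_id = tab.set_index("event_id")
        assert by_id.loc["hi", "supporting_reads"] == 10
        assert not np.isnan(by_id.loc["hi", "p_value"])  # tested
        assert by_id.loc["lo", "supporting_reads"] == 3  # below the >=5 default
        assert not by_id.loc["lo", "significant"]

    def test_zero_counts_in_one_condition_untestable(self):
        tab = ev.differential_psi(
            _counts([("e", "c1", "control", 0, 0), ("e", "m1", "mutant", 10, 10)])
        )
        row = tab.iloc[0]
        assert not row["testable"]
        assert np.isnan(row["p_value"]) and np.isnan(row["fdr"])

    def test_unknown_condition_label_rejected(self):
        with pytest.raises(ValueError, match="condition"):
            ev.differential_psi(_counts([("e", "s", "weird", 1, 1)]))

    def test_psi_and_delta_bounds_on_simulated_screen(self, toy, toy_counts):
        _, _, truth = toy
        ec, _, _ = toy_counts
        tab = ev.differential_psi(ec, truth.events)
        defined = tab.dropna(subset=["psi_control", "psi_mutant"])
        assert defined["psi_control"].between(0, 1).all()
        assert defined["psi_mutant"].between(0, 1).all()
        assert defined["delta_psi"].between(-1, 1).all()
        assert (tab["fdr"].dropna() >= tab["p_value"].dropna() - 1e-15).all()


class TestDistanceDistribution:
    def test_distance_definitions(self):
        ri = _gene("+", [(0, 10), (74, 90)], [(0, 90)])  # 64-nt intron
        (e_ri,) = ev.extract_events([ri])
        assert e_ri.distance() == 64
        a3 = _gene("+", [(0, 10), (20, 40)], [(0, 10), (32, 40)])  # acceptors 12 apart
        (e_a3,) = ev.extract_events([a3])
        assert e_a3.type == "A3SS" and e_a3.distance() == 12

    def test_direction_filter_and_histogram(self):
        ri = _gene("+", [(0, 10), (74, 90)], [(0, 90)])
        (e,) = ev.extract_events([ri])
        psi_table = pd.DataFrame(
            {"event_id": [e.event_id], "delta_psi": [0.3], "significant": [True]}
        )
        dist_df, hists = ev.distance_distribution(psi_table, [e], direction="increased")
        assert list(dist_df["distance"]) == [64]
        edges, counts = hists["RI"]
        assert counts.sum() == 1
        dist_df, _ = ev.distance_distribution(psi_table, [e], direction="decreased")
        assert dist_df.empty
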