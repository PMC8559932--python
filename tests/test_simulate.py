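"""The synthetic-data generator: determinism, truth consistency, file validity."""

import numpy as np
import pandas as pd
import pytest

from lariatuss import annotation as an
from lariatuss import events as ev
from lariatuss import lariat as lb
from lariatuss import simulate as sim


class TestMakeToyGenome:
    def test_identical_seed_gives_byte_identical_files(self, tmp_path):
        for d in ("a", "b"):
            genome, models, truth = sim.make_toy_genome(10, seed=42)
            (tmp_path / d).mkdir()
            an.write_fasta(genome, tmp_path / d / "g.fa")
            an.write_gtf(models, tmp_path / d / "a.gtf")
            truth.to_json(tmp_path / d / "t.json")
        for name in ("g.fa", "a.gtf", "t.json"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_bad_event_mix_rejected(self):
        with pytest.raises(sim.ConfigError, match="sum"):
            sim.make_toy_genome(3, event_mix={"RI": 0.5, "SE": 0.4}, seed=0)
        with pytest.raises(sim.ConfigError, match="unknown"):
            sim.make_toy_genome(3, event_mix={"XX": 1.0}, seed=0)

    def test_all_ri_mix_builds_retention_isoform_pairs(self):
        _, models, truth = sim.make_toy_genome(5, event_mix={"RI": 1.0}, seed=3)
        assert len(models) == 5
        assert set(truth.events_df["type"]) == {"RI"}
        for gene in models:
            n_exons = sorted(len(x) for x in gene.transcripts.values())
            assert n_exons == [1, 2]  # retained single exon vs spliced pair

    def test_truth_event_set_equals_extracted_event_set(self, toy):
        _, models, truth = toy
        recovered = ev.extract_events(models)
        key = lambda e: (e.type, e.chrom, e.strand, e.coords, e.inclusion_junctions, e.skipping_junctions)
        assert {key(e) for e in truth.events} == {key(e) for e in recovered}

    def test_a3ss_distance_rederivable_from_gtf(self, tmp_path):
        _, models, truth = sim.make_toy_genome(12, event_mix={"A3SS": 1.0}, seed=9)
        gtf = tmp_path / "a.gtf"
        an.write_gtf(models, gtf)
        reloaded = {g.gene_id: g for g in an.load_annotation(gtf)}
        for _, row in truth.events_df.iterrows():
            gene = reloaded[row["gene_id"]]
            accs = {
                s.boundary
                for s in an.enumerate_splice_sites([gene])
                if s.kind == an.ACCEPTOR
            }
            assert len(accs) == 2
            assert abs(max(accs) - min(accs)) == row["distance"]

    def test_generated_files_validate_against_loader(self, tmp_path, toy):
        genome, models, _ = toy
        an.write_fasta(genome, tmp_path / "g.fa")
        an.write_gtf(models, tmp_path / "a.gtf")
        loaded = an.load_annotation(tmp_path / "a.gtf", genome=an.read_fasta(tmp_path / "g.fa"))
        assert len(loaded) == len(models)


class TestSimulateCounts:
    def test_psi_one_means_no_skipping_reads(self, toy):
        _, _, truth = toy
        t = sim.SyntheticTruth(
            truth.seed,
            truth.events,
            truth.events_df.assign(psi_control=1.0, psi_mutant=1.0),
            truth.sites_df,
            params=truth.params,
        )
        ec, jc, _ = sim.simulate_counts(t, depth=50, n_replicates=2, seed=5)
        assert (ec["skipping"] == 0).all()

    def test_uss_one_means_no_intronic_coverage(self, toy):
        _, _, truth = toy
        t = sim.SyntheticTruth(
            truth.seed,
            truth.events,
            truth.events_df,
            truth.sites_df.assign(uss_control=1.0, uss_mutant=1.0),
            params=truth.params,
        )
        _, _, wc = sim.simulate_counts(t, seed=5)
        assert (wc["intronic_count"] == 0).all()

    def test_deep_counts_recover_psi(self, toy):
        _, _, truth = toy
        t = sim.SyntheticTruth(
            truth.seed,
            truth.events,
            truth.events_df.assign(psi_control=0.75, psi_mutant=0.75),
            truth.sites_df,
            params=truth.params,
        )
        ec, _, _ = sim.simulate_counts(t, depth=10_000, n_replicates=1, seed=6)
        psi_hat = ec["inclusion"] / (ec["inclusion"] + ec["skipping"])
        assert np.abs(psi_hat - 0.75).max() < 0.02  # binomial SE < 0.005 at this depth

    def test_junction_sums_reproduce_event_counts(self, toy_counts, toy):
        _, _, truth = toy
        ec, jc, _ = toy_counts
        events = {e.event_id: e for e in truth.events}
        for (sample, _), grp in jc.groupby(["sample", "condition"]):
            counts = dict(zip(grp["junction"], grp["count"]))
            sub = ec[ec["sample"] == sample].set_index("event_id")
            for eid, event in events.items():
                inc = sum(counts.get(k, 0) for k in event.inclusion_junctions)
                skp = sum(counts.get(k, 0) for k in event.skipping_junctions)
                assert inc == sub.loc[eid, "inclusion"]
                assert skp == sub.loc[eid, "skipping"]


class TestSimulateLariatReads:
    def test_error_free_single_bp_reads_share_the_junction(self, toy_intron):
        rs, truth = sim.simulate_lariat_reads(
            toy_intron, {-9: 1.0}, n_clones=12, a2t_rate=0.0, error_rate=0.0,
            rc_fraction=0.0, l1_range=(8, 8), l2_range=(8, 8), seed=1,
        )
        assert len(rs.reads) == 12
        j = toy_intron.offset_to_index(-9)
        expected = toy_intron.sequence[j - 7 : j + 1] + toy_intron.sequence[:8]
        assert all(seq == expected for _, seq in rs.reads)

    def test_a2t_rate_one_mutates_every_branch_adenosine(self, toy_intron):
        rs, _ = sim.simulate_lariat_reads(
            toy_intron, {-9: 1.0}, n_clones=20, a2t_rate=1.0, error_rate=0.0,
            rc_fraction=0.0, l1_range=(10, 10), l2_range=(8, 8), seed=2,
        )
        assert toy_intron.base_at(-9) == "A"
        assert all(seq[9] == "T" for _, seq in rs.reads)  # last pre-jump base

    def test_bp_freq_validation(self, toy_intron):
        with pytest.raises(sim.ConfigError, match="sum"):
            sim.simulate_lariat_reads(toy_intron, {-9: 0.5}, seed=0)
        with pytest.raises(sim.ConfigError, match="min_anchor"):
            sim.simulate_lariat_reads(toy_intron, {-2: 1.0}, seed=0)

    def test_sampled_fractions_match_truth(self, rng):
        intron = lb.IntronRef("i", sim.random_intron(rng, 90))
        _, truth = sim.simulate_lariat_reads(
            intron, {-25: 0.6, -54: 0.4}, n_clones=10_000, seed=13
        )
        frac = (truth["bp_offset"] == -25).mean()
        assert frac == pytest.approx(0.6, abs=0.02)  # multinomial sampling bound

    def test_determinism(self, toy_intron):
        a, ta = sim.simulate_lariat_reads(toy_intron, {-9: 1.0}, n_clones=30, seed=9)
        b, tb = sim.simulate_lariat_reads(toy_intron, {-9: 1.0}, n_clones=30, seed=9)
        assert a.reads == b.reads
        pd.testing.assert_frame_equal(ta, tb)
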