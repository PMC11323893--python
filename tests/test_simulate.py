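"""Synthetic-cohort generators: determinism, truth bookkeeping, and the
statistical properties the downstream stages rely on."""

import numpy as np
import pytest

from phagesv import simulate
from phagesv.model import SVType


class TestGenomes:
    def test_fixed_lengths_and_count(self):
        genomes = simulate.gen_phage_genomes(3, 10_000, 10_000, 0.5, seed=1)
        assert len(genomes) == 3
        assert all(g.length == 10_000 for g in genomes)

    def test_same_seed_gives_identical_output(self):
        a = simulate.gen_phage_genomes(3, 5_000, 9_000, 0.45, seed=7)
        b = simulate.gen_phage_genomes(3, 5_000, 9_000, 0.45, seed=7)
        assert [(g.genome_id, g.sequence) for g in a] == \
            [(g.genome_id, g.sequence) for g in b]

    def test_observed_gc_concentrates_at_target(self):
        genomes = simulate.gen_phage_genomes(10, 100_000, 100_000, 0.6, seed=2)
        seq = "".join(g.sequence for g in genomes)
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert 0.59 <= gc <= 0.61   # binomial sd at 1 Mb ~ 0.0005

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            simulate.gen_phage_genomes(0, 100, 100, 0.5)
        with pytest.raises(ValueError):
            simulate.gen_phage_genomes(1, 100, 100, 1.5)


class TestImplantSvs:
    def test_length_bookkeeping_per_type(self):
        genomes = simulate.gen_phage_genomes(1, 10_000, 10_000, 0.5, seed=3)
        for svtype, delta in (("DEL", -100), ("INS", +100), ("DUP", +100),
                              ("INV", 0)):
            mutated, truth = simulate.implant_svs(
                genomes, {svtype: 1}, len_dist=(100, 100), seed=4
            )
            assert mutated[0].length == 10_000 + delta
            assert truth[0].svtype == SVType(svtype)

    def test_truth_counts_match_request(self):
        genomes = simulate.gen_phage_genomes(10, 20_000, 20_000, 0.5, seed=5)
        counts = {"INS": 30, "DEL": 30, "DUP": 10, "INV": 10}
        _, truth = simulate.implant_svs(genomes, counts, seed=6)
        observed = {t.value: 0 for t in SVType}
        for rec in truth:
            observed[rec.svtype.value] += 1
        assert observed == counts

    def test_truth_intervals_disjoint_and_inside_margins(self):
        genomes = simulate.gen_phage_genomes(5, 20_000, 20_000, 0.5, seed=7)
        _, truth = simulate.implant_svs(genomes, {"DEL": 40}, seed=8)
        by_genome = {}
        for rec in truth:
            by_genome.setdefault(rec.contig, []).append(rec)
        for gid, records in by_genome.items():
            records.sort(key=lambda r: r.start)
            assert records[0].start >= 100
            assert records[-1].end <= 20_000 - 100
            for a, b in zip(records, records[1:]):
                assert a.end <= b.start

    def test_oversized_request_names_genome(self):
        genomes = simulate.gen_phage_genomes(1, 2_000, 2_000, 0.5, seed=9)
        with pytest.raises(ValueError, match=genomes[0].genome_id):
            simulate.implant_svs(genomes, {"DEL": 50}, len_dist=(500, 900),
                                 seed=10)


class TestCallerSimulation:
    def make_truth(self, n=50):
        genomes = simulate.gen_phage_genomes(10, 20_000, 20_000, 0.5, seed=11)
        _, truth = simulate.implant_svs(genomes, {"DEL": n}, seed=12)
        return truth, {g.genome_id: g.length for g in genomes}

    def test_degenerate_profile_reproduces_truth(self):
        truth, lengths = self.make_truth()
        profile = simulate.CallerProfile(
            "perfect", pos_jitter_sd=0, len_jitter_frac=0, fn_rate=0,
            fp_rate_per_genome=0,
        )
        callsets = simulate.simulate_caller_vcfs(truth, [profile], lengths,
                                                 seed=13)
        calls = callsets["perfect"]
        assert [(c.contig, c.start, c.length) for c in calls] == \
            [(t.contig, t.start, t.length)
             for t in sorted(truth, key=lambda r: r.record_id)]
        assert all(c.read_support >= 1 for c in calls)

    def test_fn_rate_one_gives_fp_only_callsets(self):
        truth, lengths = self.make_truth()
        profile = simulate.CallerProfile("blind", fn_rate=1.0,
                                         fp_rate_per_genome=0)
        callsets = simulate.simulate_caller_vcfs(truth, [profile], lengths,
                                                 seed=14)
        assert callsets["blind"] == []

    def test_fp_total_within_poisson_interval(self):
        truth, lengths = self.make_truth(n=10)
        profiles = [
            simulate.CallerProfile(f"caller{i}", fn_rate=1.0,
                                   fp_rate_per_genome=2.0)
            for i in range(4)
        ]
        total = 0
        for s in range(5):
            callsets = simulate.simulate_caller_vcfs(
                truth, profiles, lengths, seed=100 + s
            )
            total += sum(len(v) for v in callsets.values())
        lam = 4 * 2.0 * len(lengths) * 5   # callers x rate x genomes x reps
        assert abs(total - lam) <= 3 * np.sqrt(lam)

    def test_false_positives_are_caller_private(self):
        truth, lengths = self.make_truth(n=10)
        callsets = simulate.simulate_caller_vcfs(
            truth, simulate.DEFAULT_PROFILES, lengths, seed=15
        )
        fps = [c for calls in callsets.values() for c in calls
               if "_fp_" in c.record_id]
        for i, a in enumerate(fps):
            for b in fps[i + 1:]:
                if a.caller == b.caller:
                    continue
                assert simulate._reciprocal(a.start, a.length,
                                            b.start, b.length) < 0.8 or \
                    a.contig != b.contig or a.svtype != b.svtype


class TestExchangeSegments:
    def setup_genomes(self):
        phages = simulate.gen_phage_genomes(5, 20_000, 20_000, 0.5, seed=16)
        bacteria = simulate.gen_phage_genomes(
            3, 50_000, 50_000, 0.5, seed=17, prefix="bact", kind="bacterial"
        )
        return phages, bacteria

    def test_zero_substitution_rate_gives_full_identity(self):
        phages, bacteria = self.setup_genomes()
        _, events, hits = simulate.implant_exchange_segments(
            phages, bacteria, 10, subst_rate=0.0, seed=18
        )
        assert all(h.pct_identity == 100.0 for h in hits)
        for event in events:
            donor = next(b for b in bacteria
                         if b.genome_id == event.donor_genome_id)
            assert event.inserted_seq == donor.sequence[
                event.donor_start:event.donor_start + event.donor_len
            ]

    def test_identity_tracks_substitution_rate(self):
        phages, bacteria = self.setup_genomes()
        _, _, hits = simulate.implant_exchange_segments(
            phages, bacteria, 20, seg_len=(1000, 1000), subst_rate=0.10,
            seed=19,
        )
        for h in hits:
            assert abs(h.pct_identity - 90.0) <= 3.0  # ~3 binomial sd

    def test_no_events_leaves_phages_unchanged(self):
        phages, bacteria = self.setup_genomes()
        modified, events, hits = simulate.implant_exchange_segments(
            phages, bacteria, 0, seed=20
        )
        assert events == [] and hits == []
        assert [m.sequence for m in modified] == [p.sequence for p in phages]

    def test_inserted_segment_present_in_recipient(self):
        phages, bacteria = self.setup_genomes()
        modified, events, _ = simulate.implant_exchange_segments(
            phages, bacteria, 5, seed=21
        )
        by_id = {m.genome_id: m.sequence for m in modified}
        for event in events:
            assert event.inserted_seq in by_id[event.recipient_phage_id]


class TestCodonGenes:
    def test_matrix_pair_reaches_total_variation(self):
        t1, t2 = simulate.codon_matrix_pair(seed=22, min_tv=0.3)
        assert simulate.matrix_total_variation(t1, t2) >= 0.3

    def test_non_stochastic_matrix_names_offending_row(self):
        t1, t2 = simulate.codon_matrix_pair(seed=23)
        t1[5] = 0.0
        with pytest.raises(ValueError, match="row"):
            simulate.gen_codon_genes(t1, t2, 1, 1, 30, seed=24)

    def test_no_in_frame_stops_and_labels(self):
        t1, t2 = simulate.codon_matrix_pair(seed=25)
        seqs, labels = simulate.gen_codon_genes(t1, t2, 5, 3, 50, seed=26)
        assert sum(1 for v in labels.values() if v == "native") == 5
        assert sum(1 for v in labels.values() if v == "foreign") == 3
        for seq in seqs.values():
            assert len(seq) == 150
            codons = {seq[i:i + 3] for i in range(0, len(seq), 3)}
            assert codons.isdisjoint({"TAA", "TAG", "TGA"})

    def test_uniform_matrix_gives_uniform_codon_usage(self):
        uniform = np.full((64, 64), 1 / 64)
        seqs, _ = simulate.gen_codon_genes(uniform, uniform, 60, 0, 100,
                                           seed=27)
        counts = {}
        for seq in seqs.values():
            for i in range(0, len(seq), 3):
                counts[seq[i:i + 3]] = counts.get(seq[i:i + 3], 0) + 1
        total = sum(counts.values())
        expected = total / 61
        sd = np.sqrt(total * (1 / 61) * (60 / 61))
        for codon, count in counts.items():
            assert abs(count - expected) <= 4 * sd


class TestHgtTrees:
    def test_pure_trees_have_only_background_leaves(self):
        newicks, truths = simulate.gen_hgt_trees(3, 8, 0, seed=28)
        assert truths == []
        for nwk in newicks:
            assert "V_" not in nwk

    def test_event_counts_match_request(self):
        newicks, truths = simulate.gen_hgt_trees(4, 12, 2, seed=29)
        assert len(truths) == 8
        assert all(t.direction == "B_to_P" for t in truths)

    def test_byte_identical_per_seed(self):
        a, _ = simulate.gen_hgt_trees(3, 10, 1, seed=30)
        b, _ = simulate.gen_hgt_trees(3, 10, 1, seed=30)
        assert a == b

    def test_too_many_events_rejected(self):
        with pytest.raises(ValueError):
            simulate.gen_hgt_trees(1, 6, 4, seed=31)


class TestSpacerLibrary:
    def test_exact_spacers_are_substrings(self):
        phages = simulate.gen_phage_genomes(3, 10_000, 10_000, 0.5, seed=32)
        spacers, truth, _ = simulate.gen_spacer_library(
            phages, 10, mismatches=0, n_decoys=0, seed=33
        )
        seqs = {g.genome_id: g.sequence for g in phages}
        for sid, host in truth.items():
            assert spacers[sid] in seqs[host]

    def test_counts_and_truth_size(self):
        phages = simulate.gen_phage_genomes(3, 10_000, 10_000, 0.5, seed=34)
        spacers, truth, sources = simulate.gen_spacer_library(
            phages, 10, n_decoys=5, seed=35
        )
        assert len(spacers) == 15
        assert len(truth) == 10
        assert set(spacers) == set(sources)

    def test_decoys_have_no_near_match_by_construction(self):
        phages = simulate.gen_phage_genomes(2, 5_000, 5_000, 0.5, seed=36)
        spacers, _, _ = simulate.gen_spacer_library(
            phages, 0, n_decoys=5, seed=37
        )
        for sid, seq in spacers.items():
            for phage in phages:
                assert not simulate._hamming_scan_hit(seq, phage.sequence, 2)


class TestAbundance:
    def test_perfect_coupling_gives_unit_correlation(self):
        mat = simulate.gen_abundance_matrix(
            20, [("p", "g")], sigma=1.0, coupling_rho=1.0, seed=38
        )
        r = np.corrcoef(mat.row("p"), mat.row("g"))[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_null_coupling_mean_r_is_small(self):
        pairs = [(f"p{i}", f"g{i}") for i in range(100)]
        mat = simulate.gen_abundance_matrix(
            91, pairs, coupling_rho=0.0, seed=39
        )
        rs = [abs(np.corrcoef(mat.row(a), mat.row(b))[0, 1]) for a, b in pairs]
        assert np.mean(rs) < 0.12   # null |r| mean ~ 0.084 at n=91

    def test_values_positive_and_shape(self):
        mat = simulate.gen_abundance_matrix(
            5, [("a", "b")], uncoupled_rows=["c"], seed=40
        )
        assert (mat.values > 0).all()
        assert mat.values.shape == (3, 5)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            simulate.gen_abundance_matrix(2, [("a", "b")])
        with pytest.raises(ValueError):
            simulate.gen_abundance_matrix(5, [("a", "b")], coupling_rho=1.5)
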