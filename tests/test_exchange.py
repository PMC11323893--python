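"""GE-like classification, HT index, HGT directionality and spacers."""

import math
import random

import numpy as np
import pytest

from oracles import hamming_scan
from phagesv import exchange, io, simulate
from phagesv.model import AlignmentHit, TaxonLineage


def hit(query, subject="bactA", identity=90.0, alnlen=900, **kw):
    return AlignmentHit(query_id=query, subject_id=subject,
                        pct_identity=identity, aln_length=alnlen, **kw)


class TestGEClassification:
    def test_threshold_rule(self):
        lengths = {"sv1": 1000, "sv2": 150, "sv3": 1000}
        hits = [
            hit("sv1", identity=85.0, alnlen=850),   # cov 0.85 -> GE_like
            hit("sv2", identity=100.0, alnlen=150),  # too short regardless
            hit("sv3", identity=79.0, alnlen=1000),  # identity below cut
        ]
        cls = exchange.classify_ge_svs(lengths, hits)
        assert cls["sv1"].label == "GE_like"
        assert cls["sv2"].label == "too_short"
        assert cls["sv3"].label == "noGE_like"

    def test_coverage_is_relative_to_sv_length(self):
        lengths = {"sv": 1000}
        cls = exchange.classify_ge_svs(lengths, [hit("sv", alnlen=800)])
        assert cls["sv"].label == "noGE_like"   # 0.8 not > 0.8
        cls = exchange.classify_ge_svs(lengths, [hit("sv", alnlen=801)])
        assert cls["sv"].label == "GE_like"

    def test_best_hit_maximizes_identity_times_coverage(self):
        lengths = {"sv": 1000}
        hits = [
            hit("sv", subject="g1", identity=82.0, alnlen=1000),
            hit("sv", subject="g2", identity=95.0, alnlen=900),
        ]
        cls = exchange.classify_ge_svs(lengths, hits)
        assert cls["sv"].best_hit.subject_id == "g2"
        assert cls["sv"].matched_genomes == {"g1", "g2"}

    def test_unknown_query_warned_and_skipped(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="phagesv.exchange"):
            cls = exchange.classify_ge_svs({"sv": 1000}, [hit("ghost")])
        assert cls["sv"].label == "noGE_like"
        assert len(caplog.records) == 1

    def test_raising_thresholds_is_monotone(self):
        rng = random.Random(3)
        lengths = {f"sv{i}": rng.randrange(200, 2000) for i in range(50)}
        hits = [
            hit(f"sv{i}", identity=rng.uniform(60, 100),
                alnlen=rng.randrange(100, 2000))
            for i in range(50) for _ in range(rng.randrange(3))
        ]
        def ge_set(min_id, min_cov):
            cls = exchange.classify_ge_svs(lengths, hits, min_id=min_id,
                                           min_cov=min_cov)
            return {k for k, v in cls.items() if v.label == "GE_like"}
        base = ge_set(80, 0.8)
        assert ge_set(90, 0.8) <= base
        assert ge_set(80, 0.9) <= base

    def test_prophage_flagging_thresholds(self):
        lengths = {"sv": 1000}
        cls = exchange.classify_ge_svs(lengths, [hit("sv")])
        exchange.flag_prophage_overlap(
            cls, [hit("sv", subject="pp", identity=90.0, alnlen=600)], lengths
        )
        assert cls["sv"].prophage_flag
        cls2 = exchange.classify_ge_svs(lengths, [hit("sv")])
        exchange.flag_prophage_overlap(
            cls2, [hit("sv", subject="pp", identity=90.0, alnlen=400)], lengths
        )
        assert not cls2["sv"].prophage_flag


class TestLcaRange:
    def lineages(self):
        def lin(gid, genus, species):
            return TaxonLineage(gid, {
                "domain": "Bacteria", "phylum": "P", "class": "C",
                "order": "O", "family": "F", "genus": genus,
                "species": species,
            })
        return {
            "g1": lin("g1", "Faecalibacterium", "sp1"),
            "g2": lin("g2", "Faecalibacterium", "sp1"),
            "g3": lin("g3", "Faecalibacterium", "sp2"),
            "g4": TaxonLineage("g4", {"domain": "Archaea"}),
        }

    def test_same_species(self):
        assert exchange.lca_range(["g1", "g2"], self.lineages()) == "species"

    def test_shared_genus_only(self):
        assert exchange.lca_range(["g1", "g3"], self.lineages()) == "genus"

    def test_domain_disagreement_gives_sentinel(self):
        assert exchange.lca_range(["g1", "g4"], self.lineages()) == "none"

    def test_single_genome_reports_deepest_rank(self):
        assert exchange.lca_range(["g1"], self.lineages()) == "species"
        assert exchange.lca_range(["g4"], self.lineages()) == "domain"

    def test_missing_lineage_is_an_error(self):
        with pytest.raises(KeyError, match="ghost"):
            exchange.lca_range(["ghost"], self.lineages())


class TestCodonModel:
    def test_laplace_smoothed_single_transition(self):
        # corpus "AAAAAA": one AAA->AAA transition; with pseudocount 1
        # the AAA row is (1+1)/(64+1) for AAA and 1/65 elsewhere
        model = exchange.train_codon_model({"g": "AAAAAA"})
        aaa = exchange.CODON_INDEX["AAA"]
        assert model.transition[aaa, aaa] == pytest.approx(2 / 65)
        assert model.transition[aaa, aaa + 1] == pytest.approx(1 / 65)

    def test_empty_corpus_gives_uniform_rows(self):
        model = exchange.train_codon_model({})
        assert np.allclose(model.transition, 1 / 64)

    def test_rows_sum_to_one(self, cohort):
        native = {g: s for g, s in cohort.gene_seqs.items()
                  if cohort.gene_labels[g] == "native"}
        model = exchange.train_codon_model(native)
        assert np.allclose(model.transition.sum(axis=1), 1.0, atol=1e-9)

    def test_length_not_divisible_by_three_is_an_error(self):
        with pytest.raises(ValueError, match="badgene"):
            exchange.train_codon_model({"badgene": "AAAAAAA"})

    def test_training_is_gene_order_invariant(self, cohort):
        genes = dict(list(cohort.gene_seqs.items())[:20])
        m1 = exchange.train_codon_model(genes)
        m2 = exchange.train_codon_model(dict(reversed(list(genes.items()))))
        assert np.allclose(m1.transition, m2.transition)


class TestHtIndex:
    def test_uniform_model_scores_minus_six_exactly(self):
        model = exchange.train_codon_model({})
        for gene in ("AAAAAA", "ACGTGCAAA", "TTTCCCGGGAAA"):
            assert exchange.ht_index(gene, model) == -6.0

    def test_repeated_codon_under_half_probability(self):
        transition = np.full((64, 64), 0.5 / 63)
        np.fill_diagonal(transition, 0.5)
        model = exchange.CodonModel(transition=transition,
                                    initial=np.full(64, 1 / 64))
        assert exchange.ht_index("AAA" * 10, model) == pytest.approx(-1.0)

    def test_native_genes_score_above_foreign(self, cohort):
        native = {g: s for g, s in cohort.gene_seqs.items()
                  if cohort.gene_labels[g] == "native"}
        model = exchange.train_codon_model(native)
        ht = exchange.ht_index_table(cohort.gene_seqs, model)
        nat = [v for g, v in ht.items() if cohort.gene_labels[g] == "native"]
        foreign = [v for g, v in ht.items() if cohort.gene_labels[g] == "foreign"]
        assert np.median(foreign) < np.median(nat)


class TestHgtDetection:
    def test_clean_bipartition_has_no_events(self):
        tree = io.parse_newick("((V_1,V_2),(B_1,B_2));")
        assert exchange.detect_hgt_events(tree) == []

    def test_hand_built_nested_clade(self):
        # V_1 with sibling {B_2,B_3} and aunt {B_1}: one B_to_P event
        tree = io.parse_newick("(B_1,(V_1,(B_2,B_3)));")
        (event,) = exchange.detect_hgt_events(tree)
        assert event.direction == "B_to_P"
        assert event.recipient_leaves == frozenset({"V_1"})
        assert event.context_leaves == frozenset({"B_1", "B_2", "B_3"})

    def test_kingdom_pure_tree_has_no_events(self):
        tree = io.parse_newick("((V_1,V_2),(V_3,(V_4,V_5)));")
        assert exchange.detect_hgt_events(tree) == []

    def test_mixed_context_blocks_event(self):
        # sibling of the nested viral clade contains a viral leaf too
        tree = io.parse_newick("(B_1,(V_1,(V_2,B_3)));")
        events = exchange.detect_hgt_events(tree)
        assert all(e.recipient_leaves != frozenset({"V_1"}) for e in events)

    def test_min_support_filters_events(self):
        tree = io.parse_newick("(B_1,(V_1,(B_2,B_3))60);")
        assert exchange.detect_hgt_events(tree, min_support=80) == []
        assert len(exchange.detect_hgt_events(tree, min_support=50)) == 1

    def test_planted_events_recovered_with_direction(self):
        newicks, truths = simulate.gen_hgt_trees(
            30, leaves_per_tree=12, events_per_tree=2, seed=11
        )
        recovered = 0
        for i, nwk in enumerate(newicks):
            tree = io.parse_newick(nwk, tree_id=f"tree_{i:04d}")
            found = exchange.detect_hgt_events(tree)
            for truth in [t for t in truths if t.tree_id == tree.tree_id]:
                if any(f.direction == truth.direction
                       and f.recipient_leaves == truth.recipient_leaf_ids
                       for f in found):
                    recovered += 1
        assert recovered >= 0.95 * len(truths)

    def test_viral_background_gives_p_to_b(self):
        newicks, truths = simulate.gen_hgt_trees(
            5, leaves_per_tree=8, events_per_tree=1, seed=12,
            background_kingdom="viral",
        )
        assert all(t.direction == "P_to_B" for t in truths)
        for i, nwk in enumerate(newicks):
            tree = io.parse_newick(nwk, tree_id=f"tree_{i:04d}")
            assert any(e.direction == "P_to_B"
                       for e in exchange.detect_hgt_events(tree))


class TestSpacerMatching:
    def test_exact_substring_hits_with_zero_mismatches(self):
        genome = "ACGTACGTGGCCTTAACGGATCGATCGATTACA" * 3
        spacer = genome[10:40]
        hits = exchange.match_spacers({"sp": spacer}, {"g": genome})
        assert any(h.mismatches == 0 and h.strand == "+" for h in hits)

    def test_three_mismatches_is_no_hit(self):
        rng = np.random.default_rng(13)
        genome = "".join(rng.choice(list("ACGT"), size=2000))
        spacer = list(genome[100:130])
        for pos in (3, 11, 22):
            spacer[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[spacer[pos]]
        hits = exchange.match_spacers({"sp": "".join(spacer)}, {"g": genome})
        assert all(h.position != 100 for h in hits)

    def test_reverse_complement_found_on_minus_strand(self):
        rng = np.random.default_rng(14)
        genome = "".join(rng.choice(list("ACGT"), size=1000))
        spacer = exchange.revcomp(genome[200:230])
        hits = exchange.match_spacers({"sp": spacer}, {"g": genome})
        assert any(h.strand == "-" and h.position == 200 for h in hits)

    def test_n_counts_as_mismatch(self):
        genome = "A" * 100
        spacer = "A" * 18 + "NNN" + "A" * 9   # 3 N's -> always > 2 mismatches
        assert exchange.match_spacers({"sp": spacer}, {"g": genome}) == []

    @pytest.mark.parametrize("trial", range(10))
    def test_identical_to_brute_force_scan(self, trial):
        rng = np.random.default_rng(400 + trial)
        genome = "".join(rng.choice(list("ACGTN"), size=600,
                                    p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        spacer = "".join(rng.choice(list("ACGT"), size=25))
        got = {
            (h.position, h.strand, h.mismatches)
            for h in exchange.match_spacers({"sp": spacer}, {"g": genome},
                                            min_spacer_len=20)
        }
        assert got == set(hamming_scan(spacer, genome, 2))

    def test_host_table_aggregates_sources(self):
        hits = [
            exchange.SpacerHit("sp1", "phageA", 0, "+", 0, 30),
            exchange.SpacerHit("sp2", "phageA", 5, "+", 1, 30),
            exchange.SpacerHit("sp1", "phageB", 9, "-", 2, 30),
        ]
        table = exchange.host_table(hits, {"sp1": "tax1", "sp2": "tax2"})
        assert table == {"phageA": {"tax1", "tax2"}, "phageB": {"tax1"}}
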