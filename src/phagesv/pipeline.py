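"""End-to-end orchestration: generate a synthetic cohort, run every
pipeline stage on it, and score the results against the cohort's own
ground truth.

The default :class:`CohortConfig` defines the study conditions used
throughout the test-suite: 50 phage genomes across 5 samples, 400
implanted truth SVs, four simulated callers with 5-10 bp positional
jitter, ~10% miss rate and 2 caller-private false positives per genome.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import exchange, io, merge, simulate, sketch, stats
from .benchmark import BenchmarkResult, MatchParams, benchmark as score_callset, match_callsets
from .model import GenomeRecord, Lifestyle, SVCluster, SVRecord, SVType

logger = logging.getLogger(__name__)


@dataclass
class CohortConfig:
    """Generator settings; the defaults are the study conditions."""

    # phage genomes
    n_genomes: int = 50
    genome_len: tuple[int, int] = (15_000, 25_000)
    gc: float = 0.45
    n_unrelated: int = 10          # catalogue decoys the prefilter must drop
    # truth SVs (400 total)
    sv_counts: dict = field(default_factory=lambda: {
        "INS": 120, "DEL": 120, "DUP": 80, "INV": 80,
    })
    sv_len: tuple[int, int] = (100, 1000)
    # samples and callers
    n_samples: int = 5
    profiles: tuple = simulate.DEFAULT_PROFILES
    # bacteria and exchanged segments
    n_bacteria: int = 10
    bacteria_len: tuple[int, int] = (40_000, 60_000)
    n_exchange_events: int = 40
    exchange_seg_len: tuple[int, int] = (300, 1500)
    exchange_subst_rate: float = 0.05
    n_decoy_svs: int = 40
    n_short_svs: int = 5           # <=200 bp entries exercising the length gate
    # codon genes
    codon_tv: float = 0.3
    n_native_genes: int = 50
    n_foreign_genes: int = 50
    gene_len_codons: int = 300
    # trees
    n_hgt_trees: int = 20
    n_pure_trees: int = 10
    leaves_per_tree: int = 12
    events_per_tree: int = 1
    # spacers
    n_true_spacers: int = 30
    n_decoy_spacers: int = 6
    spacer_len: int = 32
    # abundance
    n_abundance_samples: int = 91
    coupling_rho: float = 0.8
    abundance_mu: float = 0.0
    abundance_sigma: float = 0.5
    # lifestyle signal: temperate genomes receive twice the SV shares
    temperate_fraction: float = 0.5
    temperate_weight: int = 2


@dataclass
class Cohort:
    """A fully generated synthetic cohort with its ground truth."""

    config: CohortConfig
    catalogue: list[GenomeRecord]             # reference phage genomes
    unrelated: list[GenomeRecord]             # decoy catalogue genomes
    mutated: list[GenomeRecord]               # sample-side genomes
    truth_svs: list[SVRecord]
    callsets: dict                            # sample -> caller -> records
    bacteria: list[GenomeRecord]
    transfer_events: list
    exchange_hits: list
    prophage_hits: list
    decoy_sv_lengths: dict
    decoy_sv_seqs: dict
    gene_seqs: dict
    gene_labels: dict
    annotations: list
    newicks: list[str]
    planted_hgt: list
    pure_newicks: list[str]
    spacers: dict
    spacer_truth: dict
    spacer_sources: dict
    lineages: dict
    abundance: object
    coupled_pairs: list

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {g.genome_id: g.length for g in self.catalogue}

    def sv_lengths(self) -> dict[str, int]:
        """Lengths of every GE-candidate SV sequence (events + decoys)."""
        lengths = {e.event_id: e.donor_len for e in self.transfer_events}
        lengths.update(self.decoy_sv_lengths)
        return lengths

    def sv_phage(self) -> dict[str, str]:
        return {e.event_id: e.recipient_phage_id for e in self.transfer_events}


def _spawn(seed: int, n: int) -> list[int]:
    """Derive n child seeds below 2**31 from one master seed."""
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def generate_cohort(config: Optional[CohortConfig] = None, seed: int = 0) -> Cohort:
    """Generate every pipeline input from one master seed."""
    cfg = config or CohortConfig()
    seeds = _spawn(seed, 16)

    raw_phages = simulate.gen_phage_genomes(
        cfg.n_genomes, *cfg.genome_len, gc=cfg.gc, seed=seeds[0]
    )
    unrelated = simulate.gen_phage_genomes(
        max(cfg.n_unrelated, 1), *cfg.genome_len, gc=0.5, seed=seeds[1],
        prefix="unrelated",
    )[: cfg.n_unrelated]
    bacteria = simulate.gen_phage_genomes(
        cfg.n_bacteria, *cfg.bacteria_len, gc=0.5, seed=seeds[2],
        prefix="bact", kind="bacterial",
    )
    catalogue, events, ex_hits = simulate.implant_exchange_segments(
        raw_phages, bacteria, cfg.n_exchange_events,
        seg_len=cfg.exchange_seg_len, subst_rate=cfg.exchange_subst_rate,
        seed=seeds[3],
    )

    # lifestyles, biasing SV load toward temperate phages
    rng = np.random.default_rng(seeds[4])
    weights = {}
    for g in catalogue:
        temperate = rng.random() < cfg.temperate_fraction
        g.lifestyle = Lifestyle.temperate if temperate else Lifestyle.virulent
        weights[g.genome_id] = cfg.temperate_weight if temperate else 1

    mutated, truth_svs = simulate.implant_svs(
        catalogue, cfg.sv_counts, len_dist=cfg.sv_len, seed=seeds[5],
        genome_weights=weights,
    )

    sample_seeds = _spawn(seeds[6], cfg.n_samples)
    contig_lengths = {g.genome_id: g.length for g in catalogue}
    callsets = {
        f"sample_{i}": simulate.simulate_caller_vcfs(
            truth_svs, cfg.profiles, contig_lengths,
            seed=sample_seeds[i], sample=f"sample_{i}",
        )
        for i in range(cfg.n_samples)
    }

    # decoy GE candidates: random sequences with no bacterial hit
    rng_d = np.random.default_rng(seeds[7])
    decoy_sv_seqs = {}
    for i in range(cfg.n_decoy_svs):
        length = int(rng_d.integers(*cfg.exchange_seg_len))
        decoy_sv_seqs[f"decoy_{i:04d}"] = simulate._random_seq(rng_d, length)
    for i in range(cfg.n_short_svs):
        length = int(rng_d.integers(60, 200))
        decoy_sv_seqs[f"short_{i:04d}"] = simulate._random_seq(rng_d, length)
    decoy_sv_lengths = {k: len(v) for k, v in decoy_sv_seqs.items()}

    # a couple of events overlap predicted prophage regions
    prophage_hits = [
        io.AlignmentHit(
            query_id=e.event_id, subject_id=f"prophage_of_{e.donor_genome_id}",
            pct_identity=90.0, aln_length=int(0.6 * e.donor_len),
            qstart=1, qend=int(0.6 * e.donor_len), sstart=1,
            send=int(0.6 * e.donor_len),
        )
        for e in events[:2]
    ]

    native_t, foreign_t = simulate.codon_matrix_pair(
        seed=seeds[8], min_tv=cfg.codon_tv
    )
    gene_seqs, gene_labels = simulate.gen_codon_genes(
        native_t, foreign_t, cfg.n_native_genes, cfg.n_foreign_genes,
        cfg.gene_len_codons, seed=seeds[9],
    )

    annotations = simulate.gen_gene_annotations(
        catalogue, truth_svs, seed=seeds[10]
    )

    newicks, planted = simulate.gen_hgt_trees(
        cfg.n_hgt_trees, cfg.leaves_per_tree, cfg.events_per_tree, seed=seeds[11]
    )
    pure_newicks, _ = simulate.gen_hgt_trees(
        cfg.n_pure_trees, cfg.leaves_per_tree, 0, seed=seeds[12]
    )

    spacers, spacer_truth, spacer_sources = simulate.gen_spacer_library(
        catalogue, cfg.n_true_spacers, cfg.spacer_len,
        mismatches=2, n_decoys=cfg.n_decoy_spacers, seed=seeds[13],
    )

    lineages = simulate.gen_lineages(
        [b.genome_id for b in bacteria], seed=seeds[14]
    )
    coupled_pairs = sorted(
        {
            (e.recipient_phage_id, lineages[e.donor_genome_id].ranks["genus"])
            for e in events
        }
    )
    other_rows = [g.genome_id for g in catalogue
                  if g.genome_id not in {p for p, _ in coupled_pairs}]
    abundance = simulate.gen_abundance_matrix(
        cfg.n_abundance_samples, coupled_pairs,
        mu=cfg.abundance_mu, sigma=cfg.abundance_sigma,
        coupling_rho=cfg.coupling_rho, seed=seeds[15],
        uncoupled_rows=other_rows,
    )

    return Cohort(
        config=cfg, catalogue=catalogue, unrelated=unrelated, mutated=mutated,
        truth_svs=truth_svs, callsets=callsets, bacteria=bacteria,
        transfer_events=events, exchange_hits=ex_hits,
        prophage_hits=prophage_hits, decoy_sv_lengths=decoy_sv_lengths,
        decoy_sv_seqs=decoy_sv_seqs,
        gene_seqs=gene_seqs, gene_labels=gene_labels, annotations=annotations,
        newicks=newicks, planted_hgt=planted, pure_newicks=pure_newicks,
        spacers=spacers, spacer_truth=spacer_truth,
        spacer_sources=spacer_sources, lineages=lineages,
        abundance=abundance, coupled_pairs=coupled_pairs,
    )


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Write the cohort as the on-disk formats the CLI stages consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_fasta(cohort.catalogue + cohort.unrelated, outdir / "catalogue.fasta")
    io.write_fasta(cohort.mutated, outdir / "sample_genomes.fasta")
    io.write_fasta(cohort.bacteria, outdir / "bacteria.fasta")
    io.write_sv_vcf(cohort.truth_svs, outdir / "truth.vcf",
                    contig_lengths=cohort.contig_lengths)
    for sample, by_caller in cohort.callsets.items():
        for caller, records in by_caller.items():
            io.write_sv_vcf(records, outdir / f"{sample}.{caller}.vcf",
                            contig_lengths=cohort.contig_lengths)
    io.write_hits(cohort.exchange_hits, outdir / "exchange_hits.tsv")
    io.write_hits(cohort.prophage_hits, outdir / "prophage_hits.tsv")
    io.write_lineages(cohort.lineages.values(), outdir / "lineages.tsv")
    io.write_abundance(cohort.abundance, outdir / "abundance.tsv")
    io.write_fasta(cohort.spacers, outdir / "spacers.fasta")
    io.write_genes(cohort.annotations, outdir / "genes.tsv")
    with open(outdir / "trees.nwk", "w") as fh:
        fh.write("\n".join(cohort.newicks) + "\n")
    with open(outdir / "pure_trees.nwk", "w") as fh:
        fh.write("\n".join(cohort.pure_newicks) + "\n")
    io.write_fasta({g: s for g, s in cohort.gene_seqs.items()},
                   outdir / "codon_genes.fasta")
    sv_candidates = {e.event_id: e.inserted_seq for e in cohort.transfer_events}
    sv_candidates.update(cohort.decoy_sv_seqs)
    io.write_fasta(sv_candidates, outdir / "sv_candidates.fasta")
    import pandas as pd

    pd.DataFrame(
        [{"genome_id": g.genome_id, "lifestyle": g.lifestyle.value}
         for g in cohort.catalogue]
    ).to_csv(outdir / "lifestyles.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"sv_id": e.event_id, "phage_id": e.recipient_phage_id}
         for e in cohort.transfer_events]
    ).to_csv(outdir / "sv_phage.tsv", sep="\t", index=False)


def run_pipeline(
    cohort: Cohort,
    outdir: Optional[str | Path] = None,
    merge_params: merge.MergeParams = merge.MergeParams(),
    match_params: MatchParams = MatchParams(),
) -> dict:
    """Run every stage on a generated cohort and score it against truth.

    Returns a summary dict; when ``outdir`` is given, also writes the
    nonredundant VCF, benchmark JSON, GE classification, HT table, HGT
    events, enrichment table and network edge list there.
    """
    summary: dict = {}
    contig_lengths = cohort.contig_lengths

    # --- prefilter -------------------------------------------------------
    # the sample is sketched per assembled constituent; a catalogue
    # genome is retained when any constituent is within the distance cut
    cat_sketches = {
        g.genome_id: sketch.sketch_sequence(g.sequence)
        for g in cohort.catalogue + cohort.unrelated
    }
    retained_ids: set[str] = set()
    for constituent in cohort.mutated:
        part_sketch = sketch.sketch_sequence(constituent.sequence)
        retained_ids.update(
            gid for gid, _ in sketch.select_references(cat_sketches, part_sketch)
        )
    summary["prefilter_retained"] = len(retained_ids)
    summary["prefilter_true_retained"] = sum(
        1 for g in cohort.catalogue if g.genome_id in retained_ids
    )
    summary["prefilter_decoys_retained"] = sum(
        1 for g in cohort.unrelated if g.genome_id in retained_ids
    )

    # --- per-sample and cohort merging ----------------------------------
    per_sample = {
        sample: merge.merge_sample(by_caller, merge_params, contig_lengths)
        for sample, by_caller in cohort.callsets.items()
    }
    nonredundant = merge.merge_cohort(per_sample, merge_params)
    reps = [cl.representative for cl in nonredundant]
    summary["nonredundant_svs"] = len(nonredundant)
    summary["per_type_counts"] = merge.per_type_counts(nonredundant)

    # --- benchmark against implanted truth ------------------------------
    result = score_callset(cohort.truth_svs, reps, match_params)
    summary["benchmark"] = result.as_dict()

    # merge-specific scoring: recall over truth SVs seen by >=2 callers,
    # and absence of caller-private false positives
    detectable = _detectable_truth(cohort, merge_params)
    matching = match_callsets(cohort.truth_svs, reps, match_params)
    matched_truth = {t.record_id for t, _ in matching}
    summary["merge_recall_detectable"] = (
        len(matched_truth & detectable) / len(detectable) if detectable else 1.0
    )
    summary["merge_precision"] = result.precision

    # --- GE-like classification -----------------------------------------
    sv_lengths = cohort.sv_lengths()
    classifications = exchange.classify_ge_svs(sv_lengths, cohort.exchange_hits)
    exchange.flag_prophage_overlap(
        classifications, cohort.prophage_hits, sv_lengths
    )
    labels = {c.label for c in classifications.values()}
    n_ge = sum(1 for c in classifications.values() if c.label == "GE_like")
    n_long = sum(1 for c in classifications.values() if c.label != "too_short")
    summary["ge_like_count"] = n_ge
    summary["ge_like_fraction"] = n_ge / n_long if n_long else 0.0
    summary["prophage_flagged"] = sum(
        1 for c in classifications.values() if c.prophage_flag
    )
    lca_counts: dict[str, int] = {}
    for cls in classifications.values():
        if cls.label == "GE_like":
            rank = exchange.lca_range(cls.matched_genomes, cohort.lineages)
            lca_counts[rank] = lca_counts.get(rank, 0) + 1
    summary["lca_ranks"] = lca_counts

    # --- HT index --------------------------------------------------------
    native = {g: s for g, s in cohort.gene_seqs.items()
              if cohort.gene_labels[g] == "native"}
    model = exchange.train_codon_model(native)
    ht = exchange.ht_index_table(cohort.gene_seqs, model)
    ht_native = [v for g, v in ht.items() if cohort.gene_labels[g] == "native"]
    ht_foreign = [v for g, v in ht.items() if cohort.gene_labels[g] == "foreign"]
    ht_test = stats.compare_lifestyles(ht_native, ht_foreign)
    summary["ht_median_native"] = float(np.median(ht_native))
    summary["ht_median_foreign"] = float(np.median(ht_foreign))
    summary["ht_separation_p"] = ht_test["p"]

    # --- HGT directionality ----------------------------------------------
    recovered = 0
    planted_by_tree: dict[str, list] = {}
    for ev in cohort.planted_hgt:
        planted_by_tree.setdefault(ev.tree_id, []).append(ev)
    detected_events = []
    for i, nwk in enumerate(cohort.newicks):
        tree = io.parse_newick(nwk, tree_id=f"tree_{i:04d}")
        found = exchange.detect_hgt_events(tree)
        detected_events.extend(found)
        for truth_ev in planted_by_tree.get(tree.tree_id, []):
            if any(
                f.direction == truth_ev.direction
                and f.recipient_leaves == truth_ev.recipient_leaf_ids
                for f in found
            ):
                recovered += 1
    summary["hgt_planted"] = len(cohort.planted_hgt)
    summary["hgt_recovered"] = recovered
    summary["hgt_recovery_rate"] = (
        recovered / len(cohort.planted_hgt) if cohort.planted_hgt else 1.0
    )
    pure_events = 0
    for i, nwk in enumerate(cohort.pure_newicks):
        tree = io.parse_newick(nwk, tree_id=f"pure_{i:04d}")
        pure_events += len(exchange.detect_hgt_events(tree))
    summary["hgt_events_on_pure_trees"] = pure_events

    # --- CRISPR spacers ---------------------------------------------------
    genome_seqs = {g.genome_id: g.sequence for g in cohort.catalogue}
    spacer_hits = exchange.match_spacers(cohort.spacers, genome_seqs)
    hit_pairs = {(h.spacer_id, h.genome_id) for h in spacer_hits}
    n_true_found = sum(
        1 for sid, host in cohort.spacer_truth.items() if (sid, host) in hit_pairs
    )
    decoy_hits = sum(
        1 for h in spacer_hits if h.spacer_id.startswith("spacer_decoy")
    )
    summary["spacer_true_recovered"] = n_true_found
    summary["spacer_truth_total"] = len(cohort.spacer_truth)
    summary["spacer_decoy_hits"] = decoy_hits
    hosts = exchange.host_table(spacer_hits, cohort.spacer_sources)

    # --- cohort statistics ------------------------------------------------
    sv_counts = {g.genome_id: 0 for g in cohort.catalogue}
    for cl in nonredundant:
        sv_counts[cl.representative.contig] += 1
    density = stats.sv_density(
        sv_counts, {g.genome_id: g.length for g in cohort.catalogue}
    )
    temperate = [density[g.genome_id] for g in cohort.catalogue
                 if g.lifestyle is Lifestyle.temperate]
    virulent = [density[g.genome_id] for g in cohort.catalogue
                if g.lifestyle is Lifestyle.virulent]
    lifestyle = stats.compare_lifestyles(temperate, virulent)
    summary["density_median_temperate"] = lifestyle["median_a"]
    summary["density_median_virulent"] = lifestyle["median_b"]
    summary["lifestyle_p"] = lifestyle["p"]

    gene_labels = stats.gene_sv_overlap(cohort.annotations, reps)
    gene_cats = {g.gene_id: g.level2_category for g in cohort.annotations}
    enrichment = stats.functional_enrichment(gene_labels, gene_cats)
    summary["top_enriched_category"] = enrichment[0].category if enrichment else None
    summary["top_enriched_q"] = enrichment[0].q if enrichment else None

    network = stats.build_sharing_network(
        classifications, cohort.sv_phage(), cohort.lineages
    )
    corr = stats.abundance_correlations(cohort.abundance, network)
    summary["network_edges"] = len(network)
    summary["mean_pair_abundance_r"] = corr["mean_pair_r"]
    summary["count_vs_r"] = corr["count_vs_r"]

    if outdir is not None:
        _write_outputs(
            Path(outdir), cohort, nonredundant, result, classifications,
            ht, detected_events, spacer_hits, hosts, enrichment, network,
            summary,
        )
    return summary


def _detectable_truth(cohort: Cohort, params: merge.MergeParams) -> set[str]:
    """Truth SV ids emitted by >= min_callers callers in some sample and
    not excluded by the representative-level quality filters."""
    detectable = set()
    lengths = cohort.contig_lengths
    for rec in cohort.truth_svs:
        if rec.length <= params.min_len_exclusive:
            continue
        if rec.start < params.edge_margin:
            continue
        if lengths[rec.contig] - rec.end < params.edge_margin:
            continue
        for by_caller in cohort.callsets.values():
            callers = {
                caller
                for caller, records in by_caller.items()
                if any(r.record_id.endswith(rec.record_id) for r in records)
            }
            if len(callers) >= params.min_callers:
                detectable.add(rec.record_id)
                break
    return detectable


def _write_outputs(outdir, cohort, nonredundant, result, classifications,
                   ht, hgt_events, spacer_hits, hosts, enrichment, network,
                   summary) -> None:
    import pandas as pd

    outdir.mkdir(parents=True, exist_ok=True)
    io.write_sv_vcf(
        [cl.representative for cl in nonredundant],
        outdir / "nonredundant.vcf",
        contig_lengths=cohort.contig_lengths,
    )
    with open(outdir / "benchmark.json", "w") as fh:
        json.dump(result.as_dict(), fh, indent=2)
    pd.DataFrame(
        [
            {
                "sv_id": c.sv_id, "label": c.label,
                "prophage_flag": c.prophage_flag,
                "best_subject": c.best_hit.subject_id if c.best_hit else "",
                "matched_genomes": ",".join(sorted(c.matched_genomes)),
            }
            for c in classifications.values()
        ]
    ).to_csv(outdir / "ge_classification.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"gene_id": g, "ht_index": v} for g, v in sorted(ht.items())]
    ).to_csv(outdir / "ht_index.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "tree_id": e.tree_id, "direction": e.direction,
                "recipients": ",".join(sorted(e.recipient_leaves)),
                "support": e.support,
            }
            for e in hgt_events
        ]
    ).to_csv(outdir / "hgt_events.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "spacer_id": h.spacer_id, "genome_id": h.genome_id,
                "position": h.position, "strand": h.strand,
                "mismatches": h.mismatches,
            }
            for h in spacer_hits
        ]
    ).to_csv(outdir / "spacer_hits.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"phage_id": p, "source_taxa": ",".join(sorted(t))}
            for p, t in sorted(hosts.items())
        ]
    ).to_csv(outdir / "host_assignments.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "category": r.category, "a": r.a, "b": r.b, "c": r.c, "d": r.d,
                "odds_ratio": r.odds_ratio, "p": r.p, "q": r.q,
            }
            for r in enrichment
        ]
    ).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    stats.edges_to_frame(network).to_csv(
        outdir / "network_edges.tsv", sep="\t", index=False
    )
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
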