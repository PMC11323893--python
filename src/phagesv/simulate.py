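"""Synthetic-cohort generator: every input the pipeline consumes, with
ground truth attached.

The generator emulates the structure of a virome-enriched long-read
cohort at the callset level: phage reference genomes with implanted
INS/DEL/DUP/INV truth SVs, four noisy caller callsets per sample
(positional jitter, misses, caller-private false positives), bacterial
genomes sharing transferred segments with phages at tunable divergence,
genes drawn from distinct codon-transition Markov chains, gene trees
with planted cross-kingdom nested clades, CRISPR-spacer libraries, and
lognormal abundance profiles with coupled phage-bacteria pairs.  Every
generator is a pure function of its seed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .exchange import CODONS, CODON_INDEX, STOP_CODONS, revcomp
from .model import (
    AbundanceMatrix,
    AlignmentHit,
    GeneRecord,
    GenomeRecord,
    Lifestyle,
    SVRecord,
    SVType,
    TaxonLineage,
)

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p).tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# Phage genomes and SV implantation
# ---------------------------------------------------------------------------

def gen_phage_genomes(
    n: int,
    len_min: int = 15_000,
    len_max: int = 25_000,
    gc: float = 0.45,
    seed: int = 0,
    prefix: str = "phage",
    kind: str = "phage",
) -> list[GenomeRecord]:
    """``n`` genomes of i.i.d. bases at the stated GC content, lengths
    uniform on [len_min, len_max]."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0 < gc < 1):
        raise ValueError("gc must be in (0, 1)")
    if len_min > len_max:
        raise ValueError("len_min must be <= len_max")
    rng = np.random.default_rng(seed)
    genomes = []
    for i in range(n):
        length = int(rng.integers(len_min, len_max + 1))
        genomes.append(
            GenomeRecord(
                genome_id=f"{prefix}_{i:04d}",
                sequence=_random_seq(rng, length, gc),
                kind=kind,
            )
        )
    return genomes


def implant_svs(
    genomes: Sequence[GenomeRecord],
    counts_by_type: Mapping[SVType | str, int],
    len_dist: tuple[int, int] = (100, 1000),
    seed: int = 0,
    margin: int = 100,
    spacing: int = 150,
    genome_weights: Optional[Mapping[str, int]] = None,
) -> tuple[list[GenomeRecord], list[SVRecord]]:
    """Implant truth SVs; returns (mutated genomes, truth records).

    Truth coordinates are expressed on the reference genome.  Implants
    are kept at least ``margin`` bp from the genome ends and ``spacing``
    bp apart so no two truth intervals overlap.  Mutated genome lengths
    differ from the reference by exactly the signed sum of INS/DEL
    lengths (DUP adds its length; INV preserves length).  Optional
    integer ``genome_weights`` bias how many SVs each genome receives
    (a weight-w genome gets w shares of the round-robin assignment).
    """
    rng = np.random.default_rng(seed)
    wanted = []
    for svtype, count in sorted(
        ((SVType(t) if not isinstance(t, SVType) else t), c)
        for t, c in counts_by_type.items()
    ):
        wanted.extend([svtype] * count)
    order = rng.permutation(len(wanted))
    assignments: dict[str, list[SVType]] = {g.genome_id: [] for g in genomes}
    gids = [
        g.genome_id
        for g in genomes
        for _ in range((genome_weights or {}).get(g.genome_id, 1))
    ]
    for pos, idx in enumerate(order):
        assignments[gids[pos % len(gids)]].append(wanted[idx])

    truth: list[SVRecord] = []
    mutated: list[GenomeRecord] = []
    counter = 0
    for genome in genomes:
        seq = genome.sequence
        length = len(seq)
        placed: list[tuple[int, int]] = []
        records: list[SVRecord] = []
        for svtype in assignments[genome.genome_id]:
            sv_len = int(rng.integers(len_dist[0], len_dist[1] + 1))
            lo, hi = margin, length - margin - sv_len
            if hi <= lo:
                raise ValueError(
                    f"genome {genome.genome_id} too small to host a {sv_len} bp SV"
                )
            for _ in range(2000):
                start = int(rng.integers(lo, hi))
                if all(
                    start >= e + spacing or start + sv_len + spacing <= s
                    for s, e in placed
                ):
                    break
            else:
                raise ValueError(
                    f"genome {genome.genome_id} too small to host requested SVs"
                )
            placed.append((start, start + sv_len))
            alt = _random_seq(rng, sv_len) if svtype is SVType.INS else None
            records.append(
                SVRecord(
                    contig=genome.genome_id,
                    start=start,
                    length=sv_len,
                    svtype=svtype,
                    caller="truth",
                    record_id=f"truth_{counter:05d}",
                    alt_seq=alt,
                )
            )
            counter += 1
        # apply edits right-to-left so reference coordinates stay valid
        mutated_seq = seq
        for rec in sorted(records, key=lambda r: -r.start):
            s, e = rec.start, rec.end
            if rec.svtype is SVType.DEL:
                mutated_seq = mutated_seq[:s] + mutated_seq[e:]
            elif rec.svtype is SVType.INS:
                mutated_seq = mutated_seq[:s] + rec.alt_seq + mutated_seq[s:]
            elif rec.svtype is SVType.DUP:
                mutated_seq = mutated_seq[:e] + mutated_seq[s:e] + mutated_seq[e:]
            else:  # INV
                mutated_seq = (
                    mutated_seq[:s] + revcomp(mutated_seq[s:e]) + mutated_seq[e:]
                )
        delta = sum(
            r.length if r.svtype in (SVType.INS, SVType.DUP)
            else -r.length if r.svtype is SVType.DEL
            else 0
            for r in records
        )
        assert len(mutated_seq) == length + delta, genome.genome_id
        mutated.append(replace_sequence(genome, mutated_seq))
        truth.extend(sorted(records, key=lambda r: r.start))
    return mutated, truth


def replace_sequence(genome: GenomeRecord, sequence: str) -> GenomeRecord:
    return GenomeRecord(
        genome_id=genome.genome_id, sequence=sequence,
        kind=genome.kind, lifestyle=genome.lifestyle,
    )


# ---------------------------------------------------------------------------
# Simulated caller callsets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CallerProfile:
    """Noise model of one simulated SV caller."""

    caller_id: str
    pos_jitter_sd: float = 10.0
    len_jitter_frac: float = 0.02
    fn_rate: float = 0.1
    fp_rate_per_genome: float = 2.0
    read_support_mean: float = 10.0
    fp_len_range: tuple[int, int] = (60, 1000)

    def __post_init__(self) -> None:
        if not (0 <= self.fn_rate <= 1):
            raise ValueError("fn_rate must be in [0, 1]")
        if self.pos_jitter_sd < 0 or self.len_jitter_frac < 0:
            raise ValueError("jitters must be non-negative")
        if self.fp_rate_per_genome < 0:
            raise ValueError("fp_rate_per_genome must be >= 0")
        if self.read_support_mean <= 0:
            raise ValueError("read_support_mean must be > 0")


def _reciprocal(s1: int, l1: int, s2: int, l2: int) -> float:
    overlap = min(s1 + l1, s2 + l2) - max(s1, s2)
    return overlap / max(l1, l2) if overlap > 0 else 0.0


DEFAULT_PROFILES = (
    CallerProfile("Sniffles", pos_jitter_sd=5.0, fn_rate=0.08),
    CallerProfile("cuteSV", pos_jitter_sd=8.0, fn_rate=0.10),
    CallerProfile("pbsv", pos_jitter_sd=10.0, fn_rate=0.10),
    CallerProfile("SVIM", pos_jitter_sd=10.0, fn_rate=0.12),
)


def simulate_caller_vcfs(
    truth: Sequence[SVRecord],
    profiles: Sequence[CallerProfile],
    genome_lengths: Mapping[str, int],
    seed: int = 0,
    sample: str = "sample_0",
) -> dict[str, list[SVRecord]]:
    """One noisy callset per caller profile for a single sample.

    Each truth SV is emitted with probability 1 - fn_rate, with the
    start shifted by a rounded Normal(0, pos_jitter_sd), the length
    scaled by 1 + Normal(0, len_jitter_frac) floored at 1, and read
    support drawn as 1 + Poisson(read_support_mean - 1).  False
    positives are placed uniformly at fp_rate_per_genome expected per
    genome and are caller-private by construction: a placement that
    would reciprocally overlap (>= 0.8) another caller's false positive
    of the same type on the same contig is redrawn, modelling the
    premise that each caller's artifacts arise from its own heuristics.
    False-positive record ids contain the marker ``_fp_``.
    """
    if not profiles:
        raise ValueError("need at least one caller profile")
    rng = np.random.default_rng(seed)
    truth = sorted(truth, key=lambda r: r.record_id)
    placed_fps: dict[str, list[tuple[int, int, SVType]]] = {}
    callsets: dict[str, list[SVRecord]] = {}
    for profile in profiles:
        calls: list[SVRecord] = []
        for rec in truth:
            if rng.random() < profile.fn_rate:
                continue
            start = max(0, rec.start + int(round(rng.normal(0, profile.pos_jitter_sd)))) \
                if profile.pos_jitter_sd > 0 else rec.start
            length = max(1, int(round(rec.length * (1 + rng.normal(0, profile.len_jitter_frac))))) \
                if profile.len_jitter_frac > 0 else rec.length
            support = 1 + int(rng.poisson(max(profile.read_support_mean - 1, 0)))
            calls.append(
                SVRecord(
                    contig=rec.contig,
                    start=start,
                    length=length,
                    svtype=rec.svtype,
                    caller=profile.caller_id,
                    sample=sample,
                    read_support=support,
                    record_id=f"{profile.caller_id}_{sample}_{rec.record_id}",
                )
            )
        fp_counter = 0
        for gid in sorted(genome_lengths):
            glen = genome_lengths[gid]
            for _ in range(int(rng.poisson(profile.fp_rate_per_genome))):
                for _attempt in range(100):
                    fp_len = int(rng.integers(*profile.fp_len_range))
                    fp_len = min(fp_len, max(glen - 2, 1))
                    start = int(rng.integers(0, max(glen - fp_len, 1)))
                    svtype = SVType(rng.choice([t.value for t in SVType]))
                    private = all(
                        _reciprocal(start, fp_len, s0, l0) < 0.8
                        for s0, l0, t0 in placed_fps.get(gid, ())
                        if t0 is svtype
                    )
                    if private:
                        break
                else:  # pragma: no cover - vanishingly unlikely
                    continue
                placed_fps.setdefault(gid, []).append((start, fp_len, svtype))
                support = 1 + int(rng.poisson(max(profile.read_support_mean - 1, 0)))
                calls.append(
                    SVRecord(
                        contig=gid,
                        start=start,
                        length=fp_len,
                        svtype=svtype,
                        caller=profile.caller_id,
                        sample=sample,
                        read_support=support,
                        record_id=f"{profile.caller_id}_{sample}_fp_{fp_counter:05d}",
                    )
                )
                fp_counter += 1
        callsets[profile.caller_id] = calls
    return callsets


# ---------------------------------------------------------------------------
# Bacterial genomes and exchanged segments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransferEvent:
    """Ground truth for one bacteria-to-phage exchanged segment."""

    event_id: str
    donor_genome_id: str
    recipient_phage_id: str
    donor_start: int
    donor_len: int
    insert_pos: int
    subst_rate: float
    inserted_seq: str = ""
    realized_identity: float = 100.0


def implant_exchange_segments(
    phages: Sequence[GenomeRecord],
    bacteria: Sequence[GenomeRecord],
    n_events: int,
    seg_len: tuple[int, int] = (300, 1500),
    subst_rate: float = 0.05,
    seed: int = 0,
    margin: int = 100,
) -> tuple[list[GenomeRecord], list[TransferEvent], list[AlignmentHit]]:
    """Copy bacterial segments into phages at tunable divergence.

    Each event copies a random donor segment, applies i.i.d.
    substitutions at ``subst_rate`` and inserts it into a phage.  The
    returned hit table is ground-truth-exact: the realized identity
    (100 x the fraction of unsubstituted bases) and full-coverage
    coordinates of each inserted segment, standing in for an external
    aligner.
    """
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    if not (0 <= subst_rate < 1):
        raise ValueError("subst_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    usable = [b for b in bacteria if b.length >= seg_len[1] + 2]
    if n_events > 0 and not usable:
        raise ValueError(f"no bacterial genome of length >= {seg_len[1]} bp")

    events: list[TransferEvent] = []
    hits: list[AlignmentHit] = []
    inserts: dict[str, list[tuple[int, str]]] = {p.genome_id: [] for p in phages}
    for i in range(n_events):
        donor = usable[int(rng.integers(len(usable)))]
        length = int(rng.integers(seg_len[0], seg_len[1] + 1))
        donor_start = int(rng.integers(0, donor.length - length))
        segment = donor.sequence[donor_start:donor_start + length]
        arr = np.frombuffer(segment.encode("ascii"), dtype=np.uint8).copy()
        sub_mask = rng.random(length) < subst_rate
        for pos in np.flatnonzero(sub_mask):
            current = arr[pos]
            choices = [b for b in _BASES if b != current]
            arr[pos] = choices[int(rng.integers(3))]
        mutated = arr.tobytes().decode("ascii")
        n_sub = int(sub_mask.sum())
        identity = 100.0 * (1 - n_sub / length)
        recipient = phages[int(rng.integers(len(phages)))]
        insert_pos = int(rng.integers(margin, recipient.length - margin))
        event_id = f"ge_{i:04d}"
        events.append(
            TransferEvent(
                event_id=event_id,
                donor_genome_id=donor.genome_id,
                recipient_phage_id=recipient.genome_id,
                donor_start=donor_start,
                donor_len=length,
                insert_pos=insert_pos,
                subst_rate=subst_rate,
                inserted_seq=mutated,
                realized_identity=identity,
            )
        )
        hits.append(
            AlignmentHit(
                query_id=event_id,
                subject_id=donor.genome_id,
                pct_identity=identity,
                aln_length=length,
                mismatches=n_sub,
                qstart=1,
                qend=length,
                sstart=donor_start + 1,
                send=donor_start + length,
                evalue=0.0,
                bitscore=2.0 * length,
            )
        )
        inserts[recipient.genome_id].append((insert_pos, mutated))

    modified = []
    for phage in phages:
        seq = phage.sequence
        for pos, segment in sorted(inserts[phage.genome_id], reverse=True):
            seq = seq[:pos] + segment + seq[pos:]
        modified.append(replace_sequence(phage, seq))
    return modified, events, hits


# ---------------------------------------------------------------------------
# Codon-chain genes
# ---------------------------------------------------------------------------

_SENSE = [i for i, c in enumerate(CODONS) if c not in STOP_CODONS]
_STOP_IDX = [CODON_INDEX[c] for c in STOP_CODONS]


def random_codon_matrix(seed_or_rng, concentration: float = 0.5) -> np.ndarray:
    """A random 64x64 row-stochastic codon transition matrix (Dirichlet
    rows)."""
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    return rng.dirichlet(np.full(64, concentration), size=64)


def matrix_total_variation(t1: np.ndarray, t2: np.ndarray) -> float:
    """Mean over rows of the total-variation distance between the two
    transition distributions."""
    return float(0.5 * np.abs(np.asarray(t1) - np.asarray(t2)).sum(axis=1).mean())


def codon_matrix_pair(
    seed: int = 0, min_tv: float = 0.3, concentration: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Two random transition matrices at total variation >= ``min_tv``."""
    rng = np.random.default_rng(seed)
    for _ in range(100):
        t1 = random_codon_matrix(rng, concentration)
        t2 = random_codon_matrix(rng, concentration)
        if matrix_total_variation(t1, t2) >= min_tv:
            return t1, t2
    raise RuntimeError(f"could not reach total variation {min_tv}")


def _check_stochastic(t: np.ndarray, name: str) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if t.shape != (64, 64):
        raise ValueError(f"{name} must be 64x64")
    rows = t.sum(axis=1)
    bad = np.flatnonzero(~np.isclose(rows, 1.0, atol=1e-8))
    if bad.size:
        raise ValueError(
            f"{name} row {CODONS[bad[0]]} sums to {rows[bad[0]]:.6f}, not 1"
        )
    return t


def _sample_codon_chain(
    rng: np.random.Generator, transition: np.ndarray, n_codons: int
) -> str:
    """A codon Markov chain with in-frame stop codons resampled away."""
    codons = []
    state = int(rng.choice(_SENSE))
    codons.append(state)
    for _ in range(n_codons - 1):
        p = transition[state].copy()
        p[_STOP_IDX] = 0.0
        total = p.sum()
        if total <= 0:
            p = np.zeros(64)
            p[_SENSE] = 1.0 / len(_SENSE)
        else:
            p = p / total
        state = int(rng.choice(64, p=p))
        codons.append(state)
    return "".join(CODONS[i] for i in codons)


def gen_codon_genes(
    native_t: np.ndarray,
    foreign_t: np.ndarray,
    n_native: int,
    n_foreign: int,
    gene_len_codons: int = 300,
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, str]]:
    """Genes as codon Markov chains; returns (sequences, truth labels).

    Native genes follow ``native_t``, foreign genes ``foreign_t``; no
    generated gene contains an in-frame stop codon.
    """
    if gene_len_codons < 10:
        raise ValueError("gene_len_codons must be >= 10")
    native_t = _check_stochastic(native_t, "native_T")
    foreign_t = _check_stochastic(foreign_t, "foreign_T")
    rng = np.random.default_rng(seed)
    seqs: dict[str, str] = {}
    labels: dict[str, str] = {}
    for i in range(n_native):
        name = f"native_{i:04d}"
        seqs[name] = _sample_codon_chain(rng, native_t, gene_len_codons)
        labels[name] = "native"
    for i in range(n_foreign):
        name = f"foreign_{i:04d}"
        seqs[name] = _sample_codon_chain(rng, foreign_t, gene_len_codons)
        labels[name] = "foreign"
    return seqs, labels


# ---------------------------------------------------------------------------
# Gene annotations on phage genomes
# ---------------------------------------------------------------------------

LEVEL2_CATEGORIES = (
    "integration:recombinase",
    "replication:polymerase",
    "packaging:terminase",
    "assembly:capsid",
    "lysis:endolysin",
    "regulation:repressor",
    "infection:tail_fiber",
    "hypothetical:unknown",
)


def gen_gene_annotations(
    genomes: Sequence[GenomeRecord],
    truth_svs: Sequence[SVRecord],
    seed: int = 0,
    gene_len: tuple[int, int] = (600, 1200),
    gap: int = 50,
    enriched_category: str = "integration:recombinase",
    enrichment_boost: float = 6.0,
) -> list[GeneRecord]:
    """Tile each genome with genes and assign level-2 categories.

    The ``enriched_category`` is drawn ``enrichment_boost`` times more
    often for genes overlapping a truth SV interval, planting a real
    enrichment signal for the Fisher-test stage to recover.
    """
    rng = np.random.default_rng(seed)
    sv_by_genome: dict[str, list[SVRecord]] = {}
    for sv in truth_svs:
        sv_by_genome.setdefault(sv.contig, []).append(sv)
    genes: list[GeneRecord] = []
    counter = 0
    base_p = np.ones(len(LEVEL2_CATEGORIES))
    enriched_idx = LEVEL2_CATEGORIES.index(enriched_category)
    for genome in genomes:
        pos = int(rng.integers(0, gap + 1))
        while pos + gene_len[0] < genome.length:
            length = int(rng.integers(*gene_len))
            end = min(pos + length, genome.length)
            overlaps = any(
                min(end, sv.end) - max(pos, sv.start) > 0
                for sv in sv_by_genome.get(genome.genome_id, ())
            )
            p = base_p.copy()
            if overlaps:
                p[enriched_idx] *= enrichment_boost
            p = p / p.sum()
            cat = LEVEL2_CATEGORIES[int(rng.choice(len(LEVEL2_CATEGORIES), p=p))]
            genes.append(
                GeneRecord(
                    genome_id=genome.genome_id,
                    start=pos,
                    end=end,
                    strand="+" if rng.random() < 0.5 else "-",
                    gene_id=f"gene_{counter:05d}",
                    level1_category=cat.split(":")[0],
                    level2_category=cat,
                    source="unknown",
                )
            )
            counter += 1
            pos = end + gap
    return genes


# ---------------------------------------------------------------------------
# Trees with planted cross-kingdom clades
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedHGTEvent:
    tree_id: str
    recipient_leaf_ids: frozenset[str]
    direction: str    # "B_to_P" | "P_to_B"


def _join_random(parts: list[str], rng: np.random.Generator) -> str:
    parts = list(parts)
    while len(parts) > 1:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        right = parts.pop(j)
        left = parts.pop(i)
        support = int(rng.integers(80, 101))
        bl = rng.uniform(0.02, 0.3)
        parts.append(f"({left},{right}){support}:{bl:.4f}")
    return parts[0]


def gen_hgt_trees(
    n_trees: int,
    leaves_per_tree: int = 12,
    events_per_tree: int = 1,
    seed: int = 0,
    background_kingdom: str = "bacterial",
) -> tuple[list[str], list[PlantedHGTEvent]]:
    """Random rooted binary trees of one kingdom with opposite-kingdom
    clades grafted inside; returns (newick strings, truth events).

    Each planted clade of 1-2 recipient leaves sits as
    ``((recipients, x), y)`` with donor-kingdom leaves x and y as its
    sibling and aunt, so the nesting rule recovers exactly the planted
    events.
    """
    if leaves_per_tree < 6:
        raise ValueError("leaves_per_tree must be >= 6")
    if 2 * events_per_tree + (1 if events_per_tree == 0 else 0) > leaves_per_tree:
        raise ValueError(
            f"{events_per_tree} events need more than {leaves_per_tree} leaves"
        )
    if background_kingdom not in ("bacterial", "viral"):
        raise ValueError("background_kingdom must be 'bacterial' or 'viral'")
    rng = np.random.default_rng(seed)
    donor_prefix = "B_" if background_kingdom == "bacterial" else "V_"
    recip_prefix = "V_" if background_kingdom == "bacterial" else "B_"
    direction = "B_to_P" if background_kingdom == "bacterial" else "P_to_B"

    newicks: list[str] = []
    truths: list[PlantedHGTEvent] = []
    for t in range(n_trees):
        tree_id = f"tree_{t:04d}"
        donors = [f"{donor_prefix}t{t}_{i}:{rng.uniform(0.02, 0.3):.4f}"
                  for i in range(leaves_per_tree)]
        donor_labels = [d.split(":")[0] for d in donors]
        parts: list[str] = []
        used = 0
        for e in range(events_per_tree):
            n_recip = int(rng.integers(1, 3))
            recip_labels = [f"{recip_prefix}t{t}e{e}_{i}" for i in range(n_recip)]
            recips = [f"{lab}:{rng.uniform(0.02, 0.3):.4f}" for lab in recip_labels]
            clade = recips[0] if n_recip == 1 else _join_random(recips, rng)
            x, y = donors[used], donors[used + 1]
            used += 2
            s1 = int(rng.integers(80, 101))
            s2 = int(rng.integers(80, 101))
            parts.append(
                f"(({clade},{x}){s1}:{rng.uniform(0.02, 0.3):.4f},{y})"
                f"{s2}:{rng.uniform(0.02, 0.3):.4f}"
            )
            truths.append(
                PlantedHGTEvent(
                    tree_id=tree_id,
                    recipient_leaf_ids=frozenset(recip_labels),
                    direction=direction,
                )
            )
        parts.extend(donors[used:])
        newicks.append(_join_random(parts, rng) + ";")
        del donor_labels
    return newicks, truths


# ---------------------------------------------------------------------------
# CRISPR-spacer library
# ---------------------------------------------------------------------------

def _hamming_scan_hit(spacer: str, genome: str, max_mismatches: int) -> bool:
    """True if any genome window on either strand is within
    ``max_mismatches`` substitutions of the spacer."""
    m = len(spacer)
    if len(genome) < m:
        return False
    g = np.frombuffer(genome.encode("ascii"), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(g, m)
    for probe in (spacer, revcomp(spacer)):
        sp = np.frombuffer(probe.encode("ascii"), dtype=np.uint8)
        if (windows != sp).sum(axis=1).min() <= max_mismatches:
            return True
    return False


def gen_spacer_library(
    phages: Sequence[GenomeRecord],
    n_true: int,
    spacer_len: int = 32,
    mismatches: int = 2,
    n_decoys: int = 10,
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, str], dict[str, str]]:
    """Spacers copied from phage windows plus verified decoys.

    Returns (spacers, truth hosts, spacer sources): ``truth`` maps each
    true spacer to its host phage; ``sources`` assigns every spacer —
    decoys included — a bacterial source taxon.  True spacers carry
    exactly ``mismatches`` substitutions (0-2); decoys are random
    sequences verified by brute force to have no window within 2
    mismatches in any phage.
    """
    if not (0 <= mismatches <= 2):
        raise ValueError("mismatches must be 0-2")
    if any(p.length < spacer_len for p in phages):
        raise ValueError("spacer_len exceeds the shortest phage length")
    rng = np.random.default_rng(seed)
    spacers: dict[str, str] = {}
    truth: dict[str, str] = {}
    sources: dict[str, str] = {}
    for i in range(n_true):
        phage = phages[int(rng.integers(len(phages)))]
        start = int(rng.integers(0, phage.length - spacer_len + 1))
        window = phage.sequence[start:start + spacer_len]
        arr = np.frombuffer(window.encode("ascii"), dtype=np.uint8).copy()
        if mismatches:
            positions = rng.choice(spacer_len, size=mismatches, replace=False)
            for pos in positions:
                choices = [b for b in _BASES if b != arr[pos]]
                arr[pos] = choices[int(rng.integers(3))]
        sid = f"spacer_true_{i:04d}"
        spacers[sid] = arr.tobytes().decode("ascii")
        truth[sid] = phage.genome_id
        sources[sid] = f"taxon_{i % 5:02d}"
    for i in range(n_decoys):
        for _attempt in range(200):
            candidate = _random_seq(rng, spacer_len)
            if not any(_hamming_scan_hit(candidate, p.sequence, 2) for p in phages):
                break
        else:
            raise RuntimeError("could not generate a clean decoy spacer")
        sid = f"spacer_decoy_{i:04d}"
        spacers[sid] = candidate
        sources[sid] = f"taxon_decoy_{i % 3:02d}"
    return spacers, truth, sources


# ---------------------------------------------------------------------------
# Abundance matrix with coupled pairs
# ---------------------------------------------------------------------------

def gen_abundance_matrix(
    n_samples: int,
    coupled_pairs: Sequence[tuple[str, str]],
    mu: float = 0.0,
    sigma: float = 0.5,
    coupling_rho: float = 0.8,
    seed: int = 0,
    uncoupled_rows: Sequence[str] = (),
) -> AbundanceMatrix:
    """Lognormal abundance with latent-Gaussian-coupled pairs.

    Uncoupled rows are i.i.d. lognormal(mu, sigma) across samples; each
    coupled pair shares a latent Gaussian at correlation
    ``coupling_rho`` before exponentiation.  The second member of each
    pair (the bacterial genus, typically) owns the shared latent, so one
    genus can couple several phages; a first-pair member recurring with
    a different partner keeps its first latent.
    """
    if n_samples < 3:
        raise ValueError("need n_samples >= 3 for correlations to be defined")
    if not (0 <= coupling_rho <= 1):
        raise ValueError("coupling_rho must be in [0, 1]")
    rng = np.random.default_rng(seed)
    row_ids: list[str] = []
    rows: list[np.ndarray] = []
    partner_latent: dict[str, np.ndarray] = {}
    for _a, b in coupled_pairs:
        if b not in partner_latent:
            partner_latent[b] = rng.normal(size=n_samples)
    tail = np.sqrt(max(0.0, 1 - coupling_rho**2))
    for a, b in coupled_pairs:
        z = partner_latent[b]
        za = coupling_rho * z + tail * rng.normal(size=n_samples)
        for rid, zz in ((a, za), (b, z)):
            if rid in row_ids:
                continue
            row_ids.append(rid)
            rows.append(np.exp(mu + sigma * zz))
    for rid in uncoupled_rows:
        if rid in row_ids:
            continue
        row_ids.append(rid)
        rows.append(np.exp(mu + sigma * rng.normal(size=n_samples)))
    sample_ids = [f"S{i:03d}" for i in range(n_samples)]
    return AbundanceMatrix(row_ids=row_ids, sample_ids=sample_ids,
                           values=np.vstack(rows) if rows else
                           np.empty((0, n_samples)))


# ---------------------------------------------------------------------------
# Bacterial lineages
# ---------------------------------------------------------------------------

def gen_lineages(
    genome_ids: Sequence[str],
    n_genera: int = 5,
    seed: int = 0,
) -> dict[str, TaxonLineage]:
    """Assign each bacterial genome a 7-rank lineage, spreading genomes
    over ``n_genera`` genera within two families."""
    rng = np.random.default_rng(seed)
    lineages = {}
    for gid in genome_ids:
        genus_i = int(rng.integers(n_genera))
        family_i = genus_i % 2
        lineages[gid] = TaxonLineage(
            genome_id=gid,
            ranks={
                "domain": "Bacteria",
                "phylum": "Bacillota",
                "class": "Clostridia",
                "order": "Eubacteriales",
                "family": f"family_{family_i}",
                "genus": f"genus_{genus_i:02d}",
                "species": f"species_{gid}",
            },
        )
    return lineages
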