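"""Phage-bacteria genetic-exchange analysis.

Four independent lines of evidence about cross-kingdom exchange:

* GE-like classification — an SV longer than 200 bp whose sequence hits
  a bacterial genome at >80% identity over >80% of its own length is
  called "GE (genetic exchange)-like"; shorter SVs are out of scope and
  hits into predicted prophage regions are flagged so phage-on-phage
  homology is not mistaken for bacterial exchange.
* HT index — a per-gene codon-neighbour typicality score from a
  first-order Markov chain over the 64 codons trained on the gene's own
  genome; horizontally acquired genes score low because their
  codon-pair bias reflects the donor genome.
* HGT directionality — on a rooted gene tree whose leaves carry kingdom
  labels, a maximal one-kingdom clade whose sibling and aunt leaves all
  belong to the other kingdom is a nested transfer: the surrounding
  kingdom donated, the nested clade received.
* CRISPR-spacer host prediction — a spacer matching a phage window on
  either strand with at most two substitutions links the phage to the
  spacer's source taxon.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .io import PhyloTree
from .model import AlignmentHit, Kingdom, TaxonLineage, RANKS

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# GE-like SV classification
# ---------------------------------------------------------------------------

@dataclass
class GEClassification:
    sv_id: str
    label: str                       # "GE_like" | "noGE_like" | "too_short"
    best_hit: Optional[AlignmentHit] = None
    matched_genomes: set[str] = field(default_factory=set)
    prophage_flag: bool = False


def classify_ge_svs(
    sv_lengths: Mapping[str, int],
    hits: Iterable[AlignmentHit],
    min_len: int = 200,
    min_id: float = 80.0,
    min_cov: float = 0.8,
) -> dict[str, GEClassification]:
    """Label every SV as GE_like / noGE_like / too_short.

    ``sv_lengths`` maps SV id to its sequence length; ``hits`` are
    alignments of SV sequences (queries) to bacterial genomes
    (subjects).  An SV of length <= ``min_len`` is ``too_short``;
    otherwise it is ``GE_like`` iff some hit exceeds ``min_id`` percent
    identity with coverage (alignment length over SV length) above
    ``min_cov``.  The best hit maximises identity x coverage.
    """
    out = {
        sv_id: GEClassification(
            sv_id=sv_id,
            label="too_short" if length <= min_len else "noGE_like",
        )
        for sv_id, length in sv_lengths.items()
    }
    for hit in hits:
        cls = out.get(hit.query_id)
        if cls is None:
            logger.warning("hit for unknown SV %r skipped", hit.query_id)
            continue
        if cls.label == "too_short":
            continue
        coverage = hit.aln_length / sv_lengths[hit.query_id]
        if hit.pct_identity > min_id and coverage > min_cov:
            cls.matched_genomes.add(hit.subject_id)
            cls.label = "GE_like"
            score = hit.pct_identity * min(coverage, 1.0)
            if cls.best_hit is None:
                cls.best_hit = hit
            else:
                best_cov = min(cls.best_hit.aln_length
                               / sv_lengths[cls.best_hit.query_id], 1.0)
                if score > cls.best_hit.pct_identity * best_cov:
                    cls.best_hit = hit
    return out


def flag_prophage_overlap(
    classifications: Mapping[str, GEClassification],
    prophage_hits: Iterable[AlignmentHit],
    sv_lengths: Mapping[str, int],
    min_id: float = 80.0,
    min_cov: float = 0.5,
) -> None:
    """Set ``prophage_flag`` on SVs whose sequence aligns into a
    predicted prophage region at >80% identity and >50% coverage."""
    for hit in prophage_hits:
        cls = classifications.get(hit.query_id)
        if cls is None or hit.query_id not in sv_lengths:
            continue
        coverage = hit.aln_length / sv_lengths[hit.query_id]
        if hit.pct_identity > min_id and coverage > min_cov:
            cls.prophage_flag = True


def lca_range(
    matched_genomes: Iterable[str],
    lineages: Mapping[str, TaxonLineage],
) -> str:
    """Taxonomic rank of the last common ancestor of the matched genomes.

    A single genome reports its own deepest present rank; genomes
    disagreeing already at domain report the sentinel ``"none"``.
    """
    genomes = sorted(set(matched_genomes))
    if not genomes:
        return "none"
    for gid in genomes:
        if gid not in lineages:
            raise KeyError(f"no lineage for genome {gid!r}")
    deepest = "none"
    for rank in RANKS:
        values = {lineages[g].ranks.get(rank) for g in genomes}
        if len(values) == 1 and None not in values and "" not in values:
            deepest = rank
        else:
            break
    return deepest


# ---------------------------------------------------------------------------
# Codon Markov model and HT index
# ---------------------------------------------------------------------------

_BASES = "ACGT"
CODONS = tuple("".join(c) for c in itertools.product(_BASES, repeat=3))
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass
class CodonModel:
    """First-order Markov chain over the 64 codons."""

    transition: np.ndarray      # (64, 64) row-stochastic
    initial: np.ndarray         # (64,) probabilities
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        if self.transition.shape != (64, 64):
            raise ValueError("transition matrix must be 64x64")
        rows = self.transition.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-9):
            bad = int(np.argmax(np.abs(rows - 1.0)))
            raise ValueError(f"transition row {CODONS[bad]} sums to {rows[bad]!r}")
        if (self.transition <= 0).any():
            raise ValueError("transition entries must be positive after smoothing")


def _codon_indices(seq: str, name: str = "gene") -> np.ndarray:
    seq = seq.upper()
    if len(seq) % 3 != 0:
        raise ValueError(f"{name}: length {len(seq)} not divisible by 3")
    if len(seq) < 6:
        raise ValueError(f"{name}: need at least 2 codons")
    try:
        return np.array(
            [CODON_INDEX[seq[i:i + 3]] for i in range(0, len(seq), 3)], dtype=int
        )
    except KeyError as exc:
        raise ValueError(f"{name}: non-ACGT codon {exc}") from None


def train_codon_model(
    gene_seqs: Mapping[str, str] | Sequence[str],
    pseudocount: float = 1.0,
) -> CodonModel:
    """Train the codon transition model of one genome.

    Adjacent in-frame codon pairs are pooled across all genes, Laplace
    smoothed by ``pseudocount`` and row normalised; the initial
    distribution is the smoothed first-codon frequency.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if isinstance(gene_seqs, Mapping):
        items = list(gene_seqs.items())
    else:
        items = [(f"gene_{i}", s) for i, s in enumerate(gene_seqs)]
    counts = np.zeros((64, 64))
    first = np.zeros(64)
    for name, seq in items:
        idx = _codon_indices(seq, name)
        first[idx[0]] += 1
        np.add.at(counts, (idx[:-1], idx[1:]), 1)
    counts += pseudocount
    first += pseudocount
    return CodonModel(
        transition=counts / counts.sum(axis=1, keepdims=True),
        initial=first / first.sum(),
        pseudocount=pseudocount,
    )


def ht_index(gene_seq: str, model: CodonModel) -> float:
    """Mean log2 transition probability of the gene's codon chain.

    HT = (1/(L-1)) sum_i log2 P(c_{i+1} | c_i) over the gene's L codons;
    lower values mean the gene's codon-pair usage is atypical for the
    genome the model was trained on.
    """
    idx = _codon_indices(gene_seq)
    return float(np.mean(np.log2(model.transition[idx[:-1], idx[1:]])))


def ht_index_table(
    gene_seqs: Mapping[str, str], model: CodonModel
) -> dict[str, float]:
    return {name: ht_index(seq, model) for name, seq in gene_seqs.items()}


# ---------------------------------------------------------------------------
# HGT directionality from tree topology
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HGTEvent:
    tree_id: str
    direction: str                  # "B_to_P" | "P_to_B"
    recipient_leaves: frozenset[str]
    context_leaves: frozenset[str]
    support: Optional[float] = None


def _leaf_labels(node) -> list[str]:
    return [lf.taxon.label for lf in node.leaf_iter()]


def _node_support(node) -> Optional[float]:
    label = node.label
    if label is None:
        return None
    try:
        return float(label)
    except ValueError:
        return None


def detect_hgt_events(tree: PhyloTree, min_support: float = 0.0) -> list[HGTEvent]:
    """Directed cross-kingdom transfers from nested clades.

    For every maximal clade C whose leaves all share kingdom X, the
    sibling leaves S (under the other children of C's parent) and the
    aunt leaves A (under the other children of C's grandparent) are
    collected; C is a transfer into X iff S is non-empty and S and A are
    uniformly the other kingdom Y (direction Y -> X).  Viral recipients
    make a B_to_P event, bacterial recipients a P_to_B event.

    A clade hanging directly off the root is never an event: with no
    grandparent there is no second level of surrounding context, and a
    clean bipartition of the two kingdoms would otherwise read as two
    reciprocal transfers.
    """
    king = tree.kingdoms
    events: list[HGTEvent] = []
    root = tree.tree.seed_node

    def clade_kingdoms(node) -> set[Kingdom]:
        return {king[l] for l in _leaf_labels(node)}

    for node in tree.tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            continue
        kinds = clade_kingdoms(node)
        if len(kinds) != 1:
            continue
        (x,) = kinds
        parent_kinds = clade_kingdoms(parent)
        if parent_kinds == {x}:
            continue  # not maximal: a pure ancestor exists or handled above
        # maximality: the parent clade is mixed, so `node` is a maximal pure clade
        siblings = [c for c in parent.child_nodes() if c is not node]
        s_leaves = [l for c in siblings for l in _leaf_labels(c)]
        if not s_leaves:
            continue
        grand = parent.parent_node
        if grand is None:
            continue
        aunts = [c for c in grand.child_nodes() if c is not parent]
        a_leaves = [l for c in aunts for l in _leaf_labels(c)]
        y = Kingdom.bacterial if x is Kingdom.viral else Kingdom.viral
        if any(king[l] is not y for l in s_leaves + a_leaves):
            continue
        support = _node_support(parent)
        if min_support > 0 and (support is None or support < min_support):
            continue
        direction = "B_to_P" if x is Kingdom.viral else "P_to_B"
        events.append(
            HGTEvent(
                tree_id=tree.tree_id,
                direction=direction,
                recipient_leaves=frozenset(_leaf_labels(node)),
                context_leaves=frozenset(s_leaves + a_leaves),
                support=support,
            )
        )
    return events


# ---------------------------------------------------------------------------
# CRISPR-spacer matching
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SpacerHit:
    spacer_id: str
    genome_id: str
    position: int                  # 0-based window start on the + strand
    strand: str                    # "+" | "-"
    mismatches: int
    matched_len: int


_SPACER_CODE = np.full(256, 4, dtype=np.int8)  # N and anything else: code 4
for _b, _c in zip(b"ACGT", range(4)):
    _SPACER_CODE[_b] = _c


def _encode(seq: str) -> np.ndarray:
    return _SPACER_CODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


def match_spacers(
    spacers: Mapping[str, str],
    genomes: Mapping[str, str],
    max_mismatches: int = 2,
    min_spacer_len: int = 20,
) -> list[SpacerHit]:
    """Full-length spacer-vs-genome scan with at most two substitutions.

    Every genome window of spacer length on either strand at Hamming
    distance <= ``max_mismatches`` is reported (no indels); ``N`` never
    matches anything, on either side.  Matching the full spacer with at
    most two substitutions simultaneously satisfies the >95% identity
    rule for spacers of >=41 bp; shorter spacers keep their mismatch
    count so stricter callers can refilter.
    """
    hits: list[SpacerHit] = []
    genome_codes = {gid: _encode(seq) for gid, seq in genomes.items()}
    for sid in sorted(spacers):
        seq = spacers[sid]
        m = len(seq)
        if m < min_spacer_len:
            logger.warning("spacer %s shorter than %d bp: skipped", sid, min_spacer_len)
            continue
        for strand, sp_seq in (("+", seq), ("-", revcomp(seq))):
            sp = _encode(sp_seq)
            for gid in sorted(genome_codes):
                codes = genome_codes[gid]
                if len(codes) < m:
                    continue
                windows = np.lib.stride_tricks.sliding_window_view(codes, m)
                # N (code 4) on either side always mismatches
                mism = (
                    (windows != sp[np.newaxis, :])
                    | (windows == 4)
                    | (sp[np.newaxis, :] == 4)
                ).sum(axis=1)
                for pos in np.flatnonzero(mism <= max_mismatches):
                    hits.append(
                        SpacerHit(
                            spacer_id=sid,
                            genome_id=gid,
                            position=int(pos),
                            strand=strand,
                            mismatches=int(mism[pos]),
                            matched_len=m,
                        )
                    )
    return hits


def host_table(
    hits: Iterable[SpacerHit],
    spacer_sources: Mapping[str, str],
) -> dict[str, set[str]]:
    """Map each phage genome to the set of taxa whose spacers hit it."""
    table: dict[str, set[str]] = {}
    for hit in hits:
        source = spacer_sources.get(hit.spacer_id)
        if source is None:
            logger.warning("no source taxon for spacer %s", hit.spacer_id)
            continue
        table.setdefault(hit.genome_id, set()).add(source)
    return table
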