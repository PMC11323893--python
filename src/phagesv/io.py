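"""Readers and writers for every standard format the pipeline touches.

VCF goes through pysam, FASTA through Biopython, Newick through dendropy
and tabular files through pandas.  All conversions between the 1-based
VCF convention and the package's 0-based half-open coordinates happen
here and nowhere else.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    RANKS,
    AbundanceMatrix,
    AlignmentHit,
    GeneRecord,
    GenomeRecord,
    Kingdom,
    Lifestyle,
    SVRecord,
    SVType,
    TaxonLineage,
)

logger = logging.getLogger(__name__)

_VALID_BASES = set("ACGTN")


def _info_get(info, key, default=None):
    """INFO lookup tolerant of keys missing from the header entirely."""
    try:
        return info.get(key, default)
    except (KeyError, ValueError):
        return default


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_INFO_LINES = [
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
    '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">',
    '##INFO=<ID=RE,Number=1,Type=Integer,Description="Supporting reads">',
    '##INFO=<ID=CALLER,Number=1,Type=String,Description="Source caller">',
    '##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Source sample">',
    '##INFO=<ID=SUPP_CALLERS,Number=1,Type=Integer,Description="Distinct supporting callers">',
    '##INFO=<ID=SUPP_SAMPLES,Number=1,Type=Integer,Description="Distinct supporting samples">',
]


def read_sv_vcf(path: str | Path) -> list[SVRecord]:
    """Read SV records from a VCF, skipping malformed records with a warning.

    Read support is taken from INFO ``RE``, then INFO ``SUPPORT``, then
    FORMAT ``DV`` of the first sample; absent everywhere -> 0.  Negative
    ``SVLEN`` (deletions) is normalised to its absolute value.
    """
    records: list[SVRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = rec.info
            svtype = _info_get(info, "SVTYPE")
            svlen = _info_get(info, "SVLEN")
            if isinstance(svlen, tuple):
                svlen = svlen[0] if svlen else None
            if svtype is None or svlen is None:
                logger.warning(
                    "skipping VCF record %s:%d: missing SVTYPE/SVLEN",
                    rec.contig, rec.pos,
                )
                continue
            try:
                svtype = SVType(str(svtype))
            except ValueError:
                logger.warning(
                    "skipping VCF record %s:%d: unknown SVTYPE %r",
                    rec.contig, rec.pos, svtype,
                )
                continue
            length = abs(int(svlen))
            if length < 1:
                logger.warning(
                    "skipping VCF record %s:%d: SVLEN of 0", rec.contig, rec.pos
                )
                continue
            support = _info_get(info, "RE")
            if support is None:
                support = _info_get(info, "SUPPORT")
            if support is None and rec.samples:
                first = rec.samples[next(iter(rec.samples))]
                support = first.get("DV") if "DV" in first else None
            if isinstance(support, tuple):
                support = support[0]
            alt_seq = None
            if svtype is SVType.INS and rec.alts:
                alt = rec.alts[0]
                if alt and not alt.startswith("<") and len(alt) > len(rec.ref or ""):
                    alt_seq = alt[len(rec.ref or ""):]
            records.append(
                SVRecord(
                    contig=rec.contig,
                    start=rec.pos - 1,
                    length=length,
                    svtype=svtype,
                    caller=str(_info_get(info, "CALLER", "")),
                    sample=str(_info_get(info, "SAMPLE", "")),
                    read_support=int(support) if support is not None else 0,
                    record_id=rec.id or "",
                    alt_seq=alt_seq,
                )
            )
    return records


def write_sv_vcf(
    records: Sequence[SVRecord],
    path: str | Path,
    contig_lengths: Optional[dict[str, int]] = None,
) -> None:
    """Write SV records as a VCF 4.2 file (uncompressed)."""
    header = pysam.VariantHeader()
    for line in _INFO_LINES:
        header.add_line(line)
    contigs = dict(contig_lengths or {})
    for rec in records:
        contigs.setdefault(rec.contig, None)
    for name, length in contigs.items():
        if length is None:
            header.add_line(f"##contig=<ID={name}>")
        else:
            header.add_line(f"##contig=<ID={name},length={length}>")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in records:
            if rec.svtype is SVType.INS and rec.alt_seq:
                alleles = ("N", "N" + rec.alt_seq)
            else:
                alleles = ("N", f"<{rec.svtype.value}>")
            svlen = -rec.length if rec.svtype is SVType.DEL else rec.length
            vrec = out.new_record(
                contig=rec.contig,
                start=rec.start,
                alleles=alleles,
                id=rec.record_id or None,
            )
            vrec.info["SVTYPE"] = rec.svtype.value
            vrec.info["SVLEN"] = svlen
            vrec.info["RE"] = rec.read_support
            if rec.caller:
                vrec.info["CALLER"] = rec.caller
            if rec.sample:
                vrec.info["SAMPLE"] = rec.sample
            vrec.stop = rec.end
            out.write(vrec)


def write_cluster_vcf(
    clusters,
    path: str | Path,
    contig_lengths: Optional[dict[str, int]] = None,
) -> None:
    """Write SV clusters as a VCF of their representatives, annotated
    with SUPP_CALLERS and SUPP_SAMPLES counts."""
    records = [cl.representative for cl in clusters]
    write_sv_vcf(records, path, contig_lengths=contig_lengths)
    # pysam offers no in-place INFO rewrite on a closed file; re-emit
    # with the support annotations patched into the INFO column
    lines = Path(path).read_text().splitlines()
    out, i = [], 0
    for line in lines:
        if line.startswith("#"):
            out.append(line)
            continue
        fields = line.split("\t")
        cl = clusters[i]
        fields[7] += (
            f";SUPP_CALLERS={len(cl.callers)};SUPP_SAMPLES={len(cl.samples)}"
        )
        out.append("\t".join(fields))
        i += 1
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(
    path: str | Path,
    kind: str = "phage",
    lifestyle: Lifestyle = Lifestyle.unknown,
) -> list[GenomeRecord]:
    """Read plain or gzipped FASTA; ids are the first whitespace token.

    Sequences are uppercased; characters outside ``{A,C,G,T,N}`` are
    replaced by ``N`` with a warning.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    genomes: list[GenomeRecord] = []
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = str(rec.seq).upper()
            if not set(seq) <= _VALID_BASES:
                n_bad = sum(1 for c in seq if c not in _VALID_BASES)
                logger.warning(
                    "%s: %d non-nucleotide letters replaced by N", rec.id, n_bad
                )
                seq = "".join(c if c in _VALID_BASES else "N" for c in seq)
            genomes.append(GenomeRecord(genome_id=rec.id, sequence=seq, kind=kind,
                                        lifestyle=lifestyle))
    return genomes


def write_fasta(genomes: Iterable[GenomeRecord] | dict[str, str],
                path: str | Path) -> None:
    if isinstance(genomes, dict):
        records = [SeqRecord(Seq(s), id=g, description="") for g, s in genomes.items()]
    else:
        records = [SeqRecord(Seq(g.sequence), id=g.genome_id, description="")
                   for g in genomes]
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


# ---------------------------------------------------------------------------
# 12-column tabular alignment hits
# ---------------------------------------------------------------------------

def read_hits(path: str | Path) -> list[AlignmentHit]:
    """Read a 12-column tab-separated hit table (blastn outfmt-6 dialect).

    Short or malformed rows are rejected with a warning instead of
    aborting the parse.
    """
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                logger.warning("hits line %d: expected 12 columns, got %d",
                               lineno, len(fields))
                continue
            try:
                hits.append(
                    AlignmentHit(
                        query_id=fields[0],
                        subject_id=fields[1],
                        pct_identity=float(fields[2]),
                        aln_length=int(fields[3]),
                        mismatches=int(fields[4]),
                        gap_opens=int(fields[5]),
                        qstart=int(fields[6]),
                        qend=int(fields[7]),
                        sstart=int(fields[8]),
                        send=int(fields[9]),
                        evalue=float(fields[10]),
                        bitscore=float(fields[11]),
                    )
                )
            except ValueError as exc:
                logger.warning("hits line %d rejected: %s", lineno, exc)
    return hits


def write_hits(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id, h.subject_id, f"{h.pct_identity:.3f}",
                        h.aln_length, h.mismatches, h.gap_opens,
                        h.qstart, h.qend, h.sstart, h.send,
                        h.evalue if h.evalue is not None else 0.0,
                        h.bitscore if h.bitscore is not None else 0.0,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Newick trees with kingdom-labelled leaves
# ---------------------------------------------------------------------------

class PhyloTree:
    """A rooted tree whose leaves carry a kingdom label.

    Kingdoms are resolved from leaf-name prefixes (default ``B_`` for
    bacterial, ``V_`` for viral) at parse time.
    """

    def __init__(self, tree: dendropy.Tree, kingdoms: dict[str, Kingdom],
                 tree_id: str = "") -> None:
        self.tree = tree
        self.kingdoms = kingdoms
        self.tree_id = tree_id

    @property
    def leaf_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def kingdom_of(self, label: str) -> Kingdom:
        return self.kingdoms[label]


def parse_newick(
    newick: str,
    bacterial_prefix: str = "B_",
    viral_prefix: str = "V_",
    tree_id: str = "",
) -> PhyloTree:
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    kingdoms: dict[str, Kingdom] = {}
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        if label.startswith(bacterial_prefix):
            kingdoms[label] = Kingdom.bacterial
        elif label.startswith(viral_prefix):
            kingdoms[label] = Kingdom.viral
        else:
            raise ValueError(f"unlabeled kingdom: {label}")
    return PhyloTree(tree, kingdoms, tree_id=tree_id)


def read_newick(
    path: str | Path,
    bacterial_prefix: str = "B_",
    viral_prefix: str = "V_",
) -> list[PhyloTree]:
    """Read one PhyloTree per Newick statement in the file."""
    trees = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            trees.append(
                parse_newick(line, bacterial_prefix, viral_prefix,
                             tree_id=f"{Path(path).stem}_{i}")
            )
    return trees


# ---------------------------------------------------------------------------
# Lineage and abundance tables
# ---------------------------------------------------------------------------

def read_lineages(path: str | Path) -> dict[str, TaxonLineage]:
    """TSV with columns: genome_id, domain, phylum, ..., species."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    lineages: dict[str, TaxonLineage] = {}
    for _, row in df.iterrows():
        gid = row["genome_id"]
        ranks = {r: row[r] for r in RANKS if r in df.columns and row[r]}
        lineages[gid] = TaxonLineage(genome_id=gid, ranks=ranks)
    return lineages


def write_lineages(lineages: Iterable[TaxonLineage], path: str | Path) -> None:
    rows = [
        {"genome_id": lin.genome_id, **{r: lin.ranks.get(r, "") for r in RANKS}}
        for lin in lineages
    ]
    pd.DataFrame(rows, columns=["genome_id", *RANKS]).to_csv(
        path, sep="\t", index=False
    )


def read_abundance(path: str | Path) -> AbundanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return AbundanceMatrix(
        row_ids=[str(i) for i in df.index],
        sample_ids=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
    )


def write_abundance(matrix: AbundanceMatrix, path: str | Path) -> None:
    pd.DataFrame(
        np.asarray(matrix.values), index=matrix.row_ids, columns=matrix.sample_ids
    ).to_csv(path, sep="\t")


def read_genes(path: str | Path) -> list[GeneRecord]:
    """TSV gene table: genome_id, start, end, strand, gene_id, level1, level2, source."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return [
        GeneRecord(
            genome_id=row["genome_id"],
            start=int(row["start"]),
            end=int(row["end"]),
            strand=row["strand"],
            gene_id=row["gene_id"],
            level1_category=row.get("level1_category", ""),
            level2_category=row.get("level2_category", ""),
            source=row.get("source", "unknown"),
        )
        for _, row in df.iterrows()
    ]


def write_genes(genes: Iterable[GeneRecord], path: str | Path) -> None:
    rows = [
        {
            "genome_id": g.genome_id, "start": g.start, "end": g.end,
            "strand": g.strand, "gene_id": g.gene_id,
            "level1_category": g.level1_category,
            "level2_category": g.level2_category, "source": g.source,
        }
        for g in genes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
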