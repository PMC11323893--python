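"""Domain types shared by the whole pipeline.

Coordinates are 0-based, half-open everywhere inside the package; the
1-based VCF convention is converted at the I/O boundary only.  The
effective end of every SV — insertions included — is ``start + length``,
so all four SV types can be compared with plain interval arithmetic.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence


class SVType(str, enum.Enum):
    """The four structural-variant classes handled by the pipeline."""

    INS = "INS"
    DEL = "DEL"
    DUP = "DUP"
    INV = "INV"


class Kingdom(str, enum.Enum):
    bacterial = "bacterial"
    viral = "viral"


class Lifestyle(str, enum.Enum):
    temperate = "temperate"
    virulent = "virulent"
    unknown = "unknown"


#: taxonomic ranks from broadest to most specific
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")


@dataclass(frozen=True)
class SVRecord:
    """A single SV call — the atom of the pipeline.

    ``start`` is 0-based on the reference contig; ``length`` is the SV
    length in bp (always positive, also for deletions).  ``alt_seq`` is
    the inserted sequence and is meaningful for INS only.
    """

    contig: str
    start: int
    length: int
    svtype: SVType
    caller: str = ""
    sample: str = ""
    read_support: int = 0
    record_id: str = ""
    alt_seq: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start for {self.record_id!r}")
        if self.length < 1:
            raise ValueError(f"SV length must be >= 1 ({self.record_id!r})")

    @property
    def end(self) -> int:
        """Effective end coordinate: start + length for every SV type."""
        return self.start + self.length

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class GenomeRecord:
    genome_id: str
    sequence: str
    kind: str = "phage"
    lifestyle: Lifestyle = Lifestyle.unknown

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneRecord:
    """A protein-coding gene with functional-category and source labels."""

    genome_id: str
    start: int
    end: int
    strand: str
    gene_id: str
    level1_category: str = ""
    level2_category: str = ""
    source: str = "unknown"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad gene interval for {self.gene_id!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id!r}")


@dataclass(frozen=True)
class AlignmentHit:
    """One row of a 12-column tabular alignment (blastn outfmt-6 dialect)."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int = 0
    gap_opens: int = 0
    qstart: int = 0
    qend: int = 0
    sstart: int = 0
    send: int = 0
    evalue: Optional[float] = None
    bitscore: Optional[float] = None


@dataclass(frozen=True)
class TaxonLineage:
    """Ordered lineage of one genome; ranks may be absent below some depth."""

    genome_id: str
    ranks: Mapping[str, str]

    def __post_init__(self) -> None:
        seen_gap = False
        for rank in RANKS:
            value = self.ranks.get(rank)
            if value:
                if seen_gap:
                    raise ValueError(
                        f"lineage of {self.genome_id!r} has a gap above rank {rank!r}"
                    )
            else:
                seen_gap = True

    def deepest_rank(self) -> Optional[str]:
        deepest = None
        for rank in RANKS:
            if self.ranks.get(rank):
                deepest = rank
        return deepest


@dataclass
class SVCluster:
    """A merged group of SV calls with an elected representative."""

    members: list[SVRecord]
    representative: SVRecord

    @property
    def callers(self) -> set[str]:
        return {m.caller for m in self.members}

    @property
    def samples(self) -> set[str]:
        return {m.sample for m in self.members}

    @property
    def read_support_max(self) -> int:
        return max(m.read_support for m in self.members)

    def __post_init__(self) -> None:
        if self.representative not in self.members:
            raise ValueError("representative must be a cluster member")


@dataclass
class AbundanceMatrix:
    """Non-negative abundance of taxa (rows) across samples (columns)."""

    row_ids: list[str]
    sample_ids: list[str]
    values: "object"  # numpy (n_rows, n_samples) array

    def __post_init__(self) -> None:
        import numpy as np

        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.sample_ids)):
            raise ValueError("abundance matrix shape does not match ids")
        if (self.values < 0).any():
            raise ValueError("negative abundance values")

    def row(self, row_id: str):
        return self.values[self.row_ids.index(row_id)]


def sv_by_id(records: Sequence[SVRecord]) -> dict[str, SVRecord]:
    return {r.record_id: r for r in records}
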