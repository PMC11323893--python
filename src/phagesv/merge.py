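"""Ensemble merging of multi-caller SV callsets.

Within a sample, calls of the same type on the same contig are grouped
into non-overlapping coordinate groups; inside each group, calls are
nodes of a graph with an edge wherever two calls share a mutual
(reciprocal) overlap of at least 80% of the longer call, and the graph —
a "corrupted clique" graph, since positional jitter between callers
deletes edges — is clustered with the Cluster Affinity Search Technique
(CAST).  Clusters supported by at least two callers, at least two reads,
longer than 50 bp and at least 100 bp from the contig ends survive; the
member from the highest-priority caller represents the cluster.

The same machinery merges per-sample representatives across samples into
a nonredundant cohort callset whose representatives are the most
prevalent calls in the population.

Insertions take part in the interval arithmetic through the convention
that the end of an INS is its start plus its length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model import SVCluster, SVRecord, SVType

logger = logging.getLogger(__name__)

DEFAULT_CALLER_PRIORITY = ("Sniffles", "cuteSV", "pbsv", "SVIM")


@dataclass(frozen=True)
class MergeParams:
    """Quality filters and clustering thresholds of the merge."""

    min_mutual_overlap: float = 0.8
    cast_t: float = 0.5
    min_callers: int = 2
    min_reads: int = 2
    min_len_exclusive: int = 50   # "longer than 50 bp" read strictly
    edge_margin: int = 100
    caller_priority: tuple[str, ...] = DEFAULT_CALLER_PRIORITY

    def __post_init__(self) -> None:
        if not (0 < self.min_mutual_overlap <= 1):
            raise ValueError("min_mutual_overlap must be in (0, 1]")
        if not (0 < self.cast_t <= 1):
            raise ValueError("cast_t must be in (0, 1]")

    def caller_rank(self, caller: str) -> int:
        try:
            return self.caller_priority.index(caller)
        except ValueError:
            return len(self.caller_priority)


def reciprocal_overlap(a: SVRecord, b: SVRecord) -> float:
    """Mutual overlap: intersection length over the longer SV's length.

    Defined as 0 for records on different contigs or of different types.
    """
    if a.contig != b.contig or a.svtype != b.svtype:
        return 0.0
    overlap = min(a.end, b.end) - max(a.start, b.start)
    if overlap <= 0:
        return 0.0
    return overlap / max(a.length, b.length)


def _tie_key(rec: SVRecord, params: MergeParams) -> tuple:
    return (rec.start, rec.length, params.caller_rank(rec.caller), rec.record_id)


def overlap_groups(records: Sequence[SVRecord]) -> list[list[SVRecord]]:
    """Partition same-contig, same-type records into connected components
    of the >=1 bp interval-overlap relation (a left-to-right sweep)."""
    if not records:
        return []
    ordered = sorted(records, key=lambda r: (r.start, r.length, r.record_id))
    groups: list[list[SVRecord]] = [[ordered[0]]]
    reach = ordered[0].end
    for rec in ordered[1:]:
        if rec.start < reach:
            groups[-1].append(rec)
        else:
            groups.append([rec])
        reach = max(reach, rec.end)
    return groups


def cast_cluster(
    group: Sequence[SVRecord],
    min_mutual_overlap: float = 0.8,
    cast_t: float = 0.5,
    params: Optional[MergeParams] = None,
) -> list[list[SVRecord]]:
    """CAST clustering of one overlap group.

    The graph has an edge between two records iff their reciprocal
    overlap reaches ``min_mutual_overlap``.  Clusters open at the
    maximum-degree unassigned node, greedily add the unassigned node of
    highest affinity (edge count into the cluster) while that affinity is
    at least ``cast_t * |C|``, then drop members whose affinity falls
    below the same bound, and close once stable.  All ties break
    deterministically on (start, length, caller-priority rank, record id).
    """
    if params is None:
        params = MergeParams(min_mutual_overlap=min_mutual_overlap, cast_t=cast_t)
    n = len(group)
    if n == 0:
        return []
    order = sorted(range(n), key=lambda i: _tie_key(group[i], params))
    pref_of = [0] * n
    for pos, idx in enumerate(order):
        pref_of[idx] = pos  # lower = preferred
    adj: dict[int, set[int]] = {i: set() for i in range(n)}
    for ii in range(n):
        for jj in range(ii + 1, n):
            if reciprocal_overlap(group[ii], group[jj]) >= min_mutual_overlap:
                adj[ii].add(jj)
                adj[jj].add(ii)
    clusters = _cast_on_adjacency(n, adj, pref_of, cast_t)
    return [[group[i] for i in cl] for cl in clusters]


def _cast_on_adjacency(
    n: int,
    adj: Mapping[int, set[int]],
    pref: Sequence[int],
    cast_t: float,
) -> list[list[int]]:
    """CAST on an abstract graph of nodes 0..n-1.

    ``pref`` assigns each node its tie-break priority (lower wins).
    Returns clusters, each ordered by preference, in opening order.
    """
    unassigned = set(range(n))
    clusters: list[list[int]] = []
    while unassigned:
        seed = min(
            unassigned,
            key=lambda i: (-len(adj[i] & unassigned), pref[i]),
        )
        cluster = {seed}
        unassigned.discard(seed)
        max_iters = 50 + 10 * n
        for _ in range(max_iters):
            changed = False
            # ADD phase
            while unassigned:
                best = min(
                    unassigned,
                    key=lambda i: (-len(adj[i] & cluster), pref[i]),
                )
                if len(adj[best] & cluster) >= cast_t * len(cluster):
                    cluster.add(best)
                    unassigned.discard(best)
                    changed = True
                else:
                    break
            # REMOVE phase (a singleton closes rather than self-evicting)
            while len(cluster) > 1:
                worst = min(
                    cluster,
                    key=lambda i: (len(adj[i] & (cluster - {i})), pref[i]),
                )
                if len(adj[worst] & (cluster - {worst})) < cast_t * len(cluster):
                    cluster.discard(worst)
                    unassigned.add(worst)
                    changed = True
                else:
                    break
            if not changed:
                break
        clusters.append(sorted(cluster, key=lambda i: pref[i]))
    return clusters


def _elect_representative(members: Sequence[SVRecord], params: MergeParams) -> SVRecord:
    """Member from the highest-priority caller; ties by smaller start,
    then record id."""
    return min(
        members,
        key=lambda r: (params.caller_rank(r.caller), r.start, r.record_id),
    )


def merge_sample(
    callsets_by_caller: Mapping[str, Sequence[SVRecord]],
    params: MergeParams = MergeParams(),
    contig_lengths: Optional[Mapping[str, int]] = None,
) -> list[SVCluster]:
    """Merge one sample's per-caller callsets into filtered SV clusters.

    Filters are applied to the elected representative: at least
    ``min_callers`` distinct callers in the cluster, representative read
    support >= ``min_reads``, representative length > ``min_len_exclusive``
    and the representative interval at least ``edge_margin`` bp away from
    both contig ends (the end-side check needs ``contig_lengths``).
    """
    pool: list[SVRecord] = []
    for caller, records in callsets_by_caller.items():
        if params.caller_rank(caller) == len(params.caller_priority):
            logger.warning("unknown caller %r treated as lowest priority", caller)
        for rec in records:
            if rec.caller != caller:
                rec = replace(rec, caller=caller)
            pool.append(rec)
    samples = {r.sample for r in pool}
    if len(samples) > 1:
        raise ValueError(f"merge_sample expects one sample, got {sorted(samples)}")
    pool.sort(key=lambda r: (r.contig, r.svtype.value, *_tie_key(r, params)))

    by_key: dict[tuple[str, SVType], list[SVRecord]] = {}
    for rec in pool:
        by_key.setdefault((rec.contig, rec.svtype), []).append(rec)

    out: list[SVCluster] = []
    for (contig, _svtype), records in sorted(
        by_key.items(), key=lambda kv: (kv[0][0], kv[0][1].value)
    ):
        for grp in overlap_groups(records):
            for members in cast_cluster(
                grp, params.min_mutual_overlap, params.cast_t, params
            ):
                rep = _elect_representative(members, params)
                if len({m.caller for m in members}) < params.min_callers:
                    continue
                if rep.read_support < params.min_reads:
                    continue
                if rep.length <= params.min_len_exclusive:
                    continue
                if rep.start < params.edge_margin:
                    continue
                if contig_lengths is not None and contig in contig_lengths:
                    if contig_lengths[contig] - rep.end < params.edge_margin:
                        continue
                out.append(SVCluster(members=list(members), representative=rep))
    return out


def merge_cohort(
    per_sample_clusters: Mapping[str, Sequence[SVCluster]],
    params: MergeParams = MergeParams(),
) -> list[SVCluster]:
    """Merge per-sample cluster representatives into nonredundant SVs.

    The cohort representative of each cluster is the member recurring
    (mutual overlap >= ``min_mutual_overlap``) in the most samples —
    the most prevalent call in the population.  Ties break on smaller
    start, then shorter length, then sample id.
    """
    reps: list[SVRecord] = []
    for sample in sorted(per_sample_clusters):
        for cl in per_sample_clusters[sample]:
            reps.append(cl.representative)
    reps.sort(key=lambda r: (r.contig, r.svtype.value, *_tie_key(r, params)))

    by_key: dict[tuple[str, SVType], list[SVRecord]] = {}
    for rec in reps:
        by_key.setdefault((rec.contig, rec.svtype), []).append(rec)

    out: list[SVCluster] = []
    for (_contig, _svtype), records in sorted(
        by_key.items(), key=lambda kv: (kv[0][0], kv[0][1].value)
    ):
        for grp in overlap_groups(records):
            for members in cast_cluster(
                grp, params.min_mutual_overlap, params.cast_t, params
            ):
                support = {}
                for m in members:
                    support[m] = len(
                        {
                            o.sample
                            for o in members
                            if reciprocal_overlap(m, o) >= params.min_mutual_overlap
                        }
                    )
                rep = min(
                    members,
                    key=lambda m: (-support[m], m.start, m.length, m.sample),
                )
                out.append(SVCluster(members=list(members), representative=rep))
    return out


def per_type_counts(clusters: Sequence[SVCluster]) -> dict[str, int]:
    counts = {t.value: 0 for t in SVType}
    for cl in clusters:
        counts[cl.representative.svtype.value] += 1
    return counts


def presence_matrix(clusters: Sequence[SVCluster]) -> pd.DataFrame:
    """Binary nonredundant-SV x sample presence matrix."""
    samples = sorted({s for cl in clusters for s in cl.samples})
    ids = [cl.representative.record_id or f"cluster_{i}" for i, cl in enumerate(clusters)]
    mat = np.zeros((len(clusters), len(samples)), dtype=int)
    for i, cl in enumerate(clusters):
        for s in cl.samples:
            mat[i, samples.index(s)] = 1
    return pd.DataFrame(mat, index=ids, columns=samples)
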