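"""Collapse raw annotated reads into a unique, error-suppressed transcript set.

Two curation paths, mirroring how repertoire libraries are prepared:

* **UMI path** (:func:`umi_consensus`): reads sharing a unique molecular
  identifier are grouped, sub-clustered at 97% identity to split UMI
  collisions, and each subcluster is collapsed to a majority-vote consensus;
  exact-duplicate consensus sequences (multiple mRNAs of one cell) are then
  merged, and singletons — consensus records with neither UMI duplicates nor
  consensus duplicates — are removed.
* **cluster path** (:func:`cluster_dedup_no_umi`): exact duplicates are
  collapsed into abundances, reads are greedily clustered at 99% identity
  around the most abundant seeds, the seed of each cluster is kept, and
  clusters of total size < 2 are dropped as likely artifacts.

Both paths are fully deterministic: no randomness, documented tie-breaks.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import edlib

from .model import SequenceRecord
from .align import pairwise_identity


@dataclass
class CurationParams:
    umi_subcluster_identity: float = 0.97
    no_umi_cluster_identity: float = 0.99
    min_cluster_size: int = 2
    min_repertoire_unique: int = 1700

    def __post_init__(self) -> None:
        for name in ("umi_subcluster_identity", "no_umi_cluster_identity"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name}={v} outside (0, 1]")
        if self.min_cluster_size < 1 or self.min_repertoire_unique < 1:
            raise ValueError("sizes must be >= 1")


@dataclass
class Cluster:
    centroid: SequenceRecord
    members: list[SequenceRecord] = field(default_factory=list)

    @property
    def total_abundance(self) -> int:
        return sum(m.abundance for m in self.members)


@dataclass
class UMIGroup:
    umi: str
    members: list[SequenceRecord]
    subclusters: list[Cluster] = field(default_factory=list)
    consensus_per_subcluster: list[SequenceRecord] = field(default_factory=list)


def _sort_key(r: SequenceRecord) -> tuple[int, int, str]:
    # abundance descending, then longer first, then lexicographic sequence
    return (-r.abundance, -len(r.nt), r.nt)


def _meets_threshold(a: str, b: str, threshold: float) -> bool:
    """Exactly ``pairwise_identity(a, b) >= threshold`` via a banded search."""
    if a == b:
        return True
    m = max(len(a), len(b))
    k = int((1.0 - threshold) * m + 1e-9)  # identity >= t  <=>  distance <= k
    if k <= 0:
        return False
    d = edlib.align(a, b, mode="NW", task="distance", k=k)["editDistance"]
    return d != -1


def greedy_cluster(
    records: list[SequenceRecord], identity_threshold: float
) -> list[Cluster]:
    """USEARCH-style greedy centroid clustering.

    Records are visited in abundance-descending order (ties: longer first,
    then lexicographic sequence); each joins the first existing centroid
    whose identity to it is >= the threshold, otherwise it founds a new
    cluster. Centroids are therefore pairwise below the threshold.
    """
    clusters: list[Cluster] = []
    exact: dict[str, Cluster] = {}
    for rec in sorted(records, key=_sort_key):
        home = exact.get(rec.nt)
        if home is None:
            for cl in clusters:
                if _meets_threshold(cl.centroid.nt, rec.nt, identity_threshold):
                    home = cl
                    break
        if home is None:
            home = Cluster(centroid=rec)
            clusters.append(home)
            exact[rec.nt] = home
        home.members.append(rec)
    return clusters


def _star_consensus(cluster: Cluster) -> str:
    """Column-wise majority consensus, star-aligned to the centroid.

    Every member is pairwise-aligned (edlib, global) to the centroid; votes
    are abundance-weighted per centroid column, insertions are kept only on
    a majority, majority-gap columns are dropped, and ties go to the
    centroid (the most abundant member).
    """
    c = cluster.centroid.nt
    if all(m.nt == c for m in cluster.members):
        return c
    col_votes: list[Counter] = [Counter() for _ in range(len(c))]
    ins_votes: dict[int, Counter] = defaultdict(Counter)  # after column i
    total = cluster.total_abundance
    for m in cluster.members:
        if m.nt == c:
            for i, base in enumerate(c):
                col_votes[i][base] += m.abundance
            continue
        aln = edlib.align(m.nt, c, mode="NW", task="path")
        nice = edlib.getNiceAlignment(aln, m.nt, c)
        qa, ta = nice["query_aligned"], nice["target_aligned"]
        col = -1
        pending_ins: list[str] = []
        for qb, tb in zip(qa, ta):
            if tb == "-":
                pending_ins.append(qb)
                continue
            if pending_ins:
                ins_votes[col]["".join(pending_ins)] += m.abundance
                pending_ins = []
            col += 1
            col_votes[col][qb] += m.abundance
        if pending_ins:
            ins_votes[col]["".join(pending_ins)] += m.abundance
    out: list[str] = []
    for i, votes in enumerate(col_votes):
        best = max(votes.values())
        winners = [b for b, n in votes.items() if n == best]
        base = c[i] if c[i] in winners else sorted(winners)[0]
        if base != "-":
            out.append(base)
        ins = ins_votes.get(i)
        if ins:
            seq, n = ins.most_common(1)[0]
            if n * 2 > total:
                out.append(seq)
    return "".join(out)


def group_by_umi(records: list[SequenceRecord], params: CurationParams) -> list[UMIGroup]:
    by_umi: dict[str, list[SequenceRecord]] = defaultdict(list)
    for r in records:
        if r.umi is None:
            raise ValueError(
                f"record {r.read_id!r} has no UMI; use the non-UMI cluster path"
            )
        by_umi[r.umi].append(r)
    groups = []
    for umi in sorted(by_umi):
        g = UMIGroup(umi=umi, members=by_umi[umi])
        g.subclusters = greedy_cluster(g.members, params.umi_subcluster_identity)
        g.consensus_per_subcluster = [
            SequenceRecord(
                read_id=cl.centroid.read_id,
                nt=_star_consensus(cl),
                umi=umi,
                abundance=cl.total_abundance,
            )
            for cl in g.subclusters
        ]
        groups.append(g)
    return groups


def umi_consensus(
    records: list[SequenceRecord], params: CurationParams | None = None
) -> tuple[list[SequenceRecord], list[tuple[str, str]]]:
    """UMI-based consensus curation; returns (unique records, drop log)."""
    params = params or CurationParams()
    groups = group_by_umi(records, params)
    consensuses: list[tuple[SequenceRecord, int]] = []  # (record, umi dup count)
    for g in groups:
        for cl, cons in zip(g.subclusters, g.consensus_per_subcluster):
            consensuses.append((cons, len(cl.members)))

    by_seq: dict[str, list[tuple[SequenceRecord, int]]] = defaultdict(list)
    for cons, n_umi_dup in consensuses:
        by_seq[cons.nt].append((cons, n_umi_dup))

    kept: list[SequenceRecord] = []
    drops: list[tuple[str, str]] = []
    for seq, entries in by_seq.items():
        entries.sort(key=lambda e: _sort_key(e[0]))
        rep, _ = entries[0]
        n_consensus_dup = len(entries)
        has_umi_dup = any(n > 1 for _, n in entries)
        merged = SequenceRecord(
            read_id=rep.read_id, nt=seq, umi=rep.umi,
            abundance=sum(e[0].abundance for e in entries),
        )
        if n_consensus_dup > 1 or has_umi_dup:
            kept.append(merged)
        else:
            drops.append((rep.read_id, "singleton"))
    kept.sort(key=_sort_key)
    return kept, drops


def exact_collapse(records: list[SequenceRecord]) -> list[SequenceRecord]:
    """Merge byte-identical sequences, summing abundance (duplicate counting)."""
    by_seq: dict[str, list[SequenceRecord]] = defaultdict(list)
    for r in records:
        by_seq[r.nt].append(r)
    out = []
    for seq, group in by_seq.items():
        group.sort(key=_sort_key)
        out.append(
            SequenceRecord(
                read_id=group[0].read_id, nt=seq, umi=group[0].umi,
                abundance=sum(g.abundance for g in group),
            )
        )
    out.sort(key=_sort_key)
    return out


def cluster_dedup_no_umi(
    records: list[SequenceRecord], params: CurationParams | None = None
) -> tuple[list[SequenceRecord], list[tuple[str, str]]]:
    """Cluster-based curation for libraries without UMIs.

    Exact duplicates are collapsed first (sequencing depth becomes
    abundance), then greedy clustering at ``no_umi_cluster_identity``; each
    cluster's seed is emitted with the cluster's total abundance, and
    clusters with total size < ``min_cluster_size`` are dropped.
    """
    params = params or CurationParams()
    collapsed = exact_collapse(records)
    clusters = greedy_cluster(collapsed, params.no_umi_cluster_identity)
    kept: list[SequenceRecord] = []
    drops: list[tuple[str, str]] = []
    for cl in clusters:
        total = cl.total_abundance
        if total < params.min_cluster_size:
            drops.append((cl.centroid.read_id, f"cluster_size_{total}"))
            continue
        kept.append(
            SequenceRecord(
                read_id=cl.centroid.read_id, nt=cl.centroid.nt,
                umi=cl.centroid.umi, abundance=total,
            )
        )
    kept.sort(key=_sort_key)
    return kept, drops


def repertoire_filter(
    unique: list[SequenceRecord], params: CurationParams | None = None
) -> bool:
    """True iff the repertoire passes the minimum-unique-transcript filter."""
    params = params or CurationParams()
    return len(unique) >= params.min_repertoire_unique
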