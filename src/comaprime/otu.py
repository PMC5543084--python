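"""Pairwise identity and greedy centroid OTU clustering of amplicons.

Amplicon surveys summarise diversity by clustering sequences into operational
taxonomic units (OTUs) at a fixed identity threshold — 95% is the convention
adopted here for comammox amoA fragments.  Identity is computed from a global
alignment with free terminal gaps (matches / aligned columns, terminal-gap
columns excluded), so equal-length indel-free pairs reduce to plain Hamming
identity.

Clustering is greedy centroid clustering: sequences are processed by
descending length (ties broken lexicographically by id); each sequence joins
the highest-identity existing centroid at or above the threshold, else founds
a new cluster.  A final re-assignment pass moves every member to its best
centroid, so the output is stable under a best-centroid re-check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio import Align

__all__ = ["OtuClustering", "pairwise_identity", "cluster_otus"]


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -4.0
    aligner.extend_gap_score = -1.0
    # free end gaps: identity should not punish length differences at the ends
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # Biopython < 1.86 naming
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical positions under global free-end-gap alignment.

    Counted as matches / aligned columns with terminal gap columns excluded;
    symmetric, and 1.0 for identical sequences.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    a, b = a.upper(), b.upper()
    if a == b:
        return 1.0
    aln = _ALIGNER.align(a, b)[0]
    s1, s2 = _gapped_rows(aln)
    # trim terminal-gap columns
    start = 0
    end = len(s1)
    while start < end and (s1[start] == "-" or s2[start] == "-"):
        if s1[start] != "-" and s2[start] != "-":
            break
        start += 1
    while end > start and (s1[end - 1] == "-" or s2[end - 1] == "-"):
        if s1[end - 1] != "-" and s2[end - 1] != "-":
            break
        end -= 1
    cols = end - start
    if cols <= 0:
        return 0.0
    matches = sum(
        1 for i in range(start, end) if s1[i] == s2[i] and s1[i] != "-"
    )
    return matches / cols


def _gapped_rows(aln) -> tuple[str, str]:
    return str(aln[0]), str(aln[1])


@dataclass(frozen=True)
class OtuClustering:
    threshold: float
    clusters: tuple[tuple[str, tuple[str, ...]], ...]  # (centroid_id, member_ids)
    assignments: Mapping[str, int]  # id -> cluster index

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def cluster_otus(
    seqs: Mapping[str, str] | Sequence[tuple[str, str]],
    threshold: float = 0.95,
) -> OtuClustering:
    """Greedy centroid clustering at a fixed identity threshold.

    Processing order: descending sequence length, ties lexicographic by id.
    After centroid selection, every member is re-assigned to its
    highest-identity centroid (>= threshold guaranteed), so re-checking
    assignments changes nothing.  Clusters are disjoint and exhaustive, and
    every member has identity >= threshold to its centroid.
    """
    items = list(seqs.items()) if isinstance(seqs, Mapping) else list(seqs)
    if not items:
        raise ValueError("need at least one sequence")
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    ids = [i for i, _ in items]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    by_id = dict(items)
    order = sorted(ids, key=lambda i: (-len(by_id[i]), i))

    centroids: list[str] = []
    for sid in order:
        best_ident = -1.0
        for cid in centroids:
            ident = pairwise_identity(by_id[sid], by_id[cid])
            best_ident = max(best_ident, ident)
        if best_ident < threshold:
            centroids.append(sid)

    members: list[list[str]] = [[] for _ in centroids]
    assignments: dict[str, int] = {}
    for sid in order:
        best_idx, best_ident = -1, -1.0
        for idx, cid in enumerate(centroids):
            ident = (
                1.0 if sid == cid else pairwise_identity(by_id[sid], by_id[cid])
            )
            if ident > best_ident:
                best_idx, best_ident = idx, ident
        members[best_idx].append(sid)
        assignments[sid] = best_idx

    clusters = tuple(
        (cid, tuple(ms)) for cid, ms in zip(centroids, members)
    )
    return OtuClustering(threshold, clusters, assignments)
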