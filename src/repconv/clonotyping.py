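"""Clone assignment within samples and convergent clustering across samples.

Two levels of grouping:

1. **Within-sample clones** — rearrangements sharing V gene, J gene and
   junction nucleotide length are merged by single-linkage when their
   normalized junction Hamming distance is at or below ``nt_threshold``
   (Change-O-style single-nucleotide Hamming model; default 0.15,
   configurable).

2. **Cross-sample convergent clusters** — clones sharing V gene, J gene
   and CDR-H3 amino-acid length are clustered greedily by descending
   abundance, each clone joining the existing cluster whose
   representative has the *highest* CDR-H3 identity >= the threshold
   (CD-HIT accurate-mode semantics, ``-g 1``: best-matching cluster,
   not first-found), otherwise founding a new cluster.  "At least 85%
   identity" is inclusive (identity >= 0.85 clusters).

Because lengths are constrained equal inside a bucket, identity is
positional: matching positions / length, with no alignment step.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np

from .airr_io import Rearrangement, RepertoireSample


class CloneKey(NamedTuple):
    """The (V gene, J gene, CDR-H3 length) bucket that gates sharing."""

    v_gene: str
    j_gene: str
    cdr3_length: int


@dataclass
class Clone:
    """A within-sample clone: one inferred B-cell lineage in one sample."""

    clone_id: str
    sample_id: str
    subject_id: str
    v_gene: str
    j_gene: str
    junction_aa: str
    member_count: int
    umi_total: int
    isotypes: Counter = field(default_factory=Counter)
    mean_shm_percent: float | None = None
    rearrangements: list[Rearrangement] = field(default_factory=list, repr=False)

    @property
    def cdr3_length(self) -> int:
        return len(self.junction_aa)

    @property
    def key(self) -> CloneKey:
        return CloneKey(self.v_gene, self.j_gene, self.cdr3_length)

    @property
    def dominant_isotype(self) -> str:
        """Most frequent member isotype (ties: lexicographically first)."""
        if not self.isotypes:
            return "unknown"
        top = max(self.isotypes.values())
        return min(iso for iso, n in self.isotypes.items() if n == top)


@dataclass
class ConvergentCluster:
    """A shared-clonotype cluster: clones from >= 1 samples matching in
    V/J/length and >= threshold CDR-H3 identity to the representative."""

    cluster_id: str
    key: CloneKey
    representative_aa: str
    members: set[tuple[str, str]] = field(default_factory=set)  # (sample_id, clone_id)
    carrier_samples: set[str] = field(default_factory=set)
    carrier_subjects: set[str] = field(default_factory=set)


def cdr3_identity(a: str, b: str) -> float:
    """Positional amino-acid identity between equal-length CDR-H3 strings.

    Equals 1 - Hamming/length; symmetric.  Unequal lengths violate the
    key-bucketing contract and raise.
    """
    if len(a) != len(b):
        raise ValueError(
            f"cdr3_identity requires equal lengths ({len(a)} != {len(b)}); "
            "bucketing by CloneKey was violated"
        )
    if not a:
        raise ValueError("empty CDR-H3")
    return sum(x == y for x, y in zip(a, b)) / len(a)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def assign_clones(
    sample: RepertoireSample, nt_threshold: float = 0.15
) -> list[Clone]:
    """Group a sample's rearrangements into clones.

    Rearrangements are bucketed by (V gene, J gene, junction nucleotide
    length); within a bucket, pairs whose normalized junction Hamming
    distance is <= ``nt_threshold`` are merged by single-linkage into one
    clone (chains connect: A-B and B-C close implies {A,B,C} even when
    A-C is distant).  Singletons form their own clones.

    The representative ``junction_aa`` is the member with the highest
    ``umi_count`` (ties: lexicographically smallest junction_aa).  Clone
    ids are deterministic and independent of input row order.
    """
    if not (0.0 <= nt_threshold <= 1.0):
        raise ValueError("nt_threshold must lie in [0, 1]")
    buckets: dict[tuple[str, str, int], list[Rearrangement]] = {}
    for r in sample.rearrangements:
        buckets.setdefault((r.v_gene, r.j_gene, len(r.junction_nt)), []).append(r)

    clusters: list[list[Rearrangement]] = []
    for (v, j, nt_len), members in buckets.items():
        # order-independent: sort members before pairing
        members = sorted(members, key=lambda r: (r.junction_nt, r.sequence_id))
        uf = _UnionFind(len(members))
        max_mismatches = nt_threshold * nt_len + 1e-9  # guard float rounding
        for i in range(len(members)):
            for k in range(i + 1, len(members)):
                if _hamming(members[i].junction_nt, members[k].junction_nt) <= max_mismatches:
                    uf.union(i, k)
        groups: dict[int, list[Rearrangement]] = {}
        for idx, r in enumerate(members):
            groups.setdefault(uf.find(idx), []).append(r)
        clusters.extend(groups.values())

    # deterministic clone ids: sort clusters by their smallest sequence_id
    clusters.sort(key=lambda ms: min(r.sequence_id for r in ms))
    clones = []
    for n, members in enumerate(clusters):
        rep = min(members, key=lambda r: (-r.umi_count, r.junction_aa, r.sequence_id))
        clones.append(
            Clone(
                clone_id=f"{sample.sample_id}.c{n:05d}",
                sample_id=sample.sample_id,
                subject_id=sample.subject_id,
                v_gene=rep.v_gene,
                j_gene=rep.j_gene,
                junction_aa=rep.junction_aa,
                member_count=len(members),
                umi_total=sum(r.umi_count for r in members),
                isotypes=Counter(r.isotype for r in members),
                rearrangements=list(members),
            )
        )
    return clones


def clone_sort_key(clone: Clone) -> tuple:
    """Processing order for greedy clustering and top-n truncation:
    descending UMI total, descending member count, then lexicographic
    junction and ids so the order is total and permutation-stable."""
    return (
        -clone.umi_total,
        -clone.member_count,
        clone.junction_aa,
        clone.sample_id,
        clone.clone_id,
    )


def cluster_convergent(
    clones: Iterable[Clone], threshold: float = 0.85
) -> list[ConvergentCluster]:
    """Cluster clones from many samples into convergent clusters.

    Within each (V, J, CDR-H3 length) bucket, clones are processed in
    the order of :func:`clone_sort_key`; each joins the existing
    cluster whose representative has the highest identity >= threshold
    (earliest-founded cluster on exact identity ties) or founds a new
    cluster with itself as representative.  Deterministic given the
    total ordering, hence stable under input permutation.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("identity threshold must lie in (0, 1]")
    buckets: dict[CloneKey, list[Clone]] = {}
    for c in clones:
        buckets.setdefault(c.key, []).append(c)

    out: list[ConvergentCluster] = []
    for key in sorted(buckets):
        ordered = sorted(buckets[key], key=clone_sort_key)
        reps: list[str] = []
        cluster_members: list[list[Clone]] = []
        rep_matrix: np.ndarray | None = None  # reps x length uint8 codes
        length = key.cdr3_length
        for clone in ordered:
            best_i, best_ident = -1, -1.0
            if reps:
                codes = np.frombuffer(clone.junction_aa.encode(), dtype=np.uint8)
                idents = (rep_matrix == codes).mean(axis=1)
                i = int(np.argmax(idents))  # argmax takes earliest on ties
                if idents[i] >= threshold - 1e-12 and idents[i] > best_ident:
                    best_i, best_ident = i, float(idents[i])
            if best_i >= 0:
                cluster_members[best_i].append(clone)
            else:
                reps.append(clone.junction_aa)
                cluster_members.append([clone])
                row = np.frombuffer(clone.junction_aa.encode(), dtype=np.uint8)
                rep_matrix = (
                    row[None, :]
                    if rep_matrix is None
                    else np.vstack([rep_matrix, row])
                )
        for i, members in enumerate(cluster_members):
            cluster = ConvergentCluster(
                cluster_id=f"{key.v_gene}|{key.j_gene}|{length}|{i:04d}",
                key=key,
                representative_aa=reps[i],
                members={(c.sample_id, c.clone_id) for c in members},
                carrier_samples={c.sample_id for c in members},
                carrier_subjects={c.subject_id for c in members},
            )
            # post-hoc invariant: every member within the identity radius
            for c in members:
                assert cdr3_identity(c.junction_aa, cluster.representative_aa) >= threshold - 1e-12
            out.append(cluster)
    return out
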