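"""Shared test fixtures-in-code: clone builders and independent oracles.

The oracles deliberately re-derive results with plain-Python loops and
explicit matrices so they stay independent of the vectorised library
paths they check.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from itertools import combinations

import numpy as np
from scipy.stats import rankdata

from repconv import Clone, Rearrangement, RepertoireSample


def make_rearrangement(
    seq_id="r1",
    v="IGHV1-1*01",
    j="IGHJ4*01",
    junction_aa="CARDYW",
    junction_nt=None,
    isotype="IGHM",
    umi=1,
    obs=None,
    germ=None,
) -> Rearrangement:
    return Rearrangement(
        sequence_id=seq_id,
        v_call=v,
        j_call=j,
        junction_aa=junction_aa,
        junction_nt=junction_nt if junction_nt is not None else "ACG" * len(junction_aa),
        isotype=isotype,
        umi_count=umi,
        v_sequence_alignment=obs,
        v_germline_alignment=germ,
    )


def make_clone(
    junction_aa,
    sample="s1",
    subject=None,
    v="IGHV1-1",
    j="IGHJ4",
    umi=1,
    members=1,
    isotype="IGHM",
    clone_id=None,
    shm=None,
) -> Clone:
    return Clone(
        clone_id=clone_id or f"{sample}:{junction_aa}:{umi}",
        sample_id=sample,
        subject_id=subject or sample,
        v_gene=v,
        j_gene=j,
        junction_aa=junction_aa,
        member_count=members,
        umi_total=umi,
        isotypes=Counter({isotype: members}),
        mean_shm_percent=shm,
    )


def make_sample(rearrangements, sample_id="s1", subject=None, group="", tissue="LN"):
    return RepertoireSample(
        sample_id=sample_id,
        subject_id=subject or sample_id,
        tissue=tissue,
        group=group,
        rearrangements=list(rearrangements),
    )


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def oracle_identity(a: str, b: str) -> float:
    assert len(a) == len(b)
    return sum(x == y for x, y in zip(a, b)) / len(a)


def oracle_greedy_clusters(clones, threshold=0.85):
    """Brute-force best-representative greedy clustering.

    Same processing order as the library (abundance-descending with the
    full tie-break chain), but membership decided through an explicit
    per-bucket identity computation in pure Python.  Returns a set of
    frozensets of (sample_id, clone_id).
    """
    buckets = defaultdict(list)
    for c in clones:
        buckets[(c.v_gene, c.j_gene, len(c.junction_aa))].append(c)
    result = set()
    for members in buckets.values():
        order = sorted(
            members,
            key=lambda c: (-c.umi_total, -c.member_count, c.junction_aa, c.sample_id, c.clone_id),
        )
        clusters = []  # [representative_aa, [clones]]
        for c in order:
            best, best_ident = None, -1.0
            for entry in clusters:
                ident = oracle_identity(c.junction_aa, entry[0])
                if ident >= threshold - 1e-12 and ident > best_ident:
                    best, best_ident = entry, ident
            if best is None:
                clusters.append([c.junction_aa, [c]])
            else:
                best[1].append(c)
        for _, cs in clusters:
            result.add(frozenset((x.sample_id, x.clone_id) for x in cs))
    return result


def oracle_single_linkage(strings, threshold):
    """Connected components under normalized Hamming <= threshold,
    grown by naive frontier expansion."""
    n = len(strings)
    close = [
        [
            sum(a != b for a, b in zip(strings[i], strings[j])) / len(strings[i])
            <= threshold + 1e-9
            for j in range(n)
        ]
        for i in range(n)
    ]
    unseen = set(range(n))
    components = []
    while unseen:
        frontier = {unseen.pop()}
        comp = set(frontier)
        while frontier:
            nxt = {
                j for i in frontier for j in list(unseen) if close[i][j]
            }
            unseen -= nxt
            comp |= nxt
            frontier = nxt
        components.append(frozenset(comp))
    return set(components)


def oracle_ranksum_p(x, y, alternative="two-sided"):
    """Exact rank-sum p by full enumeration over pooled midranks."""
    x, y = list(x), list(y)
    pooled = np.asarray(x + y, dtype=float)
    ranks = rankdata(pooled)
    n = len(x)
    w_obs = ranks[:n].sum()
    total = ge = le = 0
    for chosen in combinations(range(len(pooled)), n):
        w = ranks[list(chosen)].sum()
        total += 1
        if w >= w_obs - 1e-9:
            ge += 1
        if w <= w_obs + 1e-9:
            le += 1
    p_greater, p_less = ge / total, le / total
    if alternative == "greater":
        return p_greater
    if alternative == "less":
        return p_less
    return min(1.0, 2 * min(p_greater, p_less))


def oracle_derive_list(case_clones_by_sample, control_clones_by_sample,
                       min_case_carriers=2, top_n=None, threshold=0.85):
    """Disease-list derivation by direct enumeration: joint greedy
    clustering (oracle implementation), then the presence/absence rule
    applied with explicit loops.  Returns retained clusters as
    frozensets of (sample_id, clone_id)."""
    pool = []
    lookup = {}
    for sid, clones in case_clones_by_sample.items():
        kept = (
            sorted(clones, key=lambda c: (-c.umi_total, -c.member_count,
                                          c.junction_aa, c.sample_id, c.clone_id))[:top_n]
            if top_n is not None
            else list(clones)
        )
        pool.extend(kept)
        for c in kept:
            lookup[(c.sample_id, c.clone_id)] = c
    for sid, clones in control_clones_by_sample.items():
        pool.extend(clones)
        for c in clones:
            lookup[(c.sample_id, c.clone_id)] = c
    case_samples = set(case_clones_by_sample)
    retained = set()
    for cluster in oracle_greedy_clusters(pool, threshold):
        case_subjects = set()
        has_control = False
        for sid, cid in cluster:
            if sid in case_samples:
                case_subjects.add(lookup[(sid, cid)].subject_id)
            else:
                has_control = True
        if not has_control and len(case_subjects) >= min_case_carriers:
            retained.add(cluster)
    return retained
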