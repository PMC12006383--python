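"""Sharing statistics, disease-associated clone lists, and enrichment.

The quantities here drive the case/control questions:

* ``subsampled_sharing`` — depth-matched sharing: repeatedly draw a
  fixed number of patients and a fixed number of unique clones per
  patient, cluster the union, and count clusters carried by two or more
  patients (reported per iteration, so depth differences between
  repertoires cannot masquerade as convergence).
* ``derive_disease_list`` — clusters present in at least
  ``min_case_carriers`` case subjects and absent from every control
  (absence judged at the cluster level after joint clustering: a
  near-identical control clone disqualifies the cluster), optionally
  after restricting each case sample to its top-n most expanded clones.
* ``score_enrichment`` — per-sample proportion of clones (or of UMIs)
  matching a derived list.
* ``compare_groups`` — unpaired two-sample rank-sum (Mann-Whitney)
  test: exact enumeration for combined n <= 12 (ties handled through
  midrank-equivalent pair counting), normal approximation with tie
  correction otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .clonotyping import (
    Clone,
    CloneKey,
    ConvergentCluster,
    cdr3_identity,
    clone_sort_key,
    cluster_convergent,
)

logger = logging.getLogger("repconv")


# ---------------------------------------------------------------------------
# rank-sum test
# ---------------------------------------------------------------------------

#: Largest combined sample size handled by exact enumeration.
EXACT_ENUMERATION_MAX_N = 12

_SIDEDNESS = {"two-sided", "greater", "less", "one-sided"}


@dataclass
class RankSumResult:
    statistic: float  # Mann-Whitney U of the first group
    pvalue: float
    method: str  # "exact" | "asymptotic" | "degenerate"
    sidedness: str
    note: str = ""


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for x against y: pairs x>y plus half-credit for ties."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def compare_groups(
    values_by_group: Mapping[str, Sequence[float]],
    sidedness: str = "two-sided",
) -> RankSumResult:
    """Unpaired two-sample rank-sum (Mann-Whitney) test.

    ``sidedness='greater'`` (alias ``'one-sided'``) tests whether the
    first-listed group tends to exceed the second.  For combined
    n <= 12 the null distribution of U is enumerated over every
    assignment of pooled values to groups (exact even with ties);
    larger samples use the normal approximation with tie correction
    and continuity correction.  All-identical inputs give p = 1.
    """
    if sidedness not in _SIDEDNESS:
        raise ValueError(f"sidedness must be one of {sorted(_SIDEDNESS)}")
    alternative = "greater" if sidedness == "one-sided" else sidedness
    if len(values_by_group) != 2:
        raise ValueError("compare_groups requires exactly two groups")
    (name_x, vx), (name_y, vy) = values_by_group.items()
    x = np.asarray(list(vx), dtype=float)
    y = np.asarray(list(vy), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("each group needs at least one value")

    u_obs = _u_statistic(x, y)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return RankSumResult(
            statistic=u_obs,
            pvalue=1.0,
            method="degenerate",
            sidedness=alternative,
            note=f"all values identical across {name_x} and {name_y}",
        )

    n, m = len(x), len(y)
    if n + m <= EXACT_ENUMERATION_MAX_N:
        total = comb(n + m, n)
        n_ge = n_le = 0
        idx_all = range(n + m)
        for chosen in combinations(idx_all, n):
            mask = np.zeros(n + m, dtype=bool)
            mask[list(chosen)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            if u >= u_obs - 1e-12:
                n_ge += 1
            if u <= u_obs + 1e-12:
                n_le += 1
        p_greater = n_ge / total
        p_less = n_le / total
        if alternative == "greater":
            p = p_greater
        elif alternative == "less":
            p = p_less
        else:
            p = min(1.0, 2.0 * min(p_greater, p_less))
        return RankSumResult(u_obs, p, "exact", alternative)

    res = stats.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
    return RankSumResult(u_obs, float(res.pvalue), "asymptotic", alternative)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg FDR adjustment."""
    return stats.false_discovery_control(np.asarray(pvalues, dtype=float), method="bh")


# ---------------------------------------------------------------------------
# subsampled sharing
# ---------------------------------------------------------------------------


def _filter_stratum(clones: Sequence[Clone], stratum: str | None) -> list[Clone]:
    if stratum is None:
        return list(clones)
    return [c for c in clones if c.dominant_isotype == stratum]


def subsampled_sharing(
    clones_by_patient: Mapping[str, Sequence[Clone]],
    n_patients: int,
    n_clones: int,
    n_iter: int,
    stratum: str | None = None,
    seed: int = 0,
    threshold: float = 0.85,
    group: str = "",
) -> pd.DataFrame:
    """Depth-matched sharing by repeated subsampling.

    Per iteration: draw ``n_patients`` eligible patients uniformly
    without replacement, draw ``n_clones`` unique clones per patient
    without replacement, cluster the union and count clusters present
    in >= 2 distinct patients.  Patients with fewer than ``n_clones``
    unique clones in the stratum are excluded (and logged) rather than
    resampled with replacement.  Deterministic given ``seed``
    (per-iteration spawned substreams).

    Returns a tidy frame: group, stratum, iteration, n_patients_drawn,
    n_clones_per_patient, shared_clone_count.
    """
    eligible: dict[str, list[Clone]] = {}
    for patient, clones in clones_by_patient.items():
        in_stratum = _filter_stratum(clones, stratum)
        if len(in_stratum) >= n_clones:
            eligible[patient] = in_stratum
        else:
            logger.info(
                "subsampled_sharing: patient %s excluded "
                "(%d < %d unique clones in stratum %s)",
                patient,
                len(in_stratum),
                n_clones,
                stratum or "all",
            )
    if len(eligible) < n_patients:
        raise ValueError(
            f"only {len(eligible)} patients have >= {n_clones} unique clones "
            f"in stratum {stratum or 'all'}; {n_patients} required"
        )

    patients = sorted(eligible)
    rows = []
    substreams = np.random.SeedSequence(seed).spawn(n_iter)
    for it, ss in enumerate(substreams):
        rng = np.random.default_rng(ss)
        drawn = [patients[i] for i in rng.choice(len(patients), n_patients, replace=False)]
        union: list[Clone] = []
        for patient in drawn:
            pool = eligible[patient]
            idx = rng.choice(len(pool), n_clones, replace=False)
            union.extend(pool[i] for i in idx)
        clusters = cluster_convergent(union, threshold=threshold)
        shared = sum(1 for cl in clusters if len(cl.carrier_subjects) >= 2)
        rows.append(
            {
                "group": group,
                "stratum": stratum or "all",
                "iteration": it,
                "n_patients_drawn": n_patients,
                "n_clones_per_patient": n_clones,
                "shared_clone_count": shared,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# disease-associated clone lists
# ---------------------------------------------------------------------------


@dataclass
class DiseaseClonotypeList:
    """Convergent clusters present in >= min_case_carriers case subjects
    and absent (at cluster level) from every control sample."""

    list_id: str
    case_group: str
    control_groups: tuple[str, ...]
    min_case_carriers: int
    refinement: str  # "none" or "top_n_expanded(n=...)"
    threshold: float
    clusters: list[ConvergentCluster] = field(default_factory=list)
    #: case-carrier subject count per cluster_id, frozen at derivation.
    case_carrier_counts: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.clusters)

    def by_key(self) -> dict[CloneKey, list[ConvergentCluster]]:
        index: dict[CloneKey, list[ConvergentCluster]] = {}
        for cl in self.clusters:
            index.setdefault(cl.key, []).append(cl)
        return index

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cluster_id": cl.cluster_id,
                "v_gene": cl.key.v_gene,
                "j_gene": cl.key.j_gene,
                "cdr3_length": cl.key.cdr3_length,
                "representative_aa": cl.representative_aa,
                "n_case_carriers": self.case_carrier_counts.get(cl.cluster_id, 0),
            }
            for cl in self.clusters
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "cluster_id",
                "v_gene",
                "j_gene",
                "cdr3_length",
                "representative_aa",
                "n_case_carriers",
            ],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls, path: str | Path, list_id: str = "", threshold: float = 0.85
    ) -> "DiseaseClonotypeList":
        df = pd.read_csv(path, sep="\t", dtype={"cdr3_length": int})
        clusters = [
            ConvergentCluster(
                cluster_id=str(rec["cluster_id"]),
                key=CloneKey(str(rec["v_gene"]), str(rec["j_gene"]), int(rec["cdr3_length"])),
                representative_aa=str(rec["representative_aa"]),
            )
            for rec in df.to_dict("records")
        ]
        counts = {
            str(rec["cluster_id"]): int(rec.get("n_case_carriers", 0))
            for rec in df.to_dict("records")
        }
        return cls(
            list_id=list_id or Path(path).stem,
            case_group="",
            control_groups=(),
            min_case_carriers=2,
            refinement="unknown",
            threshold=threshold,
            clusters=clusters,
            case_carrier_counts=counts,
        )


def top_expanded(clones: Sequence[Clone], top_n: int) -> list[Clone]:
    """A sample's top-n most expanded clones (by UMI total, ties by
    member count then lexicographic junction)."""
    return sorted(clones, key=clone_sort_key)[:top_n]


def derive_disease_list(
    case_clones_by_sample: Mapping[str, Sequence[Clone]],
    control_clones_by_sample: Mapping[str, Sequence[Clone]],
    min_case_carriers: int = 2,
    top_n: int | None = None,
    threshold: float = 0.85,
    list_id: str = "disease_list",
    case_group: str = "case",
    control_groups: tuple[str, ...] = ("control",),
) -> DiseaseClonotypeList:
    """Derive the disease-associated clone list.

    Case and control clones are clustered jointly; retained clusters
    have >= ``min_case_carriers`` distinct case *subjects* and no
    control member at all (a control clone inside the 85% radius
    disqualifies the cluster).  With ``top_n``, each case sample is
    first truncated to its top-n expanded clones; controls are never
    truncated (absence must hold against the full control repertoire).
    """
    if not case_clones_by_sample:
        raise ValueError("empty case set")
    if min_case_carriers < 2:
        raise ValueError("min_case_carriers must be >= 2 (sharing needs two carriers)")

    case_samples = set(case_clones_by_sample)
    pool: list[Clone] = []
    for sid, clones in case_clones_by_sample.items():
        kept = top_expanded(clones, top_n) if top_n is not None else list(clones)
        pool.extend(kept)
    for sid, clones in control_clones_by_sample.items():
        pool.extend(clones)

    clusters = cluster_convergent(pool, threshold=threshold)
    retained: list[ConvergentCluster] = []
    counts: dict[str, int] = {}
    for cl in clusters:
        case_subjects = set()
        has_control = False
        for sample_id, clone_id in cl.members:
            if sample_id in case_samples:
                case_subjects.update(
                    c.subject_id
                    for c in case_clones_by_sample[sample_id]
                    if c.clone_id == clone_id
                )
            else:
                has_control = True
        if has_control or len(case_subjects) < min_case_carriers:
            continue
        retained.append(cl)
        counts[cl.cluster_id] = len(case_subjects)

    refinement = "none" if top_n is None else f"top_n_expanded(n={top_n})"
    logger.info(
        "derive_disease_list %s: %d clusters retained of %d "
        "(cases=%d samples, controls=%d samples, refinement=%s)",
        list_id,
        len(retained),
        len(clusters),
        len(case_clones_by_sample),
        len(control_clones_by_sample),
        refinement,
    )
    return DiseaseClonotypeList(
        list_id=list_id,
        case_group=case_group,
        control_groups=tuple(control_groups),
        min_case_carriers=min_case_carriers,
        refinement=refinement,
        threshold=threshold,
        clusters=retained,
        case_carrier_counts=counts,
    )


def evaluate_against_planted(
    dlist: DiseaseClonotypeList,
    prototypes: Mapping[str, tuple[str, str, str]],
    threshold: float = 0.85,
) -> dict:
    """Score a derived list against planted ground truth.

    A planted clone (``id -> (v_gene, j_gene, prototype junction)``)
    counts as recovered when some retained cluster matches its key and
    its representative is within the identity radius of the prototype;
    retained clusters matching no prototype are false positives.
    Returns recovered/missed planted ids, false-positive cluster ids
    and the recall fraction.
    """
    recovered, missed = set(), set()
    matched_clusters: set[str] = set()
    for pid, (v, j, proto) in prototypes.items():
        key = CloneKey(v, j, len(proto))
        hit = False
        for cl in dlist.clusters:
            if cl.key == key and cdr3_identity(cl.representative_aa, proto) >= threshold - 1e-12:
                hit = True
                matched_clusters.add(cl.cluster_id)
        (recovered if hit else missed).add(pid)
    false_pos = sorted(
        cl.cluster_id for cl in dlist.clusters if cl.cluster_id not in matched_clusters
    )
    recall = len(recovered) / len(prototypes) if prototypes else float("nan")
    return {
        "recovered": sorted(recovered),
        "missed": sorted(missed),
        "false_positive_clusters": false_pos,
        "recall": recall,
    }


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------


def clone_matches_list(
    clone: Clone, index: Mapping[CloneKey, Sequence[ConvergentCluster]], threshold: float
) -> bool:
    """Membership rule: key equality plus >= threshold identity to a
    stored cluster representative."""
    for cl in index.get(clone.key, ()):
        if cdr3_identity(clone.junction_aa, cl.representative_aa) >= threshold - 1e-12:
            return True
    return False


def score_enrichment(
    dlist: DiseaseClonotypeList,
    query_clones_by_sample: Mapping[str, Sequence[Clone]],
    weight: str = "clone",
    by_isotype: bool = False,
) -> pd.DataFrame:
    """Per-sample proportion of clones (or UMIs) matching the list.

    ``weight='clone'`` counts each unique clone once
    (matched clones / total clones); ``weight='umi'`` weights by
    abundance (matched UMI sum / total UMI sum).  With ``by_isotype``
    each isotype stratum is scored separately ('unknown' excluded);
    empty strata are omitted with a log notice, never reported as 0/0.
    """
    if weight not in {"clone", "umi"}:
        raise ValueError("weight must be 'clone' or 'umi'")
    index = dlist.by_key()
    rows = []
    for sample_id in sorted(query_clones_by_sample):
        clones = list(query_clones_by_sample[sample_id])
        strata = (
            sorted({c.dominant_isotype for c in clones} - {"unknown"})
            if by_isotype
            else [None]
        )
        for stratum in strata:
            subset = _filter_stratum(clones, stratum)
            if not subset:
                logger.info(
                    "score_enrichment: sample %s has no clones in stratum %s; omitted",
                    sample_id,
                    stratum or "all",
                )
                continue
            matched = [c for c in subset if clone_matches_list(c, index, dlist.threshold)]
            if weight == "clone":
                num, den = len(matched), len(subset)
            else:
                num = sum(c.umi_total for c in matched)
                den = sum(c.umi_total for c in subset)
            rows.append(
                {
                    "sample_id": sample_id,
                    "stratum": stratum or "all",
                    "weight": weight,
                    "matched": num,
                    "total": den,
                    "proportion": num / den,
                }
            )
    return pd.DataFrame(
        rows, columns=["sample_id", "stratum", "weight", "matched", "total", "proportion"]
    )


def enrichment_group_test(
    enrichment: pd.DataFrame,
    group_of_sample: Mapping[str, str],
    case_group: str,
    control_group: str,
    sidedness: str = "greater",
) -> pd.DataFrame:
    """Rank-sum comparison of enrichment proportions, per stratum, with
    Benjamini-Hochberg correction across strata when several are tested."""
    rows = []
    for stratum, sub in enrichment.groupby("stratum"):
        groups = sub["sample_id"].map(group_of_sample)
        case_vals = sub.loc[groups == case_group, "proportion"].tolist()
        ctrl_vals = sub.loc[groups == control_group, "proportion"].tolist()
        if not case_vals or not ctrl_vals:
            continue
        res = compare_groups({case_group: case_vals, control_group: ctrl_vals}, sidedness)
        rows.append(
            {
                "stratum": stratum,
                "n_case": len(case_vals),
                "n_control": len(ctrl_vals),
                "median_case": float(np.median(case_vals)),
                "median_control": float(np.median(ctrl_vals)),
                "statistic": res.statistic,
                "pvalue": res.pvalue,
                "method": res.method,
                "sidedness": res.sidedness,
            }
        )
    out = pd.DataFrame(rows)
    if len(out) > 1:
        out["p_adj_bh"] = bh_adjust(out["pvalue"].to_numpy())
    elif len(out) == 1:
        out["p_adj_bh"] = out["pvalue"]
    return out


# ---------------------------------------------------------------------------
# dominant clones
# ---------------------------------------------------------------------------


def dominant_clone_tally(
    dlist: DiseaseClonotypeList,
    query_clones_by_sample: Mapping[str, Sequence[Clone]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank listed clusters by carrier-sample count.

    Returns ``(tally, membership)``: the tally sorted by descending
    carrier count (ties: cluster_id) and an upset-style boolean
    membership matrix (samples x clusters).
    """
    index = dlist.by_key()
    sample_ids = sorted(query_clones_by_sample)
    membership = pd.DataFrame(
        False, index=sample_ids, columns=[cl.cluster_id for cl in dlist.clusters]
    )
    for sample_id in sample_ids:
        for clone in query_clones_by_sample[sample_id]:
            for cl in index.get(clone.key, ()):
                if (
                    cdr3_identity(clone.junction_aa, cl.representative_aa)
                    >= dlist.threshold - 1e-12
                ):
                    membership.loc[sample_id, cl.cluster_id] = True
    tally = (
        membership.sum(axis=0)
        .rename("carrier_count")
        .rename_axis("cluster_id")
        .reset_index()
        .sort_values(["carrier_count", "cluster_id"], ascending=[False, True])
        .reset_index(drop=True)
    )
    return tally, membership
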