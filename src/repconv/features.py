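"""Somatic hypermutation, isotype composition and gene-usage statistics.

SHM is the percent mismatch between the observed V region and its
germline over comparable positions (CDR1/2 + framework; positions where
either string carries a gap or N are excluded from numerator and
denominator alike).  The unit of analysis follows the two-step
averaging used throughout: per-sequence values are averaged to a
clone-level mean first, then clone-level means are averaged per sample
(and isotype), so expanded clones do not dominate sample summaries.
Gene usage is always counted at unique-clone level — each VDJ
rearrangement once, never read/UMI-weighted — so differential mRNA
content between isotypes cannot skew proportions.
"""

from __future__ import annotations

import logging
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .airr_io import Rearrangement
from .clonotyping import Clone
from .convergence import (
    DiseaseClonotypeList,
    bh_adjust,
    clone_matches_list,
    compare_groups,
)

logger = logging.getLogger("repconv")

#: Characters excluded from SHM comparison (gaps and ambiguous bases).
_MASK_CHARS = set(".-Nn")

#: Clones below this SHM percent count as lowly mutated (strict <).
LOWLY_MUTATED_THRESHOLD = 1.0


def compute_shm(r: Rearrangement) -> float | None:
    """Percent mismatch of the V region to germline.

    100 x mismatching comparable positions / comparable positions,
    where a position is comparable when neither string has a gap/N
    there.  Returns None (record skipped, with notice) when the
    alignment pair is absent or has zero comparable positions.
    """
    obs, germ = r.v_sequence_alignment, r.v_germline_alignment
    if obs is None or germ is None:
        return None
    if len(obs) != len(germ):
        raise ValueError(
            f"alignment length mismatch for {r.sequence_id}: {len(obs)} != {len(germ)}"
        )
    comparable = mismatch = 0
    for a, b in zip(obs, germ):
        if a in _MASK_CHARS or b in _MASK_CHARS:
            continue
        comparable += 1
        if a != b:
            mismatch += 1
    if comparable == 0:
        logger.info("compute_shm: %s has zero comparable positions; skipped", r.sequence_id)
        return None
    return 100.0 * mismatch / comparable


def annotate_clone_shm(clones: Sequence[Clone]) -> None:
    """Fill each clone's ``mean_shm_percent`` with the mean over members
    (members without a computable value are skipped)."""
    for clone in clones:
        vals = [v for v in (compute_shm(r) for r in clone.rearrangements) if v is not None]
        clone.mean_shm_percent = float(np.mean(vals)) if vals else None


def shm_records(clones_by_sample: Mapping[str, Sequence[Clone]]) -> pd.DataFrame:
    """Clone-level SHM table: one row per clone with a computable value.

    Columns: clone_id, sample_id, subject_id, isotype (dominant member
    isotype), shm_percent, lowly_mutated (< 1%).
    """
    rows = []
    for sample_id in sorted(clones_by_sample):
        clones = clones_by_sample[sample_id]
        annotate_clone_shm(clones)
        for clone in clones:
            if clone.mean_shm_percent is None:
                continue
            rows.append(
                {
                    "clone_id": clone.clone_id,
                    "sample_id": sample_id,
                    "subject_id": clone.subject_id,
                    "isotype": clone.dominant_isotype,
                    "shm_percent": clone.mean_shm_percent,
                    "lowly_mutated": clone.mean_shm_percent < LOWLY_MUTATED_THRESHOLD,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["clone_id", "sample_id", "subject_id", "isotype", "shm_percent", "lowly_mutated"],
    )


def shm_by_isotype(clones_by_sample: Mapping[str, Sequence[Clone]]) -> pd.DataFrame:
    """Per-sample, per-isotype mean SHM and lowly-mutated clone fraction.

    Clone-level means first, then the unweighted mean over clones per
    sample and isotype ('unknown' isotype excluded).  Empty strata are
    simply absent from the output.
    """
    records = shm_records(clones_by_sample)
    records = records[records["isotype"] != "unknown"]
    if records.empty:
        return pd.DataFrame(
            columns=["sample_id", "isotype", "n_clones", "mean_shm_percent", "lowly_mutated_fraction"]
        )
    out = (
        records.groupby(["sample_id", "isotype"], as_index=False)
        .agg(
            n_clones=("clone_id", "size"),
            mean_shm_percent=("shm_percent", "mean"),
            lowly_mutated_fraction=("lowly_mutated", "mean"),
        )
        .sort_values(["sample_id", "isotype"])
        .reset_index(drop=True)
    )
    return out


def shm_isotype_group_test(
    summary: pd.DataFrame,
    group_of_sample: Mapping[str, str],
    group_a: str,
    group_b: str,
    column: str = "mean_shm_percent",
    sidedness: str = "two-sided",
) -> pd.DataFrame:
    """Per-isotype rank-sum comparison of sample-level SHM summaries,
    BH-corrected across isotypes."""
    rows = []
    for isotype, sub in summary.groupby("isotype"):
        groups = sub["sample_id"].map(group_of_sample)
        a = sub.loc[groups == group_a, column].tolist()
        b = sub.loc[groups == group_b, column].tolist()
        if not a or not b:
            continue
        res = compare_groups({group_a: a, group_b: b}, sidedness)
        rows.append(
            {
                "isotype": isotype,
                "n_a": len(a),
                "n_b": len(b),
                "median_a": float(np.median(a)),
                "median_b": float(np.median(b)),
                "statistic": res.statistic,
                "pvalue": res.pvalue,
                "method": res.method,
            }
        )
    out = pd.DataFrame(rows)
    if len(out) > 1:
        out["p_adj_bh"] = bh_adjust(out["pvalue"].to_numpy())
    elif len(out) == 1:
        out["p_adj_bh"] = out["pvalue"]
    return out


def shm_assoc_vs_nonassoc(
    dlist: DiseaseClonotypeList,
    clones_by_sample: Mapping[str, Sequence[Clone]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """SHM of list-matching vs non-matching clones, per isotype.

    Unit: one value per unique clone per sample (clone-level mean SHM).
    Returns (values, tests): the flagged clone table and per-isotype
    two-sided rank-sum results with BH correction; strata with an empty
    side are omitted.
    """
    index = dlist.by_key()
    records = shm_records(clones_by_sample)
    flags = {}
    for sample_id, clones in clones_by_sample.items():
        for clone in clones:
            flags[(sample_id, clone.clone_id)] = clone_matches_list(
                clone, index, dlist.threshold
            )
    records = records.assign(
        associated=[
            flags[(s, c)] for s, c in zip(records["sample_id"], records["clone_id"])
        ]
    )
    records = records[records["isotype"] != "unknown"]

    rows = []
    for isotype, sub in records.groupby("isotype"):
        assoc = sub.loc[sub["associated"], "shm_percent"].tolist()
        nonassoc = sub.loc[~sub["associated"], "shm_percent"].tolist()
        if not assoc or not nonassoc:
            logger.info("shm_assoc_vs_nonassoc: isotype %s has an empty side; omitted", isotype)
            continue
        res = compare_groups({"associated": assoc, "non_associated": nonassoc})
        rows.append(
            {
                "isotype": isotype,
                "n_associated": len(assoc),
                "n_non_associated": len(nonassoc),
                "median_associated": float(np.median(assoc)),
                "median_non_associated": float(np.median(nonassoc)),
                "statistic": res.statistic,
                "pvalue": res.pvalue,
                "method": res.method,
            }
        )
    tests = pd.DataFrame(rows)
    if len(tests) > 1:
        tests["p_adj_bh"] = bh_adjust(tests["pvalue"].to_numpy())
    elif len(tests) == 1:
        tests["p_adj_bh"] = tests["pvalue"]
    return records, tests


# ---------------------------------------------------------------------------
# gene usage
# ---------------------------------------------------------------------------


def gene_usage(
    clones_by_sample: Mapping[str, Sequence[Clone]],
    gene_field: str = "v",
    by_isotype: bool = False,
) -> pd.DataFrame:
    """Unique-clone gene-usage proportions per sample (and stratum).

    Each clone counts once regardless of size.  Proportions sum to 1
    within each sample x stratum.
    """
    if gene_field not in {"v", "j"}:
        raise ValueError("gene_field must be 'v' or 'j'")
    attr = "v_gene" if gene_field == "v" else "j_gene"
    rows = []
    for sample_id in sorted(clones_by_sample):
        clones = list(clones_by_sample[sample_id])
        strata = (
            sorted({c.dominant_isotype for c in clones} - {"unknown"})
            if by_isotype
            else [None]
        )
        for stratum in strata:
            subset = (
                [c for c in clones if c.dominant_isotype == stratum]
                if stratum is not None
                else clones
            )
            if not subset:
                continue
            counts = pd.Series([getattr(c, attr) for c in subset]).value_counts()
            for gene, n in counts.items():
                rows.append(
                    {
                        "sample_id": sample_id,
                        "stratum": stratum or "all",
                        "gene": gene,
                        "n_clones": int(n),
                        "proportion": n / len(subset),
                    }
                )
    return pd.DataFrame(rows, columns=["sample_id", "stratum", "gene", "n_clones", "proportion"])


def usage_difference_index(
    disease_means: Mapping[str, float], control_means: Mapping[str, float]
) -> pd.Series:
    """Per-gene usage-difference index in [-1, 1]:
    (disease - control) / (disease + control) on mean proportions.

    0/0 (gene absent from both) is reported as missing; negative inputs
    are an error.  Antisymmetric under swapping groups.
    """
    genes = sorted(set(disease_means) | set(control_means))
    out = {}
    for g in genes:
        d = float(disease_means.get(g, 0.0))
        c = float(control_means.get(g, 0.0))
        if d < 0 or c < 0:
            raise ValueError(f"negative mean proportion for gene {g}")
        out[g] = np.nan if d + c == 0 else (d - c) / (d + c)
    return pd.Series(out, name="usage_difference_index")


def usage_group_difference(
    usage: pd.DataFrame,
    group_of_sample: Mapping[str, str],
    disease_group: str,
    control_group: str,
) -> pd.DataFrame:
    """Per-gene usage-difference index plus rank-sum test with BH
    correction across genes (the heatmap statistic)."""
    usage = usage.assign(group=usage["sample_id"].map(group_of_sample))
    wide = usage.pivot_table(
        index="sample_id", columns="gene", values="proportion", fill_value=0.0, observed=True
    )
    sample_groups = {s: group_of_sample.get(s) for s in wide.index}
    d_samples = [s for s, g in sample_groups.items() if g == disease_group]
    c_samples = [s for s, g in sample_groups.items() if g == control_group]
    if not d_samples or not c_samples:
        raise ValueError("both groups need at least one sample with usage data")
    idx = usage_difference_index(
        wide.loc[d_samples].mean().to_dict(), wide.loc[c_samples].mean().to_dict()
    )
    rows = []
    for gene in idx.index:
        res = compare_groups(
            {
                disease_group: wide.loc[d_samples, gene].tolist(),
                control_group: wide.loc[c_samples, gene].tolist(),
            }
        )
        rows.append(
            {
                "gene": gene,
                "difference_index": idx[gene],
                "statistic": res.statistic,
                "pvalue": res.pvalue,
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj_bh"] = bh_adjust(out["pvalue"].to_numpy())
    return out


def j_usage_test(
    counts_a: Mapping[str, int], counts_b: Mapping[str, int]
) -> dict:
    """Pearson chi-squared comparison of per-J-gene clone counts.

    Overall statistic on the full genes x 2 contingency table (no
    continuity correction), then a post-hoc pass over all gene pairs as
    2x2 sub-tables with Bonferroni correction (p x number of pairs,
    capped at 1).  An expected cell < 1 attaches a small-sample warning
    but the computation proceeds.
    """
    genes = sorted(g for g in set(counts_a) | set(counts_b)
                   if counts_a.get(g, 0) + counts_b.get(g, 0) > 0)
    if len(genes) < 2:
        raise ValueError("need at least two J genes with nonzero totals")
    table = np.array(
        [[counts_a.get(g, 0) for g in genes], [counts_b.get(g, 0) for g in genes]],
        dtype=float,
    )
    chi2, p, dof, expected = stats.chi2_contingency(table, correction=False)
    warning = "expected cell < 1; chi-squared approximation unreliable" if (expected < 1).any() else ""

    n_pairs = len(genes) * (len(genes) - 1) // 2
    posthoc = []
    for g1, g2 in combinations(genes, 2):
        sub = np.array(
            [
                [counts_a.get(g1, 0), counts_a.get(g2, 0)],
                [counts_b.get(g1, 0), counts_b.get(g2, 0)],
            ],
            dtype=float,
        )
        if sub.sum(axis=0).min() == 0 or sub.sum(axis=1).min() == 0:
            sub_chi2, sub_p = 0.0, 1.0
        else:
            sub_chi2, sub_p, _, _ = stats.chi2_contingency(sub, correction=False)
        posthoc.append(
            {
                "gene_pair": f"{g1} vs {g2}",
                "chi2": float(sub_chi2),
                "pvalue": float(sub_p),
                "p_bonferroni": min(1.0, float(sub_p) * n_pairs),
            }
        )
    return {
        "chi2": float(chi2),
        "pvalue": float(p),
        "dof": int(dof),
        "warning": warning,
        "posthoc": pd.DataFrame(posthoc),
    }


def cdr3_length_compare(
    lengths_a: Sequence[float], lengths_b: Sequence[float]
) -> dict:
    """Mean CDR-H3 lengths of two clone sets with a two-sided rank-sum
    comparison."""
    if len(lengths_a) == 0 or len(lengths_b) == 0:
        raise ValueError("length collections must be nonempty")
    res = compare_groups({"a": list(lengths_a), "b": list(lengths_b)}, "two-sided")
    return {
        "mean_a": float(np.mean(lengths_a)),
        "mean_b": float(np.mean(lengths_b)),
        "difference": float(np.mean(lengths_a) - np.mean(lengths_b)),
        "statistic": res.statistic,
        "pvalue": res.pvalue,
        "method": res.method,
    }


#: Sub-isotype families for within-class composition.
SUBISOTYPE_FAMILIES = {
    "IgA": ("IGHA1", "IGHA2"),
    "IgG": ("IGHG1", "IGHG2", "IGHG3", "IGHG4"),
}


def subisotype_proportions(
    clones_by_sample: Mapping[str, Sequence[Clone]]
) -> pd.DataFrame:
    """Per-sample proportions of unique clones within the IgA (A1/A2)
    and IgG (G1-G4) subclass families.

    Counting is clone-level (each unique VDJ once), so read or UMI
    duplication cannot skew the composition.  A family absent from a
    sample is omitted.
    """
    rows = []
    for sample_id in sorted(clones_by_sample):
        iso_counts = pd.Series(
            [c.dominant_isotype for c in clones_by_sample[sample_id]]
        ).value_counts()
        for family, members in SUBISOTYPE_FAMILIES.items():
            family_total = int(sum(iso_counts.get(m, 0) for m in members))
            if family_total == 0:
                continue
            for m in members:
                rows.append(
                    {
                        "sample_id": sample_id,
                        "family": family,
                        "subclass": m,
                        "n_clones": int(iso_counts.get(m, 0)),
                        "proportion": iso_counts.get(m, 0) / family_total,
                    }
                )
    return pd.DataFrame(
        rows, columns=["sample_id", "family", "subclass", "n_clones", "proportion"]
    )
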