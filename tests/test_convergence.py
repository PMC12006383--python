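"""Sharing statistics, disease-list derivation, enrichment scoring and
the rank-sum test, each checked against ground truth or enumeration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import repconv
from repconv import (
    SimulationConfig,
    assign_clones,
    compare_groups,
    derive_disease_list,
    dominant_clone_tally,
    evaluate_against_planted,
    score_enrichment,
    simulate_dataset,
    subsampled_sharing,
)
from helpers import make_clone, oracle_derive_list, oracle_ranksum_p


def clones_by_sample_from(samples):
    return {s.sample_id: assign_clones(s) for s in samples}


def split_case_control(samples, clones):
    cases = {s.sample_id: clones[s.sample_id] for s in samples if s.group == "case"}
    ctrls = {s.sample_id: clones[s.sample_id] for s in samples if s.group == "control"}
    return cases, ctrls


# ---------------------------------------------------------------------------
# rank-sum test
# ---------------------------------------------------------------------------


class TestCompareGroups:
    def test_extreme_split_two_sided(self):
        res = compare_groups({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert res.method == "exact"
        assert res.pvalue == pytest.approx(0.1)  # 2 x 1/20

    def test_one_sided_is_half_for_extreme_split(self):
        two = compare_groups({"a": [1, 2, 3], "b": [4, 5, 6]}, "two-sided")
        one = compare_groups({"a": [1, 2, 3], "b": [4, 5, 6]}, "less")
        assert one.pvalue == pytest.approx(two.pvalue / 2)

    def test_identical_groups_p_one(self):
        res = compare_groups({"a": [2, 2, 2], "b": [2, 2]})
        assert res.pvalue == 1.0 and res.method == "degenerate"

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.permutation(40)[:5].tolist()
            y = rng.permutation(np.arange(40, 80))[:6].tolist()
            ours = compare_groups({"x": x, "y": y}, "two-sided")
            ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert ours.pvalue == pytest.approx(ref.pvalue, rel=1e-9)

    @given(
        st.lists(st.integers(0, 5), min_size=1, max_size=6),
        st.lists(st.integers(0, 5), min_size=1, max_size=6),
        st.sampled_from(["two-sided", "greater", "less"]),
    )
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_exact_agrees_with_enumeration_oracle(self, x, y, alternative):
        # ties included on purpose: midrank enumeration must agree
        if len(set(x + y)) == 1:
            return
        ours = compare_groups({"x": x, "y": y}, alternative)
        assert ours.pvalue == pytest.approx(oracle_ranksum_p(x, y, alternative))

    def test_asymptotic_path_above_enumeration_limit(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, 30).tolist()
        y = rng.normal(0.8, 1, 30).tolist()
        res = compare_groups({"x": x, "y": y})
        assert res.method == "asymptotic" and res.pvalue < 0.05

    def test_null_pvalues_uniform(self):
        # calibration: under H0 the two-sided p-values are ~ Uniform(0,1)
        rng = np.random.default_rng(17)
        pvals = []
        for _ in range(200):
            x = rng.normal(size=30).tolist()
            y = rng.normal(size=30).tolist()
            pvals.append(compare_groups({"x": x, "y": y}).pvalue)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_requires_two_groups(self):
        with pytest.raises(ValueError, match="two groups"):
            compare_groups({"a": [1]})


# ---------------------------------------------------------------------------
# subsampled sharing
# ---------------------------------------------------------------------------


class TestSubsampledSharing:
    def test_disjoint_keys_share_nothing(self):
        by_patient = {
            f"p{i}": [
                make_clone("CARDYWAAAAAAW", v=f"IGHV{i}-1", sample=f"p{i}", clone_id=f"c{k}")
                for k in range(5)
            ]
            for i in range(4)
        }
        out = subsampled_sharing(by_patient, n_patients=3, n_clones=5, n_iter=4, seed=0)
        assert (out["shared_clone_count"] == 0).all()

    def test_identical_repertoires_share_everything(self):
        junctions = [f"C{c * 11}W" for c in "AEFGH"]  # mutually dissimilar
        by_patient = {
            p: [make_clone(j, sample=p, clone_id=j) for j in junctions]
            for p in ("p1", "p2")
        }
        out = subsampled_sharing(by_patient, n_patients=2, n_clones=5, n_iter=3, seed=1)
        assert (out["shared_clone_count"] == len(junctions)).all()

    def test_patients_below_floor_excluded_and_error_when_too_few(self):
        by_patient = {
            "big": [make_clone(f"CARD{c}WAAAAAAW", sample="big", clone_id=str(i))
                    for i, c in enumerate("AEFGHIKL")],
            "small": [make_clone("CARDYWAAAAAAW", sample="small", clone_id="x")],
        }
        with pytest.raises(ValueError, match="stratum all"):
            subsampled_sharing(by_patient, n_patients=2, n_clones=5, n_iter=2, seed=0)

    def test_planted_sharing_recovered_against_paired_null(self):
        kw = dict(
            n_case_subjects=8,
            n_control_subjects=0,
            clones_per_subject=100,
            public_penetrance=1.0,
            seed=3,
        )
        planted, _ = simulate_dataset(SimulationConfig(public_clone_count=10, **kw))
        null, _ = simulate_dataset(SimulationConfig(public_clone_count=0, **kw))

        def run(samples):
            by_patient = {}
            for s in samples:
                by_patient.setdefault(s.subject_id, []).extend(assign_clones(s))
            return subsampled_sharing(by_patient, 8, 100, n_iter=10, seed=9)

        shared = run(planted)["shared_clone_count"]
        shared_null = run(null)["shared_clone_count"]
        assert (shared >= 10).all()
        excess = shared.mean() - shared_null.mean()
        assert abs(excess - 10) <= 2  # sampling envelope around the 10 planted

    def test_deterministic_given_seed(self):
        by_patient = {
            p: [make_clone(f"CARD{c}WAAAAAAW", sample=p, clone_id=f"{p}{c}") for c in "AEFGH"]
            for p in ("p1", "p2", "p3")
        }
        a = subsampled_sharing(by_patient, 2, 3, 5, seed=4)
        b = subsampled_sharing(by_patient, 2, 3, 5, seed=4)
        assert a.equals(b)

    def test_mean_sharing_monotone_in_clone_depth(self):
        cfg = SimulationConfig(
            n_case_subjects=8,
            n_control_subjects=0,
            clones_per_subject=300,
            public_clone_count=30,
            public_penetrance=0.8,
            seed=6,
        )
        samples, _ = simulate_dataset(cfg)
        by_patient = {}
        for s in samples:
            by_patient.setdefault(s.subject_id, []).extend(assign_clones(s))
        means = [
            subsampled_sharing(by_patient, 6, n, n_iter=10, seed=2)["shared_clone_count"].mean()
            for n in (50, 150, 300)
        ]
        assert means[0] <= means[1] <= means[2]


# ---------------------------------------------------------------------------
# disease-list derivation
# ---------------------------------------------------------------------------


class TestDeriveDiseaseList:
    def _toy(self):
        shared = "CARDYWAAAAAAAW"  # length 14
        cases = {
            f"s{i}": [make_clone(shared, sample=f"s{i}", subject=f"p{i}", clone_id=f"c{i}")]
            for i in range(3)
        }
        return shared, cases

    def test_present_in_cases_absent_in_controls_retained(self):
        _, cases = self._toy()
        dlist = derive_disease_list(cases, {})
        assert len(dlist) == 1
        assert dlist.case_carrier_counts[dlist.clusters[0].cluster_id] == 3

    def test_any_control_member_disqualifies(self):
        shared, cases = self._toy()
        near = shared[:5] + "F" + shared[6:]  # 13/14 identity to shared
        controls = {"hc1": [make_clone(near, sample="hc1", subject="hc1", clone_id="k")]}
        assert len(derive_disease_list(cases, controls)) == 0

    def test_min_carriers_enforced(self):
        _, cases = self._toy()
        two_only = {k: v for k, v in list(cases.items())[:2]}
        assert len(derive_disease_list(two_only, {}, min_case_carriers=3)) == 0
        with pytest.raises(ValueError, match=">= 2"):
            derive_disease_list(cases, {}, min_case_carriers=1)

    def test_empty_case_set_error(self):
        with pytest.raises(ValueError, match="empty case"):
            derive_disease_list({}, {})

    def test_top_n_refinement_drops_unexpanded(self):
        big = make_clone("CARDYWAAAAAAAW", sample="s1", subject="p1", umi=100, clone_id="big")
        small = make_clone("CTTTYWAAAAAAAW", sample="s1", subject="p1", umi=1, clone_id="small")
        big2 = make_clone("CARDYWAAAAAAAW", sample="s2", subject="p2", umi=50, clone_id="big2")
        small2 = make_clone("CTTTYWAAAAAAAW", sample="s2", subject="p2", umi=1, clone_id="small2")
        full = derive_disease_list({"s1": [big, small], "s2": [big2, small2]}, {})
        refined = derive_disease_list({"s1": [big, small], "s2": [big2, small2]}, {}, top_n=1)
        assert len(full) == 2 and len(refined) == 1
        assert refined.clusters[0].representative_aa == "CARDYWAAAAAAAW"

    def test_matches_bruteforce_oracle_on_simulation(self):
        cfg = SimulationConfig(
            n_case_subjects=6,
            n_control_subjects=3,
            clones_per_subject=120,
            public_clone_count=15,
            public_penetrance=0.6,
            seed=31,
        )
        samples, truth = simulate_dataset(cfg)
        clones = clones_by_sample_from(samples)
        cases, ctrls = split_case_control(samples, clones)
        dlist = derive_disease_list(cases, ctrls)
        got = {frozenset(cl.members) for cl in dlist.clusters}
        assert got == oracle_derive_list(cases, ctrls)

    def test_antimonotone_in_control_set(self):
        cfg = SimulationConfig(
            n_case_subjects=6,
            n_control_subjects=6,
            clones_per_subject=150,
            public_clone_count=20,
            public_penetrance=0.7,
            public_in_controls=True,
            control_penetrance=0.4,
            seed=12,
        )
        samples, _ = simulate_dataset(cfg)
        clones = clones_by_sample_from(samples)
        cases, ctrls = split_case_control(samples, clones)
        ctrl_ids = sorted(ctrls)
        sizes = [
            len(derive_disease_list(cases, {k: ctrls[k] for k in ctrl_ids[:n]}))
            for n in (0, 3, 6)
        ]
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_recall_collapses_as_controls_gain_the_clones(self):
        recalls = []
        for pen in (0.1, 0.5, 1.0):
            cfg = SimulationConfig(
                n_case_subjects=8,
                n_control_subjects=8,
                clones_per_subject=150,
                public_clone_count=20,
                public_penetrance=0.8,
                public_in_controls=True,
                control_penetrance=pen,
                seed=14,
            )
            samples, truth = simulate_dataset(cfg)
            clones = clones_by_sample_from(samples)
            cases, ctrls = split_case_control(samples, clones)
            dlist = derive_disease_list(cases, ctrls)
            recalls.append(
                evaluate_against_planted(dlist, truth.public_prototypes)["recall"]
            )
        assert recalls[0] > recalls[1] > recalls[2]
        assert recalls[2] <= 0.05


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------


class TestScoreEnrichment:
    def _setup(self):
        shared = "CARDYWAAAAAAAW"
        cases = {
            f"s{i}": [make_clone(shared, sample=f"s{i}", subject=f"p{i}", clone_id="c", umi=10)]
            + [
                # private decoys: subject-specific interiors keep them
                # from ever sharing a cluster across subjects
                make_clone("C" + ch * 5 + ("D" if i == 0 else "K") * 7 + "W",
                           sample=f"s{i}", subject=f"p{i}",
                           clone_id=f"x{ch}", v="IGHV9-1", umi=5)
                for ch in "DEFG"
            ]
            for i in range(2)
        }
        dlist = derive_disease_list(cases, {})
        return cases, dlist

    def test_clone_proportion(self):
        cases, dlist = self._setup()
        out = score_enrichment(dlist, cases, weight="clone")
        assert out["proportion"].tolist() == pytest.approx([1 / 5] * len(out))

    def test_umi_proportion(self):
        cases, dlist = self._setup()
        out = score_enrichment(dlist, cases, weight="umi")
        assert out["proportion"].tolist() == pytest.approx([10 / 30] * len(out))

    def test_deriving_samples_score_positive(self):
        cfg = SimulationConfig(
            n_case_subjects=6,
            n_control_subjects=3,
            clones_per_subject=120,
            public_clone_count=15,
            public_penetrance=0.8,
            seed=41,
        )
        samples, _ = simulate_dataset(cfg)
        clones = clones_by_sample_from(samples)
        cases, ctrls = split_case_control(samples, clones)
        dlist = derive_disease_list(cases, ctrls)
        assert len(dlist) > 0
        contributing = set().union(*(cl.carrier_samples for cl in dlist.clusters))
        out = score_enrichment(dlist, cases).set_index("sample_id")
        for sample_id in contributing:
            assert out.loc[sample_id, "proportion"] > 0

    def test_empty_stratum_omitted(self):
        cases, dlist = self._setup()
        out = score_enrichment(dlist, cases, by_isotype=True)
        assert set(out["stratum"]) == {"IGHM"}  # only isotype present


def test_dominant_clone_tally_ranks_by_carriers():
    shared_a = "CARDYWAAAAAAAW"
    shared_b = "CTTTYWAAAAAAAW"
    samples = {}
    for i in range(5):
        clones = [make_clone(shared_a, sample=f"s{i}", subject=f"p{i}", clone_id="a")]
        if i < 3:
            clones.append(make_clone(shared_b, sample=f"s{i}", subject=f"p{i}", clone_id="b"))
        samples[f"s{i}"] = clones
    dlist = derive_disease_list(samples, {})
    tally, membership = dominant_clone_tally(dlist, samples)
    assert tally["carrier_count"].tolist() == [5, 3]
    row = membership.loc["s0"]
    assert row.sum() == 2  # s0 carries both clusters
    assert membership.loc["s4"].sum() == 1


def test_full_penetrance_tally_saturates():
    cfg = SimulationConfig(
        n_case_subjects=8,
        n_control_subjects=2,
        clones_per_subject=100,
        public_clone_count=6,
        public_penetrance=1.0,
        seed=55,
    )
    samples, _ = simulate_dataset(cfg)
    clones = clones_by_sample_from(samples)
    cases, ctrls = split_case_control(samples, clones)
    dlist = derive_disease_list(cases, ctrls)
    tally, _ = dominant_clone_tally(dlist, cases)
    assert (tally["carrier_count"].head(6) == 8).all()
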