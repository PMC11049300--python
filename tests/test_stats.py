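"""Aggregation, rank tests, Kruskal-Wallis/Dunn and ROC/Youden analysis."""

import itertools
import json

import numpy as np
import pandas as pd
import pytest

from p31vaso.simulate import CohortSpec, simulate_cohort, truth_to_measurements
from p31vaso.stats import (
    AggregateScope,
    PatientRecord,
    StatsConfig,
    aggregate,
    kruskal_dunn,
    rank_sum_test,
    roc_youden,
    run_analysis,
)


# -- independent oracles ----------------------------------------------------

def brute_force_ranksum_p(a, b):
    """Exact two-sided Mann-Whitney p by enumerating all group assignments."""
    combined = np.concatenate([a, b])
    n = len(a)
    u_obs = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
    center = n * (len(b)) / 2.0
    count = total = 0
    for idx in itertools.combinations(range(len(combined)), n):
        mask = np.zeros(len(combined), bool)
        mask[list(idx)] = True
        u = sum((x > y) + 0.5 * (x == y) for x in combined[mask] for y in combined[~mask])
        total += 1
        if abs(u - center) >= abs(u_obs - center) - 1e-12:
            count += 1
    return count / total


def brute_force_auc(scores, labels):
    """Concordant-pair proportion with half credit for ties."""
    pos = scores[labels]
    neg = scores[~labels]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


# -- fixtures ---------------------------------------------------------------

def _manifest_and_measurements(ph_by_voxel):
    """One-patient cohort with explicit per-voxel pH values."""
    rows = []
    meas = []
    for i, (hemi, terr, ph) in enumerate(ph_by_voxel):
        vid = f"v{i}"
        rows.append(
            {
                "patient_id": "P01", "group": "vasospasm",
                "aneurysm_location": "MCA", "hunt_hess": 2,
                "treatment": "clipping", "affected_side": "right",
                "affected_territory": "MCA", "voxel_id": vid,
                "hemisphere": hemi, "territory": terr,
            }
        )
        meas.append(
            {
                "voxel_id": vid, "patient_id": "P01", "hemisphere": hemi,
                "territory": terr, "pmg": 3.7, "mg_mM": 0.2, "ph": ph,
                "quality_pass": True,
            }
        )
    return pd.DataFrame(meas), pd.DataFrame(rows)


class TestAggregate:
    def test_cumulative_mean(self):
        voxels = [("left", "MCA", 7.0), ("left", "MCA", 7.0),
                  ("right", "MCA", 7.1), ("right", "MCA", 7.1)]
        meas, man = _manifest_and_measurements(voxels)
        table, excl = aggregate(meas, man, "cumulative", min_voxels_per_hemisphere=2)
        assert excl == []
        assert table.ph.iloc[0] == pytest.approx(7.05)

    def test_affected_side_filters_hemisphere(self):
        voxels = [("left", "MCA", 6.0), ("right", "MCA", 7.2), ("right", "MCA", 7.4)]
        meas, man = _manifest_and_measurements(voxels)
        table, _ = aggregate(meas, man, "affected_side", min_voxels_per_hemisphere=2)
        assert table.ph.iloc[0] == pytest.approx(7.3)  # left voxel excluded

    def test_quality_failures_never_enter(self):
        voxels = [("right", "MCA", 7.0), ("right", "MCA", 7.0), ("right", "MCA", 9.9)]
        meas, man = _manifest_and_measurements(voxels)
        meas.loc[meas.ph > 9, "quality_pass"] = False
        table, _ = aggregate(meas, man, "cumulative", min_voxels_per_hemisphere=1)
        assert table.ph.iloc[0] == pytest.approx(7.0)

    def test_empty_selection_drops_patient_with_reason(self):
        voxels = [("left", "BA", 7.0)]
        meas, man = _manifest_and_measurements(voxels)  # affected side is right
        table, excl = aggregate(meas, man, "affected_side")
        assert len(table) == 0
        assert excl[0]["patient_id"] == "P01"
        assert "affected_side" in excl[0]["reason"] or "scope" in excl[0]["reason"]

    def test_insufficient_voxels_flagged_not_dropped(self):
        voxels = [("right", "MCA", 7.0), ("right", "MCA", 7.1)]
        meas, man = _manifest_and_measurements(voxels)
        table, _ = aggregate(meas, man, "affected_side", min_voxels_per_hemisphere=4)
        assert len(table) == 1
        assert bool(table.insufficient_voxels.iloc[0])

    def test_scope_nesting_on_lateral_territory(self):
        _, man, truth = simulate_cohort(CohortSpec(seed=8), synthesize_waveforms=False)
        meas = truth_to_measurements(truth, man)
        merged = man.merge(meas[["voxel_id"]], on="voxel_id")

        def voxel_set(scope):
            ids = set()
            for pid, sub in merged.groupby("patient_id"):
                meta = sub.iloc[0]
                if scope == "cumulative":
                    sel = sub
                elif scope == "affected_side":
                    sel = sub[sub.hemisphere == meta.affected_side]
                else:
                    sel = sub[(sub.territory == meta.affected_territory)
                              & (sub.hemisphere == meta.affected_side)]
                ids |= set(sel.voxel_id)
            return ids

        assert voxel_set("affected_territory") <= voxel_set("affected_side")
        assert voxel_set("affected_side") <= voxel_set("cumulative")

    def test_localized_effect_amplified_in_territory_scope(self):
        """With an effect confined to the affected territory, the
        territory-scope group difference exceeds the cumulative one."""
        rows, meas = [], []
        for p in range(8):
            pid = f"P{p:02d}"
            group = "vasospasm" if p < 4 else "control"
            for i, (hemi, terr) in enumerate(
                itertools.product(["left", "right"], ["MCA", "PCA"])
            ):
                for k in range(4):
                    vid = f"{pid}-{i}-{k}"
                    ph = 7.0
                    if group == "vasospasm" and hemi == "right" and terr == "MCA":
                        ph = 7.3
                    rows.append(
                        {"patient_id": pid, "group": group,
                         "aneurysm_location": "MCA", "hunt_hess": 2,
                         "treatment": "clipping", "affected_side": "right",
                         "affected_territory": "MCA", "voxel_id": vid,
                         "hemisphere": hemi, "territory": terr}
                    )
                    meas.append(
                        {"voxel_id": vid, "patient_id": pid, "hemisphere": hemi,
                         "territory": terr, "pmg": 3.7, "mg_mM": 0.2, "ph": ph,
                         "quality_pass": True}
                    )
        man, meas = pd.DataFrame(rows), pd.DataFrame(meas)

        def diff(scope):
            table, _ = aggregate(meas, man, scope)
            g = table.groupby("group").ph.mean()
            return g["vasospasm"] - g["control"]

        assert diff("affected_territory") > diff("cumulative") > 0

    def test_patient_record_validation(self):
        with pytest.raises(ValueError):
            PatientRecord("P1", "other", "MCA", 2, "clipping", "left", "MCA")
        with pytest.raises(ValueError):
            PatientRecord("P1", "control", "MCA", 6, "clipping", "left", "MCA")
        with pytest.raises(ValueError):
            AggregateScope("everything")


class TestRankSum:
    def test_textbook_exact_case(self):
        res = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(0.1)  # 2 / C(6,3)

    def test_group_against_itself(self):
        res = rank_sum_test([1.0, 2.0, 5.0], [1.0, 2.0, 5.0])
        assert res.p_value == pytest.approx(1.0)

    def test_degenerate_identical_values(self):
        res = rank_sum_test([2.0, 2.0], [2.0, 2.0, 2.0])
        assert res.p_value == 1.0
        assert "identical" in res.note

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])

    def test_exact_matches_enumeration_up_to_4v4(self, rng):
        for _ in range(20):
            n_a = rng.integers(2, 5)
            n_b = rng.integers(2, 5)
            a = rng.normal(size=n_a)
            b = rng.normal(size=n_b)
            res = rank_sum_test(a, b)
            assert res.method == "exact"
            assert res.p_value == pytest.approx(brute_force_ranksum_p(a, b), abs=1e-12)

    def test_type_one_error_at_study_sample_size(self):
        """Null rejection rate at n=7 vs 6 stays near the nominal 5%.

        The exact test is conservative here: discreteness of the U
        distribution puts the attained size at 60/1716 = 0.035, so the
        replicate count is chosen to keep Monte-Carlo error well below
        the distance to the tolerance band edge.
        """
        rng = np.random.default_rng(77)
        n_reps = 4000
        rejections = sum(
            rank_sum_test(rng.normal(size=7), rng.normal(size=6)).p_value < 0.05
            for _ in range(n_reps)
        )
        assert abs(rejections / n_reps - 0.05) <= 0.02


class TestKruskalDunn:
    def test_identical_groups_degenerate(self):
        res = kruskal_dunn({"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]})
        # identical values *between* groups but rank variation within:
        # H is 0 because mean ranks coincide
        assert res.h_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_h(self):
        # groups {1,2},{3,4},{5,6}: ranks 1..6, mean ranks 1.5, 3.5, 5.5
        # H = 12/(N(N+1)) * sum n_i (rbar_i - (N+1)/2)^2 = 12/42 * 2*(2^2+0+2^2)
        res = kruskal_dunn({"a": [1, 2], "b": [3, 4], "c": [5, 6]})
        expected = 12.0 / (6 * 7) * (2 * 4 + 0 + 2 * 4)
        assert res.h_statistic == pytest.approx(expected, abs=1e-10)

    def test_empty_group_listed(self):
        with pytest.raises(ValueError, match="b"):
            kruskal_dunn({"a": [1.0], "b": [], "c": [2.0]})

    def test_fewer_than_three_groups_rejected(self):
        with pytest.raises(ValueError):
            kruskal_dunn({"a": [1.0], "b": [2.0]})

    def test_dunn_adjustment_orders(self):
        res = kruskal_dunn({"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]},
                           adjustment="holm")
        assert (res.pairwise.p_adj >= res.pairwise.p_raw - 1e-15).all()
        none = kruskal_dunn({"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]},
                            adjustment="none")
        assert (none.pairwise.p_adj == none.pairwise.p_raw).all()

    def test_null_strata_rarely_significant(self):
        """Strata drawn from one distribution: omnibus non-significant >= 90%."""
        rng = np.random.default_rng(123)
        sizes = (4, 3, 3, 3)
        hits = 0
        for _ in range(500):
            groups = {str(i): rng.normal(size=n) for i, n in enumerate(sizes)}
            hits += kruskal_dunn(groups).p_value < 0.05
        assert hits / 500 <= 0.10


class TestRocYouden:
    def test_perfect_separation(self):
        res = roc_youden([1, 2, 3, 10, 11, 12], [False] * 3 + [True] * 3)
        assert res.auc == 1.0
        assert res.j == 1.0
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_worked_example(self):
        res = roc_youden([0.1, 0.4, 0.35, 0.8], [False, False, True, True])
        assert res.auc == pytest.approx(0.75)

    def test_lower_is_positive_direction(self):
        res = roc_youden([1, 2, 3, 10, 11, 12], [True] * 3 + [False] * 3,
                         direction="lower_is_positive")
        assert res.auc == 1.0

    def test_no_auto_flipping(self):
        # positives score LOW but direction says high: AUC < 0.5 stays
        res = roc_youden([1, 2, 3, 10, 11, 12], [True] * 3 + [False] * 3)
        assert res.auc == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_youden([1, 2], [True, True])

    def test_auc_matches_brute_force_on_random_data(self, rng):
        for _ in range(100):
            n = rng.integers(4, 15)
            scores = rng.integers(0, 6, size=n).astype(float)  # ties likely
            labels = np.zeros(n, bool)
            labels[rng.choice(n, size=rng.integers(1, n), replace=False)] = True
            if labels.all() or not labels.any():
                continue
            res = roc_youden(scores, labels)
            assert res.auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    def test_auc_rank_sum_duality(self, rng):
        """AUC * n_pos * n_neg equals the Mann-Whitney U of the positives."""
        from scipy.stats import mannwhitneyu
        for _ in range(100):
            pos = rng.integers(0, 8, size=rng.integers(2, 8)).astype(float)
            neg = rng.integers(0, 8, size=rng.integers(2, 8)).astype(float)
            scores = np.concatenate([pos, neg])
            labels = np.array([True] * len(pos) + [False] * len(neg))
            auc = roc_youden(scores, labels).auc
            u = mannwhitneyu(pos, neg, method="asymptotic").statistic
            assert auc * len(pos) * len(neg) == pytest.approx(u, abs=1e-9)

    def test_youden_optimality_exhaustive(self, rng):
        for _ in range(30):
            scores = rng.normal(size=12)
            labels = rng.random(12) < 0.5
            if labels.all() or not labels.any():
                continue
            res = roc_youden(scores, labels)
            for t in scores:
                sens = (scores[labels] >= t).mean()
                spec = (scores[~labels] < t).mean()
                assert sens + spec - 1.0 <= res.j + 1e-12

    def test_permutation_null_auc_is_half(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=13)
        aucs = []
        for _ in range(1000):
            labels = np.zeros(13, bool)
            labels[rng.choice(13, size=7, replace=False)] = True
            aucs.append(roc_youden(scores, labels).auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)


@pytest.fixture(scope="module")
def cohort():
    _, man, truth = simulate_cohort(CohortSpec(seed=21), synthesize_waveforms=False)
    return truth_to_measurements(truth, man), man


class TestRunAnalysis:
    def test_report_structure_complete(self, cohort):
        meas, man = cohort
        report = run_analysis(meas, man)
        for scope in ("cumulative", "affected_side", "affected_territory"):
            for marker in ("Mg", "pH"):
                block = report["scopes"][scope]["markers"][marker]
                assert 0.0 <= block["p_value"] <= 1.0
                assert 0.0 <= block["roc"]["auc"] <= 1.0
                assert block["vasospasm"]["n"] + block["control"]["n"] == 13
        subgroups = report["location_and_clinical_subgroups"]["Mg"]
        assert "hunt_hess" in subgroups and "treatment" in subgroups
        assert "location_subgroup_vs_others" in subgroups

    def test_injected_effect_detected_with_correct_signs(self, cohort):
        meas, man = cohort
        report = run_analysis(meas, man)
        mg = report["scopes"]["cumulative"]["markers"]["Mg"]
        ph = report["scopes"]["cumulative"]["markers"]["pH"]
        assert mg["vasospasm"]["median"] < mg["control"]["median"]
        assert ph["vasospasm"]["median"] > ph["control"]["median"]

    def test_deterministic_report(self, cohort):
        meas, man = cohort
        a = json.dumps(run_analysis(meas, man), sort_keys=True)
        b = json.dumps(run_analysis(meas, man), sort_keys=True)
        assert a == b

    def test_null_cohort_rarely_significant(self):
        """Zero-effect cohorts: each cumulative test significant <= 10%."""
        hits = {"Mg": 0, "pH": 0}
        n_reps = 100
        for rep in range(n_reps):
            spec = CohortSpec(
                seed=40_000 + rep,
                pmg_mean_vasospasm=3.75, pmg_mean_control=3.75,
                ph_mean_vasospasm=7.0, ph_mean_control=7.0,
            )
            _, man, truth = simulate_cohort(spec, synthesize_waveforms=False)
            meas = truth_to_measurements(truth, man)
            table, _ = aggregate(meas, man, "cumulative")
            a = table[table.group == "vasospasm"]
            b = table[table.group == "control"]
            hits["Mg"] += rank_sum_test(a.mg_mM, b.mg_mM).p_value < 0.05
            hits["pH"] += rank_sum_test(a.ph, b.ph).p_value < 0.05
        assert hits["Mg"] / n_reps <= 0.10
        assert hits["pH"] / n_reps <= 0.10
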