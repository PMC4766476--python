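"""Pattern clustering, the two five-criteria filters and full selection."""

import numpy as np
import pandas as pd
import pytest

from redoxscreen import (
    GROUP_A_PATTERN,
    GROUP_B_PATTERN,
    SelectionCriteria,
    apply_group_a_criteria,
    apply_group_b_criteria,
    cluster_profiles,
    filter_min_reads,
    gen_counts,
    label_cluster_pattern,
    profile_standardize,
    select_groups,
)
from redoxscreen.io import CONDITIONS
from redoxscreen.select import (
    PAIR_CDK_CTRL,
    PAIR_CPQ_CDK,
    PAIR_CPQ_PQ,
    PAIR_PQ_CTRL,
    cluster_centroids,
)
from redoxscreen.simulate import CountsSimConfig


def de_frame(genes, log2fc, q):
    return pd.DataFrame(
        {"log2fc": log2fc, "p": q, "q": q}, index=pd.Index(genes, name="gene_id")
    )


def summary_frame(genes, rows):
    return pd.DataFrame(rows, index=pd.Index(genes, name="gene_id"), columns=CONDITIONS)


class TestFilterMinReads:
    def test_enumerated_toy_matrix(self):
        counts = pd.DataFrame(
            {"s1": [1, 0, 5, 2, 3], "s2": [4, 4, 0, 2, 1]},
            index=[f"g{i}" for i in range(5)],
        )
        kept = filter_min_reads(counts, 1)
        assert list(kept) == ["g0", "g3", "g4"]

    def test_zero_threshold_keeps_all(self, counts_sim):
        counts, _, _ = counts_sim
        assert len(filter_min_reads(counts, 0)) == len(counts)


class TestProfileStandardize:
    def test_single_condition_spike(self):
        z, flat = profile_standardize(summary_frame(["g"], [[0.0, 3.0, 0.0, 0.0]]))
        assert flat.empty
        assert z.loc["g", "Paraquat"] > 0
        assert (z.loc["g", ["Control", "Cdk12i", "Cdk12i_Paraquat"]] < 0).all()

    def test_constant_profile_flagged_flat(self):
        z, flat = profile_standardize(summary_frame(["g"], [[5.0, 5.0, 5.0, 5.0]]))
        assert list(flat) == ["g"] and z.empty

    def test_rows_have_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        z, _ = profile_standardize(
            summary_frame([f"g{i}" for i in range(20)], rng.lognormal(2, 1, (20, 4)))
        )
        assert np.allclose(z.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(z.std(axis=1, ddof=0), 1, atol=1e-12)


def naive_average_linkage(X: np.ndarray, k: int):
    """Brute-force agglomerative oracle: recompute every cluster-pair average
    of one-minus-Pearson distances at each merge step."""
    n = len(X)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d[i, j] = 1 - np.corrcoef(X[i], X[j])[0, 1]
    clusters = [{i} for i in range(n)]
    while len(clusters) > k:
        best, pair = None, None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                avg = np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or avg < best - 1e-12:
                    best, pair = avg, (a, b)
        a, b = pair
        clusters[a] |= clusters.pop(b)
    return {frozenset(c) for c in clusters}


def partition_of(assign: pd.Series):
    out = {}
    for pos, c in enumerate(assign):
        out.setdefault(c, set()).add(pos)
    return {frozenset(v) for v in out.values()}


class TestClusterProfiles:
    def test_identical_profiles_stay_together(self):
        X = pd.DataFrame(
            [[1, 2, 3, 4], [1, 2, 3, 4], [4, 3, 2, 1]], index=["a", "b", "c"], dtype=float
        )
        assign = cluster_profiles(X, 2)
        assert assign["a"] == assign["b"] != assign["c"]

    def test_anticorrelated_profiles_split_first(self):
        X = pd.DataFrame(
            [[1, 2, 3, 4], [4, 3, 2, 1], [1.1, 2, 3, 3.9]], index=["a", "b", "c"], dtype=float
        )
        assign = cluster_profiles(X, 2)
        assert assign["a"] == assign["c"] != assign["b"]

    def test_two_shape_groups_recovered(self):
        up = [[0.1, 2.0, 0.2, 0.1], [0.2, 2.2, 0.1, 0.3], [0.0, 1.8, 0.3, 0.2]]
        down = [[2.0, 0.1, 0.2, 2.1], [1.8, 0.2, 0.1, 2.0], [2.2, 0.3, 0.2, 1.9]]
        X = pd.DataFrame(up + down, index=list("abcdef"), dtype=float)
        assign = cluster_profiles(X, 2)
        assert partition_of(assign) == naive_average_linkage(X.to_numpy(), 2)

    @pytest.mark.parametrize("n,k", [(4, 2), (5, 2), (6, 3), (6, 2)])
    def test_matches_brute_force_oracle(self, n, k):
        rng = np.random.default_rng(n * 10 + k)
        for _ in range(25):
            X = rng.normal(size=(n, 4))
            assign = cluster_profiles(pd.DataFrame(X), k)
            assert partition_of(assign) == naive_average_linkage(X, k)

    def test_deterministic(self, selection):
        p = selection.profiles
        a1 = cluster_profiles(p, 16)
        a2 = cluster_profiles(p.copy(), 16)
        pd.testing.assert_series_equal(a1, a2)

    def test_k_larger_than_profiles_rejected(self):
        with pytest.raises(ValueError):
            cluster_profiles(pd.DataFrame(np.eye(3)), 4)


class TestLabelClusterPattern:
    @pytest.mark.parametrize(
        "centroid,expected",
        [
            ([-0.5, 1.5, -0.5, -0.5], ("low", "high", "low", "low")),
            ([-0.5, -0.5, -0.5, 1.5], ("low", "low", "low", "high")),
            ([0.0, 0.0, 0.0, 0.0], ("low", "low", "low", "low")),
        ],
    )
    def test_sign_labelling_with_tie_rule(self, centroid, expected):
        assert label_cluster_pattern(centroid) == expected


class TestGroupACriteria:
    def geometric_case(self, ctrl, pq, cdk):
        genes = ["g"]
        de = {
            PAIR_PQ_CTRL: de_frame(genes, [2.0], [0.01]),
            PAIR_CDK_CTRL: de_frame(genes, [-0.5], [0.5]),
        }
        summary = summary_frame(genes, [[ctrl, pq, cdk, 1.0]])
        return apply_group_a_criteria(genes, de, summary)

    def test_geometric_mean_bound_passes(self):
        selected, audit = self.geometric_case(1.0, 9.0, 2.0)
        assert audit.loc["g", "geom_bound"] == pytest.approx(3.0)
        assert audit.loc["g", "c5_geometric_mean"]
        assert selected == ["g"]

    def test_geometric_mean_boundary_is_strict(self):
        selected, audit = self.geometric_case(4.0, 4.0, 4.0)
        assert not audit.loc["g", "c5_geometric_mean"]
        assert selected == []

    def test_all_criteria_satisfied_by_construction(self):
        genes = ["g"]
        de = {
            PAIR_PQ_CTRL: de_frame(genes, [2.0], [0.01]),
            PAIR_CDK_CTRL: de_frame(genes, [-0.5], [0.9]),
        }
        summary = summary_frame(genes, [[1.0, 9.0, 2.0, 1.0]])
        selected, _ = apply_group_a_criteria(genes, de, summary)
        assert selected == ["g"]

    def test_missing_comparison_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            apply_group_a_criteria(["g"], {}, summary_frame(["g"], [[1, 1, 1, 1]]))


class TestGroupBCriteria:
    def full_de(self, genes, lfc3=2.0, q3=0.001, q4=0.001, lfc5=2.0, q5=0.001):
        return {
            PAIR_CPQ_PQ: de_frame(genes, [lfc3], [q3]),
            PAIR_CDK_CTRL: de_frame(genes, [0.5], [q4]),
            PAIR_CPQ_CDK: de_frame(genes, [lfc5], [q5]),
        }

    def test_constructed_hit_selected(self):
        selected, _ = apply_group_b_criteria(["g"], self.full_de(["g"]))
        assert selected == ["g"]

    def test_zero_fold_change_fails_strictly(self):
        selected, audit = apply_group_b_criteria(["g"], self.full_de(["g"], lfc3=0.0))
        assert selected == [] and not audit.loc["g", "c3_up_cpq_vs_pq"]

    def test_single_criterion_ablation_shows_in_audit(self):
        selected, audit = apply_group_b_criteria(["g"], self.full_de(["g"], q4=0.5))
        assert selected == []
        assert not audit.loc["g", "c4_changed_cdk_vs_ctrl"]
        assert audit.loc["g", "c3_up_cpq_vs_pq"] and audit.loc["g", "c5_up_cpq_vs_cdk"]


class TestSelectGroups:
    def test_planted_recovery_default_config(self, counts_sim, selection):
        counts, design, truth = counts_sim
        for grp in ("group_a", "group_b"):
            sel, tru = set(getattr(selection, grp)), truth.genes(grp)
            assert len(sel & tru) / len(tru) >= 0.9
            assert len(sel & tru) / len(sel) >= 0.9

    def test_audit_covers_every_gene_and_selected_pass_all(self, counts_sim, selection):
        counts, _, _ = counts_sim
        audit = selection.audit
        assert set(audit.index) == set(counts.index)
        for g in selection.group_a:
            assert audit.loc[g, ["c1_min_reads", "c2a_pattern_cluster",
                                 "a_c3_pq_induced", "a_c4_not_down_in_cdk12i",
                                 "a_c5_geometric_mean"]].all()

    def test_null_matrix_selects_nearly_nothing(self, null_sim):
        counts, design, truth = null_sim
        res = select_groups(counts, design)
        assert len(res.group_a) + len(res.group_b) <= 0.05 * len(counts)

    def test_flat_matrix_selects_nothing(self):
        counts = pd.DataFrame(
            5, index=[f"g{i}" for i in range(10)],
            columns=[f"{c}_{r}" for c in CONDITIONS for r in (1, 2, 3)],
        )
        design = pd.DataFrame(
            {"condition": [c for c in CONDITIONS for _ in range(3)],
             "replicate": [1, 2, 3] * 4},
            index=pd.Index(counts.columns, name="sample_id"),
        )
        res = select_groups(counts, design)
        assert res.group_a == [] and res.group_b == []

    def test_scale_invariance_of_decisions(self, counts_sim, selection):
        counts, design, _ = counts_sim
        scaled = select_groups(counts * 3, design)
        assert scaled.group_a == selection.group_a
        assert scaled.group_b == selection.group_b

    def test_tightening_thresholds_shrinks_groups(self, counts_sim, selection):
        counts, design, _ = counts_sim
        tighter = SelectionCriteria(
            lfc_pq_ctrl_min=2.0, q_pq_ctrl_max=0.01,
            lfc_cpq_pq_min=1.0, q_cpq_pq_max=0.01,
            q_cdk_ctrl_max=0.01, lfc_cpq_cdk_min=1.0, q_cpq_cdk_max=0.01,
        )
        res = select_groups(counts, design, tighter)
        assert set(res.group_a) <= set(selection.group_a)
        assert set(res.group_b) <= set(selection.group_b)

    def test_missing_condition_rejected(self, counts_sim):
        counts, design, _ = counts_sim
        broken = design.copy()
        broken["condition"] = broken["condition"].replace("Paraquat", "Control")
        with pytest.raises(ValueError, match="Paraquat"):
            select_groups(counts, broken)

    def test_pattern_templates_are_the_published_shapes(self, selection):
        """Pooled pattern clusters carry the planted shapes."""
        pats = set(selection.clusters["pattern"])
        assert "-".join(GROUP_A_PATTERN) in pats
        assert "-".join(GROUP_B_PATTERN) in pats
        # centroid of the A-pattern pool peaks at Paraquat
        cents = cluster_centroids(selection.profiles,
                                  selection.clusters["cluster_id"])
        for cid, row in cents.iterrows():
            if label_cluster_pattern(row) == GROUP_A_PATTERN:
                assert row["Paraquat"] == row.max()
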