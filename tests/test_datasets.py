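"""Training-table construction: aggregation, grading, labels, sampling."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mtqsar import (
    AffinityMatrix,
    DockingRuns,
    GradedLabel,
    TrainingTable,
    aggregate_docking_energies,
    assemble_training_table,
    build_sampling_plan,
    cluster_activity_group,
    derive_combined_labels,
    unify_structure_labels,
)
from mtqsar.datasets import GRADE_ORDER, read_labels_csv, write_labels_csv, round_half_up


class TestAggregateDockingEnergies:
    def test_minimum_of_pool(self):
        runs = [DockingRuns("c1", "s1", (-5.1, -6.3, -4.0))]
        m = aggregate_docking_energies(runs)
        assert m.delta_e[0, 0] == -6.3

    def test_singleton_pool_identity(self):
        m = aggregate_docking_energies([DockingRuns("c1", "s1", (-7.25,))])
        assert m.delta_e[0, 0] == -7.25

    def test_cell_leq_every_pooled_value(self):
        rng = np.random.default_rng(3)
        runs = [
            DockingRuns(f"c{i}", f"s{j}", tuple(rng.uniform(-11, -1, size=6)))
            for i in range(4)
            for j in range(3)
        ]
        m = aggregate_docking_energies(runs)
        pools = {(r.compound_id, r.site_id): r.energies for r in runs}
        for i, c in enumerate(m.compound_ids):
            for j, s in enumerate(m.site_ids):
                assert all(m.delta_e[i, j] <= e for e in pools[(c, s)])
                assert m.delta_e[i, j] == min(pools[(c, s)])

    def test_missing_pair_identified(self):
        runs = [
            DockingRuns("c1", "s1", (-5.0,)),
            DockingRuns("c1", "s2", (-5.0,)),
            DockingRuns("c2", "s1", (-5.0,)),
        ]
        with pytest.raises(ValueError, match=r"c2.*s2|missing"):
            aggregate_docking_energies(runs)

    def test_duplicate_pair_rejected(self):
        runs = [DockingRuns("c1", "s1", (-5.0,)), DockingRuns("c1", "s1", (-6.0,))]
        with pytest.raises(ValueError, match="duplicate"):
            aggregate_docking_energies(runs)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            DockingRuns("c1", "s1", ())


class TestClusterActivityGroup:
    def test_well_separated_five_clusters(self):
        values = [100, 98, 97, 60, 61, 30, 29, 10, 11, 0, 1]
        grades = cluster_activity_group(values, k=5, higher_is_better=True)
        assert grades == [
            "high", "high", "high",
            "moderate", "moderate",
            "low", "low",
            "active", "active",
            "inactive", "inactive",
        ]

    def test_lower_is_better_direction(self):
        # potency-style measure: smallest value is the best cluster
        values = [1, 2, 50, 51, 100, 101, 200, 201, 400, 401]
        grades = cluster_activity_group(values, k=5, higher_is_better=False)
        assert grades[:2] == ["high", "high"]
        assert grades[-2:] == ["inactive", "inactive"]

    def test_degenerate_all_equal(self):
        with pytest.warns(UserWarning, match="reducing k"):
            grades = cluster_activity_group([7.0] * 10, k=5)
        assert len(set(grades)) == 1

    def test_seed_and_scale_stability(self):
        values = np.arange(1, 501, dtype=float)
        a = cluster_activity_group(values, k=5, seed=0)
        b = cluster_activity_group(values, k=5, seed=99)
        c = cluster_activity_group(3.5 * values + 11.0, k=5, seed=0)
        assert a == b == c

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            cluster_activity_group([1.0, float("nan"), 3.0, 4.0, 5.0], k=2)

    def test_partition_cost_not_worse_than_restart_kmeans(self):
        # the DP solution is the optimal SSQ partition, so it can never lose
        # to sklearn's restart heuristic
        from sklearn.cluster import KMeans

        from mtqsar.datasets import _kmeans_1d

        rng = np.random.default_rng(7)
        vals = rng.gamma(2.0, 10.0, size=80)

        def ssq(labels):
            return sum(
                ((vals[labels == c] - vals[labels == c].mean()) ** 2).sum()
                for c in np.unique(labels)
            )

        ours = ssq(_kmeans_1d(vals, 5))
        theirs = ssq(KMeans(5, n_init=10, random_state=0).fit_predict(vals.reshape(-1, 1)))
        assert ours <= theirs + 1e-8


class TestUnifyStructureLabels:
    @pytest.mark.parametrize(
        "levels, expected",
        [
            (["high"], "high"),
            (["high", "moderate"], "high"),  # avg 2.5 rounds half-up to 3
            (["low", "inactive", "inactive"], "inactive"),  # avg 1/3 rounds to 0
            (["moderate", "low"], "moderate"),  # avg 1.5 rounds half-up to 2
            (["active"], "active"),
            (["active", "high"], "high"),  # bare "active" excluded from average
        ],
    )
    def test_averaging(self, levels, expected):
        records = [GradedLabel("c1", lv) for lv in levels]
        assert unify_structure_labels(records).level == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            unify_structure_labels([])

    def test_mixed_compounds_rejected(self):
        with pytest.raises(ValueError):
            unify_structure_labels([GradedLabel("c1", "high"), GradedLabel("c2", "low")])


class TestCombinedLabels:
    @pytest.mark.parametrize(
        "level, expected",
        [
            ("high", ("h", "hm", "a")),
            ("moderate", ("nh", "hm", "a")),
            ("low", ("nh", "nhm", "a")),
            ("active", ("nh", "nhm", "a")),
            ("inactive", ("nh", "nhm", "na")),
        ],
    )
    def test_mapping(self, level, expected):
        c = derive_combined_labels(level)
        assert (c.lev_h, c.lev_hm, c.lev_a) == expected

    def test_monotone_nesting(self):
        for level in GRADE_ORDER:
            c = derive_combined_labels(level)
            if c.lev_h == "h":
                assert c.lev_hm == "hm"
            if c.lev_hm == "hm":
                assert c.lev_a == "a"

    def test_unknown_grade_rejected(self):
        with pytest.raises(ValueError):
            derive_combined_labels("superb")


class TestSamplingPlan:
    def test_block_rule_n14(self):
        plan = build_sampling_plan(14)
        assert plan.roles(0) == [
            "train", "train", "train", "train", "train", "test", "val",
            "train", "train", "train", "train", "train", "test", "val",
        ]

    def test_role_counts_one_block(self):
        plan = build_sampling_plan(7)
        for v in range(7):
            roles = plan.roles(v)
            assert roles.count("train") == 5
            assert roles.count("test") == 1
            assert roles.count("val") == 1

    def test_position_roles_are_permutation_across_variants(self):
        plan = build_sampling_plan(21)
        for i in range(21):
            across = sorted(plan.roles(v)[i] for v in range(7))
            assert across == sorted(["train"] * 5 + ["test", "val"])

    def test_shift_by_one(self):
        plan = build_sampling_plan(21)
        for v in range(1, 7):
            assert plan.roles(v)[1:] == plan.roles(v - 1)[:-1]

    def test_exact_proportions_when_divisible(self):
        plan = build_sampling_plan(70)
        for v in range(7):
            roles = plan.roles(v)
            assert roles.count("train") == 50
            assert roles.count("test") == 10

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            build_sampling_plan(6)


class TestAssembleTrainingTable:
    def _matrix(self, n=10, k=17, seed=0):
        rng = np.random.default_rng(seed)
        codes = [f"c{i:02d}" for i in range(n)]
        sites = [f"S{j}" for j in range(k)]
        return AffinityMatrix(codes, sites, rng.uniform(-11, -1, size=(n, k)))

    def test_29_columns(self):
        m = self._matrix()
        labels = [GradedLabel(c, "low") for c in m.compound_ids]
        table = assemble_training_table(m, labels)
        assert table.n_columns == 29
        assert len(table) == 10

    def test_sort_invariance(self):
        m = self._matrix()
        labels = [GradedLabel(c, "moderate") for c in m.compound_ids]
        t1 = assemble_training_table(m, labels)
        perm = np.random.default_rng(1).permutation(len(m.compound_ids))
        m2 = AffinityMatrix(
            [m.compound_ids[i] for i in perm], m.site_ids, m.delta_e[perm]
        )
        t2 = assemble_training_table(m2, labels[::-1])
        assert t1 == t2

    def test_orphans_listed(self):
        m = self._matrix()
        labels = [GradedLabel(c, "low") for c in m.compound_ids[:-1]]
        labels.append(GradedLabel("ghost", "low"))
        with pytest.raises(ValueError, match="ghost"):
            assemble_training_table(m, labels)

    def test_csv_round_trip(self, tmp_path):
        m = self._matrix()
        labels = [GradedLabel(c, "high") for c in m.compound_ids]
        table = assemble_training_table(m, labels)
        path = tmp_path / "table.csv"
        table.to_csv(path)
        loaded = TrainingTable.read_csv(path)
        assert loaded.site_ids == table.site_ids
        np.testing.assert_allclose(loaded.energies, table.energies, rtol=1e-5)


def test_affinity_csv_round_trip(tmp_path):
    rng = np.random.default_rng(0)
    m = AffinityMatrix(["a", "b"], ["S1", "S2"], rng.uniform(-9, -2, (2, 2)))
    m.to_csv(tmp_path / "m.csv")
    m2 = AffinityMatrix.read_csv(tmp_path / "m.csv")
    assert m2.compound_ids == m.compound_ids
    np.testing.assert_allclose(m2.delta_e, m.delta_e, rtol=1e-5)
    header = (tmp_path / "m.csv").read_text().splitlines()[0]
    assert header.startswith("code,")


def test_labels_csv_round_trip(tmp_path):
    labels = [GradedLabel("c1", "high"), GradedLabel("c2", "inactive")]
    write_labels_csv(labels, tmp_path / "l.csv")
    assert read_labels_csv(tmp_path / "l.csv") == labels


def test_round_half_up():
    assert round_half_up(2.5) == 3
    assert round_half_up(98.85, 1) == 98.9
    assert round_half_up(0.25, 1) == 0.3


def test_sdf_property_ingestion(tmp_path):
    rdkit = pytest.importorskip("rdkit")
    from mtqsar.datasets import read_sdf_labels

    methane = (
        "mol-1\n  synthetic\n\n"
        "  1  0  0  0  0  0  0  0  0  0999 V2000\n"
        "    0.0000    0.0000    0.0000 C   0  0\n"
        "M  END\n"
        "> <NAME>\nCPD-1\n\n> <ACTIVITY_LEVEL>\nhigh\n\n$$$$\n"
        "mol-2\n  synthetic\n\n"
        "  1  0  0  0  0  0  0  0  0  0999 V2000\n"
        "    0.0000    0.0000    0.0000 N   0  0\n"
        "M  END\n"
        "> <NAME>\nCPD-2\n\n> <ACTIVITY_LEVEL>\ninactive\n\n$$$$\n"
    )
    path = tmp_path / "two.sdf"
    path.write_text(methane)
    labels = read_sdf_labels(path)
    assert labels == [GradedLabel("CPD-1", "high"), GradedLabel("CPD-2", "inactive")]
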