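import numpy as np
import pandas as pd
import pytest

from backbones import (
    FREE,
    PROHIBITED,
    REQUIRED,
    assign_constraints,
    build_constraint_mask,
    generate_preschool,
    generate_random_bipartite,
    load_world,
    project,
    save_world,
    validate_or_coerce_mask,
)


class TestRandomBipartite:
    def test_deterministic_for_fixed_seed(self):
        a = generate_random_bipartite(20, 100, 0.5, seed=42)
        b = generate_random_bipartite(20, 100, 0.5, seed=42)
        assert a == b

    def test_degenerate_density_rejected(self):
        for d in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                generate_random_bipartite(5, 5, d)
        assert generate_random_bipartite(5, 100, 0.999, seed=1).n_edges >= 495

    def test_edge_count_near_binomial_expectation(self):
        counts = [
            generate_random_bipartite(20, 100, 0.5, seed=s).n_edges for s in range(30)
        ]
        expected = 1000
        sd = np.sqrt(2000 * 0.25)  # binomial SD of one draw
        assert abs(np.mean(counts) - expected) <= 3 * sd / np.sqrt(30)


class TestAssignConstraints:
    def test_zero_percent_is_all_free(self, random_graph):
        m = assign_constraints(random_graph, 0, 0, seed=1)
        assert (m.M == FREE).all()

    def test_exact_counts_at_consistent_positions(self, rng):
        g = generate_random_bipartite(25, 40, 0.5, seed=3)
        m = assign_constraints(g, 10, 20, seed=4)
        n_present = g.n_edges
        n_absent = 1000 - n_present
        assert m.n_required == int(np.floor(0.10 * n_present + 0.5))
        assert m.n_prohibited == int(np.floor(0.20 * n_absent + 0.5))
        # consistency by construction: strict validation passes
        validate_or_coerce_mask(g, m, "strict")

    def test_percent_domain(self, random_graph):
        with pytest.raises(ValueError):
            assign_constraints(random_graph, -1, 0)
        with pytest.raises(ValueError):
            assign_constraints(random_graph, 0, 101)


class TestPreschoolWorld:
    def test_default_shape_matches_study_design(self):
        world = generate_preschool(seed=0)
        assert world.graph.shape == (53, 1829)

    def test_invariants_hold_by_construction(self, small_world):
        w = small_world
        child_idx = {c: i for i, c in enumerate(w.children["child_id"])}
        for k, row in w.groups.iterrows():
            members = np.where(w.graph.B[:, k] == 1)[0]
            assert child_idx[row["focal_child_id"]] in members
            for i in members:
                assert w.children["classroom"][i] == row["classroom"]
                sched = w.children["schedule"][i]
                assert sched == "FULL" or sched == row["session"]
        # strict validation under all three constraint families
        mask = build_constraint_mask(w, which=("focal", "age", "time"))
        validate_or_coerce_mask(w.graph, mask, "strict")
        # truth edges stay within classrooms
        same = (
            w.children["classroom"].to_numpy()[:, None]
            == w.children["classroom"].to_numpy()[None, :]
        )
        assert (w.truth[~same] == 0).all()

    def test_no_eligible_focal_child_errors(self):
        # a one-child classroom whose only child attends PM: AM groups impossible
        with pytest.raises(ValueError):
            for s in range(20):  # some seed will draw an AM group for classroom 3yo
                w = generate_preschool(
                    n_children=3,
                    n_groups=30,
                    classroom_split=(1, 2),
                    schedule_probs=(0.0, 1.0, 0.0),
                    seed=s,
                )

    def test_neutral_assortativity_is_truth_blind(self):
        # with multiplier 1 the planted friendships must not affect co-membership
        diffs, ses = [], []
        for s in range(8):
            w = generate_preschool(
                n_children=12,
                n_groups=200,
                classroom_split=(6, 6),
                truth_density=0.3,
                assortativity=1.0,
                seed=100 + s,
            )
            P = project(w.graph).P
            same = (
                w.children["classroom"].to_numpy()[:, None]
                == w.children["classroom"].to_numpy()[None, :]
            )
            iu = np.triu_indices(12, k=1)
            vals = P[iu]
            is_truth = w.truth[iu] == 1
            in_class = same[iu]
            t = vals[is_truth & in_class]
            n = vals[~is_truth & in_class]
            diffs.append(t.mean() - n.mean())
            ses.append(np.sqrt(t.var(ddof=1) / t.size + n.var(ddof=1) / n.size))
        pooled = np.mean(diffs)
        pooled_se = np.sqrt(np.sum(np.square(ses))) / len(ses)
        assert abs(pooled) <= 3 * pooled_se

    def test_high_assortativity_raises_truth_pair_overlap(self, small_world):
        w = small_world
        P = project(w.graph).P
        iu = np.triu_indices(16, k=1)
        same = (
            w.children["classroom"].to_numpy()[:, None]
            == w.children["classroom"].to_numpy()[None, :]
        )
        vals, is_truth, in_class = P[iu], w.truth[iu] == 1, same[iu]
        assert vals[is_truth & in_class].mean() > vals[~is_truth & in_class].mean()

    def test_world_bundle_round_trip(self, tmp_path, small_world):
        save_world(small_world, tmp_path / "bundle")
        w2 = load_world(tmp_path / "bundle")
        assert np.array_equal(w2.graph.B, small_world.graph.B)
        assert w2.graph.row_labels == small_world.graph.row_labels
        assert np.array_equal(w2.truth, small_world.truth)
        pd.testing.assert_frame_equal(
            w2.children, small_world.children.astype(str), check_dtype=False
        )


class TestBuildConstraintMask:
    def test_empty_rule_set_is_all_free(self, toy_tables):
        children, groups, _ = toy_tables
        m = build_constraint_mask(children, groups, which=())
        assert (m.M == FREE).all()

    def test_toy_world_hand_enumeration(self, toy_tables):
        children, groups, _ = toy_tables
        # age rule: each group prohibits the 2 children of the other classroom
        m_age = build_constraint_mask(children, groups, which=("age",))
        assert m_age.n_prohibited == 3 * 2
        assert (m_age.M[2:, 0] == PROHIBITED).all()  # 4yo children vs 3yo group g1
        # all FULL schedules: the time rule prohibits nothing
        m_time = build_constraint_mask(children, groups, which=("time",))
        assert m_time.n_prohibited == 0
        # focal rule: one REQUIRED cell per group at the focal child
        m_focal = build_constraint_mask(children, groups, which=("focal",))
        assert m_focal.n_required == 3
        assert m_focal.M[0, 0] == REQUIRED  # a focal for g1
        assert m_focal.M[2, 1] == REQUIRED  # c focal for g2
        assert m_focal.M[1, 2] == REQUIRED  # b focal for g3

    def test_mask_composition_union(self, small_world):
        w = small_world
        m_fa = build_constraint_mask(w, which=("focal", "age"))
        m_f = build_constraint_mask(w, which=("focal",))
        m_a = build_constraint_mask(w, which=("age",))
        assert np.array_equal(m_fa.M, m_f.union(m_a).M)

    def test_prohibited_overlap_subadditivity(self, small_world):
        w = small_world
        n_age = build_constraint_mask(w, which=("age",)).n_prohibited
        n_time = build_constraint_mask(w, which=("time",)).n_prohibited
        n_both = build_constraint_mask(w, which=("age", "time")).n_prohibited
        assert n_both <= n_age + n_time

    def test_inconsistent_focal_attributes_error(self):
        children = pd.DataFrame(
            {"child_id": ["a"], "classroom": ["3yo"], "schedule": ["AM"]}
        )
        groups = pd.DataFrame(
            {
                "group_id": ["g1"],
                "classroom": ["3yo"],
                "session": ["PM"],
                "focal_child_id": ["a"],
            }
        )
        with pytest.raises(ValueError, match="focal"):
            build_constraint_mask(children, groups, which=("focal", "time"))

    def test_unknown_family_rejected(self, toy_tables):
        children, groups, _ = toy_tables
        with pytest.raises(ValueError):
            build_constraint_mask(children, groups, which=("focal", "weather"))
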