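import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from backbones import (
    BipartiteGraph,
    ConstraintMask,
    edge_pvalues,
    extract_backbone,
    fit_probabilities,
    pb_tail_exact,
    pb_tail_rna,
    project,
)


def enumeration_tail(probs, w):
    """Brute-force oracle: sum over all 2^m outcomes of the Bernoulli vector."""
    probs = np.asarray(probs, dtype=float)
    m = probs.size
    bits = (np.arange(2**m)[:, None] >> np.arange(m)) & 1
    outcome_p = np.prod(np.where(bits == 1, probs, 1.0 - probs), axis=1)
    return float(outcome_p[bits.sum(axis=1) >= w].sum())


class TestExactTail:
    def test_all_zero_probs(self):
        assert pb_tail_exact([0.0, 0.0, 0.0], 0) == 1.0
        assert pb_tail_exact([0.0, 0.0, 0.0], 1) == 0.0

    def test_closed_form_half_half(self):
        assert pb_tail_exact([0.5, 0.5], 2) == pytest.approx(0.25, abs=1e-15)

    def test_matches_enumeration(self, rng):
        for _ in range(20):
            m = int(rng.integers(1, 13))
            probs = rng.random(m)
            w = int(rng.integers(0, m + 1))
            assert pb_tail_exact(probs, w) == pytest.approx(
                enumeration_tail(probs, w), abs=1e-12
            )

    def test_deterministic_cells_fold_in(self):
        probs = [1.0, 1.0, 0.0, 0.5]
        # two certain successes shift the support
        assert pb_tail_exact(probs, 2) == 1.0
        assert pb_tail_exact(probs, 3) == 0.5
        assert pb_tail_exact(probs, 4) == 0.0

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            pb_tail_exact([1.2], 0)
        with pytest.raises(ValueError):
            pb_tail_exact([0.5], 2)


class TestRnaTail:
    def test_degenerate_equals_exact(self):
        assert pb_tail_rna([0.0, 0.0], 1) == pb_tail_exact([0.0, 0.0], 1)
        assert pb_tail_rna([1.0, 1.0], 2) == pb_tail_exact([1.0, 1.0], 2)

    def test_close_to_exact_at_moderate_n(self):
        probs = [0.3] * 200
        assert pb_tail_rna(probs, 70) == pytest.approx(pb_tail_exact(probs, 70), abs=5e-3)

    def test_symmetric_midpoint_tail_at_least_half(self):
        probs = [0.5] * 100
        assert pb_tail_rna(probs, 50) >= 0.5

    def test_clamped_to_unit_interval(self, rng):
        probs = rng.random(50)
        for w in (0, 10, 25, 50):
            assert 0.0 <= pb_tail_rna(probs, w) <= 1.0


@settings(deadline=None, max_examples=30, derandomize=True)
@given(seed=st.integers(0, 5000), m=st.integers(1, 40))
def test_tail_monotone_in_weight(seed, m):
    probs = np.random.default_rng(seed).random(m)
    exact = [pb_tail_exact(probs, w) for w in range(m + 1)]
    assert all(a >= b - 1e-15 for a, b in zip(exact, exact[1:]))
    rna = [pb_tail_rna(probs, w) for w in range(m + 1)]
    assert all(a >= b - 1e-9 for a, b in zip(rna, rna[1:]))


class TestEdgePvalues:
    def test_zero_weight_pair_has_p_one(self):
        B = np.array([[1, 0, 0], [0, 1, 1]])
        g = BipartiteGraph(B)
        q = fit_probabilities(g)
        tests = edge_pvalues(g, q, method="exact")
        assert tests[0].observed_weight == 0
        assert tests[0].p_value == 1.0

    def test_point_mass_null_gives_p_one(self):
        g = BipartiteGraph(np.ones((2, 5), dtype=int))
        q = fit_probabilities(g)
        (t,) = edge_pvalues(g, q, method="exact")
        assert t.observed_weight == 5
        assert t.p_value == 1.0

    def test_matches_monte_carlo_null(self, rng):
        B = (rng.random((6, 10)) < 0.5).astype(int)
        g = BipartiteGraph(B)
        q = fit_probabilities(g)
        tests = edge_pvalues(g, q, method="exact")
        n_draws = 10_000
        draws = rng.random((n_draws, 6, 10)) < q.Q
        P = project(g).P
        for t in tests:
            null_w = (draws[:, t.i, :] & draws[:, t.j, :]).sum(axis=1)
            emp = (null_w >= P[t.i, t.j]).mean()
            se = np.sqrt(max(emp * (1 - emp), 1e-12) / n_draws)
            assert abs(t.p_value - emp) <= 3 * se + 0.005

    def test_exact_and_rna_agree(self, rng):
        B = (rng.random((8, 60)) < 0.4).astype(int)
        g = BipartiteGraph(B)
        q = fit_probabilities(g)
        pe = {(t.i, t.j): t.p_value for t in edge_pvalues(g, q, method="exact")}
        pr = {(t.i, t.j): t.p_value for t in edge_pvalues(g, q, method="rna")}
        for key in pe:
            assert pe[key] == pytest.approx(pr[key], abs=2e-2)


class TestExtractBackbone:
    def test_tiny_alpha_gives_empty_backbone(self, random_graph):
        bb = extract_backbone(random_graph, alpha=1e-9)
        assert bb.n_edges == 0

    def test_empty_mask_equals_no_mask(self, random_graph):
        b1 = extract_backbone(random_graph, None, alpha=0.05)
        b2 = extract_backbone(random_graph, ConstraintMask.all_free(*random_graph.shape), alpha=0.05)
        assert np.array_equal(b1.A, b2.A)

    def test_planted_high_overlap_pair_is_retained(self, rng):
        # two agents share 15 artifacts amid sparse noise; their projection
        # weight far exceeds what their degrees alone explain
        B = (rng.random((20, 80)) < 0.1).astype(int)
        B[0, :15] = 1
        B[1, :15] = 1
        bb = extract_backbone(BipartiteGraph(B), alpha=0.05)
        assert bb.A[0, 1] == 1

    def test_backbone_subset_of_positive_weights(self, rng):
        B = (rng.random((10, 40)) < 0.35).astype(int)
        g = BipartiteGraph(B)
        bb = extract_backbone(g, alpha=0.5)
        P = project(g).P
        assert ((bb.A == 1) <= (P > 0)).all()

    def test_nesting_in_alpha(self, rng):
        B = (rng.random((10, 40)) < 0.35).astype(int)
        B[2, :20] = 1
        B[3, :20] = 1
        g = BipartiteGraph(B)
        lo = extract_backbone(g, alpha=0.01)
        hi = extract_backbone(g, alpha=0.3)
        assert ((lo.A == 1) <= (hi.A == 1)).all()

    def test_alpha_domain(self, random_graph):
        with pytest.raises(ValueError):
            extract_backbone(random_graph, alpha=0.0)

    def test_export_helpers(self, tmp_path, rng):
        B = (rng.random((6, 20)) < 0.4).astype(int)
        bb = extract_backbone(BipartiteGraph(B), alpha=0.4)
        bb.to_edgelist_tsv(tmp_path / "bb.tsv")
        table = bb.pvalue_table()
        assert len(table) == 15
        assert ((table["p"] >= 0) & (table["p"] <= 1)).all()
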