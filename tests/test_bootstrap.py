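import numpy as np
import pandas as pd
import pytest

import crosstalk.simulate as sim
from crosstalk.bootstrap import (
    DifferentialEdge,
    EdgeCountTable,
    bootstrap_edges,
    differential_edges,
    differential_frame,
    enhancement_analysis,
    permutation_test,
)
from crosstalk.exceptions import VocabularyMismatchError


def table(counts, condition="case", n_iter=100, types=("A", "B", "C")):
    return EdgeCountTable(
        condition=condition, n_iter=n_iter, counts=counts, cell_types=types
    )


@pytest.fixture(scope="module")
def planted_expr():
    """Case carries a 4-type network with strong edges; control none."""
    truth = sim.make_truth(n_types=4, n_edges=2, seed=3, edge_strengths=(0.96,), leak=0.02, fraction_sd=0.01)
    control = sim.make_truth(n_types=4, n_edges=0, seed=3)
    expr = sim.simulate_case_control(
        truth, control, n_samples=20, cells_per_sample=600, seed=4
    )
    return expr, truth


class TestBootstrapEdges:
    def test_single_iteration_deterministic(self, planted_expr):
        expr, truth = planted_expr
        kw = dict(n_iter=1, min_cells=10, seed=11, cell_types=list(truth.cell_types))
        a = bootstrap_edges(expr, "case", **kw)
        b = bootstrap_edges(expr, "case", **kw)
        assert a.counts == b.counts
        assert all(c in (0, 1) for c in a.counts.values())

    def test_counts_bounded_and_no_self_pairs(self, planted_expr):
        expr, truth = planted_expr
        t = bootstrap_edges(
            expr, "case", n_iter=5, min_cells=10, seed=0,
            cell_types=list(truth.cell_types),
        )
        for (u, v), c in t.counts.items():
            assert u != v and 0 <= c <= 5

    def test_planted_dependence_dominates(self, planted_expr):
        expr, truth = planted_expr
        t = bootstrap_edges(
            expr, "case", n_iter=20, min_cells=10, seed=1,
            cell_types=list(truth.cell_types),
        )
        und = t.undirected()
        planted = {frozenset(e) for e in truth.edges}
        best_planted = min(und.get(p, 0) for p in planted)
        worst_null = max(
            (c for p, c in und.items() if p not in planted), default=0
        )
        assert best_planted >= 15
        assert worst_null <= 5

    def test_cell_frac_one_identical_iterations(self, planted_expr):
        # without subsampling every iteration sees the same composition, so
        # pair-level support is all-or-nothing; only the orientation of
        # direction-unidentifiable edges may alternate between iterations
        expr, truth = planted_expr
        t = bootstrap_edges(
            expr, "case", n_iter=5, cell_frac=1.0, min_cells=10, seed=2,
            cell_types=list(truth.cell_types),
        )
        assert all(c in (0, 5) for c in t.undirected().values())

    def test_unknown_condition_raises(self, planted_expr):
        expr, _ = planted_expr
        with pytest.raises(ValueError, match="nope"):
            bootstrap_edges(expr, "nope", n_iter=1, min_cells=10)


class TestDifferentialEdges:
    def test_exclusive_edge_scores_plus_n_iter(self):
        case = table({("T_Regulatory", "Fibroblast"): 100}, types=("T_Regulatory", "Fibroblast"))
        control = table({}, condition="control", types=("T_Regulatory", "Fibroblast"))
        (edge,) = differential_edges(case, control, threshold=20)
        assert edge.score == 100 and edge.case_count == 100

    def test_below_threshold_excluded(self):
        case = table({("A", "B"): 15})
        control = table({("A", "B"): 15}, condition="control")
        assert differential_edges(case, control, threshold=20) == []

    def test_identical_tables_score_zero(self):
        counts = {("A", "B"): 60, ("B", "C"): 30}
        out = differential_edges(table(counts), table(counts, "control"))
        assert all(e.score == 0 for e in out) and len(out) == 2

    def test_sorted_by_magnitude_then_name(self):
        case = table({("A", "B"): 90, ("B", "C"): 40, ("A", "C"): 65})
        control = table({("B", "C"): 100}, condition="control")
        out = differential_edges(case, control)
        assert [e.pair for e in out] == [("A", "B"), ("A", "C"), ("B", "C")]
        frame = differential_frame(out)
        assert list(frame.columns) == [
            "cell_type1", "cell_type2", "case_count", "control_count", "score"
        ]

    def test_mismatched_n_iter_rejected(self):
        with pytest.raises(ValueError, match="n_iter"):
            differential_edges(table({}, n_iter=100), table({}, n_iter=50))


class TestEnhancement:
    def _pairs(self, orig_case, orig_ctrl, comb_case, comb_ctrl):
        return (
            (table(orig_case), table(orig_ctrl, "control")),
            (table(comb_case), table(comb_ctrl, "control")),
        )

    def test_grown_positive_score_is_enhanced(self):
        orig, comb = self._pairs({("A", "B"): 40}, {}, {("A", "B"): 61}, {})
        out = enhancement_analysis(orig, comb)
        assert out.loc[0, "enhanced"] and out.loc[0, "combined_score"] == 61

    def test_grown_negative_score_is_enhanced(self):
        orig, comb = self._pairs({}, {("A", "B"): 40}, {}, {("A", "B") : 43})
        out = enhancement_analysis(orig, comb, threshold=20)
        # -40 -> -43: same sign, larger magnitude
        assert out.loc[0, "enhanced"]

    def test_shrunk_magnitude_not_enhanced(self):
        orig, comb = self._pairs({("A", "B"): 40}, {}, {("A", "B"): 35}, {})
        assert not enhancement_analysis(orig, comb).loc[0, "enhanced"]

    def test_sign_flip_not_enhanced(self):
        orig, comb = self._pairs({("A", "B"): 40}, {}, {}, {("A", "B"): 80})
        assert not enhancement_analysis(orig, comb).loc[0, "enhanced"]

    def test_vocabulary_mismatch_lists_types(self):
        orig = (table({("A", "B"): 40}), table({}, "control"))
        comb = (
            table({}, types=("X", "Y")),
            table({}, "control", types=("X", "Y")),
        )
        with pytest.raises(VocabularyMismatchError, match="'A'.*'B'"):
            enhancement_analysis(orig, comb)


class TestPermutationTest:
    @pytest.fixture(scope="class")
    def two_cohorts(self):
        truth = sim.make_truth(n_types=4, n_edges=2, seed=3, edge_strengths=(0.9,), leak=0.05, fraction_sd=0.01)
        null = sim.make_truth(n_types=4, n_edges=0, seed=3)
        rngs = np.random.SeedSequence(9).generate_state(2) % 2**31
        base = sim.simulate_case_control(
            truth, null, n_samples=10, cells_per_sample=150, seed=int(rngs[0])
        )
        new = sim.simulate_case_control(
            truth, null, n_samples=8, cells_per_sample=150, seed=int(rngs[1])
        )
        new.obs["sample_id"] = "new_" + new.obs["sample_id"].astype(str)
        return base, new

    def test_p_value_in_unit_interval_and_never_zero(self, two_cohorts):
        base, new = two_cohorts
        res = permutation_test(
            base, new, n_perm=20, threshold=5, n_iter=5, min_cells=10, seed=0
        )
        assert 0 < res.p_value <= 1
        assert len(res.null) == 20

    def test_add_one_formula(self):
        # direct check of the estimator on a synthetic null
        null = np.array([0.1] * 99)
        observed = 0.5
        p = (1 + (null >= observed).sum()) / (1 + len(null))
        assert p == pytest.approx(0.01)

    def test_small_n_perm_warns(self, two_cohorts):
        base, new = two_cohorts
        with pytest.warns(UserWarning, match="resolution"):
            permutation_test(
                base, new, n_perm=5, threshold=5, n_iter=3, min_cells=10, seed=1
            )

    def test_overlapping_sample_ids_rejected(self, two_cohorts):
        base, _ = two_cohorts
        with pytest.raises(ValueError, match="overlap"):
            permutation_test(base, base, n_perm=20, n_iter=2, min_cells=10)

    def test_self_null_p_value_not_extreme(self, two_cohorts):
        """When the 'new' cohort is itself a label permutation, the observed
        enhancement is a draw from the null, so p should not be small."""
        base, new = two_cohorts
        rng = np.random.default_rng(4)
        shuffled = new.copy()
        types = sorted(shuffled.obs["cell_type"].unique())
        for s in shuffled.obs["sample_id"].unique():
            perm = dict(zip(types, rng.permutation(types)))
            sel = shuffled.obs["sample_id"] == s
            shuffled.obs.loc[sel, "cell_type"] = shuffled.obs.loc[
                sel, "cell_type"
            ].map(perm)
        ps = [
            permutation_test(
                base, shuffled, n_perm=19, threshold=5, n_iter=4,
                min_cells=10, seed=seed,
            ).p_value
            for seed in range(3)
        ]
        assert np.median(ps) >= 0.2
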