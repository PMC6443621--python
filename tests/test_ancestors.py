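import dendropy
import numpy as np
import pytest

from beetlemorph.ancestors import (
    PhyloShapeMap,
    compare_nodes_to_groups,
    length_width_ratio,
    reconstruct_ancestral_shapes,
    squared_change_parsimony,
)
from beetlemorph.errors import ParameterError, ReconciliationError
from beetlemorph.procrustes import gpa

from conftest import balanced_tree_newick, random_tree_newick


def get_tree(newick):
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = True
    return tree


def incidence_least_squares(tree, tip_values):
    """Independent oracle: minimize the squared-change objective as a
    linear least-squares problem over the edge-incidence matrix."""
    internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    idx = {id(n): i for i, n in enumerate(internal)}
    d = len(np.atleast_1d(next(iter(tip_values.values()))))
    rows = []
    consts = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        row = np.zeros(len(internal))
        const = np.zeros(d)
        row[idx[id(node.parent_node)]] = 1.0
        if node.is_leaf():
            const = np.atleast_1d(np.asarray(tip_values[node.taxon.label], float))
        else:
            row[idx[id(node)]] = -1.0
        rows.append(row)
        consts.append(const)
    A = np.asarray(rows)
    b = np.asarray(consts)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return {internal[i].label or f"#{i}": sol[i] for i in range(len(internal))}


class TestSquaredChangeParsimony:
    def test_star_tree_root_is_tip_mean(self):
        tree = get_tree("(A,B,C,D);")
        vals = {"A": 1.0, "B": 3.0, "C": 10.0, "D": 12.0}
        rec = squared_change_parsimony(tree, {k: np.array([v]) for k, v in vals.items()})
        (root_val,) = rec.values()
        assert root_val[0] == pytest.approx(6.5, abs=1e-12)

    @pytest.mark.parametrize("dim", [1, 3, 8])
    def test_star_tree_any_dimension(self, rng, dim):
        tree = get_tree("(A,B,C,D,E);")
        vals = {t: rng.normal(size=dim) for t in "ABCDE"}
        rec = squared_change_parsimony(tree, vals)
        (root_val,) = rec.values()
        np.testing.assert_allclose(root_val, np.mean(list(vals.values()), axis=0),
                                   atol=1e-12)

    def test_constant_tips_propagate(self):
        tree = get_tree(balanced_tree_newick(8))
        vals = {f"t{i}": np.array([4.0, -1.0]) for i in range(8)}
        rec = squared_change_parsimony(tree, vals)
        for v in rec.values():
            np.testing.assert_allclose(v, [4.0, -1.0], atol=1e-12)

    def test_four_taxon_matches_least_squares(self):
        tree = get_tree("((t0,t1),(t2,t3));")
        vals = {"t0": np.array([1.0]), "t1": np.array([3.0]),
                "t2": np.array([10.0]), "t3": np.array([12.0])}
        rec = squared_change_parsimony(tree, vals)
        oracle = incidence_least_squares(get_tree("((t0,t1),(t2,t3));"), vals)
        for (ka, va), (kb, vb) in zip(sorted(rec.items()), sorted(oracle.items())):
            np.testing.assert_allclose(va, vb, atol=1e-8)

    def test_random_trees_match_least_squares(self, rng):
        for s in range(20):
            n = int(rng.integers(3, 9))
            newick = random_tree_newick(rng, n)
            vals = {f"t{i}": rng.normal(size=2) for i in range(n)}
            from beetlemorph.ancestors import label_internal_nodes

            t1, t2 = get_tree(newick), get_tree(newick)
            rec = squared_change_parsimony(t1, vals)
            label_internal_nodes(t2)  # same preorder labels as t1 received
            oracle = incidence_least_squares(t2, vals)
            for label, v in rec.items():
                np.testing.assert_allclose(v, oracle[label], atol=1e-8)

    def test_local_optimality(self, rng):
        newick = random_tree_newick(rng, 7)
        tree = get_tree(newick)
        vals = {f"t{i}": rng.normal(size=2) for i in range(7)}
        rec = squared_change_parsimony(tree, vals)

        def objective(node_vals):
            total = 0.0
            for node in tree.preorder_node_iter():
                if node.parent_node is None:
                    continue
                child = (
                    vals[node.taxon.label]
                    if node.is_leaf()
                    else node_vals[node.label]
                )
                total += np.sum((node_vals[node.parent_node.label] - child) ** 2)
            return total

        best = objective(rec)
        for _ in range(1000):
            perturbed = {k: v + rng.normal(0, 0.1, v.shape) for k, v in rec.items()}
            assert objective(perturbed) >= best - 1e-12

    def test_linearity(self, rng):
        newick = random_tree_newick(rng, 6)
        X = {f"t{i}": rng.normal(size=3) for i in range(6)}
        Y = {f"t{i}": rng.normal(size=3) for i in range(6)}
        a, b = 2.5, -1.25
        combo = {k: a * X[k] + b * Y[k] for k in X}
        rx = squared_change_parsimony(get_tree(newick), X)
        ry = squared_change_parsimony(get_tree(newick), Y)
        rc = squared_change_parsimony(get_tree(newick), combo)
        for label in rc:
            np.testing.assert_allclose(rc[label], a * rx[label] + b * ry[label],
                                       atol=1e-10)

    def test_unrooted_rejected(self):
        tree = get_tree("(A,B,C);")
        tree.is_rooted = False
        with pytest.raises(ParameterError):
            squared_change_parsimony(tree, {t: np.zeros(1) for t in "ABC"})

    def test_missing_tip_named(self):
        tree = get_tree("(A,B);")
        with pytest.raises(ReconciliationError, match="B"):
            squared_change_parsimony(tree, {"A": np.zeros(1)})


class TestReconstructShapes:
    def test_two_tip_midpoint(self, rng):
        tree = get_tree("(A,B);")
        sa = rng.normal(size=(6, 2))
        sb = rng.normal(size=(6, 2))
        out = reconstruct_ancestral_shapes(
            PhyloShapeMap(tree=tree, tip_shapes={"A": sa, "B": sb})
        )
        (root,) = out.node_shapes.values()
        np.testing.assert_allclose(root, (sa + sb) / 2, atol=1e-12)

    def test_rotation_equivariance(self, rng):
        newick = random_tree_newick(rng, 6)
        shapes = {f"t{i}": rng.normal(size=(5, 2)) for i in range(6)}
        theta = 0.9
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        out1 = reconstruct_ancestral_shapes(
            PhyloShapeMap(tree=get_tree(newick), tip_shapes=shapes)
        )
        out2 = reconstruct_ancestral_shapes(
            PhyloShapeMap(
                tree=get_tree(newick),
                tip_shapes={k: v @ R.T for k, v in shapes.items()},
            )
        )
        for label in out1.node_shapes:
            np.testing.assert_allclose(
                out2.node_shapes[label], out1.node_shapes[label] @ R.T, atol=1e-10
            )

    def test_root_error_shrinks_with_tip_count(self):
        # consistency: at fixed tree height (same evolutionary time), denser
        # taxon sampling averages away more Brownian noise at the root
        from beetlemorph.procrustes import procrustes_distance
        from beetlemorph.simulate import make_base_outline, simulate_bm_on_tree

        base = make_base_outline("pronotum", 25)
        errors = {}
        for n_tips, depth in ((8, 3), (64, 6)):
            errs = []
            for s in range(60):
                tree = get_tree(balanced_tree_newick(n_tips))
                sim = simulate_bm_on_tree(
                    tree, base, rate=5e-4, seed=s, branch_length=1.0 / depth
                )
                out = reconstruct_ancestral_shapes(
                    PhyloShapeMap(tree=tree, tip_shapes=sim.tip_shapes)
                )
                root_label = tree.seed_node.label
                errs.append(
                    procrustes_distance(out.node_shapes[root_label], base)
                )
            errors[n_tips] = np.mean(errs)
        assert errors[64] < errors[8]


class TestNodeAffinity:
    def test_node_at_group_mean(self, rng):
        consensus = rng.normal(size=(5, 2))
        consensus /= np.linalg.norm(consensus - consensus.mean(0))
        consensus -= consensus.mean(0)
        X = np.vstack(
            [rng.normal(0, 0.01, (10, 10)), rng.normal(0.3, 0.01, (10, 10))]
        )
        labels = np.array(["near"] * 10 + ["far"] * 10)
        node_shape = (consensus.ravel() + X[:10].mean(axis=0)).reshape(5, 2)
        table = compare_nodes_to_groups({"n1": node_shape}, X, labels, consensus)
        row = table.iloc[0]
        assert row["nearest_mahalanobis"] == "near"
        assert row["nearest_procrustes"] == "near"
        assert row["procrustes_near"] < 1e-10

    def test_symmetric_tie_reported(self, rng):
        consensus = np.array([[1.0, 0], [0, 1], [-1, 0], [0, -1]])
        consensus = consensus / np.linalg.norm(consensus)
        d = 8
        offset = np.zeros(d)
        offset[0] = 0.5
        A = rng.normal(0, 0.01, (20, d)) + offset
        B = rng.normal(0, 0.01, (20, d)) - offset
        # exactly symmetrize the two groups so the midpoint node ties
        B = -A
        X = np.vstack([A, B])
        labels = np.array(["plus"] * 20 + ["minus"] * 20)
        node = consensus  # zero tangent deviation: equidistant by symmetry
        table = compare_nodes_to_groups({"mid": node}, X, labels, consensus)
        assert table.iloc[0]["nearest_mahalanobis"] == "minus|plus"


class TestLengthWidthRatio:
    def test_square_and_rectangle(self):
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        assert length_width_ratio(square) == pytest.approx(1.0)
        rect = np.array([[0, 0], [2, 0], [2, 1], [0, 1]], dtype=float)
        assert length_width_ratio(rect) == pytest.approx(2.0)

    def test_ellipse_ratio(self):
        t = np.linspace(0, 2 * np.pi, 2000, endpoint=False)
        ellipse = np.column_stack([1.571 * np.cos(t), np.sin(t)])
        assert length_width_ratio(ellipse) == pytest.approx(1.571, abs=0.01)

    def test_orientation_invariance(self, rng):
        t = np.linspace(0, 2 * np.pi, 500, endpoint=False)
        ellipse = np.column_stack([2.0 * np.cos(t), np.sin(t)])
        theta = rng.uniform(0, np.pi)
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        assert length_width_ratio(ellipse @ R.T) == pytest.approx(
            length_width_ratio(ellipse), rel=1e-9
        )

    def test_degenerate(self):
        with pytest.raises(ParameterError):
            length_width_ratio(np.column_stack([np.arange(5.0), np.zeros(5)]))
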