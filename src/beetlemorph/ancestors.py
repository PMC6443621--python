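"""Squared-change-parsimony reconstruction of ancestral shapes.

Ancestral states on a rooted tree minimize the sum over edges of the
squared change divided by branch length.  This is a convex quadratic
problem whose stationarity conditions are linear: each internal node's
value is the branch-length-weighted mean of its neighbors' values, which
we solve exactly (per coordinate, all coordinates at once) via a sparse
graph-Laplacian system.  Equal branch lengths — the same expected amount
of change on every branch — are the default evolutionary model.

Because the estimator is linear in the tip data, reconstructing a
landmark configuration coordinate-wise is rotation-equivariant and can
be applied directly to Procrustes-aligned tip shapes.

Node-versus-extant-group affinities report both the Mahalanobis distance
(pooled within-group covariance over all extant groups) and the partial
Procrustes distance to each group's mean shape; the two metrics can
legitimately disagree and both nearest groups are recorded, with ties
reported rather than broken.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.linalg import spsolve

from beetlemorph.errors import ParameterError, ReconciliationError, ShapeMismatchError
from beetlemorph.discriminate import mahalanobis_distance, pooled_within_covariance
from beetlemorph.procrustes import procrustes_distance

__all__ = [
    "PhyloShapeMap",
    "label_internal_nodes",
    "squared_change_parsimony",
    "reconstruct_ancestral_shapes",
    "compare_nodes_to_groups",
    "length_width_ratio",
]

log = logging.getLogger(__name__)


def label_internal_nodes(tree: dendropy.Tree, fmt: str = "node{}") -> dendropy.Tree:
    """Assign deterministic labels to unlabeled internal nodes (preorder,
    numbering from 1 at the root)."""
    i = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        i += 1
        if not node.label:
            node.label = fmt.format(i)
    return tree


def _node_key(node: dendropy.Node) -> str:
    if node.is_leaf():
        return node.taxon.label
    return node.label


def squared_change_parsimony(
    tree: dendropy.Tree,
    tip_values: dict[str, np.ndarray],
    branch_length: float = 1.0,
    use_tree_lengths: bool = False,
) -> dict[str, np.ndarray]:
    """Exact squared-change-parsimony states for all internal nodes.

    Minimizes sum_edges ||value(parent) - value(child)||^2 / length(edge)
    with the root value free.  ``branch_length`` (default 1.0) is applied
    to every edge unless ``use_tree_lengths`` requests the tree's own
    lengths.  Returns internal-node label -> value vector.
    """
    if not tree.is_rooted:
        raise ParameterError("tree must be rooted; root it before reconstruction")
    leaves = [l for l in tree.leaf_node_iter()]
    if len(leaves) < 2:
        raise ParameterError("tree needs at least 2 tips")
    for leaf in leaves:
        if leaf.taxon.label not in tip_values:
            raise ReconciliationError(f"tip {leaf.taxon.label!r} has no value")
    dims = {np.atleast_1d(np.asarray(v, dtype=float)).shape for v in tip_values.values()}
    if len(dims) != 1:
        raise ShapeMismatchError(f"tip values differ in shape: {sorted(dims)}")
    label_internal_nodes(tree)
    internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    index = {id(n): i for i, n in enumerate(internal)}
    d = int(np.prod(next(iter(dims))))
    m = len(internal)
    rows, cols, vals = [], [], []
    rhs = np.zeros((m, d))
    diag = np.zeros(m)
    for node in internal:
        i = index[id(node)]
        neighbors = list(node.child_nodes())
        if node.parent_node is not None:
            neighbors.append(node.parent_node)
        for nb in neighbors:
            child = nb if nb in node.child_nodes() else node
            edge_len = branch_length
            if use_tree_lengths:
                edge_len = child.edge.length
                if edge_len is None or edge_len <= 0:
                    raise ParameterError(
                        f"edge above {_node_key(child)!r} lacks a positive length"
                    )
            w = 1.0 / edge_len
            diag[i] += w
            if nb.is_leaf():
                rhs[i] += w * np.asarray(tip_values[nb.taxon.label], dtype=float).ravel()
            else:
                rows.append(i)
                cols.append(index[id(nb)])
                vals.append(-w)
    rows.extend(range(m))
    cols.extend(range(m))
    vals.extend(diag)
    L = csr_matrix((vals, (rows, cols)), shape=(m, m))
    sol = spsolve(L, rhs)
    sol = np.atleast_2d(sol)
    if sol.shape != (m, d):  # spsolve squeezes single-column systems
        sol = sol.reshape(m, d)
    shape = next(iter(dims))
    return {internal[i].label: sol[i].reshape(shape) for i in range(m)}


@dataclass
class PhyloShapeMap:
    """A rooted tree whose tips carry mean shapes and whose internal
    nodes carry reconstructed ancestral configurations."""

    tree: dendropy.Tree
    tip_shapes: dict[str, np.ndarray]  # tip label -> k x 2
    node_shapes: dict[str, np.ndarray] = field(default_factory=dict)
    branch_length: float = 1.0


def reconstruct_ancestral_shapes(shape_map: PhyloShapeMap) -> PhyloShapeMap:
    """Fill ``node_shapes`` by squared-change parsimony on the flattened
    landmark coordinates (each structure reconstructed independently)."""
    ks = {v.shape for v in shape_map.tip_shapes.values()}
    if len(ks) != 1:
        raise ShapeMismatchError(f"tip shapes differ in landmark count: {sorted(ks)}")
    node_values = squared_change_parsimony(
        shape_map.tree,
        {k: v.ravel() for k, v in shape_map.tip_shapes.items()},
        branch_length=shape_map.branch_length,
    )
    k = next(iter(ks))
    shape_map.node_shapes = {name: v.reshape(k) for name, v in node_values.items()}
    return shape_map


def compare_nodes_to_groups(
    node_shapes: dict[str, np.ndarray],
    tangent,
    labels,
    consensus: np.ndarray,
    tie_rel_tol: float = 1e-9,
) -> pd.DataFrame:
    """Distance from each reconstructed node to each extant group.

    For every node: the Mahalanobis distance to each group's tangent mean
    (pooled within-group covariance over all extant groups) and the
    partial Procrustes distance to each group's mean configuration.  The
    nearest group under each metric is recorded; exact ties are reported
    joined with '|'.  Groups with fewer than 2 members are excluded from
    the Mahalanobis columns (covariance undefined) with a log entry.
    """
    X = np.asarray(tangent, dtype=float)
    labels = np.asarray(labels)
    names = sorted(pd.unique(labels))
    big = [g for g in names if (labels == g).sum() >= 2]
    for g in names:
        if g not in big:
            log.info("group %r has < 2 members; excluded from Mahalanobis affinity", g)
    mask = np.isin(labels, big)
    pooled = pooled_within_covariance(X[mask], labels[mask])
    means = {g: X[labels == g].mean(axis=0) for g in names}
    mean_configs = {
        g: (consensus.ravel() + means[g]).reshape(consensus.shape) for g in names
    }
    rows = []
    for node, shape in node_shapes.items():
        node_tan = shape.ravel() - consensus.ravel()
        row: dict = {"node": node}
        mah = {}
        # node deviations may have small components outside the retained
        # basis of the extant covariance; the distance is restricted to it
        for g in big:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mah[g] = mahalanobis_distance(node_tan, means[g], pooled)
            row[f"mahalanobis_{g}"] = mah[g]
        proc = {}
        for g in names:
            proc[g] = procrustes_distance(shape, mean_configs[g])
            row[f"procrustes_{g}"] = proc[g]
        row["nearest_mahalanobis"] = _argmin_with_ties(mah, tie_rel_tol)
        row["nearest_procrustes"] = _argmin_with_ties(proc, tie_rel_tol)
        rows.append(row)
    return pd.DataFrame(rows)


def _argmin_with_ties(dists: dict[str, float], rel_tol: float) -> str:
    best = min(dists.values())
    tol = rel_tol * max(best, 1e-300)
    winners = sorted(g for g, v in dists.items() if v <= best + tol)
    return "|".join(winners)


def length_width_ratio(config) -> float:
    """Extent along the configuration's first principal axis divided by
    the greatest extent along the perpendicular axis.

    The anatomical length/width of an outline, measured label-free by
    aligning the configuration to its own principal axes.
    """
    pts = np.asarray(config, dtype=float)
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered
    _, vecs = np.linalg.eigh(cov)
    proj = centered @ vecs[:, ::-1]  # major axis first
    length = float(np.ptp(proj[:, 0]))
    width = float(np.ptp(proj[:, 1]))
    if width == 0.0:
        raise ParameterError("degenerate configuration: zero width")
    return length / width
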