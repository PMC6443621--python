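"""Group discrimination: pooled covariance, Mahalanobis distance, CVA,
and permutation tests of group separation.

Procrustes-aligned 2-D shape data are rank-deficient (4 degrees of
freedom are removed by translation, rotation and scaling), so every
covariance-based statistic here works in a retained eigenbasis: the
subspace of pooled within-group covariance eigenvalues exceeding
``1e-9 * lambda_max``.  Mahalanobis distances use the pseudo-inverse
restricted to that basis; canonical variates are computed in the
whitened retained space, which makes the pooled within-group covariance
of the canonical scores exactly the identity.

Permutation tests permute group labels freely (group sizes fixed) and
use the add-one Monte-Carlo p-value estimator
``p = (#{null >= observed} + 1) / (rounds + 1)``, which is never 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from beetlemorph.errors import ParameterError

__all__ = [
    "PooledCovariance",
    "CvaResult",
    "PermutationResult",
    "pooled_within_covariance",
    "mahalanobis_distance",
    "cva",
    "permutation_test",
    "pairwise_group_tests",
]

log = logging.getLogger(__name__)

DEFAULT_SEED = 20190325
RANK_TOL = 1e-9


@dataclass
class PooledCovariance:
    """Pooled within-group covariance with its retained eigenbasis."""

    matrix: np.ndarray  # d x d
    eigenvalues: np.ndarray  # retained, descending
    retained_basis: np.ndarray  # d x r orthonormal columns
    rank: int
    n: int
    n_groups: int


def _group_indices(labels) -> dict[str, np.ndarray]:
    labels = np.asarray(labels)
    return {g: np.flatnonzero(labels == g) for g in pd.unique(labels)}


def pooled_within_covariance(tangent, labels, rank_tol: float = RANK_TOL) -> PooledCovariance:
    """Sum of per-group centered cross-products divided by (n - g)."""
    X = np.asarray(tangent, dtype=float)
    groups = _group_indices(labels)
    if len(groups) < 2:
        raise ParameterError("need at least 2 groups")
    for g, idx in groups.items():
        if len(idx) < 2:
            raise ParameterError(f"group {g!r} has a single member; covariance undefined")
    n, d = X.shape
    S = np.zeros((d, d))
    for idx in groups.values():
        C = X[idx] - X[idx].mean(axis=0)
        S += C.T @ C
    S /= n - len(groups)
    vals, vecs = np.linalg.eigh(S)
    vals, vecs = vals[::-1], vecs[:, ::-1]
    keep = vals > rank_tol * max(vals[0], 0.0)
    rank = int(keep.sum())
    return PooledCovariance(
        matrix=S,
        eigenvalues=vals[:rank],
        retained_basis=vecs[:, :rank],
        rank=rank,
        n=n,
        n_groups=len(groups),
    )


def mahalanobis_distance(mean_a, mean_b, pooled: PooledCovariance) -> float:
    """D = sqrt((mu_a - mu_b)^T W^+ (mu_a - mu_b)) in the retained basis."""
    if pooled.rank < 1:
        raise ParameterError("pooled covariance has rank 0")
    d = np.asarray(mean_a, dtype=float) - np.asarray(mean_b, dtype=float)
    y = pooled.retained_basis.T @ d
    outside = d - pooled.retained_basis @ y
    nd = np.linalg.norm(d)
    if nd > 0 and np.linalg.norm(outside) > 1e-6 * nd:
        warnings.warn(
            "mean difference has a component outside the retained covariance "
            "basis; Mahalanobis distance restricted to the basis",
            stacklevel=2,
        )
    return float(np.sqrt((y**2 / pooled.eigenvalues).sum()))


@dataclass
class CvaResult:
    """Canonical variate axes and scores."""

    axes: np.ndarray  # d x a (in original tangent coordinates)
    scores: np.ndarray  # n x a
    eigenvalues: np.ndarray  # a, between/within variance ratios, descending
    group_means: dict = field(default_factory=dict)  # group -> a-vector of mean scores
    pooled: PooledCovariance | None = None


def cva(tangent, labels) -> CvaResult:
    """Canonical variate analysis in the retained whitened basis.

    Solves the between- vs pooled-within-group generalized eigenproblem;
    at most (g - 1) axes.  Canonical scores have identity pooled
    within-group covariance, so squared Euclidean distances between group
    mean scores are squared Mahalanobis distances.
    """
    X = np.asarray(tangent, dtype=float)
    pooled = pooled_within_covariance(X, labels)
    groups = _group_indices(labels)
    g = len(groups)
    grand = X.mean(axis=0)
    # whiten: y = Lambda^{-1/2} U^T (x - grand)
    W = pooled.retained_basis / np.sqrt(pooled.eigenvalues)
    Y = (X - grand) @ W
    B = np.zeros((pooled.rank, pooled.rank))
    for idx in groups.values():
        m = Y[idx].mean(axis=0)
        B += len(idx) * np.outer(m, m)
    B /= max(g - 1, 1)
    vals, vecs = np.linalg.eigh(B)
    vals, vecs = vals[::-1], vecs[:, ::-1]
    a = min(g - 1, pooled.rank)
    vecs = vecs[:, :a]
    # deterministic sign convention, as in the ordination module
    for j in range(vecs.shape[1]):
        i = int(np.argmax(np.abs(vecs[:, j])))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    scores = Y @ vecs
    axes = W @ vecs
    labels_arr = np.asarray(labels)
    means = {gname: scores[idx].mean(axis=0) for gname, idx in groups.items()}
    return CvaResult(
        axes=axes,
        scores=scores,
        eigenvalues=np.maximum(vals[:a], 0.0),
        group_means=means,
        pooled=pooled,
    )


@dataclass
class PermutationResult:
    observed: float
    p_value: float
    rounds: int
    seed: int
    null_mean: float
    null_sd: float


def permutation_test(statistic, data, labels, rounds: int = 10000, seed: int = DEFAULT_SEED) -> PermutationResult:
    """Generic label-permutation test.

    ``statistic(data, labels)`` must be deterministic.  Labels are
    permuted uniformly at random (group sizes preserved by construction);
    ``p = (#{null >= observed} + 1) / (rounds + 1)``.
    """
    if rounds < 1:
        raise ParameterError(f"rounds must be >= 1, got {rounds}")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    observed = float(statistic(data, labels))
    null = np.empty(rounds)
    for i in range(rounds):
        null[i] = statistic(data, rng.permutation(labels))
    p = (int((null >= observed).sum()) + 1) / (rounds + 1)
    return PermutationResult(
        observed=observed,
        p_value=p,
        rounds=rounds,
        seed=seed,
        null_mean=float(null.mean()),
        null_sd=float(null.std()),
    )


def _pair_permutation_pvalues(Xp, n1, rounds, rng):
    """Vectorized two-group permutation p-values for one pair.

    ``Xp``: pair's data projected into the retained eigenbasis of its
    *total* covariance (fixed under label permutation), columns scaled so
    Euclidean norm = total-covariance Mahalanobis form.  Returns p-values
    for the Procrustes-distance statistic (norm of tangent mean
    difference) and the Mahalanobis statistic.

    For two groups the pooled within-group scatter is the total scatter
    minus the between term c * d d^T (c = n1*n2/n), so by
    Sherman–Morrison D^2 = (n-2) q / (1 - c q) with q = d^T T^+ d — a
    monotone function of q, which makes q an equivalent permutation
    statistic.
    """
    n = Xp.shape[0]
    n2 = n - n1
    c = n1 * n2 / n
    masks = np.zeros((rounds + 1, n), dtype=float)
    masks[0, :n1] = 1.0  # observed labeling: first n1 rows are group 1
    for r in range(1, rounds + 1):
        masks[r, rng.permutation(n)[:n1]] = 1.0
    # mean difference for each permutation, all at once
    sums1 = masks @ Xp
    total = Xp.sum(axis=0)
    d_euc = sums1 / n1 - (total - sums1) / n2
    proc_stat = np.linalg.norm(d_euc, axis=1)
    q = (d_euc**2).sum(axis=1)  # columns pre-whitened by total covariance
    p_proc = (int((proc_stat[1:] >= proc_stat[0]).sum()) + 1) / (rounds + 1)
    p_mah = (int((q[1:] >= q[0]).sum()) + 1) / (rounds + 1)
    return p_proc, p_mah


def pairwise_group_tests(
    tangent,
    labels,
    rounds: int = 10000,
    seed: int = DEFAULT_SEED,
    rank_tol: float = RANK_TOL,
) -> pd.DataFrame:
    """All pairwise Mahalanobis/Procrustes distances with permutation p-values.

    For each group pair: the Mahalanobis distance uses the pair's pooled
    within-group covariance (two-group discriminant analysis); the
    Procrustes distance is the norm of the tangent mean difference
    (partial Procrustes distance between mean shapes, exact to first
    order at the consensus).  Both are tested with ``rounds`` free label
    permutations.  Returns a tidy frame with one row per pair.
    """
    if rounds < 1:
        raise ParameterError(f"rounds must be >= 1, got {rounds}")
    X = np.asarray(tangent, dtype=float)
    labels = np.asarray(labels)
    groups = _group_indices(labels)
    names = sorted(groups)
    rows = []
    rng = np.random.default_rng(seed)
    for i, ga in enumerate(names):
        for gb in names[i + 1 :]:
            ia, ib = groups[ga], groups[gb]
            if len(ia) < 2 or len(ib) < 2:
                log.info("skipping pair (%s, %s): a group has < 2 members", ga, gb)
                continue
            pair = np.vstack([X[ia], X[ib]])
            n1 = len(ia)
            mu_a = X[ia].mean(axis=0)
            mu_b = X[ib].mean(axis=0)
            proc_d = float(np.linalg.norm(mu_a - mu_b))
            pooled = pooled_within_covariance(
                pair, ["a"] * n1 + ["b"] * len(ib), rank_tol=rank_tol
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mah_d = mahalanobis_distance(mu_a, mu_b, pooled)
            # project onto the pair's total-covariance eigenbasis (fixed
            # under permutation) and whiten for the Mahalanobis statistic
            centered = pair - pair.mean(axis=0)
            T = centered.T @ centered / (len(pair) - 1)
            tvals, tvecs = np.linalg.eigh(T)
            tvals, tvecs = tvals[::-1], tvecs[:, ::-1]
            keep = tvals > rank_tol * max(tvals[0], 0.0)
            Xw = centered @ (tvecs[:, keep] / np.sqrt(tvals[keep]))
            Xe = centered @ tvecs[:, keep]
            # Procrustes statistic needs unwhitened coordinates; run both
            p_proc, _ = _pair_permutation_pvalues(
                Xe, n1, rounds, np.random.default_rng(rng.integers(2**31))
            )
            _, p_mah = _pair_permutation_pvalues(
                Xw, n1, rounds, np.random.default_rng(rng.integers(2**31))
            )
            rows.append(
                {
                    "group_a": ga,
                    "group_b": gb,
                    "n_a": n1,
                    "n_b": len(ib),
                    "mahalanobis_d": mah_d,
                    "procrustes_d": proc_d,
                    "p_mahalanobis": p_mah,
                    "p_procrustes": p_proc,
                    "rounds": rounds,
                    "seed": seed,
                }
            )
    return pd.DataFrame(rows)


def distance_matrix_layout(pairs: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Square groups x groups table: distances below the diagonal,
    permutation p-values above (the supplementary-table layout)."""
    names = sorted(set(pairs["group_a"]) | set(pairs["group_b"]))
    M = pd.DataFrame(np.nan, index=names, columns=names)
    dcol = f"{metric}_d"
    pcol = f"p_{metric}"
    for _, r in pairs.iterrows():
        a, b = r["group_a"], r["group_b"]
        lo, hi = sorted([a, b])
        M.loc[hi, lo] = r[dcol]
        M.loc[lo, hi] = r[pcol]
    return M
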