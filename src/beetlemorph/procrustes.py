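"""Generalized Procrustes analysis and Procrustes shape distances.

Configurations of k landmarks in 2-D are placed in a common shape space
by removing position (centroid at the origin), size (unit centroid size)
and orientation (least-squares rotation to an iteratively re-estimated
consensus).  Reflections are excluded throughout: all specimens are
digitized in a consistent dorsal orientation, so an improper fit could
only arise from silently flipping a near-symmetric outline.

After convergence the consensus is rotated to a canonical orientation
(major principal axis along x, sign fixed by the largest-magnitude
coordinate), which makes the aligned coordinates invariant — not just
equivariant — under arbitrary similarity transforms of the inputs.

Tangent-space coordinates are the orthogonal projection of the aligned
(unit-size) configurations onto the linear tangent space at the
consensus; multivariate statistics downstream operate on these.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from beetlemorph.errors import DegenerateShapeError, ShapeMismatchError

__all__ = [
    "AlignedSet",
    "center_and_scale",
    "centroid_size",
    "gpa",
    "optimal_rotation",
    "procrustes_distance",
    "tangent_project",
]


def centroid_size(coords) -> float:
    """Root summed squared distances of landmarks from their centroid."""
    c = np.asarray(coords, dtype=float)
    return float(np.sqrt(((c - c.mean(axis=0)) ** 2).sum()))


def center_and_scale(coords):
    """Translate centroid to origin and scale to unit centroid size.

    Returns ``(normalized k x 2 array, original centroid size)``.
    """
    c = np.asarray(coords, dtype=float)
    centered = c - c.mean(axis=0)
    size = np.sqrt((centered**2).sum())
    if size == 0.0:
        raise DegenerateShapeError("all landmarks coincide; zero centroid size")
    return centered / size, float(size)


def optimal_rotation(A, B) -> np.ndarray:
    """Proper rotation R (2x2, det +1) minimizing ||A @ R - B||_F.

    Solved by singular-value decomposition of ``A.T @ B`` with the
    reflection branch excluded by a sign correction on the smallest
    singular vector.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    U, _, Vt = np.linalg.svd(A.T @ B)
    d = np.sign(np.linalg.det(U @ Vt))
    if d == 0:
        d = 1.0
    D = np.diag([1.0, d])
    return U @ D @ Vt


def _canonical_rotation(consensus: np.ndarray) -> np.ndarray:
    """Proper rotation taking the consensus to a deterministic orientation.

    Major principal axis of the consensus along x; sign chosen so the
    flattened consensus coordinate of largest magnitude is positive.
    """
    cov = consensus.T @ consensus
    vals, vecs = np.linalg.eigh(cov)
    # eigh returns ascending; principal axis last
    v1 = vecs[:, 1]
    v2 = np.array([-v1[1], v1[0]])  # +90 deg, guarantees det +1
    R = np.column_stack([v1, v2])
    rotated = consensus @ R
    flat = rotated.ravel()
    j = int(np.argmax(np.abs(flat)))
    if flat[j] < 0:
        R = -R  # 180-degree flip, still proper
    return R


@dataclass
class AlignedSet:
    """Result of generalized Procrustes analysis.

    ``aligned`` holds the superimposed configurations (centroid at origin,
    unit centroid size); ``consensus`` is the renormalized mean shape;
    ``tangent`` the n x 2k orthogonal tangent-space projections.
    """

    aligned: np.ndarray  # n x k x 2
    consensus: np.ndarray  # k x 2
    centroid_sizes: np.ndarray  # n
    tangent: np.ndarray  # n x 2k
    iterations: int
    converged: bool
    labels: list[str] | None = None

    @property
    def n(self) -> int:
        return self.aligned.shape[0]

    @property
    def k(self) -> int:
        return self.aligned.shape[1]


def _align_all(normed: np.ndarray, consensus: np.ndarray) -> np.ndarray:
    out = np.empty_like(normed)
    for i in range(normed.shape[0]):
        out[i] = normed[i] @ optimal_rotation(normed[i], consensus)
    return out


def gpa(configs, tol: float = 1e-8, max_iter: int = 100, labels=None) -> AlignedSet:
    """Generalized Procrustes superimposition of an n x k x 2 stack.

    Iterates: normalize all configurations, rotate each to the current
    consensus, recompute the consensus as the renormalized arithmetic
    mean, until the root-mean-square consensus shift drops below ``tol``.
    The consensus is initialized from the first configuration and
    canonically oriented on exit, so the output is invariant under
    similarity transforms of any input.

    Non-convergence within ``max_iter`` returns the partial result with
    ``converged=False``.
    """
    arr = np.asarray(configs, dtype=float)
    if arr.ndim != 3 or arr.shape[2] != 2:
        raise ShapeMismatchError(f"expected n x k x 2 array, got shape {arr.shape}")
    n, k, _ = arr.shape
    if n < 2:
        raise ShapeMismatchError("GPA needs at least 2 configurations")
    normed = np.empty_like(arr)
    sizes = np.empty(n)
    for i in range(n):
        normed[i], sizes[i] = center_and_scale(arr[i])
    consensus = normed[0].copy()
    iterations = 0
    converged = False
    aligned = normed
    for iterations in range(1, max_iter + 1):
        aligned = _align_all(normed, consensus)
        mean = aligned.mean(axis=0)
        norm = np.sqrt((mean**2).sum())
        if norm == 0.0:
            raise DegenerateShapeError("degenerate consensus (zero mean shape)")
        new_consensus = mean / norm
        # orient the new consensus consistently with the old one so the
        # convergence criterion measures shape change, not rotation drift
        new_consensus = new_consensus @ optimal_rotation(new_consensus, consensus)
        shift = np.sqrt(((new_consensus - consensus) ** 2).mean())
        consensus = new_consensus
        if shift < tol:
            converged = True
            break
    # final pass against the converged consensus, then canonicalize
    aligned = _align_all(normed, consensus)
    R = _canonical_rotation(consensus)
    consensus = consensus @ R
    aligned = aligned @ R
    result = AlignedSet(
        aligned=aligned,
        consensus=consensus,
        centroid_sizes=sizes,
        tangent=np.empty((n, 2 * k)),
        iterations=iterations,
        converged=converged,
        labels=list(labels) if labels is not None else None,
    )
    result.tangent = tangent_project(result)
    return result


def tangent_project(aligned: AlignedSet) -> np.ndarray:
    """Orthogonal projection of aligned shapes onto the tangent space.

    The tangent space at the consensus is the hyperplane orthogonal to
    the consensus direction (the scaling direction on the unit sphere of
    shapes).  Coordinates are deviations from the consensus, so the
    consensus itself maps to the zero vector.  The projection is
    idempotent.
    """
    c = aligned.consensus.ravel()
    c = c / np.linalg.norm(c)
    X = aligned.aligned.reshape(aligned.n, -1)
    return X - np.outer(X @ c, c)


def project_to_tangent(coords: np.ndarray, consensus: np.ndarray) -> np.ndarray:
    """Project flattened shape rows onto the tangent space at ``consensus``."""
    c = consensus.ravel()
    c = c / np.linalg.norm(c)
    X = np.atleast_2d(np.asarray(coords, dtype=float))
    return X - np.outer(X @ c, c)


def tangent_to_configuration(tangent_row: np.ndarray, consensus: np.ndarray) -> np.ndarray:
    """Map a tangent-space deviation vector back to a k x 2 configuration."""
    c = consensus.ravel()
    return (c + np.asarray(tangent_row, dtype=float)).reshape(consensus.shape)


def procrustes_distance(A, B) -> float:
    """Partial Procrustes distance between two configurations.

    Both shapes are normalized to unit centroid size and optimally
    rotated (proper rotations only); the distance is the root summed
    squared coordinate difference.  Symmetric, and zero iff the shapes
    are identical up to a similarity transform.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ShapeMismatchError(f"configurations differ in shape: {A.shape} vs {B.shape}")
    a, _ = center_and_scale(A)
    b, _ = center_and_scale(B)
    R = optimal_rotation(a, b)
    return float(np.linalg.norm(a @ R - b))
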