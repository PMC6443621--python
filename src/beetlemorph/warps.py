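"""Thin-plate-spline warps between landmark configurations.

The 2-D thin-plate spline interpolates a deformation that maps a
reference configuration exactly onto a target, decomposing it into an
affine part and a non-affine part whose smoothness cost is the bending
energy.  The kernel is U(r) = r^2 log r^2 with U(0) = 0, the standard
choice in the morphometric literature.  Bending energy is the quadratic
form of the non-affine weights in the kernel matrix; it vanishes exactly
when the target is an affine image of the reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from beetlemorph.errors import DegenerateShapeError, ShapeMismatchError

__all__ = ["TpsWarp", "tps_fit", "tps_evaluate", "deformation_grid"]


def _kernel(r2: np.ndarray) -> np.ndarray:
    # U(r) = r^2 log r^2, continuous at 0 with U(0) = 0
    out = np.zeros_like(r2)
    nz = r2 > 0
    out[nz] = r2[nz] * np.log(r2[nz])
    return out


@dataclass
class TpsWarp:
    reference: np.ndarray  # k x 2
    target: np.ndarray  # k x 2
    affine: np.ndarray  # 3 x 2: rows constant, x, y
    weights: np.ndarray  # k x 2 non-affine kernel weights
    bending_energy: float


def tps_fit(reference, target) -> TpsWarp:
    """Fit the interpolating thin-plate spline taking reference landmarks
    exactly onto target landmarks.

    Raises :class:`DegenerateShapeError` for a collinear reference (the
    interpolation system is singular).
    """
    ref = np.asarray(reference, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if ref.shape != tgt.shape or ref.ndim != 2 or ref.shape[1] != 2:
        raise ShapeMismatchError(
            f"reference/target must both be k x 2, got {ref.shape} and {tgt.shape}"
        )
    k = len(ref)
    if k < 3:
        raise ShapeMismatchError(f"thin-plate spline needs k >= 3 landmarks, got {k}")
    P = np.column_stack([np.ones(k), ref])
    if np.linalg.matrix_rank(P, tol=1e-10 * max(1.0, np.abs(ref).max())) < 3:
        raise DegenerateShapeError("collinear reference configuration; TPS system singular")
    diff = ref[:, None, :] - ref[None, :, :]
    K = _kernel((diff**2).sum(axis=2))
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = K
    L[:k, k:] = P
    L[k:, :k] = P.T
    rhs = np.zeros((k + 3, 2))
    rhs[:k] = tgt
    sol = np.linalg.solve(L, rhs)
    W = sol[:k]
    A = sol[k:]
    energy = float(np.einsum("id,ij,jd->", W, K, W))
    return TpsWarp(
        reference=ref,
        target=tgt,
        affine=A,
        weights=W,
        bending_energy=max(energy, 0.0),
    )


def tps_evaluate(warp: TpsWarp, points) -> np.ndarray:
    """Apply a fitted warp to arbitrary m x 2 points."""
    p = np.atleast_2d(np.asarray(points, dtype=float))
    diff = p[:, None, :] - warp.reference[None, :, :]
    U = _kernel((diff**2).sum(axis=2))
    P = np.column_stack([np.ones(len(p)), p])
    return P @ warp.affine + U @ warp.weights


def deformation_grid(warp: TpsWarp, cells: int = 20, margin: float = 0.2):
    """Warped grid lines for deformation plots.

    A (cells x cells)-cell grid spanning the reference bounding box
    enlarged by ``margin`` on each side; returns (horizontal, vertical)
    lists of warped polylines.
    """
    lo = warp.reference.min(axis=0)
    hi = warp.reference.max(axis=0)
    span = hi - lo
    lo = lo - margin / 2 * span
    hi = hi + margin / 2 * span
    xs = np.linspace(lo[0], hi[0], cells + 1)
    ys = np.linspace(lo[1], hi[1], cells + 1)
    dense_x = np.linspace(lo[0], hi[0], 10 * cells + 1)
    dense_y = np.linspace(lo[1], hi[1], 10 * cells + 1)
    horizontal = [
        tps_evaluate(warp, np.column_stack([dense_x, np.full_like(dense_x, y)]))
        for y in ys
    ]
    vertical = [
        tps_evaluate(warp, np.column_stack([np.full_like(dense_y, x), dense_y]))
        for x in xs
    ]
    return horizontal, vertical
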