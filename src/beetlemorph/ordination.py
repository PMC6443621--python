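"""Principal-component morphospace and equal-frequency ellipses.

PCA is an eigendecomposition of the sample covariance (divisor n-1) of
tangent-space coordinates.  Eigenvector signs are fixed deterministically
(the largest-magnitude loading of each axis is made positive) so scores
and plots are reproducible across runs and platforms.

A coverage-C equal-frequency ellipse for a group's 2-D scores is the
mean-centered covariance ellipse scaled by sqrt(chi2.ppf(C, df=2)); under
bivariate normality it contains a fraction ~C of the group's points.
Additional shapes (e.g. reconstructed ancestors) can be projected into an
existing ordination, or pooled with the extant data before ordination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from beetlemorph.errors import DegenerateShapeError, ParameterError, ShapeMismatchError

__all__ = ["ShapeSpace", "FrequencyEllipse", "pca", "equal_frequency_ellipse", "project_into"]


@dataclass
class ShapeSpace:
    """A fitted PCA of tangent coordinates."""

    mean: np.ndarray  # 2k
    eigenvectors: np.ndarray  # 2k x m, orthonormal columns
    eigenvalues: np.ndarray  # m, nonincreasing, >= 0
    scores: np.ndarray  # n x m
    variance_fraction: np.ndarray  # m

    @property
    def n_axes(self) -> int:
        return self.eigenvectors.shape[1]


@dataclass
class FrequencyEllipse:
    """An equal-frequency ellipse: center, semi-axes (nonincreasing), angle."""

    center: np.ndarray
    semi_axes: np.ndarray
    orientation: float  # radians, major axis vs +x
    coverage: float

    def contains(self, points) -> np.ndarray:
        """Boolean mask of points inside (or on) the ellipse."""
        p = np.atleast_2d(np.asarray(points, dtype=float)) - self.center
        ca, sa = np.cos(self.orientation), np.sin(self.orientation)
        u = p[:, 0] * ca + p[:, 1] * sa
        v = -p[:, 0] * sa + p[:, 1] * ca
        return (u / self.semi_axes[0]) ** 2 + (v / self.semi_axes[1]) ** 2 <= 1.0

    def boundary(self, n: int = 200) -> np.ndarray:
        """n x 2 polyline tracing the ellipse (for plotting)."""
        t = np.linspace(0, 2 * np.pi, n)
        xy = np.column_stack([self.semi_axes[0] * np.cos(t), self.semi_axes[1] * np.sin(t)])
        ca, sa = np.cos(self.orientation), np.sin(self.orientation)
        R = np.array([[ca, -sa], [sa, ca]])
        return xy @ R.T + self.center


def pca(tangent) -> ShapeSpace:
    """PCA of an n x d tangent matrix (sample covariance, divisor n-1)."""
    X = np.asarray(tangent, dtype=float)
    n, d = X.shape
    if n < 3:
        raise ParameterError(f"PCA needs n >= 3 rows, got {n}")
    mean = X.mean(axis=0)
    C = X - mean
    # SVD of the centered data is numerically safer than eigh of C.T @ C
    U, s, Vt = np.linalg.svd(C, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    vecs = Vt.T
    # deterministic sign: largest-magnitude loading positive per axis
    for j in range(vecs.shape[1]):
        i = int(np.argmax(np.abs(vecs[:, j])))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    scores = C @ vecs
    total = eigenvalues.sum()
    frac = eigenvalues / total if total > 0 else np.zeros_like(eigenvalues)
    return ShapeSpace(
        mean=mean,
        eigenvectors=vecs,
        eigenvalues=eigenvalues,
        scores=scores,
        variance_fraction=frac,
    )


def equal_frequency_ellipse(scores2d, coverage: float = 0.90) -> FrequencyEllipse:
    """Ellipse expected to contain a fraction ``coverage`` of a 2-D sample.

    Built from the sample mean and covariance, with radii scaled by the
    square root of the chi-square quantile at ``coverage`` with 2 degrees
    of freedom.
    """
    if not 0.0 < coverage < 1.0:
        raise ParameterError(f"coverage must be in (0, 1), got {coverage}")
    p = np.asarray(scores2d, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2:
        raise ShapeMismatchError(f"expected n x 2 scores, got shape {p.shape}")
    if len(p) < 3:
        raise ParameterError(f"ellipse needs n >= 3 points per group, got {len(p)}")
    center = p.mean(axis=0)
    cov = np.cov(p, rowvar=False)
    vals, vecs = np.linalg.eigh(cov)
    if vals[0] <= 0 or not np.isfinite(vals).all():
        raise DegenerateShapeError("singular group covariance; ellipse undefined")
    scale = stats.chi2.ppf(coverage, df=2)
    semi = np.sqrt(vals[::-1] * scale)  # nonincreasing
    major = vecs[:, 1]
    orientation = float(np.arctan2(major[1], major[0]))
    return FrequencyEllipse(center=center, semi_axes=semi, orientation=orientation, coverage=coverage)


def project_into(space: ShapeSpace, extra) -> np.ndarray:
    """Express extra tangent rows in an existing ordination's axes."""
    E = np.atleast_2d(np.asarray(extra, dtype=float))
    if E.shape[1] != space.mean.shape[0]:
        raise ShapeMismatchError(
            f"dimension mismatch: space is {space.mean.shape[0]}-D, extra is {E.shape[1]}-D"
        )
    return (E - space.mean) @ space.eigenvectors
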