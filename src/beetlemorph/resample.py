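"""Arc-length resampling of digitized outline curves.

A digitized outline is an ordered polyline; "resampling by length" places
``k`` semilandmarks at equal chord-length intervals along it, the first
and last coinciding exactly with the curve's endpoints.  Arc length is
measured on the piecewise-linear interpolant (chord length), not on a
spline fit, which is the reproducible behavior of outline-digitizing
tools.  No semilandmark sliding is applied: the resampled points are
treated as fixed landmarks downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from beetlemorph.errors import DegenerateShapeError, ParameterError

__all__ = ["ResampledCurve", "resample_by_arclength"]


@dataclass
class ResampledCurve:
    """A curve resampled to ``k`` equally spaced (by arc length) points."""

    points: np.ndarray  # k x 2
    k: int
    source_id: str = ""


def resample_by_arclength(curve, k: int, source_id: str = "") -> ResampledCurve:
    """Resample an open polyline to ``k`` points equally spaced by chord length.

    Output points lie on the piecewise-linear interpolant of the input at
    cumulative positions ``i * L / (k - 1)``, ``i = 0..k-1`` where ``L`` is
    total chord length.  Endpoints are preserved exactly.  ``k`` larger
    than the input resolution is fine (interpolation densifies).

    Raises
    ------
    ParameterError
        if ``k < 2`` or the curve has fewer than 2 points.
    DegenerateShapeError
        if all input points coincide (zero total length).
    """
    pts = np.asarray(curve, dtype=float).reshape(-1, 2)
    if k < 2:
        raise ParameterError(f"k must be >= 2, got {k}")
    if len(pts) < 2:
        raise ParameterError(f"curve needs >= 2 points, got {len(pts)}")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = seg.sum()
    if total == 0.0:
        raise DegenerateShapeError("all curve points coincide; zero arc length")
    # cumulative chord length at each input vertex
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, total, k)
    out = np.empty((k, 2))
    out[:, 0] = np.interp(targets, cum, pts[:, 0])
    out[:, 1] = np.interp(targets, cum, pts[:, 1])
    # endpoints exact regardless of interpolation round-off
    out[0] = pts[0]
    out[-1] = pts[-1]
    return ResampledCurve(points=out, k=k, source_id=source_id)
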