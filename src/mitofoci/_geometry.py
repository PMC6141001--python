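"""Closed-polygon arc-length geometry shared by simulation and profiling."""

from __future__ import annotations

import numpy as np

__all__ = ["ensure_ccw", "perimeter_length", "resample_boundary"]


def _closed(vertices: np.ndarray) -> np.ndarray:
    v = np.asarray(vertices, dtype=float)
    if np.all(v[0] == v[-1]):
        return v
    return np.vstack([v, v[0]])


def signed_area(vertices: np.ndarray) -> float:
    v = _closed(vertices)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x[:-1] * y[1:] - x[1:] * y[:-1]))


def ensure_ccw(vertices: np.ndarray) -> np.ndarray:
    """Return vertices ordered counterclockwise (positive signed area in
    (x, y) coordinates)."""
    v = np.asarray(vertices, dtype=float)
    return v if signed_area(v) > 0 else v[::-1]


def perimeter_length(vertices: np.ndarray) -> float:
    v = _closed(vertices)
    return float(np.sum(np.hypot(np.diff(v[:, 0]), np.diff(v[:, 1]))))


def resample_boundary(vertices: np.ndarray, n_samples: int):
    """Resample a closed polygon at ``n_samples`` equally spaced arc positions.

    Returns
    -------
    points : (n, 2) array
        Sample coordinates (x, y), starting at the first vertex.
    fractions : (n,) array
        Arc-length fractions in [0, 1).
    normals : (n, 2) array
        Unit inward normals, from the central-difference tangent of the
        resampled curve (equivalent to the angle-bisector normal at
        vertices of the dense polyline).
    perimeter : float
        Total perimeter length.
    """
    v = _closed(ensure_ccw(vertices))
    seg = np.hypot(np.diff(v[:, 0]), np.diff(v[:, 1]))
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    perimeter = float(cum[-1])
    s = np.arange(n_samples) * perimeter / n_samples
    x = np.interp(s, cum, v[:, 0])
    y = np.interp(s, cum, v[:, 1])
    pts = np.column_stack([x, y])
    nxt = np.roll(pts, -1, axis=0)
    prv = np.roll(pts, 1, axis=0)
    tang = nxt - prv
    norm = np.hypot(tang[:, 0], tang[:, 1])
    norm[norm == 0] = 1.0
    tang /= norm[:, None]
    # interior lies to the left of CCW travel
    normals = np.column_stack([-tang[:, 1], tang[:, 0]])
    return pts, s / perimeter, normals, perimeter
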