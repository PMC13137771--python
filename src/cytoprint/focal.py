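"""Locating the aberrated focus of a traced ray bundle.

The focus of a bundle is defined geometrically, as in a spot diagram: each
ray is a line, and at every height z the bundle forms a cloud of (x, y)
intersection points with the horizontal plane.  The z position of the focus
is the plane where the summed population variance V(z) = var_x + var_y of
that cloud is smallest; the lateral focus position is the center of mass of
the cloud in that plane.  The focal displacement is the difference between
this position and the nominal (refraction-free) focus.  The focus width is
quantified by V at the focal plane: ``spot_variance`` is V itself (um^2) and
``spot_size`` is sqrt(V) (um), the RMS lateral spread of the ray cloud, which
is the scale compared against the 400 nm diffraction limit.

Because each ray's x and y are affine functions of z, V(z) is an exact
quadratic polynomial in z, so a coarse scan followed by a three-point
parabola refinement recovers the minimum to machine precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .optics import Ray

#: Rays steeper than this |dz| are usable; flatter ones cannot be evaluated
#: on a horizontal plane.
DEGENERATE_DZ = 1e-12
#: A bundle whose directions span less than this angle (rad) is treated as
#: parallel: the rays no longer intersect and the focus search diverges.
PARALLEL_ANGLE = 1e-6
#: Fraction of degenerate rays above which the result is flagged diverged.
MAX_DEGENERATE_FRACTION = 0.10


class InsufficientBundleError(ValueError):
    """Fewer than three usable rays: no meaningful variance minimum exists."""


class DivergedFocusError(ValueError):
    """Operation requested on a diverged focus result."""


@dataclass(frozen=True)
class SearchWindow:
    """z-search window around the nominal focus for the variance minimum."""

    half_width: float = 2.0     # um either side of nominal z
    coarse_step: float = 0.02   # um (20 nm) coarse-scan step


@dataclass(frozen=True)
class FocusResult:
    position: np.ndarray            # (x*, y*, z*) um
    displacement: np.ndarray        # position - nominal, um
    displacement_magnitude: float   # |displacement|, um
    spot_variance: float            # var_x + var_y at the focal plane, um^2
    spot_size: float                # sqrt(spot_variance), um (RMS lateral spread)
    diverged: bool

    def to_dict(self) -> dict:
        return {
            "position": [float(v) for v in self.position],
            "displacement": [float(v) for v in self.displacement],
            "displacement_magnitude": float(self.displacement_magnitude),
            "spot_variance": float(self.spot_variance),
            "spot_size": float(self.spot_size),
            "diverged": bool(self.diverged),
        }


def positions_at_z(rays: list[Ray], z: float) -> tuple[np.ndarray, np.ndarray]:
    """(x, y) of each ray's line at height z, order preserving.

    Returns ``(points, degenerate)`` where ``points`` is (n, 2) and
    ``degenerate`` flags rays whose |dz| < 1e-12; degenerate entries hold
    NaN and are excluded from downstream statistics.
    """
    o = np.array([r.origin for r in rays], dtype=float).reshape(-1, 3)
    d = np.array([r.direction for r in rays], dtype=float).reshape(-1, 3)
    return _positions_at_z_arrays(o, d, z)


def _positions_at_z_arrays(o: np.ndarray, d: np.ndarray,
                           z: float) -> tuple[np.ndarray, np.ndarray]:
    degenerate = np.abs(d[:, 2]) < DEGENERATE_DZ
    t = np.where(degenerate, np.nan, (z - o[:, 2]) / np.where(degenerate, 1.0, d[:, 2]))
    pts = o[:, :2] + t[:, None] * d[:, :2]
    pts[degenerate] = np.nan
    return pts, degenerate


def _diverged_result(nominal: np.ndarray) -> FocusResult:
    nan3 = np.full(3, np.nan)
    return FocusResult(position=nan3, displacement=nan3,
                       displacement_magnitude=math.nan, spot_variance=math.nan,
                       spot_size=math.nan, diverged=True)


def focus_arrays(origins: np.ndarray, dirs: np.ndarray, nominal: np.ndarray,
                 window: SearchWindow = SearchWindow()) -> FocusResult:
    """Vectorized focus search on a bundle given as arrays."""
    nominal = np.asarray(nominal, dtype=float)
    usable = np.abs(dirs[:, 2]) >= DEGENERATE_DZ
    n_total = len(dirs)
    n_usable = int(usable.sum())
    if n_usable < 3:
        raise InsufficientBundleError(
            f"need >= 3 usable rays, got {n_usable} of {n_total}")
    if n_total and (n_total - n_usable) / n_total > MAX_DEGENERATE_FRACTION:
        return _diverged_result(nominal)

    o = origins[usable]
    d = dirs[usable]

    # near-parallel bundle: rays no longer intersect, the search diverges
    mean_dir = d.mean(axis=0)
    mean_dir /= np.linalg.norm(mean_dir)
    cosang = np.clip(d @ mean_dir, -1.0, 1.0)
    max_dev = float(np.max(np.arccos(cosang)))
    if 2.0 * max_dev < PARALLEL_ANGLE:
        return _diverged_result(nominal)

    # per-ray affine coefficients: x(z) = bx + sx * z
    s = d[:, :2] / d[:, 2:3]
    b = o[:, :2] - s * o[:, 2:3]

    z0 = float(nominal[2])
    n_steps = int(round(2 * window.half_width / window.coarse_step))
    zs = z0 - window.half_width + window.coarse_step * np.arange(n_steps + 1)

    # V(z) = var_x + var_y of the spot diagram at each z (population variance)
    pts_x = b[:, 0:1] + s[:, 0:1] * zs[None, :]
    pts_y = b[:, 1:2] + s[:, 1:2] * zs[None, :]
    V = pts_x.var(axis=0) + pts_y.var(axis=0)

    i = int(np.argmin(V))  # argmin takes the first (smallest-z) minimum
    if i == 0 or i == len(zs) - 1:
        return _diverged_result(nominal)

    # V is exactly quadratic in z: the parabola through the three samples
    # around the coarse minimum recovers the vertex exactly.
    z1, z2, z3 = zs[i - 1], zs[i], zs[i + 1]
    v1, v2, v3 = V[i - 1], V[i], V[i + 1]
    denom = (v1 - 2 * v2 + v3)
    if denom <= 0:
        z_star = float(z2)
    else:
        z_star = float(z2 + 0.5 * window.coarse_step * (v1 - v3) / denom)

    px = b[:, 0] + s[:, 0] * z_star
    py = b[:, 1] + s[:, 1] * z_star
    x_star = float(px.mean())
    y_star = float(py.mean())
    spot_var = float(px.var() + py.var())

    position = np.array([x_star, y_star, z_star])
    disp = position - nominal
    return FocusResult(position=position, displacement=disp,
                       displacement_magnitude=float(np.linalg.norm(disp)),
                       spot_variance=spot_var,
                       spot_size=math.sqrt(max(spot_var, 0.0)),
                       diverged=False)


def find_focus(rays: list[Ray], nominal, window: SearchWindow = SearchWindow()) -> FocusResult:
    """Locate the minimal-variance focus of a ray bundle.

    ``nominal`` is the refraction-free focal point; the search scans z over
    ``nominal_z +/- window.half_width``.  A minimum on the window boundary,
    a near-parallel bundle, or an excess of degenerate rays yields a result
    with ``diverged=True`` rather than an error.
    """
    origins = np.array([r.origin for r in rays], dtype=float).reshape(-1, 3)
    dirs = np.array([r.direction for r in rays], dtype=float).reshape(-1, 3)
    return focus_arrays(origins, dirs, np.asarray(nominal, float), window)


def displacement_of(nominal, result: FocusResult) -> np.ndarray:
    """Focal displacement vector: found position minus nominal focus."""
    if result.diverged:
        raise DivergedFocusError("displacement undefined for a diverged focus")
    return result.position - np.asarray(nominal, dtype=float)
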