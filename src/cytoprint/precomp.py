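"""CAD pre-compensation against refraction-induced focal shifts.

If the focus lands at v + d(v) when aimed at v, printing a model pre-deformed
by the inverse map makes the polymerized structure match the design: each
vertex v is replaced by the point v' solving v' + d(v') = v.  The focal
displacement field d is small (<= ~0.5 um over a 10 um droplet) and smooth,
so the fixed-point iteration v' <- v - d(v') is a contraction and converges
in a few steps.

The field is given as a meridian-plane :class:`~cytoprint.fieldmap.FieldMap`;
by rotational symmetry its (radial, axial) components are interpolated
bilinearly in (rho, z) and rotated back into 3D using each point's azimuth.
"""

from __future__ import annotations

import math

import numpy as np
import trimesh

from .fieldmap import FieldMap


class OutOfFieldError(ValueError):
    """A point lies outside the mapped (converged) region of the field."""


class ConvergenceError(RuntimeError):
    """Fixed-point inversion failed to converge for some vertices."""


class _MeridianInterpolator:
    """Bilinear interpolation of (d_rho, d_z) on the map's (rho, z) grid.

    Cells with any invalid corner (unsampled, diverged, or NaN) are treated
    as outside the field.
    """

    def __init__(self, fmap: FieldMap):
        self.rho_ax = np.unique(np.round(fmap.rho / fmap.grid_spacing).astype(int))
        self.z_ax = np.unique(np.round(fmap.z / fmap.grid_spacing).astype(int))
        self.h = fmap.grid_spacing
        nr, nz = len(self.rho_ax), len(self.z_ax)
        self.d_rho = np.full((nz, nr), np.nan)
        self.d_z = np.full((nz, nr), np.nan)
        ri = np.searchsorted(self.rho_ax, np.round(fmap.rho / self.h).astype(int))
        zi = np.searchsorted(self.z_ax, np.round(fmap.z / self.h).astype(int))
        ok = ~fmap.diverged & np.isfinite(fmap.disp_rho) & np.isfinite(fmap.disp_z)
        self.d_rho[zi[ok], ri[ok]] = fmap.disp_rho[ok]
        self.d_z[zi[ok], ri[ok]] = fmap.disp_z[ok]
        self.rho0 = self.rho_ax[0] * self.h
        self.z0 = self.z_ax[0] * self.h

    def __call__(self, rho: np.ndarray, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        fr = (np.asarray(rho, float) - self.rho0) / self.h
        fz = (np.asarray(z, float) - self.z0) / self.h
        ir = np.floor(fr).astype(int)
        iz = np.floor(fz).astype(int)
        # clamp so that points exactly on the upper grid line use the last cell
        ir = np.clip(ir, 0, self.d_rho.shape[1] - 2)
        iz = np.clip(iz, 0, self.d_rho.shape[0] - 2)
        tr = fr - ir
        tz = fz - iz
        out = (tr < -1e-9) | (tr > 1 + 1e-9) | (tz < -1e-9) | (tz > 1 + 1e-9)

        def bil(a):
            v = (a[iz, ir] * (1 - tr) * (1 - tz)
                 + a[iz, ir + 1] * tr * (1 - tz)
                 + a[iz + 1, ir] * (1 - tr) * tz
                 + a[iz + 1, ir + 1] * tr * tz)
            return v

        dr, dz = bil(self.d_rho), bil(self.d_z)
        bad = out | ~np.isfinite(dr) | ~np.isfinite(dz)
        if np.any(bad):
            idx = np.nonzero(bad)[0][:10]
            raise OutOfFieldError(
                f"{int(bad.sum())} point(s) outside the mapped field "
                f"(first indices: {idx.tolist()})")
        return dr, dz


def _interp_points(points: np.ndarray, interp: _MeridianInterpolator) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(points, float))
    rho = np.hypot(pts[:, 0], pts[:, 1])
    phi = np.arctan2(pts[:, 1], pts[:, 0])
    dr, dz = interp(rho, pts[:, 2])
    return np.column_stack([dr * np.cos(phi), dr * np.sin(phi), dz])


def displacement_at(point, fmap: FieldMap) -> np.ndarray:
    """Focal displacement vector at a 3D point, interpolated from the map."""
    d = _interp_points(np.asarray(point, float).reshape(1, 3),
                       _MeridianInterpolator(fmap))
    return d[0]


def push_forward(points, fmap: FieldMap) -> np.ndarray:
    """Apply the focal-shift field: where aiming at p actually prints, p + d(p)."""
    pts = np.atleast_2d(np.asarray(points, float))
    return pts + _interp_points(pts, _MeridianInterpolator(fmap))


def pre_deform_points(points, fmap: FieldMap, tol: float = 1e-3,
                      max_iter: int = 50) -> np.ndarray:
    """Invert the field at each point: solve v' + d(v') = v.

    ``tol`` is the per-point convergence threshold in um (default 1 nm).
    """
    if not tol > 0:
        raise ValueError("tol must be positive")
    v = np.atleast_2d(np.asarray(points, float))
    interp = _MeridianInterpolator(fmap)
    x = v.copy()
    active = np.ones(len(v), dtype=bool)
    for _ in range(max_iter):
        d = _interp_points(x[active], interp)
        new = v[active] - d
        change = np.linalg.norm(new - x[active], axis=1)
        x[active] = new
        still = change >= tol
        idx = np.nonzero(active)[0]
        active[idx[~still]] = False
        if not np.any(active):
            return x
    raise ConvergenceError(
        f"pre-deformation did not converge for vertices "
        f"{np.nonzero(active)[0][:20].tolist()} after {max_iter} iterations")


def pre_deform(mesh: trimesh.Trimesh, fmap: FieldMap, tol: float = 1e-3,
               max_iter: int = 50) -> trimesh.Trimesh:
    """Pre-deform a mesh opposite to the focal-shift field.

    Every vertex is moved to the pre-image of its design position under the
    field, so that printing the returned mesh yields the original design.
    Topology (faces) is unchanged.
    """
    new_vertices = pre_deform_points(mesh.vertices, fmap, tol=tol,
                                     max_iter=max_iter)
    return trimesh.Trimesh(vertices=new_vertices, faces=mesh.faces.copy(),
                           process=False)


def synthetic_field(fn, rho_max: float, z_range: tuple[float, float],
                    spacing: float = 0.25) -> FieldMap:
    """Build a FieldMap from an analytic displacement function.

    ``fn(rho, z) -> (d_rho, d_z)`` is evaluated on a regular grid; useful
    for testing the inversion against fields with a known closed form.
    """
    rho_ax = spacing * np.arange(int(math.floor(rho_max / spacing)) + 1)
    j0 = int(math.ceil(z_range[0] / spacing - 1e-9))
    j1 = int(math.floor(z_range[1] / spacing + 1e-9))
    z_ax = spacing * np.arange(j0, j1 + 1)
    rr, zz = np.meshgrid(rho_ax, z_ax)
    rho, z = rr.ravel(), zz.ravel()
    dr = np.empty_like(rho)
    dz = np.empty_like(rho)
    for i in range(len(rho)):
        dr[i], dz[i] = fn(rho[i], z[i])
    mag = np.sqrt(dr ** 2 + dz ** 2)
    return FieldMap(rho=rho, z=z, disp_rho=dr, disp_z=dz, disp_mag=mag,
                    spot_size=np.zeros_like(rho),
                    diverged=np.zeros(len(rho), dtype=bool),
                    radius_frac=np.zeros_like(rho), grid_spacing=spacing,
                    provenance={"synthetic": True})
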