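"""Far-field diffraction of printed micro-grating barcodes.

A grating printed inside a cell can be read out remotely: illuminated with
a laser it produces a far-field pattern whose peak geometry reflects the
lattice symmetry and period, and whose rotation follows the grating's
orientation.  This module builds binary transmission masks of pillar
gratings (square or hexagonal lattice within a circular aperture) and
computes their scalar Fraunhofer pattern as the squared magnitude of the
zero-padded 2D discrete Fourier transform.  Diffraction angles follow the
grating equation sin(theta) = lambda * f, with f the spatial frequency in
cycles/um.  Only peak positions and relative magnitudes are meaningful;
absolute intensities are not calibrated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage


class ResolutionError(ValueError):
    """The sampling grid is too coarse for the requested period."""


@dataclass
class TransmissionMask:
    values: np.ndarray        # (n, n) binary transmission
    dx: float                 # sample spacing, um
    pillar_centers: np.ndarray  # (m, 2) lattice points inside the aperture


def lattice_points(lattice: str, period: float, radius: float) -> np.ndarray:
    """Lattice points of a square or hexagonal lattice within a circle."""
    if period <= 0:
        raise ValueError("period must be positive")
    if lattice == "square":
        a1 = np.array([period, 0.0])
        a2 = np.array([0.0, period])
    elif lattice in ("hex", "hexagonal"):
        a1 = np.array([period, 0.0])
        a2 = np.array([period / 2.0, period * math.sqrt(3.0) / 2.0])
    else:
        raise ValueError(f"unknown lattice {lattice!r}")
    n = int(math.ceil(2.0 * radius / period)) + 2
    pts = []
    for i in range(-n, n + 1):
        for j in range(-n, n + 1):
            p = i * a1 + j * a2
            if p @ p <= radius * radius + 1e-12:
                pts.append(p)
    return np.array(pts).reshape(-1, 2)


def grating_aperture(lattice: str = "square", period: float = 1.0,
                     aperture_radius: float = 10.0,
                     samples_per_period: int = 16,
                     fill: float = 0.5,
                     antialias: int = 1) -> TransmissionMask:
    """Binary pillar-grating mask within a circular aperture.

    ``fill`` is the pillar diameter as a fraction of the period.
    With ``antialias=1`` the mask is strictly binary; ``antialias=k > 1``
    supersamples each cell k*k times and stores the pillar coverage
    fraction, which removes the Cartesian rasterization bias that otherwise
    breaks the lattice symmetry of off-axis peak magnitudes.
    """
    if samples_per_period < 8:
        raise ResolutionError("need >= 8 samples per period")
    if antialias < 1:
        raise ValueError("antialias must be >= 1")
    dx = period / samples_per_period
    half = int(math.ceil(aperture_radius / dx)) + 1
    n = 2 * half + 1
    ss = int(antialias)
    fine = dx / ss
    axf = (np.arange(n * ss) - (n * ss - 1) / 2.0) * fine
    xx, yy = np.meshgrid(axf, axf)
    centers = lattice_points(lattice, period, aperture_radius)
    maskf = np.zeros_like(xx, dtype=bool)
    r_pillar = 0.5 * fill * period
    for cx, cy in centers:
        maskf |= (xx - cx) ** 2 + (yy - cy) ** 2 <= r_pillar ** 2
    values = maskf.reshape(n, ss, n, ss).mean(axis=(1, 3))
    return TransmissionMask(values=values, dx=dx, pillar_centers=centers)


@dataclass
class FarField:
    intensity: np.ndarray   # (N, N), fft-shifted
    fx: np.ndarray          # spatial frequencies along each axis, cycles/um
    wavelength: float
    peaks: list             # list of dicts: fx, fy, sin_theta_x/y, intensity

    @property
    def frequency_bin(self) -> float:
        return float(self.fx[1] - self.fx[0])


def far_field(mask: TransmissionMask, wavelength: float = 0.633,
              pad_factor: int = 4, peak_threshold: float = 0.01) -> FarField:
    """Scalar Fraunhofer far field of a transmission mask.

    The intensity is |DFT|^2 on a grid zero-padded by ``pad_factor``;
    ``peaks`` lists local maxima above ``peak_threshold`` of the central
    peak with their angular coordinates sin(theta) = wavelength * f.
    """
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    v = mask.values
    if v.size == 0 or not np.any(v):
        raise ValueError("mask is empty")
    n = max(v.shape)
    N = int(pad_factor * n)
    F = np.fft.fftshift(np.fft.fft2(v, s=(N, N)))
    I = np.abs(F) ** 2
    fx = np.fft.fftshift(np.fft.fftfreq(N, d=mask.dx))

    footprint = np.ones((3, 3), dtype=bool)
    local_max = (I == ndimage.maximum_filter(I, footprint=footprint,
                                             mode="constant"))
    thresh = peak_threshold * I.max()
    iy, ix = np.nonzero(local_max & (I > thresh))
    peaks = []
    for j, i in zip(iy, ix):
        peaks.append({
            "fx": float(fx[i]), "fy": float(fx[j]),
            "sin_theta_x": float(wavelength * fx[i]),
            "sin_theta_y": float(wavelength * fx[j]),
            "intensity": float(I[j, i]),
        })
    peaks.sort(key=lambda p: -p["intensity"])
    return FarField(intensity=I, fx=fx, wavelength=wavelength, peaks=peaks)


def rotate_pattern(mask: TransmissionMask, angle_deg: float) -> TransmissionMask:
    """Rotate a mask in its plane by resampling (bilinear).

    The far field of the rotated mask equals the rotated far field up to
    interpolation error.
    """
    if angle_deg % 360.0 == 0.0:
        return TransmissionMask(values=mask.values.copy(), dx=mask.dx,
                                pillar_centers=mask.pillar_centers.copy())
    # with rows interpreted as +y, ndimage.rotate(angle) turns the content
    # clockwise in (x, y); negate so a positive angle is counterclockwise
    rotated = ndimage.rotate(mask.values, -angle_deg, reshape=False, order=1)
    th = math.radians(angle_deg)
    rot = np.array([[math.cos(th), -math.sin(th)],
                    [math.sin(th), math.cos(th)]])
    centers = mask.pillar_centers @ rot.T
    return TransmissionMask(values=rotated, dx=mask.dx, pillar_centers=centers)


def first_order_peaks(field: FarField, f_lattice: float,
                      tol_bins: float = 1.5) -> list:
    """Peaks whose radial frequency is within ``tol_bins`` bins of
    ``f_lattice`` (e.g. 1/period for a square lattice)."""
    tol = tol_bins * field.frequency_bin
    out = []
    for p in field.peaks:
        fr = math.hypot(p["fx"], p["fy"])
        if abs(fr - f_lattice) <= tol:
            out.append(p)
    return out
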