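"""Meridian-plane maps of focal displacement and spot size inside the droplet.

The droplet/bundle geometry is rotationally symmetric about the optical
axis, so scanning nominal foci over a half-plane (radial coordinate rho >= 0,
height z) characterizes the whole droplet volume.  For every grid point a
converging bundle is aimed at the point, traced through the droplet surface,
and focused by the minimal-variance criterion; the map records the focal
displacement vector and spot size per point.

Two passes are distinguished, matching how the droplet is analyzed: the
*map* is rendered only within 0.96 of the droplet radius, because bundles
aimed near the upper droplet edge refract into near-parallel rays and the
focus search diverges there; the *printable-volume* statistic additionally
includes radii up to the full droplet radius, with diverged points counted
as exceeding the diffraction limit.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field

import numpy as np

from .optics import (BundleSpec, DropletSpec, _disc_points_fibonacci,
                     _disc_points_grid, _disc_points_random, trace_arrays)
from .focal import SearchWindow, focus_arrays

#: Spot-size threshold for "printable at full resolution": the diffraction
#: limit of the printing system, 400 nm.
DIFFRACTION_LIMIT = 0.4
#: Radial cutoff (fraction of droplet radius) for map rendering.
RADIAL_CUTOFF = 0.96


class EmptyFieldMapError(ValueError):
    """The map holds no sampled points."""


@dataclass(frozen=True)
class FieldMapConfig:
    radial_cutoff: float = RADIAL_CUTOFF
    grid_spacing: float = 0.25          # um between nominal foci
    diffraction_limit: float = DIFFRACTION_LIMIT  # um
    include_full_radius_for_volume: bool = True
    # Scale applied to the RMS spot width before comparing it with the
    # diffraction limit (1.0 compares sqrt(var_x + var_y) directly; 2.0
    # would compare a diameter-like metric instead).
    spot_size_multiplier: float = 1.0

    def __post_init__(self):
        if not (0.0 < self.radial_cutoff <= 1.0):
            raise ValueError("radial_cutoff must lie in (0, 1]")
        if not self.grid_spacing > 0:
            raise ValueError("grid_spacing must be positive")
        if not self.diffraction_limit > 0:
            raise ValueError("diffraction_limit must be positive")
        if not self.spot_size_multiplier > 0:
            raise ValueError("spot_size_multiplier must be positive")

    def to_dict(self) -> dict:
        return {
            "radial_cutoff": self.radial_cutoff,
            "grid_spacing": self.grid_spacing,
            "diffraction_limit": self.diffraction_limit,
            "include_full_radius_for_volume": self.include_full_radius_for_volume,
            "spot_size_multiplier": self.spot_size_multiplier,
        }


@dataclass
class FieldMap:
    """Scattered-on-a-grid samples of the focal field in a meridian half-plane.

    All per-point arrays are 1-D and aligned: entry i describes the nominal
    focus at (rho[i], 0, z[i]) in scene coordinates.
    """

    rho: np.ndarray            # radial coordinate, um (>= 0)
    z: np.ndarray              # height, um
    disp_rho: np.ndarray       # radial displacement component, um
    disp_z: np.ndarray         # axial displacement component, um
    disp_mag: np.ndarray       # |displacement|, um (NaN when diverged)
    spot_size: np.ndarray      # um (NaN when diverged)
    diverged: np.ndarray       # bool
    radius_frac: np.ndarray    # distance from droplet center / radius
    grid_spacing: float
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.rho)

    def select(self, max_radius_frac: float) -> np.ndarray:
        """Index mask of points within a radial fraction of the droplet."""
        return self.radius_frac <= max_radius_frac + 1e-12

    def max_displacement(self, max_radius_frac: float = RADIAL_CUTOFF) -> float:
        """Largest displacement magnitude over non-diverged points in range."""
        m = self.select(max_radius_frac) & ~self.diverged
        if not np.any(m):
            raise EmptyFieldMapError("no converged points within the cutoff")
        return float(np.max(self.disp_mag[m]))

    def volume_weights(self) -> np.ndarray:
        """Rotational-volume weights: w ~ rho, with the on-axis samples given
        the small effective radius spacing/8 so the axis is not zero-measure."""
        w = self.rho.astype(float).copy()
        w[w == 0.0] = self.grid_spacing / 8.0
        return w


def _unit_disc(spec: BundleSpec) -> np.ndarray:
    if spec.sampling == "fibonacci":
        return _disc_points_fibonacci(spec.n_rays)
    if spec.sampling == "grid":
        return _disc_points_grid(spec.n_rays)
    return _disc_points_random(spec.n_rays, spec.seed)


def evaluate_point(point, droplet: DropletSpec, bundle_template: BundleSpec,
                   window: SearchWindow = SearchWindow(),
                   _unit: np.ndarray | None = None):
    """Trace and focus a bundle aimed at one nominal focal point."""
    point = np.asarray(point, dtype=float)
    unit = _unit_disc(bundle_template) if _unit is None else _unit
    height = point[2] - bundle_template.origin_plane_z
    if height <= 0:
        raise ValueError("nominal focus must lie above the bundle origin plane")
    disc_radius = height * math.tan(bundle_template.half_angle)
    origins = np.empty((len(unit), 3))
    origins[:, 0] = point[0] + disc_radius * unit[:, 0]
    origins[:, 1] = point[1] + disc_radius * unit[:, 1]
    origins[:, 2] = bundle_template.origin_plane_z
    dirs = point[None, :] - origins
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    o, d, _ = trace_arrays(origins, dirs, droplet)
    return focus_arrays(o, d, point, window)


def scan_meridian(droplet: DropletSpec, bundle_template: BundleSpec,
                  config: FieldMapConfig = FieldMapConfig(),
                  window: SearchWindow = SearchWindow()) -> FieldMap:
    """Map focal displacement and spot size over the meridian half-plane.

    Grid points at multiples of ``grid_spacing`` in (rho, z) covering the
    droplet are sampled out to the full radius when
    ``include_full_radius_for_volume`` is set, otherwise out to the radial
    cutoff.  Per-point divergence is recorded in the map, never raised.
    """
    R = droplet.radius
    cz = float(droplet.center[2])
    max_frac = 1.0 if config.include_full_radius_for_volume else config.radial_cutoff
    h = config.grid_spacing

    n_rho = int(math.floor(R * max_frac / h)) + 1
    rho_ax = h * np.arange(n_rho)
    z_lo, z_hi = cz - R * max_frac, cz + R * max_frac
    j_lo = int(math.ceil(z_lo / h - 1e-9))
    j_hi = int(math.floor(z_hi / h + 1e-9))
    z_ax = h * np.arange(j_lo, j_hi + 1)

    rr, zz = np.meshgrid(rho_ax, z_ax)
    frac = np.sqrt(rr ** 2 + (zz - cz) ** 2) / R
    keep = frac <= max_frac + 1e-12
    rho_s, z_s, frac_s = rr[keep], zz[keep], frac[keep]

    n = len(rho_s)
    disp_rho = np.full(n, np.nan)
    disp_z = np.full(n, np.nan)
    disp_mag = np.full(n, np.nan)
    spot = np.full(n, np.nan)
    div = np.zeros(n, dtype=bool)

    unit = _unit_disc(bundle_template)
    for i in range(n):
        res = evaluate_point((rho_s[i], 0.0, z_s[i]), droplet, bundle_template,
                             window, _unit=unit)
        if res.diverged:
            div[i] = True
            continue
        disp_rho[i] = res.displacement[0]
        disp_z[i] = res.displacement[2]
        disp_mag[i] = res.displacement_magnitude
        spot[i] = res.spot_size

    return FieldMap(rho=rho_s, z=z_s, disp_rho=disp_rho, disp_z=disp_z,
                    disp_mag=disp_mag, spot_size=spot, diverged=div,
                    radius_frac=frac_s, grid_spacing=h,
                    provenance={"droplet": droplet.to_dict(),
                                "bundle": bundle_template.to_dict(),
                                "config": config.to_dict()})


def volume_fraction_below_limit(fmap: FieldMap,
                                config: FieldMapConfig = FieldMapConfig()) -> float:
    """Fraction of the droplet volume printable below the diffraction limit.

    Samples are weighted by distance from the axis (each meridian-plane
    point represents an annulus of the rotation volume); diverged points
    count as above the limit.
    """
    if len(fmap) == 0:
        raise EmptyFieldMapError("cannot compute a volume fraction of an empty map")
    w = fmap.volume_weights()
    scaled = config.spot_size_multiplier * fmap.spot_size
    below = (~fmap.diverged) & (scaled < config.diffraction_limit)
    return float(np.sum(w * below) / np.sum(w))


# ---------------------------------------------------------------------------
# Output: CSV dump and figures
# ---------------------------------------------------------------------------

_CSV_FIELDS = ["rho_um", "z_um", "disp_um", "spot_um", "diverged",
               "disp_rho_um", "disp_z_um", "radius_frac"]


def write_csv(fmap: FieldMap, path) -> None:
    """Dump the raw map grid to CSV (floats at full precision)."""
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(_CSV_FIELDS)
        for i in range(len(fmap)):
            wr.writerow([f"{fmap.rho[i]:.17g}", f"{fmap.z[i]:.17g}",
                         f"{fmap.disp_mag[i]:.17g}", f"{fmap.spot_size[i]:.17g}",
                         int(fmap.diverged[i]),
                         f"{fmap.disp_rho[i]:.17g}", f"{fmap.disp_z[i]:.17g}",
                         f"{fmap.radius_frac[i]:.17g}"])


def read_csv(path) -> FieldMap:
    """Rebuild a FieldMap from a CSV dump (provenance is not restored)."""
    rows = []
    with open(path, newline="") as fh:
        rd = csv.reader(fh)
        header = next(rd)
        if header[: len(_CSV_FIELDS)] != _CSV_FIELDS:
            raise ValueError(f"unexpected CSV header: {header}")
        for row in rd:
            rows.append(row)
    n = len(rows)
    arr = lambda j: np.array([float(r[j]) for r in rows])
    rho, z = arr(0), arr(1)
    spacing = float(np.min(np.diff(np.unique(rho)))) if len(np.unique(rho)) > 1 else 1.0
    return FieldMap(rho=rho, z=z, disp_mag=arr(2), spot_size=arr(3),
                    diverged=np.array([bool(int(r[4])) for r in rows]),
                    disp_rho=arr(5), disp_z=arr(6), radius_frac=arr(7),
                    grid_spacing=spacing)


def render_maps(fmap: FieldMap, out_dir) -> list[str]:
    """Write color plots of displacement and spot size plus the raw CSV.

    Returns the list of file paths written (displacement.png,
    spot_size.png, field_map.csv under ``out_dir``).
    """
    import pathlib

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if len(fmap) == 0:
        raise EmptyFieldMapError("cannot render an empty map")
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    for name, values, label in [
            ("displacement", fmap.disp_mag, "focal displacement (um)"),
            ("spot_size", fmap.spot_size, "focal spot size (um)")]:
        fig, ax = plt.subplots(figsize=(4.2, 4.2))
        sc = ax.scatter(fmap.rho, fmap.z, c=values, s=14, marker="s",
                        cmap="viridis")
        ax.scatter(fmap.rho[fmap.diverged], fmap.z[fmap.diverged],
                   c="lightgray", s=14, marker="s")
        fig.colorbar(sc, ax=ax, label=label)
        ax.set_xlabel("rho (um)")
        ax.set_ylabel("z (um)")
        ax.set_aspect("equal")
        fp = out / f"{name}.png"
        fig.savefig(fp, dpi=150)
        plt.close(fig)
        written.append(str(fp))

    csv_path = out / "field_map.csv"
    write_csv(fmap, csv_path)
    written.append(str(csv_path))
    return written
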