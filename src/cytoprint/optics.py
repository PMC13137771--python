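"""Geometric ray optics for focusing through a spherical photoresist droplet.

Two-photon polymerization inside a cell happens in an injected droplet of
unpolymerized photoresist (refractive index ~1.48) surrounded by cytoplasm
(~1.37), an index ratio of about 1.08.  Laser light focused from below the
droplet refracts at the curved droplet surface, which shifts and blurs the
focal spot.  This module provides the primitives for simulating that effect:
rays, droplet and beam-bundle specifications, ray/sphere intersection,
vectorial Snell refraction, and single-interface tracing of an NA-limited
converging bundle.

Conventions: lengths in micrometres, angles in radians; the optical axis is
+z, the substrate is the plane z = 0, and the droplet sits tangent to the
substrate (center at (0, 0, R)).  Only the entry refraction is modeled; the
focus lies inside the droplet so no second interface is crossed before it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

# Golden-angle increment used by the sunflower (Fibonacci) disc layout.
_GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))

#: Default index of unpolymerized IP-S photoresist.
N_PHOTORESIST = 1.48
#: Default interior/exterior index ratio (photoresist vs. cytoplasm).
INDEX_RATIO = 1.08
#: Numerical aperture of the printing objective (1.4 NA oil immersion).
OBJECTIVE_NA = 1.4
#: Fraction of the exterior index at which the usable NA is capped: the
#: aqueous exterior medium cannot support sin(theta) >= 1, so the entrance
#: cone is limited to 0.95 * n_outside by default.
NA_CAP_FRACTION = 0.95


class InvalidGeometryError(ValueError):
    """Scene geometry violates a precondition (e.g. origin plane above focus)."""


@dataclass(frozen=True)
class Ray:
    """A ray: origin point plus unit direction, both in scene coordinates (um).

    ``refracted`` records whether the ray has already crossed the droplet
    surface (and therefore propagates in the interior medium).
    """

    origin: np.ndarray
    direction: np.ndarray
    refracted: bool = False

    def __post_init__(self):
        o = np.asarray(self.origin, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        if o.shape != (3,) or d.shape != (3,):
            raise ValueError("Ray origin and direction must be 3-vectors")
        if not np.all(np.isfinite(o)):
            raise ValueError("Ray origin must be finite")
        norm = float(np.linalg.norm(d))
        if not math.isfinite(norm) or abs(norm - 1.0) > 1e-12:
            raise ValueError(f"Ray direction must be unit length, |d| = {norm}")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "direction", d)

    def point_at(self, t: float) -> np.ndarray:
        return self.origin + t * self.direction


@dataclass(frozen=True)
class DropletSpec:
    """Spherical photoresist droplet inside the cytoplasm.

    Defaults follow the intracellular printing geometry: a 10 um diameter
    droplet tangent to the substrate, photoresist index 1.48 inside and an
    exterior index chosen so the interior/exterior ratio is 1.08.
    """

    center: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 5.0]))
    radius: float = 5.0
    n_inside: float = N_PHOTORESIST
    n_outside: float = N_PHOTORESIST / INDEX_RATIO

    def __post_init__(self):
        c = np.asarray(self.center, dtype=float)
        if c.shape != (3,):
            raise ValueError("center must be a 3-vector")
        object.__setattr__(self, "center", c)
        if not self.radius > 0:
            raise ValueError("radius must be positive")
        if not (self.n_inside > 0 and self.n_outside > 0):
            raise ValueError("refractive indices must be positive")

    @property
    def ratio(self) -> float:
        return self.n_inside / self.n_outside

    @property
    def lowest_z(self) -> float:
        return float(self.center[2]) - self.radius

    def contains(self, point) -> bool:
        return float(np.linalg.norm(np.asarray(point, float) - self.center)) <= self.radius

    def to_dict(self) -> dict:
        return {
            "center": [float(v) for v in self.center],
            "radius": float(self.radius),
            "n_inside": float(self.n_inside),
            "n_outside": float(self.n_outside),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DropletSpec":
        return cls(np.asarray(d["center"], float), float(d["radius"]),
                   float(d["n_inside"]), float(d["n_outside"]))


def half_angle_from_na(na: float = OBJECTIVE_NA, n_outside: float = N_PHOTORESIST / INDEX_RATIO,
                       cap_fraction: float = NA_CAP_FRACTION) -> float:
    """Entrance-cone half angle for a given objective NA in a medium.

    The usable NA is capped at ``cap_fraction * n_outside`` so that the
    asin argument stays below 1 when the objective NA exceeds the index of
    the surrounding medium (as it does for a 1.4 NA oil objective focusing
    into an aqueous exterior).
    """
    if not (na > 0 and n_outside > 0 and 0 < cap_fraction < 1):
        raise ValueError("na, n_outside positive and 0 < cap_fraction < 1 required")
    effective = min(na, cap_fraction * n_outside)
    return math.asin(effective / n_outside)


@dataclass(frozen=True)
class BundleSpec:
    """An NA-limited bundle of rays converging on a nominal focal point.

    Ray origins are laid out homogeneously in a horizontal plane below the
    droplet, within the disc that the convergence cone of ``half_angle``
    cuts in that plane; every direction points at ``nominal_focus``.
    """

    nominal_focus: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 5.0]))
    half_angle: float = half_angle_from_na()
    n_rays: int = 2500
    origin_plane_z: float = -2.0
    sampling: str = "fibonacci"
    seed: int = 0

    def __post_init__(self):
        f = np.asarray(self.nominal_focus, dtype=float)
        if f.shape != (3,):
            raise ValueError("nominal_focus must be a 3-vector")
        object.__setattr__(self, "nominal_focus", f)
        if not (0.0 < self.half_angle < math.pi / 2):
            raise ValueError("half_angle must lie in (0, pi/2)")
        if self.n_rays < 1:
            raise ValueError("n_rays must be >= 1")
        if self.sampling not in ("grid", "fibonacci", "random"):
            raise ValueError(f"unknown sampling {self.sampling!r}")

    def aimed_at(self, point) -> "BundleSpec":
        return replace(self, nominal_focus=np.asarray(point, dtype=float))

    def to_dict(self) -> dict:
        return {
            "nominal_focus": [float(v) for v in self.nominal_focus],
            "half_angle": float(self.half_angle),
            "n_rays": int(self.n_rays),
            "origin_plane_z": float(self.origin_plane_z),
            "sampling": self.sampling,
            "seed": int(self.seed),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BundleSpec":
        return cls(np.asarray(d["nominal_focus"], float), float(d["half_angle"]),
                   int(d["n_rays"]), float(d["origin_plane_z"]), d["sampling"],
                   int(d.get("seed", 0)))


# ---------------------------------------------------------------------------
# Bundle construction
# ---------------------------------------------------------------------------

def _disc_points_fibonacci(n: int) -> np.ndarray:
    """n points homogeneously filling the unit disc (sunflower layout)."""
    k = np.arange(n)
    r = np.sqrt((k + 0.5) / n)
    th = k * _GOLDEN_ANGLE
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


def _disc_points_grid(n: int) -> np.ndarray:
    """Exactly n points of a square grid inside the unit disc.

    The grid pitch is shrunk until at least n nodes fall inside the disc;
    the n nodes closest to the center are kept (ties broken lexicographically
    so the result is deterministic).
    """
    m = max(1, int(math.ceil(math.sqrt(n * 4.0 / math.pi))))
    while True:
        ax = np.linspace(-1.0, 1.0, m)
        xx, yy = np.meshgrid(ax, ax)
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        r2 = np.einsum("ij,ij->i", pts, pts)
        inside = r2 <= 1.0 + 1e-12
        if inside.sum() >= n:
            pts, r2 = pts[inside], r2[inside]
            order = np.lexsort((pts[:, 1], pts[:, 0], np.round(r2, 12)))
            return pts[order[:n]]
        m += 1


def _disc_points_random(n: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    r = np.sqrt(rng.random(n))
    th = rng.random(n) * 2.0 * math.pi
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


def bundle_arrays(spec: BundleSpec) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized bundle: origins (n,3) and unit directions (n,3)."""
    fz = float(spec.nominal_focus[2])
    if spec.origin_plane_z >= fz:
        raise InvalidGeometryError(
            f"origin plane z={spec.origin_plane_z} must lie below the nominal "
            f"focus z={fz}")
    height = fz - spec.origin_plane_z
    disc_radius = height * math.tan(spec.half_angle)
    if spec.sampling == "fibonacci":
        unit = _disc_points_fibonacci(spec.n_rays)
    elif spec.sampling == "grid":
        unit = _disc_points_grid(spec.n_rays)
    else:
        unit = _disc_points_random(spec.n_rays, spec.seed)
    origins = np.empty((spec.n_rays, 3))
    origins[:, 0] = spec.nominal_focus[0] + disc_radius * unit[:, 0]
    origins[:, 1] = spec.nominal_focus[1] + disc_radius * unit[:, 1]
    origins[:, 2] = spec.origin_plane_z
    d = spec.nominal_focus[None, :] - origins
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    return origins, d


def make_bundle(spec: BundleSpec) -> list[Ray]:
    """Build the converging ray bundle described by ``spec``."""
    origins, dirs = bundle_arrays(spec)
    return [Ray(o, d) for o, d in zip(origins, dirs)]


# ---------------------------------------------------------------------------
# Intersection and refraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SphereHit:
    point: np.ndarray
    normal: np.ndarray  # unit, outward
    t: float


def intersect_sphere(ray: Ray, droplet: DropletSpec) -> SphereHit | None:
    """First forward intersection (t > 1e-9) of a ray with the droplet surface."""
    oc = ray.origin - droplet.center
    b = float(np.dot(ray.direction, oc))
    c = float(np.dot(oc, oc)) - droplet.radius ** 2
    disc = b * b - c
    if disc < 0.0:
        return None
    sq = math.sqrt(disc)
    t = -b - sq
    if t <= 1e-9:
        t = -b + sq
        if t <= 1e-9:
            return None
    p = ray.point_at(t)
    n = (p - droplet.center) / droplet.radius
    return SphereHit(point=p, normal=n, t=t)


def refract(ray: Ray, normal: np.ndarray, n_from: float, n_to: float) -> Ray:
    """Vectorial Snell refraction of a ray at an interface.

    ``normal`` is the unit surface normal (either orientation accepted).
    Raises :class:`TotalInternalReflectionError` when sin(theta_t) > 1.
    """
    n = np.asarray(normal, dtype=float)
    if abs(np.linalg.norm(n) - 1.0) > 1e-9:
        raise ValueError("normal must be unit length")
    if not (n_from > 0 and n_to > 0):
        raise ValueError("indices must be positive")
    d = ray.direction
    # orient normal against the incident direction
    if np.dot(d, n) > 0:
        n = -n
    cos_i = -float(np.dot(d, n))
    eta = n_from / n_to
    sin2_t = eta * eta * max(0.0, 1.0 - cos_i * cos_i)
    if sin2_t > 1.0:
        raise TotalInternalReflectionError(
            f"total internal reflection: sin^2(theta_t) = {sin2_t:.6f}")
    cos_t = math.sqrt(1.0 - sin2_t)
    t_dir = eta * d + (eta * cos_i - cos_t) * n
    t_dir = t_dir / np.linalg.norm(t_dir)
    return Ray(ray.origin, t_dir, refracted=True)


class TotalInternalReflectionError(ValueError):
    """The refracted angle would exceed 90 degrees; the ray is not transmitted."""


def trace_arrays(origins: np.ndarray, dirs: np.ndarray,
                 droplet: DropletSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized single-interface trace of a bundle through the droplet.

    Rays that hit the droplet are replaced by their once-refracted
    continuation starting at the entry point; rays that miss are returned
    unchanged.  Returns (origins, directions, refracted_mask).
    """
    oc = origins - droplet.center[None, :]
    b = np.einsum("ij,ij->i", dirs, oc)
    c = np.einsum("ij,ij->i", oc, oc) - droplet.radius ** 2
    disc = b * b - c
    hit = disc >= 0.0
    sq = np.sqrt(np.where(hit, disc, 0.0))
    t = -b - sq
    # rays starting inside or tangent: take the far root if the near one is behind
    far = -b + sq
    t = np.where(t > 1e-9, t, far)
    hit &= t > 1e-9

    out_o = origins.copy()
    out_d = dirs.copy()
    if np.any(hit):
        p = origins[hit] + t[hit, None] * dirs[hit]
        n = (p - droplet.center[None, :]) / droplet.radius
        d = dirs[hit]
        cos_i = -np.einsum("ij,ij->i", d, n)
        flip = cos_i < 0  # ray exits rather than enters; flip normal orientation
        n[flip] = -n[flip]
        cos_i = np.abs(cos_i)
        eta = droplet.n_outside / droplet.n_inside
        sin2_t = eta * eta * np.clip(1.0 - cos_i * cos_i, 0.0, None)
        # entering a denser medium: sin2_t < 1 always; clip guards roundoff
        cos_t = np.sqrt(np.clip(1.0 - sin2_t, 0.0, None))
        td = eta * d + (eta * cos_i - cos_t)[:, None] * n
        td /= np.linalg.norm(td, axis=1, keepdims=True)
        out_o[hit] = p
        out_d[hit] = td
    return out_o, out_d, hit


def trace_through_droplet(rays: list[Ray], droplet: DropletSpec) -> list[Ray]:
    """Trace each ray of a bundle through the droplet's entry surface."""
    if not rays:
        return []
    origins = np.array([r.origin for r in rays])
    dirs = np.array([r.direction for r in rays])
    o, d, hit = trace_arrays(origins, dirs, droplet)
    return [Ray(oi, di, refracted=bool(h)) for oi, di, h in zip(o, d, hit)]
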