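"""Parametric test objects and the canonical intracellular-printing scene.

Synthetic stand-ins for the physical study objects: watertight triangulated
meshes of the printed test structures (solid sphere, hollow sphere,
woodpile of thin walls) and the canonical scene configuration (droplet,
beam bundle, field-map and slicing parameters) used throughout the
analysis.  All meshes are in micrometres and deterministic given their
parameters.
"""

from __future__ import annotations

import math

import trimesh

from .fieldmap import FieldMapConfig
from .optics import BundleSpec, DropletSpec
from .slicer import SliceSpec


def make_sphere_mesh(diameter: float = 10.0, subdivisions: int = 4) -> trimesh.Trimesh:
    """Watertight icosphere; volume within 1% of pi*d^3/6 for subdivisions >= 3."""
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    return trimesh.creation.icosphere(subdivisions=subdivisions,
                                      radius=diameter / 2.0)


def make_hollow_sphere_mesh(outer: float = 6.0, wall: float = 0.5,
                            subdivisions: int = 4) -> trimesh.Trimesh:
    """Hollow spherical shell: outer sphere with an inward-facing inner shell.

    ``wall >= outer/2`` degenerates to a solid sphere.  The two closed
    shells together bound the wall volume, so the mesh slices to annular
    cross-sections under even-odd filling.
    """
    if not (outer > 0 and wall > 0):
        raise ValueError("outer and wall must be positive")
    shell_out = make_sphere_mesh(outer, subdivisions)
    inner_r = outer / 2.0 - wall
    if inner_r <= 0:
        return shell_out
    shell_in = trimesh.creation.icosphere(subdivisions=subdivisions,
                                          radius=inner_r)
    shell_in.invert()
    return trimesh.util.concatenate([shell_out, shell_in])


def make_woodpile_mesh(wall_thickness: float = 0.26, pitch: float = 0.8,
                       extent: float = 5.0, height: float = 2.0) -> trimesh.Trimesh:
    """Woodpile of crossed single-voxel walls.

    Two alternating tiers of parallel walls: the lower tier runs along y,
    the upper along x, with ``floor(extent/pitch) + 1`` walls per direction
    spaced by ``pitch``.  Wall thickness 0.26 um at 0.8 um pitch matches
    the printed single-voxel feature scale.
    """
    if not (wall_thickness > 0 and pitch > 0 and extent > 0 and height > 0):
        raise ValueError("all dimensions must be positive")
    if wall_thickness >= pitch:
        raise ValueError("wall_thickness must be below pitch")
    n = int(math.floor(extent / pitch)) + 1
    tier = height / 2.0
    boxes = []
    span = (n - 1) * pitch
    for i in range(n):
        off = -span / 2.0 + i * pitch
        lower = trimesh.creation.box(extents=[wall_thickness, extent, tier])
        lower.apply_translation([off, 0.0, tier / 2.0])
        boxes.append(lower)
        upper = trimesh.creation.box(extents=[extent, wall_thickness, tier])
        upper.apply_translation([0.0, off, 1.5 * tier])
        boxes.append(upper)
    return trimesh.util.concatenate(boxes)


def paper_scene() -> tuple[DropletSpec, BundleSpec, FieldMapConfig, SliceSpec]:
    """The canonical study configuration.

    10 um droplet tangent to the substrate with interior/exterior index
    ratio 1.08; a ~2500-ray NA-limited bundle (1.4 NA objective, capped at
    0.95 of the exterior index); field maps rendered within 0.96 of the
    droplet radius against a 400 nm diffraction limit; 100 nm layers and
    hatch lines written top-down at 10 000 um/s.
    """
    droplet = DropletSpec()
    bundle = BundleSpec()
    fmap_cfg = FieldMapConfig()
    slice_spec = SliceSpec()
    return droplet, bundle, fmap_cfg, slice_spec
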