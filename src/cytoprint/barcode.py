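"""4x4x4 intracellular graphical barcodes.

A barcode is a stack of four 4x4 grids of printed cylinders; each of the 64
lattice sites is occupied or empty.  Three sites are reserved: a star-shaped
cylinder at the top corner that is always present and, through its
star-shaped cross-section, fixes the orientation of the structure; and one
anchor cylinder in each of the two middle layers so that the printed stack
holds together.  The remaining 61 sites are free, so the scheme encodes 61
bits -- 2^61 (about 2.3e18) distinct codewords.

Decoding must work from an arbitrarily rotated observation, so the codec
canonicalizes a grid by the unique proper cube rotation (of the 24) that
brings the star site and the recorded star orientation back to canonical
before reading the bits.  The star's own orientation is part of the data
model: the corner site alone is stabilized by the three rotations about the
cube diagonal, and the star-shaped cross-section is what breaks that tie
physically.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np

GRID = 4
N_SITES = GRID ** 3


class MalformedBarcodeError(ValueError):
    """The grid's star bookkeeping is inconsistent or missing."""


class InvalidCodewordError(ValueError):
    """The grid violates the scheme's structural constraints."""


def _rotation_matrices() -> list[np.ndarray]:
    """The 24 proper rotations of the cube, as signed permutation matrices,
    in a fixed deterministic order (identity first)."""
    mats = []
    for perm in itertools.permutations(range(3)):
        for signs in itertools.product((1, -1), repeat=3):
            m = np.zeros((3, 3), dtype=int)
            for row, col in enumerate(perm):
                m[row, col] = signs[row]
            if round(np.linalg.det(m)) == 1:
                mats.append(m)
    mats.sort(key=lambda m: tuple(m.ravel()), reverse=True)
    assert np.array_equal(mats[0], np.eye(3, dtype=int))
    return mats


ROTATIONS: list[np.ndarray] = _rotation_matrices()
_ROT_INDEX = {tuple(m.ravel()): i for i, m in enumerate(ROTATIONS)}
IDENTITY = 0


def compose(r1: int, r2: int) -> int:
    """Index of the rotation 'apply r2, then r1'."""
    return _ROT_INDEX[tuple((ROTATIONS[r1] @ ROTATIONS[r2]).ravel())]


def inverse(r: int) -> int:
    return _ROT_INDEX[tuple(ROTATIONS[r].T.ravel())]


def rotate_site(site: tuple[int, int, int], r: int) -> tuple[int, int, int]:
    """Apply a lattice rotation to a site (x, y, z), about the cube center."""
    p = np.asarray(site, dtype=float) - 1.5
    q = ROTATIONS[r].astype(float) @ p + 1.5
    out = tuple(int(round(v)) for v in q)
    if not all(0 <= v < GRID for v in out):
        raise ValueError(f"rotated site {site} left the lattice: {out}")
    return out


def _lex_sites() -> list[tuple[int, int, int]]:
    """All 64 sites in lexicographic (layer, row, column) = (z, y, x) order."""
    return [(x, y, z) for z in range(GRID) for y in range(GRID)
            for x in range(GRID)]


@dataclass(frozen=True)
class BarcodeScheme:
    """Site reservations and cylinder geometry of the barcode lattice.

    The star occupies the canonical top corner (x=0, y=0, z=3); the two
    anchors sit directly beneath it in the middle layers (z=1 and z=2), so
    the middle-layer occupancy rule holds by construction.
    """

    star_site: tuple[int, int, int] = (0, 0, 3)
    anchor_sites: tuple = ((0, 0, 1), (0, 0, 2))
    pitch: float = 1.0              # um between site centers
    cylinder_diameter: float = 0.6  # um
    cylinder_height: float = 0.8    # um

    def __post_init__(self):
        zs = sorted(s[2] for s in self.anchor_sites)
        if len(self.anchor_sites) != 2 or zs != [1, 2]:
            raise ValueError("exactly one anchor in each middle layer required")
        if self.star_site in self.anchor_sites:
            raise ValueError("star and anchor sites must be disjoint")

    @property
    def reserved_sites(self) -> set:
        return {self.star_site, *self.anchor_sites}

    @property
    def free_sites(self) -> list[tuple[int, int, int]]:
        return [s for s in _lex_sites() if s not in self.reserved_sites]


@dataclass
class BarcodeGrid:
    """Occupancy of the 64 lattice sites plus the star's location/orientation."""

    occupancy: dict = field(default_factory=dict)  # site -> bool, all 64 sites
    star_site: tuple[int, int, int] = (0, 0, 3)
    star_orientation: int = IDENTITY               # rotation index (0..23)

    def __post_init__(self):
        for s in _lex_sites():
            self.occupancy.setdefault(s, False)
        if len(self.occupancy) != N_SITES:
            raise ValueError("occupancy must cover exactly the 64 lattice sites")

    def occupied_sites(self) -> list[tuple[int, int, int]]:
        return [s for s in _lex_sites() if self.occupancy[s]]

    def to_json(self) -> str:
        bits = [bool(self.occupancy[s]) for s in _lex_sites()]
        return json.dumps({
            "occupancy": bits,
            "star_site": list(self.star_site),
            "star_orientation": int(self.star_orientation),
            "site_order": "lexicographic (layer, row, column)",
        })

    @classmethod
    def from_json(cls, text: str) -> "BarcodeGrid":
        doc = json.loads(text)
        bits = doc["occupancy"]
        if len(bits) != N_SITES:
            raise ValueError(f"expected {N_SITES} occupancy bits, got {len(bits)}")
        occ = {s: bool(b) for s, b in zip(_lex_sites(), bits)}
        return cls(occupancy=occ, star_site=tuple(doc["star_site"]),
                   star_orientation=int(doc["star_orientation"]))


def capacity(scheme: BarcodeScheme = BarcodeScheme()) -> tuple[int, int]:
    """(number of free bits, number of distinct codewords)."""
    bits = len(scheme.free_sites)
    return bits, 1 << bits


def encode(message: int, scheme: BarcodeScheme = BarcodeScheme()) -> BarcodeGrid:
    """Encode a nonnegative integer message into a barcode grid.

    Bit k of the message (little-endian) sets the k-th free site in
    lexicographic (layer, row, column) order; star and anchors are always
    set.
    """
    bits, _ = capacity(scheme)
    if not (0 <= message < (1 << bits)):
        raise ValueError(f"message must lie in [0, 2^{bits})")
    occ = {s: False for s in _lex_sites()}
    occ[scheme.star_site] = True
    for a in scheme.anchor_sites:
        occ[a] = True
    for k, site in enumerate(scheme.free_sites):
        occ[site] = bool((message >> k) & 1)
    return BarcodeGrid(occupancy=occ, star_site=scheme.star_site,
                       star_orientation=IDENTITY)


def rotate_grid(grid: BarcodeGrid, r: int) -> BarcodeGrid:
    """Apply one of the 24 lattice rotations to a grid (occupancy, star site
    and star orientation all rotate together)."""
    occ = {rotate_site(s, r): v for s, v in grid.occupancy.items()}
    return BarcodeGrid(occupancy=occ,
                       star_site=rotate_site(grid.star_site, r),
                       star_orientation=compose(r, grid.star_orientation))


def canonicalize(grid: BarcodeGrid,
                 scheme: BarcodeScheme = BarcodeScheme()) -> tuple[BarcodeGrid, int]:
    """Rotate a grid so its star returns to the canonical corner with
    canonical orientation.  Returns (canonical grid, rotation applied)."""
    if not grid.occupancy.get(grid.star_site, False):
        raise MalformedBarcodeError("no star: the recorded star site is empty")
    r = inverse(grid.star_orientation)
    if rotate_site(grid.star_site, r) != scheme.star_site:
        raise MalformedBarcodeError(
            "star orientation inconsistent with the star site: no lattice "
            "rotation maps both to canonical")
    out = rotate_grid(grid, r)
    return out, r


def decode(grid: BarcodeGrid, scheme: BarcodeScheme = BarcodeScheme()) -> int:
    """Recover the message from a (possibly rotated) barcode grid."""
    canon, _ = canonicalize(grid, scheme)
    for a in scheme.anchor_sites:
        if not canon.occupancy[a]:
            raise InvalidCodewordError(f"anchor site {a} is empty")
    message = 0
    for k, site in enumerate(scheme.free_sites):
        if canon.occupancy[site]:
            message |= 1 << k
    return message


# ---------------------------------------------------------------------------
# Mesh export
# ---------------------------------------------------------------------------

def _star_prism(r_outer: float, height: float, n_points: int = 5,
                inner_frac: float = 0.45):
    """Watertight prism with a star cross-section, base at z=0.

    The star polygon is star-shaped about the origin, so both caps are fan
    triangulated from a center vertex.
    """
    import trimesh

    m = 2 * n_points
    ang = np.arange(m) * np.pi / n_points - np.pi / 2
    rad = np.where(np.arange(m) % 2 == 0, r_outer, inner_frac * r_outer)
    ring = np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])
    bottom = np.column_stack([ring, np.zeros(m)])
    top = np.column_stack([ring, np.full(m, height)])
    verts = np.vstack([bottom, top,
                       [[0.0, 0.0, 0.0]], [[0.0, 0.0, height]]])
    cb, ct = 2 * m, 2 * m + 1
    faces = []
    for i in range(m):
        j = (i + 1) % m
        faces.append([cb, j, i])                  # bottom cap (normal -z)
        faces.append([ct, m + i, m + j])          # top cap (normal +z)
        faces.append([i, j, m + j])               # side
        faces.append([i, m + j, m + i])
    return trimesh.Trimesh(vertices=verts, faces=np.array(faces), process=False)


def barcode_to_mesh(grid: BarcodeGrid,
                    scheme: BarcodeScheme = BarcodeScheme()):
    """Triangulated solid of a barcode: one cylinder per occupied site, a
    star prism at the star site.  Sites are disjoint (cylinder diameter and
    height below the pitch), so the concatenated mesh is watertight and can
    be sliced directly."""
    import trimesh

    solids = []
    r = scheme.cylinder_diameter / 2.0
    h = scheme.cylinder_height
    for site in grid.occupied_sites():
        cx, cy, cz = (np.asarray(site, float) * scheme.pitch)
        if site == grid.star_site:
            solid = _star_prism(r, h)
            solid.apply_translation([cx, cy, cz])
        else:
            # cylinder() is centered at the origin, extrude_polygon starts at
            # z=0; both span [cz, cz+h] after translation
            solid = trimesh.creation.cylinder(radius=r, height=h, sections=24)
            solid.apply_translation([cx, cy, cz + h / 2.0])
        solids.append(solid)
    if not solids:
        return trimesh.Trimesh()
    return trimesh.util.concatenate(solids)
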