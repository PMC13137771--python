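"""Layer/hatch print-path generation for two-photon polymerization.

The printer fills a CAD model volume layer by layer: the model is sliced
into 100 nm thick horizontal layers, each layer's cross-section is filled
with parallel hatch lines 100 nm apart, and the layers are written top-down
(furthest from the substrate first) at a galvo scan speed of 10 000 um/s.
The print time estimate is the total hatch length divided by the scan
speed; jump moves between segments are not counted, which is consistent
with the few-seconds illumination times observed for ~10 um structures.

Slicing planes are placed at half-offsets from the top of the model
(z_k = z_max - (k + 1/2) * layer_height), which makes layer counts
unambiguous for flat-topped solids.  Hatch lines run along x at half-offset
y positions within each cross-section and are traversed in a serpentine
order.  Cross-sections are computed as exact mesh/plane intersections and
filled even-odd, so voids (e.g. a hollow sphere) are handled naturally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely.geometry as sgeom
import trimesh

from .optics import DropletSpec

#: Layer thickness used by the printing protocol (100 nm).
LAYER_HEIGHT = 0.1
#: Hatch line spacing used by the printing protocol (100 nm).
HATCH_SPACING = 0.1
#: Galvo scan speed (um/s).
SCAN_SPEED = 10_000.0


class WatertightError(ValueError):
    """The mesh is not a closed, oriented solid."""


class PathParseError(ValueError):
    """A print-path file line could not be parsed."""


@dataclass(frozen=True)
class SliceSpec:
    layer_height: float = LAYER_HEIGHT   # um
    hatch_spacing: float = HATCH_SPACING  # um
    scan_speed: float = SCAN_SPEED        # um/s
    order: str = "top_down"

    def __post_init__(self):
        if not (self.layer_height > 0 and self.hatch_spacing > 0
                and self.scan_speed > 0):
            raise ValueError("layer_height, hatch_spacing, scan_speed must be > 0")
        if self.order not in ("top_down", "bottom_up"):
            raise ValueError(f"unknown order {self.order!r}")

    def to_dict(self) -> dict:
        return {"layer_height": self.layer_height,
                "hatch_spacing": self.hatch_spacing,
                "scan_speed": self.scan_speed, "order": self.order}


@dataclass
class Layer:
    z: float
    segments: list  # list of (k, 2) float arrays, polylines in um

    def length(self) -> float:
        return float(sum(np.linalg.norm(np.diff(s, axis=0), axis=1).sum()
                         for s in self.segments))


@dataclass
class PrintPath:
    layers: list            # ordered list of Layer
    scan_speed: float = SCAN_SPEED
    total_length: float = field(init=False)
    estimated_time: float = field(init=False)

    def __post_init__(self):
        self.total_length = float(sum(l.length() for l in self.layers))
        self.estimated_time = self.total_length / self.scan_speed

    def n_segments(self) -> int:
        return sum(len(l.segments) for l in self.layers)


def _open_edges(mesh: trimesh.Trimesh) -> np.ndarray:
    edges = np.sort(mesh.edges, axis=1)
    _, idx, counts = np.unique(edges, axis=0, return_index=True,
                               return_counts=True)
    return edges[idx[counts == 1]]


def _link_loops(segments_2d: np.ndarray) -> list[np.ndarray]:
    """Chain unordered 2-point segments into closed loops of vertices."""
    # merge endpoints that coincide to within rounding noise
    pts = segments_2d.reshape(-1, 2)
    keys = np.round(pts / 1e-9).astype(np.int64)
    _, first, inverse = np.unique(keys, axis=0, return_index=True,
                                  return_inverse=True)
    verts = pts[first]
    edges = inverse.reshape(-1, 2)
    edges = edges[edges[:, 0] != edges[:, 1]]
    adjacency: dict[int, list[int]] = {}
    for a, b in edges:
        adjacency.setdefault(int(a), []).append(int(b))
        adjacency.setdefault(int(b), []).append(int(a))
    seen_edges = set()
    loops = []
    for start in adjacency:
        for nxt in adjacency[start]:
            if (start, nxt) in seen_edges:
                continue
            loop = [start]
            prev, cur = start, nxt
            seen_edges.add((start, nxt))
            closed = False
            while True:
                loop.append(cur)
                seen_edges.add((cur, prev))
                if cur == start:
                    closed = True
                    break
                nbrs = [n for n in adjacency.get(cur, []) if n != prev]
                if not nbrs:
                    break
                prev, cur = cur, nbrs[0]
                seen_edges.add((prev, cur))
            if closed and len(loop) >= 4:
                loops.append(verts[np.array(loop)])
    return loops


def _cross_section(mesh: trimesh.Trimesh, z: float):
    """Shapely (multi)polygon of the mesh cross-section at height z, or None.

    The filled region is the even-odd combination of the closed contour
    loops, so nested contours (cavities) subtract from the section.
    """
    lines = trimesh.intersections.mesh_plane(mesh, plane_normal=[0, 0, 1.0],
                                             plane_origin=[0, 0, z])
    if len(lines) == 0:
        return None
    region = None
    for loop in _link_loops(np.asarray(lines)[:, :, :2]):
        poly = sgeom.Polygon(loop)
        if not poly.is_valid:
            poly = poly.buffer(0)
        if poly.is_empty:
            continue
        region = poly if region is None else region.symmetric_difference(poly)
    if region is None or region.is_empty:
        return None
    return region


def _hatch_polygon(section, spacing: float) -> list[np.ndarray]:
    """Fill a cross-section with serpentine hatch segments parallel to x."""
    minx, miny, maxx, maxy = section.bounds
    segments: list[np.ndarray] = []
    j = 0
    reverse = False
    y = miny + 0.5 * spacing
    while y < maxy:
        line = sgeom.LineString([(minx - 1.0, y), (maxx + 1.0, y)])
        inter = section.intersection(line)
        segs = []
        if not inter.is_empty:
            geoms = getattr(inter, "geoms", [inter])
            for g in geoms:
                if isinstance(g, sgeom.LineString) and g.length > 0:
                    coords = np.asarray(g.coords, dtype=float)
                    segs.append(coords)
        segs.sort(key=lambda c: float(c[:, 0].min()))
        if reverse:
            segs = [s[::-1].copy() for s in reversed(segs)]
        segments.extend(segs)
        reverse = not reverse
        j += 1
        y = miny + (j + 0.5) * spacing
    return segments


def slice_mesh(mesh: trimesh.Trimesh, spec: SliceSpec = SliceSpec()) -> PrintPath:
    """Slice a watertight mesh into a layered hatch print path."""
    if len(mesh.faces) == 0:
        raise WatertightError("mesh is empty")
    if not mesh.is_watertight:
        bad = _open_edges(mesh)
        raise WatertightError(
            f"mesh is not watertight: {len(bad)} open edge(s), e.g. "
            f"{bad[:5].tolist()}")
    z_min, z_max = float(mesh.bounds[0][2]), float(mesh.bounds[1][2])
    layers: list[Layer] = []
    k = 0
    while True:
        z = z_max - (k + 0.5) * spec.layer_height
        if z <= z_min:
            break
        section = _cross_section(mesh, z)
        if section is not None:
            segs = _hatch_polygon(section, spec.hatch_spacing)
            layers.append(Layer(z=z, segments=segs))
        else:
            layers.append(Layer(z=z, segments=[]))
        k += 1
    layers = [l for l in layers if l.segments]
    if not layers:
        warnings.warn("slicing produced an empty print path", stacklevel=2)
    if spec.order == "bottom_up":
        layers = layers[::-1]
    return PrintPath(layers=layers, scan_speed=spec.scan_speed)


def clip_to_droplet(path: PrintPath, droplet: DropletSpec) -> PrintPath:
    """Truncate the print path at the droplet surface.

    Structures slightly larger than the droplet are printed truncated at
    its edge; every hatch segment is replaced by its portion(s) inside the
    droplet sphere, and layers left empty are dropped.
    """
    cx, cy, cz = droplet.center
    R = droplet.radius
    new_layers = []
    for layer in path.layers:
        r2 = R * R - (layer.z - cz) ** 2
        if r2 <= 0:
            continue
        segs = []
        for poly in layer.segments:
            for a, b in zip(poly[:-1], poly[1:]):
                segs.extend(_clip_segment(a, b, cx, cy, r2))
        if segs:
            new_layers.append(Layer(z=layer.z, segments=segs))
    return PrintPath(layers=new_layers, scan_speed=path.scan_speed)


def _clip_segment(a, b, cx: float, cy: float, r2: float) -> list[np.ndarray]:
    """Portion of segment a-b inside the circle x^2+y^2=r2 about (cx, cy)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    d = b - a
    f = a - np.array([cx, cy])
    A = float(d @ d)
    if A == 0.0:
        return []
    B = 2.0 * float(f @ d)
    C = float(f @ f) - r2
    disc = B * B - 4 * A * C
    if disc <= 0:
        return []
    sq = np.sqrt(disc)
    t0 = max(0.0, (-B - sq) / (2 * A))
    t1 = min(1.0, (-B + sq) / (2 * A))
    if t1 <= t0:
        return []
    return [np.vstack([a + t0 * d, a + t1 * d])]


def estimate_print_time(path: PrintPath, spec: SliceSpec | None = None) -> float:
    """Illumination time in seconds: total hatch length over scan speed."""
    speed = spec.scan_speed if spec is not None else path.scan_speed
    return path.total_length / speed


# ---------------------------------------------------------------------------
# Plain-text path format
# ---------------------------------------------------------------------------
# line 1:            "printpath <n_layers> <scan_speed>"
# per layer:         "layer <z> <n_segments>"
# per polyline:      "x1 y1 x2 y2 ..." (um)

_FMT = "%.9g"


def write_path(path: PrintPath, file) -> None:
    """Write a print path in the plain-text polyline format."""
    own = isinstance(file, (str, bytes)) or hasattr(file, "__fspath__")
    fh = open(file, "w") if own else file
    try:
        fh.write(f"printpath {len(path.layers)} {_FMT % path.scan_speed}\n")
        for layer in path.layers:
            fh.write(f"layer {_FMT % layer.z} {len(layer.segments)}\n")
            for seg in layer.segments:
                fh.write(" ".join(_FMT % v for v in np.asarray(seg).ravel()))
                fh.write("\n")
    finally:
        if own:
            fh.close()


def read_path(file) -> PrintPath:
    """Read a print path written by :func:`write_path`."""
    own = isinstance(file, (str, bytes)) or hasattr(file, "__fspath__")
    fh = open(file) if own else file
    try:
        lines = fh.read().splitlines()
    finally:
        if own:
            fh.close()
    if not lines or not lines[0].startswith("printpath "):
        raise PathParseError("line 1: missing 'printpath' header")
    try:
        _, n_layers_s, speed_s = lines[0].split()
        n_layers, speed = int(n_layers_s), float(speed_s)
    except ValueError as e:
        raise PathParseError(f"line 1: bad header ({e})") from None
    layers = []
    ln = 1
    for _ in range(n_layers):
        if ln >= len(lines):
            raise PathParseError(f"line {ln + 1}: unexpected end of file")
        parts = lines[ln].split()
        if len(parts) != 3 or parts[0] != "layer":
            raise PathParseError(f"line {ln + 1}: expected 'layer <z> <count>'")
        try:
            z, count = float(parts[1]), int(parts[2])
        except ValueError as e:
            raise PathParseError(f"line {ln + 1}: {e}") from None
        ln += 1
        segs = []
        for _ in range(count):
            if ln >= len(lines):
                raise PathParseError(f"line {ln + 1}: unexpected end of file")
            try:
                vals = np.array([float(v) for v in lines[ln].split()])
            except ValueError as e:
                raise PathParseError(f"line {ln + 1}: {e}") from None
            if len(vals) < 4 or len(vals) % 2:
                raise PathParseError(
                    f"line {ln + 1}: polyline needs an even number (>= 4) of values")
            segs.append(vals.reshape(-1, 2))
            ln += 1
        layers.append(Layer(z=z, segments=segs))
    return PrintPath(layers=layers, scan_speed=speed)
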