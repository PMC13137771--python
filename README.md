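# cytoprint

Ray-optics fidelity analysis, print-path generation, and barcode design for
two-photon polymerization (TPP) inside refractive photoresist droplets in
living cells.

## The problem this models

A femtosecond laser focused through a high-NA objective can polymerize
photoresist only in the focal voxel, so arbitrary 3D microstructures can be
printed *inside* a living cell by first injecting a small droplet of
photoresist and then scanning the focus through it. The droplet, however, is
itself a small lens: its interior refractive index (1.48) is about 1.08×
that of the surrounding cytoplasm, so every ray of the converging bundle
refracts at the spherical droplet surface. The actual focus therefore lands
slightly away from the nominal focus, and the focal spot blurs — more so
near the droplet edge.

`cytoprint` quantifies and corrects this:

1. **optics** — vectorial Snell refraction of NA-limited ray bundles at the
   spherical droplet interface (`cytoprint.optics`).
2. **focal analysis** — the shifted focus is located as the axial plane of
   minimal transverse spot variance; the variance is exactly quadratic in
   z for straight rays, so the minimum is refined to a closed-form parabola
   vertex (`cytoprint.focal`).
3. **field mapping** — displacement and spot size are scanned over a
   meridian half-plane of the droplet (rotational symmetry makes one plane
   sufficient) and summarized into two headline statistics
   (`cytoprint.fieldmap`).
4. **pre-compensation** — CAD models are deformed opposite to the predicted
   shifts by fixed-point inversion of the displacement field, so the
   printed structure matches the design (`cytoprint.precomp`).
5. **slicing** — watertight meshes are converted to 100 nm layer/hatch
   serpentine paths, optionally clipped to the droplet, with print-time
   estimates at 10,000 μm/s (`cytoprint.slicer`).
6. **barcodes** — a 4×4×4 cylinder-lattice graphical barcode with a star
   orientation marker and two structural anchors encodes 61 bits
   (2⁶¹ ≈ 2.3·10¹⁸ codes) readable under arbitrary rotation
   (`cytoprint.barcode`), and pillar gratings can be read out remotely via
   their Fraunhofer far field (`cytoprint.diffraction`).
7. **fixtures** — parametric test meshes (solid/hollow spheres, woodpile)
   and the canonical scene configuration (`cytoprint.fixtures`).

### Headline results at the canonical configuration

For the canonical scene — a 10 μm droplet tangent to the substrate,
interior/exterior index ratio 1.08, 2500-ray bundles capped at NA
0.95·n_outside, 0.25 μm scan grid:

- maximum focal displacement within 0.96 of the droplet radius:
  **0.53 μm** (0.5 μm at one-decimal precision); narrower entrance-angle
  conventions give larger values (0.57 μm at cap 0.9, 0.61 μm at cap 0.8)
  because the strongly refracted marginal rays pull the least-squares focus
  back toward nominal,
- **96.5 %** of the droplet volume (rotationally weighted) keeps the RMS
  spot radius below the 400 nm diffraction limit, i.e. >90 % of the droplet
  is printable at full resolution,
- a solid 10 μm sphere slices to a 52,300 μm hatch path → **5.2 s**
  estimated print time (within the observed 3–10 s range),
- barcode capacity is exactly **61 bits**.

## Worked example

```python
import numpy as np
from cytoprint import (paper_scene, scan_meridian,
                       volume_fraction_below_limit, pre_deform,
                       slice_mesh, clip_to_droplet, estimate_print_time,
                       make_sphere_mesh, encode, decode, rotate_grid)

# 1. map the focal-shift field of the canonical droplet
droplet, bundle, map_cfg, slice_spec = paper_scene()
fmap = scan_meridian(droplet, bundle, map_cfg)       # ~7 s, 649 grid points
print(fmap.max_displacement(map_cfg.radial_cutoff))  # 0.5277 um
print(volume_fraction_below_limit(fmap, map_cfg))    # 0.9654

# 2. pre-deform a design so it prints true
design = make_sphere_mesh(diameter=6.0)
design.apply_translation([0, 0, droplet.center[2]])
corrected = pre_deform(design, fmap, tol=1e-3)       # 1 nm tolerance

# 3. slice it into the layered hatch path and estimate the print time
path = clip_to_droplet(slice_mesh(corrected, slice_spec), droplet)
print(estimate_print_time(path, slice_spec))         # ~1.1 s

# 4. encode a 61-bit message as a printable barcode
grid = encode(123_456_789)
assert decode(rotate_grid(grid, 17)) == 123_456_789  # rotation-invariant
```

The same pipeline is available from the command line:

```sh
cytoprint field --paper-defaults --out field_out      # CSV + PNG maps
cytoprint precomp design.stl --field-csv field_out/field_map.csv --out pre.stl
cytoprint slice pre.stl --clip-droplet 10 --out pre.path --report-time
cytoprint barcode encode 123456789 --mesh-out code.stl
cytoprint diffract --lattice hex --period 1.0 --out peaks.json
```

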