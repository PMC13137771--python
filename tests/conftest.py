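import numpy as np
import pytest

from cytoprint import (BundleSpec, DropletSpec, FieldMapConfig, scan_meridian)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def droplet():
    """The canonical 10 um droplet, index ratio 1.08, tangent to the substrate."""
    return DropletSpec()


@pytest.fixture(scope="session")
def coarse_field_map(droplet):
    """A reduced-size field map for interpolation/pre-compensation tests:
    0.5 um grid, 400-ray bundles.  Same physics as the full map, ~20x faster."""
    bundle = BundleSpec(n_rays=400)
    cfg = FieldMapConfig(grid_spacing=0.5)
    return scan_meridian(droplet, bundle, cfg)
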