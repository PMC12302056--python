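import numpy as np
import pytest
from hypothesis import settings

import holovib as hv

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def apligraf():
    """Default membrane/dermis/epidermis preset on agar."""
    return hv.apligraf_assembly("agar")


@pytest.fixture(scope="session")
def single_layer():
    """Uniform 1 mm hydrogel disc, the textbook single-plate reference."""
    layer = hv.LayerSpec("gel", 1e-3, 30e3, 0.48, 997.0)
    return hv.PlateAssembly(0.022, (layer,), boundary="clamped")


@pytest.fixture(scope="session")
def clamped_fundamental(apligraf):
    """(0,1) clamped mode shape scaled to 200 nm peak displacement."""
    shape = hv.mode_shape(hv.ModeIdentity(0, 1), "clamped", apligraf, grid=65)
    return shape.scaled(200e-9, unit="m")


def field_rotation_correlation(field_a, rotation_deg, field_b=None):
    """Pearson correlation between field_b and field_a rotated by rotation_deg
    (field_b defaults to field_a: self-symmetry check)."""
    field_b = field_b if field_b is not None else field_a
    x, y = field_a.coords()
    phi = np.radians(rotation_deg)
    xr = np.cos(phi) * x - np.sin(phi) * y
    yr = np.sin(phi) * x + np.cos(phi) * y
    a = field_a.sample(xr, yr)
    b = field_b.values
    ok = np.isfinite(a) & np.isfinite(b)
    return np.corrcoef(a[ok], b[ok])[0, 1]
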