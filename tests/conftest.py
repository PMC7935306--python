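"""Shared fixtures.

Heavy simulations are session-scoped and shared across test modules; they run
at a reduced acquisition scale (720 views, 212 channels of 2.28 mm pitch,
256-pixel grids at 1 mm) so the whole suite stays desk-fast while preserving
the physics (polyenergetic forward model, per-bin hardening, Poisson noise).
"""
from __future__ import annotations

import numpy as np
import pytest

from specctmar.materials import load_material_table
from specctmar.phantoms import make_head_phantom, make_iodine_cylinder
from specctmar.physics import BinConfig, build_spectrum
from specctmar.pipeline import simulate_scan
from specctmar.recon import FanGeometry, project_materials

TEST_SHAPE = 256
TEST_PIXEL = 1.0


@pytest.fixture(scope="session")
def table():
    return load_material_table()


@pytest.fixture(scope="session")
def spectrum():
    return build_spectrum(140.0)


@pytest.fixture(scope="session")
def bins():
    return BinConfig()


@pytest.fixture(scope="session")
def geometry():
    """Reduced-scale fan geometry used by the simulation fixtures."""
    return FanGeometry().scaled(2)


@pytest.fixture(scope="session")
def head_phantoms():
    """Head phantom with and without the titanium implants (same insert)."""
    with_metal = make_head_phantom(True, True, shape=TEST_SHAPE,
                                   pixel_size=TEST_PIXEL)
    without = make_head_phantom(False, True, shape=TEST_SHAPE,
                                pixel_size=TEST_PIXEL)
    return with_metal, without


@pytest.fixture(scope="session")
def head_scans(head_phantoms, geometry, spectrum, bins):
    """Noiseless paired scans (with metal, metal-free ground truth)."""
    ph_m, ph_0 = head_phantoms
    scan_m = simulate_scan(ph_m, geometry, spectrum, bins, noise=False)
    scan_0 = simulate_scan(ph_0, geometry, spectrum, bins, noise=False)
    return scan_m, scan_0


@pytest.fixture(scope="session")
def head_scan_noisy(head_phantoms, geometry, spectrum, bins):
    """Seeded noisy scan of the implanted head phantom."""
    ph_m, _ = head_phantoms
    return simulate_scan(ph_m, geometry, spectrum, bins, noise=True, seed=11)


@pytest.fixture(scope="session")
def calibration_scan(geometry, spectrum, bins):
    """Noiseless scan of the 150-mm calibration phantom."""
    from specctmar.phantoms import make_calibration_phantom
    phantom = make_calibration_phantom(shape=TEST_SHAPE, pixel_size=TEST_PIXEL)
    return phantom, simulate_scan(phantom, geometry, spectrum, bins,
                                  noise=False)


@pytest.fixture(scope="session")
def multi_energy_scan(geometry, spectrum, bins):
    """Noiseless scan of the iodine/calcium multi-energy phantom."""
    from specctmar.phantoms import make_multi_energy_phantom
    phantom = make_multi_energy_phantom(shape=TEST_SHAPE,
                                        pixel_size=TEST_PIXEL)
    return phantom, simulate_scan(phantom, geometry, spectrum, bins,
                                  noise=False)


@pytest.fixture(scope="session")
def iodine_scan(geometry, spectrum, bins):
    """Noiseless scan of the 12-cm iodine cylinder."""
    phantom = make_iodine_cylinder(12, shape=TEST_SHAPE,
                                   pixel_size=TEST_PIXEL)
    scan = simulate_scan(phantom, geometry, spectrum, bins, noise=False)
    return phantom, scan
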