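"""Shared fixtures: material table and cached synthetic phantoms.

Phantom generation is deterministic (seeded specs) and moderately costly,
so the standard study phantoms are generated once per session.
"""

from __future__ import annotations

import numpy as np
import pytest

from cementscan import classify, default_material_table, fit_tray_plane
from cementscan.synthetic_phantom import DepthProfile, PhantomSpec, generate_ct


@pytest.fixture(scope="session")
def table():
    return default_material_table()


@pytest.fixture(scope="session")
def aligned_phantom():
    """Noise-free cemented-tray phantom, axis-aligned, no cortical rim."""
    spec = PhantomSpec(seed=42, cortical_thickness_mm=0.0)
    return spec, *generate_ct(spec)


@pytest.fixture(scope="session")
def rotated_phantom():
    """Same construct tilted 7 degrees about the row axis."""
    spec = PhantomSpec(seed=42, cortical_thickness_mm=0.0, rotation_deg=7.0)
    return spec, *generate_ct(spec)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Scanner-realistic phantom: 50 HU noise, 0.4 mm partial-volume blur."""
    spec = PhantomSpec(seed=7, cortical_thickness_mm=0.0, noise_sd_hu=50.0, blur_fwhm_mm=0.4)
    return spec, *generate_ct(spec)


@pytest.fixture(scope="session")
def aligned_plane(aligned_phantom, table):
    _, vol, _ = aligned_phantom
    return fit_tray_plane(classify(vol, table), vol)
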