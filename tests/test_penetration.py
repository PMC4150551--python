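"""Tray-plane recovery, bead detection and penetration profiles."""

import numpy as np
import pytest

from cementscan import classify, fit_tray_plane, detect_beads, penetration_profile
from cementscan.errors import (
    DegenerateGeometryError,
    DepthOutOfProfileError,
    NoMetalError,
)
from cementscan.imaging_model import CTVolume
from cementscan.roi_ranges import PENETRATED
from cementscan.synthetic_phantom import DepthProfile, PhantomSpec, generate_ct


class TestTrayPlaneFit:
    def test_aligned_tray_recovers_axis_normal(self, aligned_phantom, aligned_plane):
        _, vol, truth = aligned_phantom
        assert abs(abs(aligned_plane.normal @ truth.plane.normal) - 1) < 1e-6
        assert aligned_plane.residual_mm <= 0.4  # half a slice
        # depth zero on the true underside face
        d0_err = (aligned_plane.point - truth.plane.point) @ truth.plane.normal
        assert abs(d0_err) < 1e-6

    @pytest.mark.parametrize("rotation", [7.0, 15.0])
    def test_rotated_tray_normal_within_one_degree(self, rotation, table):
        spec = PhantomSpec(seed=42, cortical_thickness_mm=0.0, rotation_deg=rotation)
        vol, truth = generate_ct(spec)
        plane = fit_tray_plane(classify(vol, table), vol)
        angle = np.degrees(
            np.arccos(np.clip(plane.normal @ truth.plane.normal, -1, 1))
        )
        assert angle < 1.0
        d0_err = (plane.point - truth.plane.point) @ truth.plane.normal
        assert abs(d0_err) < 0.8  # within one slice

    def test_no_metal_raises(self, table):
        rng = np.random.default_rng(0)
        vol = CTVolume(rng.normal(163, 152, size=(10, 20, 20)), spacing=(0.8, 0.4, 0.4))
        with pytest.raises(NoMetalError):
            fit_tray_plane(classify(vol, table), vol)

    def test_blob_metal_is_degenerate(self, table):
        vol = CTVolume(np.full((24, 24, 24), 163.0), spacing=(1, 1, 1))
        zz, yy, xx = np.meshgrid(*([np.arange(24)] * 3), indexing="ij")
        ball = (zz - 8) ** 2 + (yy - 12) ** 2 + (xx - 12) ** 2 <= 36
        vol.voxels[ball] = 3000.0
        with pytest.raises(DegenerateGeometryError):
            fit_tray_plane(classify(vol, table), vol)


class TestBeads:
    def test_single_bead_depth_within_a_voxel(self, aligned_phantom, aligned_plane, table):
        _, vol, truth = aligned_phantom
        beads = detect_beads(vol, table, aligned_plane)
        assert len(beads) == 1
        assert beads[0].depth_mm == pytest.approx(3.0, abs=0.8)
        assert 0 < beads[0].diameter_mm < 2.0

    def test_two_beads_sorted_by_depth(self, table):
        spec = PhantomSpec(seed=5, cortical_thickness_mm=0.0, bead_depths_mm=(5.0, 3.0))
        vol, _ = generate_ct(spec)
        plane = fit_tray_plane(classify(vol, table), vol)
        beads = detect_beads(vol, table, plane)
        assert len(beads) == 2
        assert beads[0].depth_mm == pytest.approx(3.0, abs=0.8)
        assert beads[1].depth_mm == pytest.approx(5.0, abs=0.8)

    def test_no_small_components_gives_empty_list(self, table):
        spec = PhantomSpec(seed=5, cortical_thickness_mm=0.0, bead_depths_mm=())
        vol, truth = generate_ct(spec)
        assert detect_beads(vol, table, truth.plane) == []


class TestProfiles:
    def test_step_phantom_profile_and_mantle_width(self, table):
        spec = PhantomSpec(
            seed=3, cortical_thickness_mm=0.0, include_keel=False,
            profile=DepthProfile(kind="step", f0=1.0, depth=3.0),
        )
        vol, _ = generate_ct(spec)
        plane = fit_tray_plane(classify(vol, table), vol)
        prof = penetration_profile(vol, table, plane)
        fractions = prof.cement_fractions
        shallow = prof.depths < 3.0 - 0.4
        deep = prof.depths > 3.0 + 0.4
        assert np.all(fractions[shallow] > 98.0)
        assert np.all(fractions[deep] < 2.0)
        assert prof.mantle_width_mm == pytest.approx(3.0, abs=0.8)

    def test_decaying_profile_is_monotone_nonincreasing(self, table):
        spec = PhantomSpec(
            seed=4, cortical_thickness_mm=0.0,
            profile=DepthProfile(kind="linear", f0=0.6, depth=6.0),
        )
        vol, _ = generate_ct(spec)
        plane = fit_tray_plane(classify(vol, table), vol)
        prof = penetration_profile(vol, table, plane)
        assert np.all(np.diff(prof.cement_fractions) <= 0.5)
        # sampling one slab deeper in a decaying phantom never measures more
        for d in (1.0, 2.0, 3.0, 4.0):
            assert prof.fraction_at(d + 0.8) <= prof.fraction_at(d) + 1e-9

    def test_uniform_trabecular_phantom_measures_no_cement(self, table):
        spec = PhantomSpec(
            seed=6, cortical_thickness_mm=0.0, include_keel=False,
            profile=DepthProfile(kind="step", f0=0.0, depth=0.0),
        )
        vol, _ = generate_ct(spec)
        plane = fit_tray_plane(classify(vol, table), vol)
        prof = penetration_profile(vol, table, plane)
        assert np.all(prof.cement_fractions < 1.0)
        assert prof.mantle_width_mm == 0.0
        assert not prof.window_3_to_5_populated

    def test_profile_rotation_invariant_below_interface(
        self, aligned_phantom, rotated_phantom, table
    ):
        """Fractions measured relative to the (true) tray plane agree between
        the aligned and 7-degree-tilted pose for all slabs clear of the tray
        interface; the first slab abuts the metal and carries the inherent
        half-voxel partial-volume ambiguity."""
        _, vol_a, truth_a = aligned_phantom
        _, vol_r, truth_r = rotated_phantom
        prof_a = penetration_profile(vol_a, table, truth_a.plane)
        prof_r = penetration_profile(vol_r, table, truth_r.plane)
        diff = np.abs(prof_a.cement_fractions[1:] - prof_r.cement_fractions[1:])
        assert np.max(diff) <= 0.5

    def test_bin_index_boundary_and_range(self, aligned_phantom, table):
        _, vol, truth = aligned_phantom
        prof = penetration_profile(vol, table, truth.plane)
        assert prof.bin_index(2.4) == 3  # boundary goes to the deeper slab
        assert prof.bin_index(3.0) == 3  # slab (2.4, 3.2]
        assert prof.bin_index(0.1) == 0
        with pytest.raises(DepthOutOfProfileError):
            prof.bin_index(12.0)
        with pytest.raises(DepthOutOfProfileError):
            prof.bin_index(-0.5)

    def test_cortical_rim_bias_is_depth_constant(self, table):
        """With a cortical rim, part of the rim is marked as penetrated
        cement (the known range overlap); the induced extra fraction is
        nearly the same at every depth, so depth *differences* are unbiased."""
        spec0 = PhantomSpec(seed=9, cortical_thickness_mm=0.0,
                            profile=DepthProfile(kind="step", f0=0.0, depth=0.0))
        spec1 = PhantomSpec(seed=9, cortical_thickness_mm=1.6,
                            profile=DepthProfile(kind="step", f0=0.0, depth=0.0))
        vol0, truth0 = generate_ct(spec0)
        vol1, _ = generate_ct(spec1)
        p0 = penetration_profile(vol0, table, truth0.plane)
        p1 = penetration_profile(vol1, table, truth0.plane)
        bias = p1.cement_fractions - p0.cement_fractions
        assert np.mean(bias) > 2.0  # the rim does inflate the raw fraction
        assert np.ptp(bias) < 2.0  # but near-constantly across depth
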