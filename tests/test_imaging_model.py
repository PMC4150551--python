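"""Volume model, HU calibration and slab resampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cementscan.errors import EmptyIntersectionError, ValidationError
from cementscan.imaging_model import (
    CTVolume,
    RescaleParams,
    extract_slice,
    hu_from_stored,
    read_dicom_series,
    read_raw_volume,
    write_raw_volume,
)


@pytest.mark.parametrize(
    "stored, slope, intercept, expected",
    [
        (0, 1.0, -1024.0, -1024.0),
        (1024, 1.0, -1024.0, 0.0),  # the water anchor of the HU scale
        (2352, 1.0, -1024.0, 1328.0),  # a pure-cement-level value
    ],
)
def test_hu_from_stored(stored, slope, intercept, expected):
    assert hu_from_stored(stored, RescaleParams(slope, intercept)) == expected


def test_zero_slope_rejected():
    with pytest.raises(ValidationError):
        RescaleParams(slope=0.0)


@given(st.integers(min_value=-(2**15), max_value=2**15))
@settings(deadline=None)
def test_stored_hu_roundtrip_identity_slope(stored):
    rescale = RescaleParams(slope=1.0, intercept=-1024.0)
    hu = hu_from_stored(stored, rescale)
    assert (hu - rescale.intercept) / rescale.slope == stored


@pytest.fixture()
def random_volume():
    rng = np.random.default_rng(11)
    return CTVolume(
        voxels=rng.normal(200, 300, size=(12, 16, 16)),
        spacing=(0.8, 0.4, 0.4),
    )


def test_native_slice_extraction_is_exact(random_volume):
    """An axis-aligned native-thickness slab reproduces the native slice."""
    k = 5
    z = (k + 0.5) * 0.8
    slc = extract_slice(random_volume, (z, 0, 0), (1, 0, 0), thickness=0.8)
    np.testing.assert_array_equal(slc.pixels, random_volume.voxels[k])
    assert slc.pixel_spacing == (0.4, 0.4)


def test_uniform_volume_stays_uniform_on_oblique_plane():
    vol = CTVolume(np.full((10, 20, 20), 500.0), spacing=(1, 1, 1))
    slc = extract_slice(vol, (5, 10, 10), (0.3, 0.2, 0.93), thickness=2.0)
    vals = slc.pixels[np.isfinite(slc.pixels)]
    assert vals.size > 0
    np.testing.assert_allclose(vals, 500.0, atol=1e-6)


def test_two_layer_slab_average():
    """A 2 mm slab straddling a 0/1000 HU interface averages to 500."""
    vol = CTVolume(np.zeros((10, 8, 8)), spacing=(1, 1, 1))
    vol.voxels[5:] = 1000.0
    slc = extract_slice(vol, (5.0, 4, 4), (1, 0, 0), thickness=2.0)
    np.testing.assert_allclose(slc.pixels[np.isfinite(slc.pixels)], 500.0, atol=1e-9)


def test_extract_commutes_with_global_offset(random_volume):
    plane = ((4.0, 3.0, 3.0), (0.2, 0.1, 0.97))
    a = extract_slice(random_volume, *plane, thickness=1.0)
    shifted = CTVolume(random_volume.voxels + 37.0, random_volume.spacing)
    b = extract_slice(shifted, *plane, thickness=1.0)
    np.testing.assert_allclose(b.pixels, a.pixels + 37.0, atol=1e-9, equal_nan=True)


def test_slab_missing_volume_raises(random_volume):
    with pytest.raises(EmptyIntersectionError):
        extract_slice(random_volume, (1000.0, 0, 0), (1, 0, 0), thickness=0.8)


def test_invalid_thickness_rejected(random_volume):
    with pytest.raises(ValidationError):
        extract_slice(random_volume, (4, 0, 0), (1, 0, 0), thickness=0.0)


def test_raw_volume_roundtrip(tmp_path, random_volume):
    write_raw_volume(random_volume, tmp_path / "vol")
    back = read_raw_volume(tmp_path / "vol")
    np.testing.assert_array_equal(back.voxels, random_volume.voxels)
    np.testing.assert_allclose(back.spacing, random_volume.spacing)


def _write_dicom_series(directory, stored, spacing=(0.8, 0.5, 0.5), jitter=0.0):
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

    directory.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    for k in range(stored.shape[0]):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "CT"
        ds.Rows, ds.Columns = stored.shape[1:]
        ds.PixelSpacing = [spacing[1], spacing[2]]
        ds.SliceThickness = spacing[0]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        z = k * spacing[0] + (jitter if k == stored.shape[0] - 1 else 0.0)
        ds.ImagePositionPatient = [0.0, 0.0, z]
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = -1024.0
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = stored[k].astype(np.uint16).tobytes()
        ds.save_as(directory / f"slice_{k:03d}.dcm", enforce_file_format=True)


def test_dicom_series_reader_applies_rescale_and_sorts(tmp_path):
    rng = np.random.default_rng(5)
    stored = rng.integers(0, 3000, size=(4, 6, 6), dtype=np.uint16)
    _write_dicom_series(tmp_path / "series", stored)
    vol = read_dicom_series(tmp_path / "series")
    np.testing.assert_array_equal(vol.voxels, stored.astype(float) - 1024.0)
    np.testing.assert_allclose(vol.spacing, [0.8, 0.5, 0.5])


def test_dicom_series_nonuniform_spacing_rejected(tmp_path):
    stored = np.zeros((4, 6, 6), dtype=np.uint16)
    _write_dicom_series(tmp_path / "bad", stored, jitter=0.05)
    with pytest.raises(ValidationError):
        read_dicom_series(tmp_path / "bad")
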