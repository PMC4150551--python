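"""Calibrated CT volume model and slab-based slice extraction.

The volume model is deliberately minimal: a 3-D grid of Hounsfield units
(HU) with physical voxel spacing, a physical origin and an axis-aligned
orientation.  Indexing convention is ``(slice, row, column)``; voxel ``i``
owns the half-open physical cell ``[origin + i*spacing, origin +
(i+1)*spacing)`` and its sample point sits at the cell centre.

Slice extraction resamples an arbitrary oblique slab of given thickness.
The reconstruction model is piecewise-constant per voxel (nearest-neighbour
sampling): every resampled value is an HU value that actually occurs in the
volume.  This matters downstream, where pixels are classified into material
HU ranges — an interpolating sampler would fabricate intermediate HU values
at material interfaces that belong to no material range at all, silently
eroding boundary pixels from every area fraction.  The slab average is
taken over several sample planes across the slab thickness, emulating the
integration of a scanner over its slice width.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._utils import as_unit_vector
from .errors import EmptyIntersectionError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "RescaleParams",
    "CTVolume",
    "PlanarSlice",
    "hu_from_stored",
    "extract_slice",
    "read_dicom_series",
    "read_raw_volume",
    "write_raw_volume",
]


@dataclass(frozen=True)
class RescaleParams:
    """Affine map from stored pixel values to Hounsfield units."""

    slope: float = 1.0
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValidationError("rescale slope must be non-zero")


def hu_from_stored(stored_value, rescale: RescaleParams):
    """Convert stored integer pixel value(s) to HU: ``slope * stored + intercept``."""
    return rescale.slope * np.asarray(stored_value, dtype=float) + rescale.intercept


@dataclass
class CTVolume:
    """A calibrated CT volume.

    Parameters
    ----------
    voxels:
        3-D array of HU values, indexed ``(slice, row, column)``.
    spacing:
        Physical voxel size per axis in mm, same axis order as ``voxels``.
    origin:
        Physical position (mm) of the corner of voxel ``(0, 0, 0)``.
    orientation:
        3x3 direction-cosine matrix mapping index axes to physical axes.
        Only axis-aligned volumes are supported.
    """

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default=None)  # type: ignore[assignment]
    orientation: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValidationError("voxels must be a 3-D array")
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.spacing.shape != (3,) or not np.all(self.spacing > 0):
            raise ValidationError("spacing must be three positive values (mm)")
        if self.origin is None:
            self.origin = np.zeros(3)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.orientation is None:
            self.orientation = np.eye(3)
        self.orientation = np.asarray(self.orientation, dtype=float)
        if not np.allclose(self.orientation, np.eye(3), atol=1e-6):
            raise ValidationError("only axis-aligned (identity orientation) volumes are supported")
        if not np.all(np.isfinite(self.voxels)):
            raise ValidationError("HU values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def voxel_centers_1d(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical coordinates of voxel centres along each axis (mm)."""
        return tuple(
            self.origin[a] + (np.arange(self.shape[a]) + 0.5) * self.spacing[a]
            for a in range(3)
        )  # type: ignore[return-value]

    def physical_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map physical points (..., 3) to fractional voxel indices."""
        points = np.asarray(points, dtype=float)
        return (points - self.origin) / self.spacing - 0.5

    def index_to_physical(self, indices: np.ndarray) -> np.ndarray:
        indices = np.asarray(indices, dtype=float)
        return self.origin + (indices + 0.5) * self.spacing


@dataclass
class PlanarSlice:
    """A resampled planar slab of HU values.

    Pixels that fall entirely outside the volume are NaN and are excluded
    from any area accounting downstream.  ``depth`` is caller-supplied
    bookkeeping: the signed distance of the slab centre from a reference
    plane, positive beneath it.
    """

    pixels: np.ndarray
    pixel_spacing: tuple[float, float]
    depth: float = 0.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValidationError("slice pixels must be a non-empty 2-D array")
        if not math.isfinite(self.depth):
            raise ValidationError("slice depth must be finite")

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.pixels)


def _inplane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Right-handed orthonormal in-plane basis (u, v) for a unit normal."""
    axes = np.eye(3)
    e = axes[int(np.argmin(np.abs(normal)))]
    u = as_unit_vector(np.cross(normal, e))
    v = np.cross(normal, u)
    return u, v


def _sample_nearest(volume: CTVolume, points: np.ndarray) -> np.ndarray:
    """Nearest-voxel HU at physical points (..., 3); NaN outside the volume."""
    idx = volume.physical_to_index(points)
    nearest = np.floor(idx + 0.5).astype(int)
    shape = np.asarray(volume.shape)
    valid = np.all((nearest >= 0) & (nearest < shape), axis=-1)
    out = np.full(points.shape[:-1], np.nan)
    if np.any(valid):
        n = nearest[valid]
        out[valid] = volume.voxels[n[:, 0], n[:, 1], n[:, 2]]
    return out


def _axis_aligned_axis(normal: np.ndarray, tol: float = 1e-9) -> int | None:
    for a in range(3):
        if abs(abs(normal[a]) - 1.0) <= tol:
            return a
    return None


def extract_slice(
    volume: CTVolume,
    point,
    normal,
    thickness: float,
    *,
    depth: float = 0.0,
    n_samples: int | None = None,
) -> PlanarSlice:
    """Resample a planar slab of given thickness centred on a plane.

    Parameters
    ----------
    point, normal:
        A point on the slab's centre plane (mm) and the plane normal.
    thickness:
        Slab thickness in mm (> 0).  The returned pixel values are averages
        of ``n_samples`` sample planes spread symmetrically across the slab.
    depth:
        Recorded on the returned slice; signed distance of this slab from
        the caller's reference plane.
    n_samples:
        Number of sample planes across the slab.  Defaults to at least one
        sample per half native spacing along the slab normal (>= 4 for a
        native-thickness slab at typical anisotropy).

    Out-of-volume samples are excluded from the per-pixel average; pixels
    with no in-volume sample are NaN.
    """
    if thickness <= 0:
        raise ValidationError("slab thickness must be > 0")
    point = np.asarray(point, dtype=float)
    normal = as_unit_vector(normal)

    if n_samples is None:
        n_samples = max(1, int(math.ceil(2.0 * thickness / float(np.min(volume.spacing)))))
    offsets = ((np.arange(n_samples) + 0.5) / n_samples - 0.5) * thickness

    axis = _axis_aligned_axis(normal)
    if axis is not None:
        # Grid anchored on native voxel centres of the two in-plane axes, so an
        # axis-aligned native-thickness slab reproduces a native slice exactly.
        inplane_axes = [a for a in range(3) if a != axis]
        cs = volume.voxel_centers_1d()
        gi, gj = np.meshgrid(cs[inplane_axes[0]], cs[inplane_axes[1]], indexing="ij")
        base = np.empty(gi.shape + (3,))
        base[..., inplane_axes[0]] = gi
        base[..., inplane_axes[1]] = gj
        base[..., axis] = point[axis]
        step_dir = np.zeros(3)
        step_dir[axis] = math.copysign(1.0, normal[axis])
        pixel_spacing = (volume.spacing[inplane_axes[0]], volume.spacing[inplane_axes[1]])
    else:
        u, v = _inplane_basis(normal)
        corners = np.array(
            [volume.origin + np.asarray(c) * volume.spacing * np.asarray(volume.shape)
             for c in np.ndindex(2, 2, 2)]
        )
        rel = corners - point
        pu, pv = rel @ u, rel @ v
        px = float(np.min(volume.spacing))
        ui = np.arange(np.min(pu) + px / 2, np.max(pu), px)
        vi = np.arange(np.min(pv) + px / 2, np.max(pv), px)
        if ui.size == 0 or vi.size == 0:
            raise EmptyIntersectionError("slab does not intersect the volume")
        gu, gv = np.meshgrid(ui, vi, indexing="ij")
        base = point + gu[..., None] * u + gv[..., None] * v
        step_dir = normal
        pixel_spacing = (px, px)

    acc = np.zeros(base.shape[:-1])
    cnt = np.zeros(base.shape[:-1], dtype=int)
    for off in offsets:
        vals = _sample_nearest(volume, base + off * step_dir)
        ok = np.isfinite(vals)
        acc[ok] += vals[ok]
        cnt += ok
    pixels = np.full(base.shape[:-1], np.nan)
    covered = cnt > 0
    if not np.any(covered):
        raise EmptyIntersectionError("slab does not intersect the volume")
    pixels[covered] = acc[covered] / cnt[covered]
    return PlanarSlice(pixels=pixels, pixel_spacing=pixel_spacing, depth=depth)


# ---------------------------------------------------------------------------
# Volume I/O


def read_dicom_series(directory, *, spacing_tol: float = 1e-3) -> CTVolume:
    """Load a single-frame CT DICOM series as a calibrated :class:`CTVolume`.

    Files are sorted by their position along the slice normal; rescale
    slope/intercept are applied per file; slice spacing must be uniform to
    within ``spacing_tol`` mm.  Only axis-aligned orientation
    (ImageOrientationPatient = [1,0,0,0,1,0]) is supported.
    """
    import pydicom

    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = []
    for p in files:
        try:
            ds = pydicom.dcmread(str(p))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            datasets.append(ds)
    if not datasets:
        raise ValidationError(f"no DICOM image files found in {directory}")

    ref = datasets[0]
    iop = np.asarray(getattr(ref, "ImageOrientationPatient", [1, 0, 0, 0, 1, 0]), dtype=float)
    if not np.allclose(iop, [1, 0, 0, 0, 1, 0], atol=1e-3):
        raise ValidationError("only axis-aligned DICOM orientation is supported")
    normal = np.cross(iop[:3], iop[3:])

    def pos(ds):
        return float(np.dot(np.asarray(ds.ImagePositionPatient, dtype=float), normal))

    datasets.sort(key=pos)
    positions = np.array([pos(ds) for ds in datasets])
    if len(datasets) > 1:
        deltas = np.diff(positions)
        if np.any(deltas <= 0):
            raise ValidationError("duplicate or non-increasing slice positions")
        if np.ptp(deltas) > spacing_tol:
            raise ValidationError(
                f"non-uniform slice spacing: range {np.ptp(deltas):.4f} mm exceeds {spacing_tol} mm"
            )
        dz = float(np.mean(deltas))
    else:
        dz = float(getattr(ref, "SliceThickness", 1.0))

    row_sp, col_sp = (float(x) for x in ref.PixelSpacing)
    slices = []
    for ds in datasets:
        rescale = RescaleParams(
            slope=float(getattr(ds, "RescaleSlope", 1.0)),
            intercept=float(getattr(ds, "RescaleIntercept", 0.0)),
        )
        slices.append(hu_from_stored(ds.pixel_array, rescale))
    voxels = np.stack(slices, axis=0)

    # ImagePositionPatient is the centre of the first transmitted pixel; our
    # origin is the corner of voxel (0,0,0).
    first = np.asarray(datasets[0].ImagePositionPatient, dtype=float)
    centre0 = np.array([first[2], first[1], first[0]])  # (z, y, x) ordering
    spacing = np.array([dz, row_sp, col_sp])
    origin = centre0 - spacing / 2
    vol = CTVolume(voxels=voxels, spacing=spacing, origin=origin)
    logger.info(
        "loaded DICOM series: %d slices, shape %s, spacing %s mm, origin %s mm",
        len(datasets), vol.shape, np.round(vol.spacing, 4), np.round(vol.origin, 4),
    )
    return vol


def write_raw_volume(volume: CTVolume, directory) -> None:
    """Write a volume as ``voxels.npy`` plus a JSON geometry sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.save(directory / "voxels.npy", volume.voxels)
    meta = {"spacing_mm": volume.spacing.tolist(), "origin_mm": volume.origin.tolist()}
    (directory / "geometry.json").write_text(json.dumps(meta, indent=2))


def read_raw_volume(directory) -> CTVolume:
    """Read a volume written by :func:`write_raw_volume`."""
    directory = Path(directory)
    voxels = np.load(directory / "voxels.npy")
    meta = json.loads((directory / "geometry.json").read_text())
    vol = CTVolume(voxels=voxels, spacing=meta["spacing_mm"], origin=meta.get("origin_mm"))
    logger.info(
        "loaded raw volume: shape %s, spacing %s mm, origin %s mm",
        vol.shape, np.round(vol.spacing, 4), np.round(vol.origin, 4),
    )
    return vol
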