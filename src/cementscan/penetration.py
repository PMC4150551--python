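"""Geometry beneath the tibial tray: plane fit, bead fiducials, depth profile.

The cement-penetration measurement is defined relative to the underside of
the metal tray: transversal slabs parallel to the tray are sampled every
0.8 mm (the native slice thickness of the validating scanner) and the
cement-penetrated area fraction of each slab is reported.  Depth zero is
the lowest point of the tray underside along the tray normal, so depth
``d`` is millimetres of bone beneath the implant.

The tray plane is recovered from the prosthesis-range voxels themselves:
the dominant metal component is reduced to its planar sheet (the tray; the
keel is rejected as an out-of-plane protrusion), a least-squares plane is
fitted through the sheet's underside voxels, and the normal is oriented
into the bone.  Small prosthesis-range components disjoint from the tray
are tantalum bead fiducials (sub-2-mm spheres placed at known depth to
match sawed physical slices to CT slices).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._utils import as_unit_vector
from .errors import (
    DegenerateGeometryError,
    DepthOutOfProfileError,
    NoMetalError,
    ValidationError,
)
from .imaging_model import CTVolume, extract_slice
from .roi_ranges import CORTICAL, PENETRATED, PROSTHESIS, TRABECULAR, MaterialTable
from .segmentation import LabelMap, SliceFractionReport, classify, slice_fractions

__all__ = [
    "TrayPlane",
    "BeadFiducial",
    "PenetrationProfile",
    "fit_tray_plane",
    "detect_beads",
    "penetration_profile",
]

#: Minimum prosthesis-component size accepted as a tray.
MIN_TRAY_VOXELS = 100

#: A metal component counts as sheet-like if its thinnest principal extent is
#: below this fraction of the next one.
SHEET_ANISOTROPY_LIMIT = 0.35

#: Components with equivalent-sphere diameter below this are bead fiducials.
MAX_BEAD_DIAMETER_MM = 2.0


@dataclass
class TrayPlane:
    """The fitted tray-underside plane with depth-zero bookkeeping.

    ``point`` lies on the depth-zero plane (through the lowest underside
    point); ``normal`` is unit length and points into the bone, so
    ``depth_of`` is positive beneath the tray.
    """

    point: np.ndarray
    normal: np.ndarray
    residual_mm: float = 0.0

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        if abs(np.linalg.norm(self.normal) - 1.0) > 1e-9:
            raise ValidationError("tray-plane normal must be unit length")
        if self.residual_mm < 0:
            raise ValidationError("plane-fit residual must be >= 0")

    def depth_of(self, points) -> np.ndarray | float:
        """Signed depth (mm) of physical points beneath the reference plane."""
        rel = np.asarray(points, dtype=float) - self.point
        return rel @ self.normal


@dataclass(frozen=True)
class BeadFiducial:
    """A tantalum bead fiducial: centroid, size and depth beneath the tray."""

    centroid_mm: tuple[float, float, float]
    diameter_mm: float
    depth_mm: float

    def __post_init__(self) -> None:
        if not 0 < self.diameter_mm < MAX_BEAD_DIAMETER_MM:
            raise ValidationError("bead diameter must be in (0, 2) mm")


def _principal_axes(points: np.ndarray):
    centroid = points.mean(axis=0)
    cov = np.cov((points - centroid).T)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    return centroid, np.sqrt(np.maximum(evals, 0.0)), evecs


def fit_tray_plane(labelmap: LabelMap, volume: CTVolume) -> TrayPlane:
    """Fit the tray-underside plane from a 3-D prosthesis label map.

    Raises :class:`NoMetalError` if no prosthesis component has at least
    100 voxels, and :class:`DegenerateGeometryError` if the dominant metal
    component is not sheet-like.
    """
    if labelmap.labels.ndim != 3:
        raise ValidationError("fit_tray_plane needs a 3-D label map")
    metal = labelmap.mask(PROSTHESIS)
    comp, n_comp = ndimage.label(metal, structure=np.ones((3, 3, 3)))
    if n_comp == 0:
        raise NoMetalError("no prosthesis-range voxels in the volume")
    sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=np.arange(1, n_comp + 1))
    tray_id = int(np.argmax(sizes)) + 1
    if sizes[tray_id - 1] < MIN_TRAY_VOXELS:
        raise NoMetalError(
            f"largest prosthesis component has {int(sizes[tray_id - 1])} voxels "
            f"(< {MIN_TRAY_VOXELS}); no tray present"
        )
    idx = np.argwhere(comp == tray_id)
    pts = volume.index_to_physical(idx)

    # Reduce the component to its planar sheet: iteratively trim points far
    # from the current mid-plane (this drops the keel, which protrudes along
    # the normal), then require sheet-like anisotropy.
    sheet = pts
    normal = None
    for _ in range(4):
        centroid, sds, evecs = _principal_axes(sheet)
        normal = evecs[:, 0]
        proj = (sheet - centroid) @ normal
        med = np.median(proj)
        scale = 1.4826 * np.median(np.abs(proj - med))
        band = max(2.0 * scale, float(np.min(volume.spacing)))
        keep = np.abs(proj - med) <= band
        if keep.all():
            break
        sheet = sheet[keep]
    centroid, sds, evecs = _principal_axes(sheet)
    normal = evecs[:, 0]
    if sds[0] > SHEET_ANISOTROPY_LIMIT * sds[1]:
        raise DegenerateGeometryError(
            "dominant metal component is not sheet-like "
            f"(thickness/width ratio {sds[0] / max(sds[1], 1e-12):.2f})"
        )

    # Orient the normal toward the bone.
    bone = (
        labelmap.mask(TRABECULAR) | labelmap.mask(PENETRATED) | labelmap.mask(CORTICAL)
        if all(m in labelmap.table.materials for m in (TRABECULAR, PENETRATED, CORTICAL))
        else ~metal
    )
    if not np.any(bone):
        raise DegenerateGeometryError("no bone-range voxels to orient the tray normal")
    bone_centroid = volume.index_to_physical(
        np.asarray(ndimage.center_of_mass(bone))
    )
    if (bone_centroid - centroid) @ normal < 0:
        normal = -normal

    # Underside voxels: per in-plane 1 mm column, the deepest sheet voxel.
    u = as_unit_vector(np.cross(normal, np.eye(3)[int(np.argmin(np.abs(normal)))]))
    v = np.cross(normal, u)
    rel = sheet - centroid
    cols = np.floor(np.stack([rel @ u, rel @ v], axis=1)).astype(int)
    proj = rel @ normal
    # Per column, keep the voxel with the largest (deepest) projection:
    # sort projections descending within columns and take each column's first.
    order_desc = np.lexsort((-proj, cols[:, 1], cols[:, 0]))
    _, first_desc = np.unique(cols[order_desc], axis=0, return_index=True)
    underside = sheet[order_desc[first_desc]]
    # Columns pierced by the keel bottom out well below the tray underside;
    # keep only columns whose deepest voxel sits at the consensus underside
    # level (within 3/4 of the voxel extent along the normal).
    u_proj = underside @ normal
    extent = float(np.abs(normal) @ volume.spacing)
    level_ok = np.abs(u_proj - np.median(u_proj)) <= 0.75 * extent
    underside = underside[level_ok]

    # Final least-squares plane through the underside voxel centres.
    u_centroid, u_sds, u_evecs = _principal_axes(underside)
    n_fit = u_evecs[:, 0]
    if n_fit @ normal < 0:
        n_fit = -n_fit
    n_fit = as_unit_vector(n_fit)
    resid = (underside - u_centroid) @ n_fit
    residual = float(np.sqrt(np.mean(resid**2)))

    # Depth zero: the tray underside *face* level.  Underside voxel centres
    # sit half a voxel above the physical face (staircased for oblique
    # trays), so take the robust centre level and shift by half the voxel
    # extent along the normal.
    half_extent = 0.5 * float(np.abs(n_fit) @ volume.spacing)
    d0 = float(np.median(underside @ n_fit)) + half_extent
    point = u_centroid + (d0 - u_centroid @ n_fit) * n_fit
    return TrayPlane(point=point, normal=n_fit, residual_mm=residual)


def detect_beads(
    volume: CTVolume, table: MaterialTable, plane: TrayPlane
) -> list[BeadFiducial]:
    """Find sub-2-mm prosthesis-range components (tantalum bead fiducials).

    The tray component itself (equivalent diameter >= 2 mm) is excluded.
    Returned sorted by depth beneath the tray plane.
    """
    lm = classify(volume, table)
    metal = lm.mask(PROSTHESIS)
    comp, n_comp = ndimage.label(metal, structure=np.ones((3, 3, 3)))
    beads: list[BeadFiducial] = []
    voxel_mm3 = float(np.prod(volume.spacing))
    for cid in range(1, n_comp + 1):
        n_vox = int(np.sum(comp == cid))
        d_eq = (6.0 * n_vox * voxel_mm3 / math.pi) ** (1.0 / 3.0)
        if d_eq >= MAX_BEAD_DIAMETER_MM:
            continue  # tray/keel-scale component
        centroid = volume.index_to_physical(
            np.asarray(ndimage.center_of_mass(comp == cid))
        )
        beads.append(
            BeadFiducial(
                centroid_mm=tuple(float(c) for c in centroid),
                diameter_mm=float(d_eq),
                depth_mm=float(plane.depth_of(centroid)),
            )
        )
    beads.sort(key=lambda b: b.depth_mm)
    return beads


@dataclass
class PenetrationProfile:
    """Cement-fraction profile at consecutive 0.8 mm slabs beneath the tray.

    Slab ``k`` covers depths ``(k*step, (k+1)*step]``; its report is
    centred at ``(k + 0.5) * step``.
    """

    slices: list[SliceFractionReport]
    step_mm: float
    policy: str = "total"
    mantle_floor_pct: float = 5.0

    def __post_init__(self) -> None:
        depths = self.depths
        if len(depths) > 1 and not np.all(np.diff(depths) > 0):
            raise ValidationError("profile depths must be strictly increasing")

    @property
    def depths(self) -> np.ndarray:
        return np.array([s.depth for s in self.slices])

    @property
    def cement_fractions(self) -> np.ndarray:
        return np.array([s.fraction(PENETRATED) for s in self.slices])

    def bin_index(self, depth: float) -> int:
        """Index of the slab containing ``depth`` (boundary goes to the deeper slab)."""
        k = int(math.floor(depth / self.step_mm + 1e-9))
        if k < 0 or k >= len(self.slices):
            raise DepthOutOfProfileError(
                f"depth {depth} mm outside profiled range (0, "
                f"{len(self.slices) * self.step_mm:.1f}] mm"
            )
        return k

    def fraction_at(self, depth: float) -> float:
        return float(self.cement_fractions[self.bin_index(depth)])

    @property
    def mantle_width_mm(self) -> float:
        """Contiguous depth from the tray with cement fraction above the floor."""
        width = 0.0
        for f in self.cement_fractions:
            if f < self.mantle_floor_pct:
                break
            width += self.step_mm
        return width

    @property
    def window_3_to_5_populated(self) -> bool:
        """True if every slab intersecting the clinically optimal 3-5 mm
        window shows cement above the mantle floor."""
        fractions = self.cement_fractions
        depths = self.depths
        in_window = (depths + self.step_mm / 2 > 3.0) & (depths - self.step_mm / 2 < 5.0)
        if not np.any(in_window):
            return False
        return bool(np.all(fractions[in_window] >= self.mantle_floor_pct))

    def summary(self) -> dict:
        out = {
            "mantle_width_mm": self.mantle_width_mm,
            "window_3_to_5_populated": self.window_3_to_5_populated,
            "mantle_floor_pct": self.mantle_floor_pct,
            "step_mm": self.step_mm,
            "policy": self.policy,
        }
        for d in (3.0, 5.0):
            try:
                out[f"fraction_at_{d:.0f}mm_pct"] = self.fraction_at(d)
            except DepthOutOfProfileError:
                out[f"fraction_at_{d:.0f}mm_pct"] = None
        return out

    def to_rows(self) -> list[dict]:
        rows = []
        for k, s in enumerate(self.slices):
            for material, frac in s.fractions.items():
                rows.append(
                    {
                        "bin": k,
                        "depth_mm": s.depth,
                        "material": material,
                        "fraction_pct": frac,
                        "pixels": s.counts[material],
                        "policy": s.policy,
                    }
                )
        return rows


def penetration_profile(
    volume: CTVolume,
    table: MaterialTable,
    plane: TrayPlane,
    depth_max: float = 10.0,
    step: float = 0.8,
    *,
    policy: str = "total",
    n_subslices: int = 4,
    mantle_floor_pct: float = 5.0,
) -> PenetrationProfile:
    """Depth-resolved material fractions in slabs parallel to the tray.

    Each ``step``-thick slab is measured as the pooled classification of
    ``n_subslices`` thin sample slices spread across the slab (classify
    first, then pool counts): pooling HU across the slab before
    classification would mix materials at interfaces into HU values that
    belong to no range, biasing the fractions down.
    """
    if step <= 0:
        raise ValidationError("step must be > 0")
    if depth_max < step:
        raise ValidationError("depth_max must be >= step")
    n_bins = int(math.floor(depth_max / step + 1e-9))
    reports: list[SliceFractionReport] = []
    for k in range(n_bins):
        centre = (k + 0.5) * step
        counts: dict[str, int] = {}
        pixel_area = None
        for j in range(n_subslices):
            off = ((j + 0.5) / n_subslices - 0.5) * step
            d = centre + off
            try:
                slc = extract_slice(
                    volume,
                    plane.point + d * plane.normal,
                    plane.normal,
                    thickness=step / n_subslices,
                    depth=d,
                    n_samples=1,
                )
                rep = slice_fractions(slc, table, policy=policy)
            except ValidationError as err:
                raise ValidationError(f"at depth {d:.2f} mm: {err}") from err
            for m, c in rep.counts.items():
                counts[m] = counts.get(m, 0) + c
            pixel_area = rep.pixel_area_mm2
        reports.append(
            SliceFractionReport(
                depth=centre,
                counts=counts,
                pixel_area_mm2=pixel_area / n_subslices,
                policy=policy,
            )
        )
    return PenetrationProfile(
        slices=reports, step_mm=step, policy=policy, mantle_floor_pct=mantle_floor_pct
    )
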