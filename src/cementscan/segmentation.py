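"""Per-pixel material classification and planar area fractions.

Every pixel/voxel is assigned the matching material range of highest
priority (smallest priority number); values matching no range stay
unclassified.  Area fractions on a planar slice are reported as a
percentage of the total scanned surface — by default *including*
prosthesis-metal pixels in the denominator, which is the convention the
measurement was validated with (the metal occupies a nearly constant share
of the cross-section over the clinically relevant depths).  An
``exclude-metal`` denominator is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .imaging_model import PlanarSlice
from .roi_ranges import PROSTHESIS, UNCLASSIFIED, MaterialTable

__all__ = [
    "UNCLASSIFIED_LABEL",
    "LabelMap",
    "SliceFractionReport",
    "classify",
    "slice_fractions",
]

#: Integer code for pixels matching no material range.
UNCLASSIFIED_LABEL = 0

#: Integer code for pixels outside the scanned volume (NaN HU).
OUTSIDE_LABEL = -1

DENOMINATOR_POLICIES = ("total", "exclude-metal")


@dataclass
class LabelMap:
    """Material labels for a 2-D or 3-D HU array.

    ``labels[i] == k`` means material ``table.materials[k-1]``; 0 means
    unclassified, -1 means outside the scanned volume.
    """

    labels: np.ndarray
    table: MaterialTable

    @property
    def names(self) -> list[str]:
        """Label-code to name mapping: index 0 is unclassified."""
        return [UNCLASSIFIED] + self.table.materials

    def code_of(self, material: str) -> int:
        if material == UNCLASSIFIED:
            return UNCLASSIFIED_LABEL
        return self.table.materials.index(material) + 1

    def mask(self, material: str) -> np.ndarray:
        return self.labels == self.code_of(material)


@dataclass
class SliceFractionReport:
    """Per-material area fractions of one planar slice.

    Fractions are percentages of the denominator implied by ``policy``;
    ``counts`` always holds raw in-volume pixel counts per material
    (including ``unclassified``).
    """

    depth: float
    counts: dict[str, int]
    pixel_area_mm2: float
    policy: str = "total"

    def __post_init__(self) -> None:
        if self.policy not in DENOMINATOR_POLICIES:
            raise ValidationError(f"unknown denominator policy {self.policy!r}")

    @property
    def n_pixels(self) -> int:
        """In-volume pixels on the slice (the total scanned surface)."""
        return int(sum(self.counts.values()))

    @property
    def denominator(self) -> int:
        n = self.n_pixels
        if self.policy == "exclude-metal":
            n -= self.counts.get(PROSTHESIS, 0)
        return n

    @property
    def area_mm2(self) -> float:
        return self.n_pixels * self.pixel_area_mm2

    def fraction(self, material: str) -> float:
        """Area percentage of ``material`` under this report's policy."""
        den = self.denominator
        if den == 0:
            raise ValidationError("zero denominator: no pixels to measure against")
        return 100.0 * self.counts.get(material, 0) / den

    @property
    def fractions(self) -> dict[str, float]:
        return {m: self.fraction(m) for m in self.counts}


def classify(values, table: MaterialTable) -> LabelMap:
    """Label each element with its highest-priority matching material range.

    ``values`` may be an HU array, a CTVolume or a PlanarSlice.  NaN
    elements (outside-volume padding) get the OUTSIDE label and take part
    in no denominator.
    """
    arr = getattr(values, "voxels", getattr(values, "pixels", values))
    arr = np.asarray(arr, dtype=float)
    labels = np.full(arr.shape, UNCLASSIFIED_LABEL, dtype=np.int16)
    # Apply least-important ranges first so higher priorities overwrite.
    for rng in table.by_priority():
        labels[rng.contains(arr)] = table.materials.index(rng.material) + 1
    labels[~np.isfinite(arr)] = OUTSIDE_LABEL
    return LabelMap(labels=labels, table=table)


def slice_fractions(
    slc: PlanarSlice, table: MaterialTable, policy: str = "total"
) -> SliceFractionReport:
    """Material area fractions of a planar slice as % of the scanned surface."""
    if policy not in DENOMINATOR_POLICIES:
        raise ValidationError(f"unknown denominator policy {policy!r}")
    lm = classify(slc, table)
    counts = {UNCLASSIFIED: int(np.sum(lm.labels == UNCLASSIFIED_LABEL))}
    for m in table.materials:
        counts[m] = int(np.sum(lm.mask(m)))
    report = SliceFractionReport(
        depth=slc.depth,
        counts=counts,
        pixel_area_mm2=float(slc.pixel_spacing[0] * slc.pixel_spacing[1]),
        policy=policy,
    )
    if report.denominator == 0:
        raise ValidationError("zero denominator: slice has no measurable pixels")
    return report


def label_map_to_png(lm: LabelMap, path, palette: dict[str, tuple[int, int, int]] | None = None) -> None:
    """Export a 2-D label map as a paletted PNG."""
    from PIL import Image

    if lm.labels.ndim != 2:
        raise ValidationError("only 2-D label maps can be exported as PNG")
    default = {
        UNCLASSIFIED: (40, 40, 40),
        "trabecular_bone": (178, 102, 66),
        "penetrated_cement": (240, 240, 225),
        "cortical_bone": (220, 200, 160),
        "prosthesis": (120, 130, 150),
    }
    palette = {**default, **(palette or {})}
    rgb = np.zeros(lm.labels.shape + (3,), dtype=np.uint8)
    for code, name in enumerate(lm.names):
        rgb[lm.labels == code] = palette.get(name, (255, 0, 255))
    Image.fromarray(rgb).save(path)
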