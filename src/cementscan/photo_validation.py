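"""Optical validation arm: colour-range cement fractions on photographs.

The CT measurement is validated against photographs of physically sawed
cross-sections: the cement's colour range is marked on the photograph and
the matching pixels are counted as a percentage of the slice, exactly
mirroring the CT-side area-fraction computation.  Correspondence between a
photograph and a CT slab is established by a tantalum bead fiducial placed
at known depth: the physical cut runs just above the bead, so the matching
CT slab is the one containing (bead depth - bead radius).

Colour similarity is Euclidean distance in raw 8-bit RGB around one or
more seed colours with a configurable tolerance — a simple, reproducible
analogue of interactive colour-range selection tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import EmptyRegionError, ValidationError
from .penetration import BeadFiducial, PenetrationProfile

__all__ = [
    "Photograph",
    "ColorRangeSpec",
    "ValidationPair",
    "photo_cement_fraction",
    "pair_with_ct",
    "read_photograph",
]


@dataclass
class Photograph:
    """An 8-bit RGB photograph of a sawed cross-section."""

    pixels: np.ndarray
    scale_mm_per_px: float | None = None
    identifier: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[-1] != 3 or self.pixels.size == 0:
            raise ValidationError("photograph must be a non-empty HxWx3 RGB array")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValidationError("RGB channel values must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)


@dataclass(frozen=True)
class ColorRangeSpec:
    """Seed colour(s) and Euclidean RGB tolerance defining 'cement-coloured'."""

    seed_rgb: tuple[int, int, int]
    tolerance: float = 0.0
    extra_seeds: tuple[tuple[int, int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.tolerance < 0:
            raise ValidationError("colour tolerance must be >= 0")

    @property
    def seeds(self) -> np.ndarray:
        return np.asarray((self.seed_rgb,) + tuple(self.extra_seeds), dtype=float)


@dataclass(frozen=True)
class ValidationPair:
    """One photograph/CT comparison row.

    Holds the photograph's cement percentage, the CT percentage in the
    corresponding slab, and the CT percentage one slab (0.8 mm) deeper —
    the deeper slab brackets the physical cut from below, so together the
    two CT values bound the expected optical percentage.
    """

    photo_pct: float
    ct_pct: float
    ct_next_pct: float | None
    depth_mm: float
    source: str = "bead"

    def __post_init__(self) -> None:
        for v in (self.photo_pct, self.ct_pct):
            if not 0 <= v <= 100:
                raise ValidationError("percentages must lie in [0, 100]")
        if self.ct_next_pct is not None and not 0 <= self.ct_next_pct <= 100:
            raise ValidationError("percentages must lie in [0, 100]")


def photo_cement_fraction(
    photo: Photograph, spec: ColorRangeSpec, region_mask: np.ndarray | None = None
) -> float:
    """Percentage of pixels within colour tolerance of any seed colour.

    ``region_mask`` restricts both numerator and denominator to a region
    (e.g. the cut surface outline); by default the whole image counts.
    """
    rgb = photo.pixels.astype(float)
    if region_mask is not None:
        region_mask = np.asarray(region_mask, dtype=bool)
        if region_mask.shape != rgb.shape[:2]:
            raise ValidationError("region mask shape does not match the photograph")
        if not np.any(region_mask):
            raise EmptyRegionError("region mask selects no pixels")
    dist2 = ((rgb[..., None, :] - spec.seeds) ** 2).sum(axis=-1)
    within = np.any(dist2 <= spec.tolerance**2, axis=-1)
    if region_mask is not None:
        within = within[region_mask]
        total = int(region_mask.sum())
    else:
        within = within.ravel()
        total = within.size
    return 100.0 * int(within.sum()) / total


def pair_with_ct(
    profile: PenetrationProfile,
    beads: list[BeadFiducial] | None,
    photo_pct: float,
    *,
    manual_depth_mm: float | None = None,
) -> ValidationPair:
    """Match a photograph percentage with its corresponding CT slab.

    The cut surface lies just above the bead, so the corresponding slab is
    the one containing (bead depth - bead radius).  With several beads the
    shallowest defines the correspondence; ``manual_depth_mm`` overrides
    beads entirely (a depth on a slab boundary goes to the deeper slab).
    """
    if manual_depth_mm is not None:
        depth = manual_depth_mm
        source = "manual"
    else:
        if not beads:
            raise ValidationError("need at least one bead or a manual depth")
        bead = min(beads, key=lambda b: b.depth_mm)
        depth = bead.depth_mm - bead.diameter_mm / 2.0
        source = "bead"
    k = profile.bin_index(depth)
    fractions = profile.cement_fractions
    ct_next = float(fractions[k + 1]) if k + 1 < len(fractions) else None
    return ValidationPair(
        photo_pct=photo_pct,
        ct_pct=float(fractions[k]),
        ct_next_pct=ct_next,
        depth_mm=depth,
        source=source,
    )


def read_photograph(path, identifier: str | None = None) -> Photograph:
    """Read a PNG/TIFF photograph as 8-bit RGB."""
    from PIL import Image

    path = Path(path)
    img = Image.open(path).convert("RGB")
    return Photograph(pixels=np.asarray(img), identifier=identifier or path.stem)
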