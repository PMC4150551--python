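"""ROI HU statistics, aggregation and material HU-range derivation.

The measurement technique rests on first-order HU statistics of selected
regions: the mean HU of a region and its within-region standard deviation,
called the *homogeneity value* (a uniformity/texture measure — cement
filling the inter-trabecular space both raises the mean and lowers the SD).
Replicate ROIs are aggregated, and an automatic-marking HU range for a
material is derived as

    mean HU  +/-  (2 * mean homogeneity + SD of homogeneity)

The shipped default :class:`MaterialTable` contains the validated ranges
for trabecular bone, cement-penetrated trabecular bone, cortical bone and
prosthesis metal.  Note that the default ranges are the validated table as
published, not the output of :func:`derive_range` on the published summary
statistics: the two are known not to coincide (the ROI inputs behind the
validated table were not published), so the table is shipped verbatim and
the derivation formula is provided for user-measured ROIs.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._utils import round_half_up
from .errors import EmptyRegionError, ValidationError

__all__ = [
    "RoiStats",
    "AggregateStats",
    "MaterialRange",
    "MaterialTable",
    "roi_statistics",
    "aggregate",
    "derive_range",
    "check_overlap",
    "default_material_table",
]


@dataclass(frozen=True)
class RoiStats:
    """Mean HU and homogeneity value (sample SD of HU) of one ROI."""

    mean_hu: float
    homogeneity: float
    n_voxels: int | None = None

    def __post_init__(self) -> None:
        if self.homogeneity < 0:
            raise ValidationError("homogeneity (an SD) must be >= 0")


@dataclass(frozen=True)
class AggregateStats:
    """Mean/SD over replicate ROI means and homogeneities."""

    mean_of_means: float
    sd_of_means: float
    mean_homogeneity: float
    sd_of_homogeneity: float
    n_rois: int

    def rounded(self) -> tuple[int, int, int, int]:
        """Integer-HU rendering (half-up) for comparison with printed tables."""
        return (
            int(round_half_up(self.mean_of_means)),
            int(round_half_up(self.sd_of_means)),
            int(round_half_up(self.mean_homogeneity)),
            int(round_half_up(self.sd_of_homogeneity)),
        )


@dataclass(frozen=True)
class MaterialRange:
    """A named HU interval with a classification priority.

    Bounds are closed unless open: ``high=None`` means unbounded above and
    then ``low`` is an exclusive bound (the "> threshold" reading used for
    prosthesis metal).  Smaller ``priority`` wins on overlap.
    """

    material: str
    low: float
    high: float | None
    priority: int

    def __post_init__(self) -> None:
        if self.high is not None and not self.low <= self.high:
            raise ValidationError(f"range for {self.material!r}: low must be <= high")

    @property
    def low_exclusive(self) -> bool:
        return self.high is None

    def contains(self, values) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.high is None:
            return values > self.low
        return (values >= self.low) & (values <= self.high)

    def intersection(self, other: "MaterialRange") -> tuple[float, float] | None:
        """Closed-interval overlap with another range, or None.

        Open-above ranges are treated as ``(low, inf)``; a shared single
        endpoint counts as overlap only if both ranges include it.
        """
        a_lo, a_hi = self.low, math.inf if self.high is None else self.high
        b_lo, b_hi = other.low, math.inf if other.high is None else other.high
        lo, hi = max(a_lo, b_lo), min(a_hi, b_hi)
        if lo > hi:
            return None
        if lo == hi:
            if (self.high is None and lo == self.low) or (other.high is None and lo == other.low):
                return None  # exclusive lower bound: endpoint not shared
        return (lo, hi)


@dataclass
class MaterialTable:
    """Ordered collection of material HU ranges."""

    ranges: list[MaterialRange] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.ranges:
            raise ValidationError("material table must be non-empty")
        names = [r.material for r in self.ranges]
        if len(set(names)) != len(names):
            raise ValidationError("material names must be unique")
        prios = [r.priority for r in self.ranges]
        if len(set(prios)) != len(prios):
            raise ValidationError("priorities must be unique within a table")

    def __iter__(self):
        return iter(self.ranges)

    def __len__(self) -> int:
        return len(self.ranges)

    def __getitem__(self, material: str) -> MaterialRange:
        for r in self.ranges:
            if r.material == material:
                return r
        raise KeyError(material)

    @property
    def materials(self) -> list[str]:
        return [r.material for r in self.ranges]

    def by_priority(self) -> list[MaterialRange]:
        """Ranges sorted from least to most important (largest priority first)."""
        return sorted(self.ranges, key=lambda r: -r.priority)

    def subset(self, materials) -> "MaterialTable":
        materials = set(materials)
        return MaterialTable([r for r in self.ranges if r.material in materials])

    # -- serialisation -----------------------------------------------------

    def to_json(self, path) -> None:
        rows = [
            {"material": r.material, "low": r.low, "high": r.high, "priority": r.priority}
            for r in self.ranges
        ]
        Path(path).write_text(json.dumps(rows, indent=2))

    @classmethod
    def from_json(cls, path) -> "MaterialTable":
        rows = json.loads(Path(path).read_text())
        return cls([MaterialRange(r["material"], r["low"], r.get("high"), r["priority"]) for r in rows])

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["material", "low", "high", "priority"])
            for r in self.ranges:
                w.writerow([r.material, r.low, "" if r.high is None else r.high, r.priority])

    @classmethod
    def from_csv(cls, path) -> "MaterialTable":
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
        return cls([
            MaterialRange(
                r["material"], float(r["low"]),
                None if r["high"] in ("", None, "null") else float(r["high"]),
                int(r["priority"]),
            )
            for r in rows
        ])


#: Materials of the shipped default table.
TRABECULAR = "trabecular_bone"
PENETRATED = "penetrated_cement"
CORTICAL = "cortical_bone"
PROSTHESIS = "prosthesis"
UNCLASSIFIED = "unclassified"


def default_material_table() -> MaterialTable:
    """The shipped, validated HU ranges for automatic ROI marking.

    Priorities encode: prosthesis metal always wins (so it can be masked);
    penetrated cement beats cortical bone on their overlap [1386, 1706]
    (the measurement target; the cortical rim contributes a small,
    depth-constant bias accepted by the method); trabecular bone last.
    """
    return MaterialTable([
        MaterialRange(PROSTHESIS, 2475, None, priority=1),
        MaterialRange(PENETRATED, 1062, 1706, priority=2),
        MaterialRange(CORTICAL, 1386, 1864, priority=3),
        MaterialRange(TRABECULAR, -192, 516, priority=4),
    ])


def roi_statistics(values, roi_mask=None) -> RoiStats:
    """Mean HU and homogeneity value (sample SD, n-1) of a region.

    ``values`` may be a raw HU array, a :class:`~cementscan.imaging_model.CTVolume`
    or a :class:`~cementscan.imaging_model.PlanarSlice`; ``roi_mask`` is a
    boolean array of the same shape (omit to use everything).  NaN pixels
    (outside-volume padding) are excluded.
    """
    arr = getattr(values, "voxels", getattr(values, "pixels", values))
    arr = np.asarray(arr, dtype=float)
    if roi_mask is None:
        sel = arr.ravel()
    else:
        roi_mask = np.asarray(roi_mask, dtype=bool)
        if roi_mask.shape != arr.shape:
            raise ValidationError("ROI mask shape does not match the data")
        sel = arr[roi_mask]
    sel = sel[np.isfinite(sel)]
    if sel.size < 2:
        raise EmptyRegionError("ROI must select at least 2 voxels")
    return RoiStats(
        mean_hu=float(np.mean(sel)),
        homogeneity=float(np.std(sel, ddof=1)),
        n_voxels=int(sel.size),
    )


def aggregate(rois) -> AggregateStats:
    """Mean and sample SD over replicate ROI means and homogeneities."""
    rois = list(rois)
    if len(rois) < 2:
        raise EmptyRegionError("need at least 2 ROIs to aggregate")
    means = np.array([r.mean_hu for r in rois], dtype=float)
    homs = np.array([r.homogeneity for r in rois], dtype=float)
    return AggregateStats(
        mean_of_means=float(np.mean(means)),
        sd_of_means=float(np.std(means, ddof=1)),
        mean_homogeneity=float(np.mean(homs)),
        sd_of_homogeneity=float(np.std(homs, ddof=1)),
        n_rois=len(rois),
    )


def derive_range(
    agg: AggregateStats, material: str = "material", priority: int = 0
) -> MaterialRange:
    """HU range for automatic marking from aggregated ROI statistics.

    half-width = 2 * mean homogeneity + SD of homogeneity;
    range = mean of means +/- half-width.
    """
    half_width = 2.0 * agg.mean_homogeneity + agg.sd_of_homogeneity
    return MaterialRange(
        material, agg.mean_of_means - half_width, agg.mean_of_means + half_width, priority
    )


def check_overlap(table: MaterialTable) -> list[tuple[str, str, tuple[float, float]]]:
    """All pairs of ranges with non-empty intersection, with the overlap interval."""
    out = []
    for i, a in enumerate(table.ranges):
        for b in table.ranges[i + 1:]:
            inter = a.intersection(b)
            if inter is not None:
                out.append((a.material, b.material, inter))
    return out
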