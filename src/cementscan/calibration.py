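"""HU-calibration QC against a water/teflon/nylon phantom.

A scanner's HU scale is anchored at water = 0 HU; periodic QC scans a
phantom with compartments of known materials and checks that each
compartment's mean HU sits within tolerance of its expected value and that
each compartment is uniform (within-compartment SD below a limit).  When
the water anchor drifts, the report suggests the additive offset that
restores it; a single-point water anchor cannot constrain the scale slope,
so only an intercept correction is ever proposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyRegionError, ValidationError
from .imaging_model import CTVolume

__all__ = ["CalibrationCriteria", "CompartmentResult", "CalibrationReport", "check_calibration"]


@dataclass(frozen=True)
class CalibrationCriteria:
    """Expected compartment HU, tolerances and uniformity limit.

    Defaults are conventional QC ballpark values and fully overridable:
    water 0 +/- 4 HU, teflon 990 +/- 30 HU, nylon 100 +/- 30 HU,
    within-compartment SD limit 15 HU.
    """

    expected_hu: dict = field(
        default_factory=lambda: {"water": 0.0, "teflon": 990.0, "nylon": 100.0}
    )
    tolerance_hu: dict = field(
        default_factory=lambda: {"water": 4.0, "teflon": 30.0, "nylon": 30.0}
    )
    uniformity_limit_hu: float = 15.0

    def __post_init__(self) -> None:
        if self.uniformity_limit_hu <= 0:
            raise ValidationError("uniformity limit must be > 0")
        for name, tol in self.tolerance_hu.items():
            if tol <= 0:
                raise ValidationError(f"tolerance for {name!r} must be > 0")


@dataclass(frozen=True)
class CompartmentResult:
    material: str
    mean_hu: float
    sd_hu: float
    mean_pass: bool
    uniformity_pass: bool

    @property
    def passed(self) -> bool:
        return self.mean_pass and self.uniformity_pass


@dataclass(frozen=True)
class CalibrationReport:
    """Per-compartment results plus the suggested additive HU offset.

    The offset is the negated measured water mean when the water mean test
    fails, else 0; applying it to the volume and re-checking makes the
    water mean test pass.
    """

    compartments: dict[str, CompartmentResult]
    suggested_offset_hu: float

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.compartments.values())

    def to_dict(self) -> dict:
        return {
            "passed": self.passed,
            "suggested_offset_hu": self.suggested_offset_hu,
            "compartments": {
                k: {
                    "mean_hu": c.mean_hu,
                    "sd_hu": c.sd_hu,
                    "mean_pass": c.mean_pass,
                    "uniformity_pass": c.uniformity_pass,
                }
                for k, c in self.compartments.items()
            },
        }


def check_calibration(
    volume: CTVolume,
    compartment_masks: dict[str, np.ndarray],
    criteria: CalibrationCriteria | None = None,
) -> CalibrationReport:
    """QC-check a calibration phantom scan.

    ``compartment_masks`` maps material name -> boolean voxel mask.  Each
    compartment passes iff |mean - expected| <= tolerance and sample SD <=
    the uniformity limit.
    """
    criteria = criteria or CalibrationCriteria()
    results: dict[str, CompartmentResult] = {}
    occupied = np.zeros(volume.shape, dtype=bool)
    for name, expected in criteria.expected_hu.items():
        mask = compartment_masks.get(name)
        if mask is None or not np.any(mask):
            raise EmptyRegionError(f"compartment mask {name!r} is missing or empty")
        mask = np.asarray(mask, dtype=bool)
        if np.any(mask & occupied):
            raise ValidationError(f"compartment mask {name!r} overlaps another compartment")
        occupied |= mask
        vals = volume.voxels[mask]
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        results[name] = CompartmentResult(
            material=name,
            mean_hu=mean,
            sd_hu=sd,
            mean_pass=abs(mean - expected) <= criteria.tolerance_hu[name],
            uniformity_pass=sd <= criteria.uniformity_limit_hu,
        )
    water = results.get("water")
    offset = -water.mean_hu if (water is not None and not water.mean_pass) else 0.0
    return CalibrationReport(compartments=results, suggested_offset_hu=offset)
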