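"""Reference per-ROI and per-slice measurements from the cadaver validation study.

These are the printed per-row values behind the study's summary tables,
packaged so that every reported "Mean (SD)" cell and the range-overlap
analysis can be recomputed from first principles (``cementscan
reproduce-tables``).  Units: HU for ROI values, percent of the transversal
slice surface for the penetration percentages.

``PROSTHESIS_INFLUENCE`` holds (mean HU, homogeneity value) pairs of
replicate ROIs measured on the same specimen with a removable prosthesis
in situ, after its removal, and on a second specimen with the prosthesis
attached — the dataset behind the finding that the metal tray does not
significantly perturb nearby HU measurements.

``PENETRATION_PCT`` holds the optical-vs-CT validation percentages for two
sawed slices: the photograph measurement, the corresponding CT slab
(matched via the tantalum bead), and the CT slab 0.8 mm deeper.

``SUMMARY_ROI_STATS`` holds the published aggregate (mean, SD of means,
mean homogeneity, SD of homogeneity, in HU) per material, used as inputs
to the range-derivation formula.
"""

from __future__ import annotations

from .roi_ranges import AggregateStats, RoiStats

__all__ = [
    "PROSTHESIS_INFLUENCE",
    "PROSTHESIS_INFLUENCE_EXPECTED",
    "PENETRATION_PCT",
    "PENETRATION_PCT_EXPECTED",
    "SUMMARY_ROI_STATS",
]

_RAW = {
    "removable_prosthesis": [
        (1377, 77), (1423, 81), (1455, 82),
        (1299, 122), (1367, 125), (1262, 133),
        (1366, 109), (1372, 80), (1436, 116),
        (1304, 82), (1377, 93), (1534, 75),
        (1413, 107), (1315, 120), (1568, 72),
    ],
    "without_prosthesis": [
        (1424, 64), (1350, 97), (1334, 76),
        (1395, 65), (1349, 89), (1421, 59),
        (1405, 39), (1400, 89), (1386, 72),
        (1428, 116), (1478, 96), (1335, 97),
        (1406, 66), (1340, 63), (1422, 69),
    ],
    "attached_prosthesis": [
        (1422, 129), (1296, 81), (1402, 91),
        (1431, 144), (1433, 161), (1338, 53),
        (1534, 102), (1497, 104), (1352, 56),
        (1436, 143), (1518, 120),
        (1479, 159), (1495, 160),
    ],
}

#: Replicate ROI measurements (mean HU, homogeneity value) per measurement arm.
PROSTHESIS_INFLUENCE: dict[str, list[RoiStats]] = {
    arm: [RoiStats(mean_hu=hu, homogeneity=hom) for hu, hom in rows]
    for arm, rows in _RAW.items()
}

#: Published rounded aggregates per arm:
#: (mean of means, SD of means, mean homogeneity, SD of homogeneity), integer HU.
PROSTHESIS_INFLUENCE_EXPECTED: dict[str, tuple[int, int, int, int]] = {
    "removable_prosthesis": (1391, 84, 98, 21),
    "without_prosthesis": (1392, 42, 77, 20),
    "attached_prosthesis": (1433, 72, 116, 38),
}

#: Optical-vs-CT penetration percentages for the two sawed validation slices.
PENETRATION_PCT: dict[str, list[float]] = {
    "photographs": [35.4, 31.3],
    "corresponding_ct": [39.7, 34.7],
    "ct_one_slice_deeper": [34.8, 30.7],
}

#: Published rounded (mean, SD) per column.
PENETRATION_PCT_EXPECTED: dict[str, tuple[float, float]] = {
    "photographs": (33.35, 2.9),
    "corresponding_ct": (37.2, 3.5),
    "ct_one_slice_deeper": (32.75, 2.9),
}

#: Published aggregate ROI statistics per material (full columns were not
#: published for these; only the aggregates are available as range-formula
#: inputs).  n_rois reflects the number of selected areas where stated.
SUMMARY_ROI_STATS: dict[str, AggregateStats] = {
    "trabecular_transversal": AggregateStats(163.0, 12.0, 152.0, 14.0, n_rois=4),
    "trabecular_coronal": AggregateStats(162.0, 24.0, 123.0, 16.0, n_rois=4),
    "pure_cement": AggregateStats(1328.0, 27.0, 66.0, 12.0, n_rois=3),
    "penetrated_cement": AggregateStats(1363.0, 30.0, 71.0, 17.0, n_rois=3),
    "beneath_tray": AggregateStats(1384.0, 53.0, 81.0, 30.0, n_rois=3),
}
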