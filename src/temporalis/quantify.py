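"""Bilateral muscle cross-sectional-area (CSA) quantification.

A predicted temporalis mask normally contains two blobs, one per side of
the head.  :func:`split_bilateral` labels 8-connected components, discards
specks below a minimum area, keeps the two largest and assigns them to the
left/right of the *image* by centroid column versus the image's central
column (the patient-side interpretation under the radiological display
convention is documented in :mod:`temporalis.imaging_io`).

CSA per side is the foreground pixel count times the physical pixel area
(row_spacing × col_spacing mm²); the per-patient value is the mean of the
two sides.  Degenerate masks — a single component, or two components on
the same side — are quantified anyway and flagged rather than rejected, so
surgically disrupted or mis-segmented cases surface in the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .imaging_io import BinaryMask

DEFAULT_MIN_COMPONENT_AREA_MM2 = 10.0


@dataclass
class BilateralCSA:
    left_mm2: float
    right_mm2: float
    mean_mm2: float
    n_components_found: int
    flags: list[str] = field(default_factory=list)


def split_bilateral(
    mask: BinaryMask, min_area_mm2: float = DEFAULT_MIN_COMPONENT_AREA_MM2
) -> tuple[BinaryMask, BinaryMask, list[str]]:
    """Split a mask into (left, right) single-muscle masks plus warning flags."""
    labels = measure.label(mask.labels, connectivity=2)
    px_area = mask.pixel_area_mm2
    props = [p for p in measure.regionprops(labels) if p.area * px_area >= min_area_mm2]
    if not props:
        raise ValueError(
            f"no component with area >= {min_area_mm2} mm² found in the mask"
        )
    flags: list[str] = []
    props.sort(key=lambda p: p.area, reverse=True)
    if len(props) > 2:
        flags.append(f"extra_components_discarded:{len(props) - 2}")
    keep = props[:2]

    midline = mask.shape[1] / 2.0
    empty = np.zeros(mask.shape, dtype=np.uint8)
    left = empty.copy()
    right = empty.copy()
    if len(keep) == 1:
        comp = keep[0]
        side = left if comp.centroid[1] < midline else right
        side[labels == comp.label] = 1
        flags.append("single_component")
    else:
        a, b = keep
        ca, cb = a.centroid[1], b.centroid[1]
        if (ca < midline) == (cb < midline):
            flags.append("both_components_same_side")
            # fall back to relative order: the more-left centroid is "left"
        first_left = ca <= cb
        left[labels == (a.label if first_left else b.label)] = 1
        right[labels == (b.label if first_left else a.label)] = 1
    return (
        BinaryMask(labels=left, spacing=mask.spacing),
        BinaryMask(labels=right, spacing=mask.spacing),
        flags,
    )


def quantify_patient(
    mask: BinaryMask, min_area_mm2: float = DEFAULT_MIN_COMPONENT_AREA_MM2
) -> BilateralCSA:
    """Left/right/mean CSA in mm² from a bilateral muscle mask."""
    left, right, flags = split_bilateral(mask, min_area_mm2)
    px_area = mask.pixel_area_mm2
    left_mm2 = float(left.labels.sum()) * px_area
    right_mm2 = float(right.labels.sum()) * px_area
    n = int(left.labels.any()) + int(right.labels.any())
    return BilateralCSA(
        left_mm2=left_mm2,
        right_mm2=right_mm2,
        mean_mm2=(left_mm2 + right_mm2) / 2.0,
        n_components_found=n,
        flags=flags,
    )
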